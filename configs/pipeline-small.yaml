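# Pipeline settings for the bundled reduced-size synthetic study.
b_net: 10
b_assoc: 499
m_perm: 199
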