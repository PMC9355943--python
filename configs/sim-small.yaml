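# Reduced-size synthetic study for quick end-to-end runs (1,000 cells).
cells_per_donor: 100
seed: 0
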