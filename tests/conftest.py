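import numpy as np
import pytest

from coexmod import (PipelineConfig, SimConfig, normalize_log, qc_filter_cells,
                     scale_within_batch, simulate_sc_dataset)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition single-cell dataset (1 cell type, 2,000 cells)."""
    cfg = SimConfig(seed=1)
    sc, truth = simulate_sc_dataset(cfg)
    return cfg, sc, truth


@pytest.fixture(scope="session")
def default_scaled(default_sim):
    """QC'd, log-normalised, per-donor scaled version of the default dataset."""
    _, sc, truth = default_sim
    qc = qc_filter_cells(sc)
    logn = normalize_log(qc)
    scaled = scale_within_batch(logn, logn.obs_meta["donor"].to_numpy())
    return scaled, logn, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def pipe_cfg():
    return PipelineConfig()
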