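import numpy as np
import pytest

from cavprox import proteomics, synthdata


@pytest.fixture(scope="session")
def small_experiment():
    """400-protein synthetic LFQ experiment with planted classes."""
    cfg = synthdata.SynthProteomeConfig(n_proteins=400, seed=11)
    table, truth = synthdata.simulate_lfq_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_logmat(small_experiment):
    _, table, _ = small_experiment
    logmat = proteomics.log2_transform(proteomics.remove_flagged_rows(table))
    return proteomics.replicate_presence_filter(logmat)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
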