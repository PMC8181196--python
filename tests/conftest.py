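import numpy as np
import pytest

from lnc6 import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small but well-separated K=6 cohort shared by read-only tests."""
    cfg = synthetic.CohortConfig(
        n_samples=120,
        n_lnc_genes=600,
        n_mrna_genes=600,
        n_marker_genes_per_subtype=80,
        effect_size=4.0,
        noise_sd=1.0,
        seed=42,
    )
    lnc, mrna, labels = synthetic.generate_training_cohort(cfg)
    return cfg, lnc, mrna, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
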