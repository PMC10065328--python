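import numpy as np
import pytest

from epiblup import PredictorPanel, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_panel(rng, n=10, p=8, kind="snp"):
    """Random polymorphic binary panel (resamples monomorphic columns)."""
    m = (rng.random((n, p)) < rng.uniform(0.2, 0.8, size=p)).astype(np.uint8)
    for j in range(p):
        while m[:, j].min() == m[:, j].max():
            m[:, j] = (rng.random(n) < 0.5).astype(np.uint8)
    return PredictorPanel(
        line_ids=[f"L{i:03d}" for i in range(n)],
        predictor_ids=[f"p{j}" for j in range(p)],
        kind=kind,
        matrix=m,
    )


@pytest.fixture
def small_panel(rng):
    return random_panel(rng, n=10, p=8)


@pytest.fixture(scope="session")
def additive_dataset():
    """Mid-size purely additive two-year dataset shared across tests."""
    cfg = SimConfig(
        n_lines=200, p_snps=200, n_regions=20, n_add_qtl=60,
        n_epi_pairs=0, epi_var_fraction=0.0,
        h2_year1=0.7, h2_year2=0.6, r_g_target=0.9, seed=101,
    )
    return simulate_dataset(cfg)
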