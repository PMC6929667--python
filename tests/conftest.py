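import numpy as np
import pytest

import painconn as pc


@pytest.fixture(scope="session")
def small_cohort():
    """Fast effect-bearing cohort shared by read-only tests."""
    edges = pc.choose_affected_edges(10, 0.2, seed=5)
    cfg = pc.CohortConfig(n_subjects=30, n_regions=10, n_timepoints=80,
                          affected_edges=edges, base_coupling=0.4,
                          corr_effect=0.4, artifact_rate=0.0, seed=11)
    return cfg, pc.generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ar1(rng, n, phi=0.9, standardize=True):
    """Reference AR(1) draw used to build domain-like test series."""
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + np.sqrt(1 - phi * phi) * e[t]
    if standardize:
        x = (x - x.mean()) / x.std()
    return x
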