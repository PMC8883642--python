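import numpy as np
import pandas as pd
import pytest

from hypervar import mvc, synthesis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_sim():
    """The standard evaluation setting: n=20000, m=10, d0=5, gamma=1.2,
    5% HVRs at 4x variance enriched at high intensities."""
    cfg = synthesis.SimulationConfig(seed=20220228)
    x, truth = synthesis.simulate_normalized(cfg)
    return cfg, x, truth


@pytest.fixture(scope="session")
def standard_tables(standard_sim):
    """Mean-variance table of the standard simulation scaled by the true
    generating curve."""
    cfg, x, truth = standard_sim
    curve = mvc.MeanVarianceCurve.from_function(cfg.mvc, *cfg.mu_range)
    table = mvc.scaled_variances(mvc.mean_variance(x), curve)
    return cfg, table, curve, truth


def make_counts(rng, n=200, m=4, lam=40.0):
    k = rng.poisson(lam, size=(n, m))
    ids = [f"chr1:{100 * i}-{100 * (i + 1)}" for i in range(n)]
    return pd.DataFrame(k, index=ids, columns=[f"s{j}" for j in range(m)])
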