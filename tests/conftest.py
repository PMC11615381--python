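import numpy as np
import pytest

from quadassort import MechanismParams, SimulationDesign, TraitSpec, simulate_quads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def binary_trait():
    return TraitSpec("dx", "binary", prevalence=0.0909)


@pytest.fixture(scope="session")
def continuous_trait():
    return TraitSpec("score", "continuous")


@pytest.fixture(scope="session")
def direct_pop_continuous(continuous_trait):
    """Direct assortment m=0.5, r_s=0.4 on a continuous phenotype, 60k quads."""
    params = MechanismParams("direct", m=0.5, r_s=0.4)
    design = SimulationDesign(n_families=60_000, traits=(continuous_trait,), seed=101)
    return simulate_quads(params, design)


@pytest.fixture(scope="session")
def direct_pop_binary(binary_trait):
    """Direct assortment on a binary (9.09% prevalence) diagnosis, 60k quads."""
    params = MechanismParams("direct", m=0.5, r_s=0.4)
    design = SimulationDesign(n_families=60_000, traits=(binary_trait,), seed=102)
    return simulate_quads(params, design)


def bivariate_binary_sample(rng, r, prev1, prev2, n):
    """Dichotomized bivariate-normal pairs: the estimator test-bench draw."""
    from scipy.stats import norm

    L = np.linalg.cholesky([[1.0, r], [r, 1.0]])
    Z = rng.standard_normal((n, 2)) @ L.T
    x = (Z[:, 0] > norm.isf(prev1)).astype(float)
    y = (Z[:, 1] > norm.isf(prev2)).astype(float)
    return x, y
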