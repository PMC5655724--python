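import numpy as np
import pytest

import hospcost as hc
from hospcost.params import HEDONICS, INPUTS, OUTPUTS, TranslogParameters


def random_translog_params(rng: np.random.Generator,
                           years=(2004, 2005),
                           scale: float = 0.05) -> TranslogParameters:
    """A random parameter set satisfying symmetry and price homogeneity."""
    no, ni, nh = len(OUTPUTS), len(INPUTS), len(HEDONICS)
    B = rng.normal(0.0, scale, (no, no))
    B = 0.5 * (B + B.T)
    gamma = rng.uniform(0.5, 1.5, ni)
    gamma /= gamma.sum()
    G = rng.normal(0.0, scale, (ni, ni))
    G = 0.5 * (G + G.T)
    r, s = G.sum(axis=1), G.sum()
    G = G - r[:, None] / ni - r[None, :] / ni + s / ni**2
    G = 0.5 * (G + G.T)
    delta = rng.normal(0.0, scale, (no, ni))
    delta -= delta.mean(axis=1, keepdims=True)
    tau = rng.normal(0.0, scale, ni)
    tau -= tau.mean()
    return TranslogParameters(
        alpha0=rng.normal(0.0, 0.2),
        beta=rng.uniform(0.05, 0.6, no),
        B=B, gamma=gamma, G=G, delta=delta, tau=tau,
        theta=rng.normal(0.0, scale, nh),
        year_effects={int(y): float(rng.normal(0.0, 0.05)) for y in years},
    )


def random_point(rng: np.random.Generator, norm) -> hc.Point:
    """A random evaluation point within a factor ~1.6 of the sample means."""
    return hc.Point(
        y=norm.outputs * np.exp(rng.uniform(-0.5, 0.5, len(OUTPUTS))),
        w=norm.prices * np.exp(rng.uniform(-0.3, 0.3, len(INPUTS))),
        z=norm.hedonics * rng.uniform(0.7, 1.3, len(HEDONICS)),
        year=int(rng.integers(2003, 2012)),
    )


@pytest.fixture(scope="session")
def norm():
    return hc.reference_normalization()


@pytest.fixture(scope="session")
def stage2_params():
    return hc.reference_parameters(stage=2)


@pytest.fixture(scope="session")
def stage1_params():
    return hc.reference_parameters(stage=1)


@pytest.fixture(scope="session")
def truth():
    return hc.ground_truth_parameters()


@pytest.fixture(scope="session")
def small_config():
    """A small panel (fast fits) with full ER coverage."""
    return hc.SimulationConfig(n_hospitals=30, years=range(2003, 2006),
                               er_coverage=1.0)


@pytest.fixture(scope="session")
def small_panel(small_config, truth):
    panel = hc.generate_panel(small_config, seed=11)
    return hc.generate_costs(panel, truth, small_config, seed=12)
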