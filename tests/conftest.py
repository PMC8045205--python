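import numpy as np
import pytest

from cirtdose import DVH, FractionationScheme, LQParameters
from cirtdose import fixtures


@pytest.fixture(scope="session")
def lq_default() -> LQParameters:
    return LQParameters()  # alpha/beta = 3.9 Gy


@pytest.fixture(scope="session")
def curve_16fx():
    return fixtures.curve("16fx")


@pytest.fixture(scope="session")
def default_curves(lq_default):
    return fixtures.default_curves(lq_default)


@pytest.fixture
def scheme():
    return FractionationScheme


def make_linear_dvh(dmax: float = 60.0, total_volume: float = 60.0,
                    n: int = 601) -> DVH:
    """Cumulative DVH falling linearly from (0 Gy, 1) to (dmax, 0)."""
    dose = np.linspace(0.0, dmax, n)
    rel = 1.0 - dose / dmax
    return DVH("rectum", total_volume, dose, rel)


def make_step_dvh(d: float = 30.0, total_volume: float = 50.0) -> DVH:
    """Near-ideal uniform-dose DVH: volume 1 up to dose d, then 0."""
    eps = 1e-9
    return DVH("rectum", total_volume,
               np.array([0.0, d, d + eps]), np.array([1.0, 1.0, 0.0]))


def random_piecewise_dvh(rng: np.random.Generator) -> DVH:
    """Random monotone cumulative DVH with irregular grid, for oracles."""
    n = int(rng.integers(5, 40))
    dose = np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, 4.0, size=n))])
    drops = rng.uniform(0.0, 1.0, size=n)
    rel = np.concatenate([[1.0], 1.0 - np.cumsum(drops) / drops.sum()])
    rel = np.clip(rel, 0.0, 1.0)
    rel = np.minimum.accumulate(rel)
    return DVH("rectum", float(rng.uniform(30, 80)), dose, rel)
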