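import numpy as np
import pytest

from kmgain import DigitizedCurve, SurvivalStepFunction


@pytest.fixture
def simple_curve() -> DigitizedCurve:
    """Sparse 3-point curve: hand-invertible (2 events at 5, 4 at 10 for n=10)."""
    return DigitizedCurve("simple", [0.0, 5.0, 10.0], [1.0, 0.8, 0.4], 10)


@pytest.fixture
def two_drop_step() -> SurvivalStepFunction:
    """Drops at 5 (to 0.8) and 10 (to 0.4); exact RMST at 12 is 9.8."""
    return SurvivalStepFunction(np.array([5.0, 10.0]), np.array([0.8, 0.4]))


def random_step(rng: np.random.Generator, max_drops: int = 12) -> SurvivalStepFunction:
    """A random valid KM-shaped step function for property tests."""
    k = int(rng.integers(1, max_drops + 1))
    times = np.sort(rng.uniform(0.5, 20.0, size=k))
    times = np.unique(np.round(times, 3))
    probs = np.sort(rng.uniform(0.0, 1.0, size=times.size))[::-1]
    probs = np.minimum(probs, 1.0 - 1e-6)
    return SurvivalStepFunction(times, probs)
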