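from __future__ import annotations

import numpy as np
import pytest

from wristfunc import modeling, synthetic
from wristfunc.signals import SignalWindow

#: activities spanning all four types and all three intensities
EIGHT_ACTIVITIES = [
    "COMPUTER WORK",
    "TV WATCHING",
    "LEISURE WALK",
    "RAPID WALK",
    "STRETCHING YOGA",
    "STRENGTH EXERCISE LEG CURL",
    "MOPPING",
    "WASHING DISHES",
]

REDUCED_GRIDS = {
    "boosted_trees": modeling.REDUCED_TREE_GRID,
    "l1_linear": modeling.REDUCED_L1_GRID,
}


def make_window(
    samples: np.ndarray, rate_hz: float = 20.0, **kwargs
) -> SignalWindow:
    samples = np.asarray(samples, dtype=float)
    return SignalWindow(
        subject_id=kwargs.get("subject_id", "S0"),
        activity_name=kwargs.get("activity_name", "LEISURE WALK"),
        window_index=0,
        samples=samples,
        sampling_rate_hz=rate_hz,
        duration_s=samples.shape[0] / rate_hz,
    )


def random_window(
    rng: np.random.Generator, n: int = 200, rate_hz: float = 20.0
) -> SignalWindow:
    base = np.array([0.1, 0.7, 0.7])
    samples = base + 0.3 * rng.standard_normal((n, 3))
    return make_window(samples, rate_hz)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects x 8 activities, 180 s bouts at 50 Hz."""
    config = synthetic.CohortConfig(
        n_lpp=10,
        n_hpp=10,
        seed=11,
        sampling_rate_hz=50.0,
        bout_duration_s=180.0,
        activities=EIGHT_ACTIVITIES,
    )
    return synthetic.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    return synthetic.featurize_cohort(small_cohort)
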