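import numpy as np
import pytest

from swayblocks.cop_data import (
    Cohort,
    Condition,
    Label,
    RawTrajectory,
    Statokinesigram,
    SubjectRecord,
)


@pytest.fixture
def uniform_raw():
    """25 s of CoP motion sampled exactly at 25 Hz."""
    t = np.arange(626) / 25.0
    rng = np.random.default_rng(7)
    x = np.cumsum(rng.normal(0, 0.02, size=626))
    y = np.cumsum(rng.normal(0, 0.03, size=626))
    return RawTrajectory(times=t, x=x, y=y, condition=Condition.EO)


@pytest.fixture
def irregular_raw():
    """25 s sampled irregularly around 34 Hz."""
    rng = np.random.default_rng(3)
    n = 851
    t = np.arange(n) / 34.0 + rng.uniform(-0.012, 0.012, size=n)
    t[0] = abs(t[0])
    x = np.sin(0.4 * t) + rng.normal(0, 0.01, size=n)
    y = np.cos(0.3 * t) + rng.normal(0, 0.01, size=n)
    return RawTrajectory(times=t, x=x, y=y, condition=Condition.EC)


@pytest.fixture
def stato():
    """A 20-s statokinesigram at 25 Hz (500 samples)."""
    rng = np.random.default_rng(5)
    x = np.cumsum(rng.normal(0, 0.02, size=500))
    y = np.cumsum(rng.normal(0, 0.03, size=500))
    return Statokinesigram(rate=25.0, x=x, y=y, condition=Condition.EO)


def make_stato(n=500, rate=25.0, seed=0, condition=Condition.EO, scale=1.0):
    rng = np.random.default_rng(seed)
    x = scale * np.cumsum(rng.normal(0, 0.02, size=n))
    y = scale * np.cumsum(rng.normal(0, 0.03, size=n))
    return Statokinesigram(rate=rate, x=x, y=y, condition=condition)


def make_tiny_cohort(n_fallers=2, n_nonfallers=4, n=250, seed=0):
    """Small cohort of statokinesigrams with faller trajectories scaled up."""
    subjects = []
    k = 0
    for i in range(n_fallers):
        subjects.append(
            SubjectRecord(
                f"F{i}",
                Label.FALLER,
                eo=make_stato(n, seed=seed + k, scale=3.0),
                ec=make_stato(n, seed=seed + k + 1, condition=Condition.EC, scale=3.0),
            )
        )
        k += 2
    for i in range(n_nonfallers):
        subjects.append(
            SubjectRecord(
                f"N{i}",
                Label.NON_FALLER,
                eo=make_stato(n, seed=seed + k),
                ec=make_stato(n, seed=seed + k + 1, condition=Condition.EC),
            )
        )
        k += 2
    return Cohort(subjects)
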