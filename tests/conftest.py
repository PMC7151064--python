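import numpy as np
import pandas as pd
import pytest

from actidep.io_depresjon import ActivitySeries
from actidep.preprocess import HourWindow
from actidep.synthetic import CohortConfig, SubjectProfile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_series(activity, subject_id="s1", group="control", start="2019-03-04 00:00:00"):
    """Gapless minute-grid series from a value list (NaN = missing)."""
    activity = np.asarray(activity, dtype=float)
    ts = pd.date_range(start=start, periods=len(activity), freq="min")
    return ActivitySeries(subject_id, group, ts, activity)


def make_window(values, label=0, hour=12, subject_id="s1"):
    import datetime

    return HourWindow(subject_id=subject_id, label=label,
                      date=datetime.date(2019, 3, 4), hour=hour,
                      values=np.asarray(values, dtype=float))


@pytest.fixture
def tiny_cohort_config():
    """A small, fast cohort preserving the default group contrast."""
    return CohortConfig(n_condition=4, n_control=5, days_per_subject=3, seed=11)


@pytest.fixture
def flat_profile():
    return SubjectProfile(group="control", mesor=50.0, amplitude=0.0,
                          night_burst_rate=0.0, zero_inflation_day=0.0,
                          dispersion=1e6)
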