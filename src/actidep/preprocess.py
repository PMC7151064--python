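"""Record equalization, hourly windowing, segment assignment, standardization.

Each subject's trace is truncated to a common length (head kept), cut into
one-hour windows of 60 consecutive minute counts aligned to the clock hour,
and assigned to segments by hour of day: DAY covers 8-20 h (13 hours), NIGHT
covers 21-23 h and 0-7 h (11 hours), FULL is all 24.  Windows containing any
missing minute are dropped whole — missing data is never imputed.  Activity
is then z-standardized with a single global mean and standard deviation
pooled over the dataset being standardized (z = (x - mean) / sd, sample SD
with denominator n-1).
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, replace

import numpy as np

from actidep.io_depresjon import ActivitySeries

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
WINDOW_MINUTES = 60


@dataclass(frozen=True)
class SegmentScheme:
    """A named subset of clock hours defining one analysis dataset."""

    kind: str
    member_hours: frozenset[int]


DAY = SegmentScheme("DAY", frozenset(range(8, 21)))
NIGHT = SegmentScheme("NIGHT", frozenset([21, 22, 23] + list(range(0, 8))))
FULL = SegmentScheme("FULL", frozenset(range(24)))

SCHEMES = {"day": DAY, "night": NIGHT, "full": FULL}


@dataclass
class HourWindow:
    """60 consecutive minute values for one clock hour of one subject.

    The unit of classification: the window inherits its subject's binary
    label (1 = condition/depressive, 0 = control).  Values are raw counts
    after segmentation and real-valued after standardization.
    """

    subject_id: str
    label: int
    date: datetime.date
    hour: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_MINUTES,):
            raise ValueError(f"window must hold exactly {WINDOW_MINUTES} values")
        if not 0 <= self.hour <= 23:
            raise ValueError(f"hour out of range: {self.hour}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class StandardizationStats:
    """Global mean and sample SD of the pooled activity being standardized."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("standard deviation must be positive")


def equalize_lengths(cohort: list[ActivitySeries], target_minutes: int | str = "auto") -> list[ActivitySeries]:
    """Truncate every series to a common length, keeping the leading prefix.

    ``target_minutes="auto"`` uses the cohort's minimum length rounded down
    to a whole day.  A numeric target longer than the shortest series raises
    a ValueError naming that subject.
    """
    if any(len(s) == 0 for s in cohort):
        raise ValueError("every series must be non-empty")
    shortest = min(cohort, key=len)
    if target_minutes == "auto":
        target = (len(shortest) // MINUTES_PER_DAY) * MINUTES_PER_DAY
        if target == 0:
            raise ValueError("shortest series is under one day; cannot auto-equalize")
    else:
        target = int(target_minutes)
        if target > len(shortest):
            raise ValueError(
                f"target_minutes={target} exceeds shortest series "
                f"({shortest.subject_id}, {len(shortest)} min)"
            )
    return [
        ActivitySeries(s.subject_id, s.group, s.timestamps[:target], s.activity[:target])
        for s in cohort
    ]


def segment_hours(series: ActivitySeries, label: int | None = None) -> list[HourWindow]:
    """Cut a minute-resolution series into per-clock-hour windows.

    A window is emitted for every clock hour fully covered by 60 consecutive
    minute samples starting at minute :00.  Windows containing any missing
    value are dropped (counted via logging); partial hours at the edges are
    skipped silently.  Values stay raw counts at this stage.
    """
    if label is None:
        label = series.label
    windows: list[HourWindow] = []
    n = len(series)
    dropped = 0
    if n == 0:
        return windows
    ts = series.timestamps
    minute_of_hour = ts.minute.to_numpy()
    starts = np.flatnonzero(minute_of_hour == 0)
    for i in starts:
        j = i + WINDOW_MINUTES
        if j > n:
            continue
        # the 60 samples must be consecutive minutes of the same clock hour
        if (ts[j - 1] - ts[i]) != np.timedelta64(WINDOW_MINUTES - 1, "m"):
            continue
        vals = series.activity[i:j]
        if np.isnan(vals).any():
            dropped += 1
            continue
        windows.append(
            HourWindow(
                subject_id=series.subject_id,
                label=label,
                date=ts[i].date(),
                hour=int(ts[i].hour),
                values=vals.copy(),
            )
        )
    if dropped:
        logger.info("%s: dropped %d window(s) containing missing data", series.subject_id, dropped)
    return windows


def split_by_segment(windows: list[HourWindow], scheme: SegmentScheme) -> list[HourWindow]:
    """Keep the windows whose hour belongs to the scheme, order preserved."""
    return [w for w in windows if w.hour in scheme.member_hours]


def fit_standardization(windows: list[HourWindow]) -> StandardizationStats:
    """Pool all minute values across windows; return their mean and sample SD."""
    if not windows:
        raise ValueError("cannot fit standardization on an empty window list")
    pooled = np.concatenate([w.values for w in windows])
    if np.unique(pooled).size < 2:
        raise ValueError("degenerate data: pooled activity has zero variance")
    return StandardizationStats(mean=float(pooled.mean()), sd=float(pooled.std(ddof=1)))


def standardize(windows: list[HourWindow], stats: StandardizationStats) -> list[HourWindow]:
    """Return new windows with every value replaced by (x - mean) / sd."""
    return [replace(w, values=(w.values - stats.mean) / stats.sd) for w in windows]
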