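"""Reading and writing actigraphy cohorts in the Depresjon file dialect.

The dialect is one CSV per subject with columns ``timestamp`` (minute
resolution), ``date`` and ``activity`` (non-negative integer counts), plus a
single ``scores`` CSV of per-subject metadata with twelve columns.  Group
membership (condition = depressed patient, control = healthy) follows the file
naming convention ``condition_N`` / ``control_N``; the scores file is metadata
only.  Activity values that do not parse as numbers (the dialect writes
``NA``) become NaN, an explicit missing marker distinct from a genuine zero
count (sleep).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ACTIVITY_COLUMNS = ["timestamp", "date", "activity"]
SCORES_COLUMNS = [
    "number", "days", "gender", "age", "afftype", "melanch",
    "inpatient", "edu", "marriage", "work", "madrs1", "madrs2",
]

AFFTYPE_NAMES = {1: "bipolar II", 2: "unipolar depressive", 3: "bipolar I"}

CONDITION = "condition"
CONTROL = "control"


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


@dataclass
class ActivitySeries:
    """One subject's per-minute activity trace.

    ``timestamps`` is a minute-resolution DatetimeIndex; ``activity`` is a
    float array where NaN marks a missing measurement.
    """

    subject_id: str
    group: str  # "condition" | "control"
    timestamps: pd.DatetimeIndex
    activity: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in (CONDITION, CONTROL):
            raise ValueError(f"group must be 'condition' or 'control', got {self.group!r}")
        self.activity = np.asarray(self.activity, dtype=float)
        if len(self.timestamps) != len(self.activity):
            raise ValueError("timestamps and activity have different lengths")
        with np.errstate(invalid="ignore"):
            if np.any(self.activity[~np.isnan(self.activity)] < 0):
                raise ValueError("activity counts must be non-negative")

    def __len__(self) -> int:
        return len(self.activity)

    @property
    def label(self) -> int:
        """Binary class label: 1 for condition, 0 for control."""
        return 1 if self.group == CONDITION else 0


@dataclass
class SubjectMeta:
    """Per-subject metadata row from the scores file."""

    subject_id: str
    days: int
    gender: object
    age: object
    afftype: str | None  # "bipolar II" | "unipolar depressive" | "bipolar I" | None
    melanch: object
    inpatient: object
    edu: object
    marriage: object
    work: object
    madrs1: float | None
    madrs2: float | None

    @property
    def group(self) -> str:
        return CONDITION if self.afftype is not None else CONTROL


def _parse_timestamps(raw: Sequence[str]) -> pd.DatetimeIndex:
    # Accepts "YYYY-MM-DD HH:MM:SS" and "YYYY-MM-DD HH:MM"; naive local time.
    ts = pd.to_datetime(list(raw), format="mixed")
    return pd.DatetimeIndex(ts)


def read_activity_csv(path: str | Path, subject_id: str, group: str) -> ActivitySeries:
    """Read one subject's activity CSV.

    Rows are kept in file order, one sample per row; unparseable activity
    values become NaN.  Raises :class:`FormatError` if the header is not
    exactly ``timestamp,date,activity`` (any order tolerated, names exact).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    for col in ACTIVITY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        return ActivitySeries(subject_id, group, pd.DatetimeIndex([]), np.array([], dtype=float))
    timestamps = _parse_timestamps(df["timestamp"])
    activity = pd.to_numeric(df["activity"], errors="coerce").to_numpy(dtype=float)
    return ActivitySeries(subject_id, group, timestamps, activity)


def write_activity_csv(series: ActivitySeries, path: str | Path) -> None:
    """Write a series in the dialect; lossless round-trip with the reader."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("timestamp,date,activity\n")
        for ts, a in zip(series.timestamps, series.activity):
            if math.isnan(a):
                act = "NA"
            else:
                act = str(int(a)) if float(a).is_integer() else repr(float(a))
            fh.write(f"{ts:%Y-%m-%d %H:%M:%S},{ts:%Y-%m-%d},{act}\n")


def read_scores(path: str | Path) -> list[SubjectMeta]:
    """Read the cohort scores CSV into one :class:`SubjectMeta` per row."""
    path = Path(path)
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in SCORES_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in SCORES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out: list[SubjectMeta] = []
    for _, row in df.iterrows():
        aff = row["afftype"]
        if pd.isna(aff) or (isinstance(aff, str) and not aff.strip()):
            afftype = None
        else:
            code = int(float(aff))
            afftype = AFFTYPE_NAMES.get(code)
            if afftype is None and code != 0:
                raise FormatError(f"{path}: unknown afftype code {code}")
        madrs1 = None if pd.isna(row["madrs1"]) else float(row["madrs1"])
        madrs2 = None if pd.isna(row["madrs2"]) else float(row["madrs2"])
        out.append(
            SubjectMeta(
                subject_id=str(row["number"]),
                days=int(row["days"]),
                gender=row["gender"],
                age=row["age"],
                afftype=afftype,
                melanch=row["melanch"],
                inpatient=row["inpatient"],
                edu=row["edu"],
                marriage=row["marriage"],
                work=row["work"],
                madrs1=madrs1,
                madrs2=madrs2,
            )
        )
    return out


def read_cohort_dir(directory: str | Path) -> list[ActivitySeries]:
    """Read every ``condition_*`` / ``control_*`` activity CSV in a directory.

    Group is assigned from the file name prefix, mirroring the public
    dataset's layout.
    """
    directory = Path(directory)
    series: list[ActivitySeries] = []
    for path in sorted(directory.glob("*.csv")):
        stem = path.stem
        if stem.startswith("condition_"):
            group = CONDITION
        elif stem.startswith("control_"):
            group = CONTROL
        else:
            continue
        series.append(read_activity_csv(path, subject_id=stem, group=group))
    if not series:
        raise FileNotFoundError(f"no condition_*/control_* CSV files in {directory}")
    return series
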