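"""Synthetic circadian actigraphy cohorts in the Depresjon file dialect.

The generator realizes the two qualitative effects the analysis targets:
depressed (condition) subjects show a blunted daytime activity amplitude and
elevated, fragmented nocturnal activity, while controls sleep quietly and are
active by day.  Per-minute counts follow a cosinor mean curve

    mu(t) = max(0, mesor + amplitude * cos(2*pi*(t - acrophase_hour*60)/1440))

with negative-binomial dispersion around mu(t), extra zeros injected during
the day (sedentary stillness), and, during night hours, Poisson-distributed
arousal bursts each adding ``burst_magnitude`` counts over a random 3-10
minute span (sleep fragmentation).  All counts are non-negative integers on a
gapless minute grid; everything is reproducible from one seed.

The default cohort is 23 condition and 32 control subjects over 14 days,
matching the composition of the public reference dataset.  Group profiles
are fixed (no between-subject heterogeneity), so when the condition profile
is set equal to the control profile the windows carry no label signal at all
— a clean null for calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from actidep.io_depresjon import ActivitySeries, SubjectMeta, write_activity_csv, SCORES_COLUMNS
from actidep.preprocess import MINUTES_PER_DAY, NIGHT


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one subject's activity process.

    mesor and amplitude are in counts/min; acrophase_hour is the clock time
    of peak activity; night_burst_rate is the expected number of nocturnal
    arousal bursts per hour; dispersion is the negative-binomial shape
    (smaller = more overdispersed).
    """

    group: str
    mesor: float
    amplitude: float
    acrophase_hour: float = 14.0
    night_burst_rate: float = 0.2
    burst_magnitude: float = 150.0
    zero_inflation_day: float = 0.10
    dispersion: float = 1.5

    def __post_init__(self) -> None:
        if self.mesor < 0 or self.amplitude < 0 or self.night_burst_rate < 0:
            raise ValueError("mesor, amplitude and night_burst_rate must be >= 0")
        if not 0 <= self.zero_inflation_day <= 1:
            raise ValueError("zero_inflation_day must be in [0, 1]")
        if not 0 <= self.acrophase_hour < 24:
            raise ValueError("acrophase_hour must be in [0, 24)")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")


# Calibrated group defaults.  Controls swing from near-silence at night to
# ~220 counts/min mid-afternoon.  Condition subjects have a flattened rhythm:
# blunted amplitude with the daytime mean level matched to controls (daily
# obligations persist regardless of condition), so the group contrast is
# concentrated at night — an elevated nocturnal floor plus frequent arousal
# bursts (sleep fragmentation).
CONTROL_PROFILE = SubjectProfile(
    group="control", mesor=115.0, amplitude=105.0, acrophase_hour=14.0,
    night_burst_rate=0.3, burst_magnitude=120.0, zero_inflation_day=0.10,
    dispersion=1.5,
)
CONDITION_PROFILE = SubjectProfile(
    group="condition", mesor=135.0, amplitude=70.0, acrophase_hour=14.0,
    night_burst_rate=3.0, burst_magnitude=180.0, zero_inflation_day=0.18,
    dispersion=1.5,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and reproducibility settings."""

    n_condition: int = 23
    n_control: int = 32
    days_per_subject: int = 14
    seed: int = 0
    condition_profile: SubjectProfile = CONDITION_PROFILE
    control_profile: SubjectProfile = CONTROL_PROFILE
    na_run_rate: float = 0.0  # expected missing-data runs per subject-day
    start_date: str = "2019-03-04"


def expected_activity(minute_of_day: int | np.ndarray, profile: SubjectProfile) -> float | np.ndarray:
    """Cosinor mean activity mu(t), clipped at zero."""
    t = np.asarray(minute_of_day, dtype=float)
    phase = 2 * np.pi * (t - profile.acrophase_hour * 60.0) / MINUTES_PER_DAY
    mu = np.maximum(0.0, profile.mesor + profile.amplitude * np.cos(phase))
    return float(mu) if np.isscalar(minute_of_day) else mu


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with mean mu and shape r (var = mu + mu^2/r)."""
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = dispersion / (dispersion + mu[pos])
        counts[pos] = rng.negative_binomial(dispersion, p)
    return counts


def simulate_subject(
    profile: SubjectProfile,
    days: int,
    rng: np.random.Generator,
    subject_id: str = "subject",
    start_date: str = "2019-03-04",
    na_run_rate: float = 0.0,
) -> ActivitySeries:
    """Simulate one subject's gapless per-minute trace over ``days`` days."""
    if days < 1:
        raise ValueError("days must be >= 1")
    n = days * MINUTES_PER_DAY
    minute_of_day = np.arange(n) % MINUTES_PER_DAY
    mu = expected_activity(minute_of_day, profile)
    counts = _nb_counts(mu, profile.dispersion, rng)

    # daytime zero-inflation: sedentary stillness
    hour_of_day = minute_of_day // 60
    is_day = ~np.isin(hour_of_day, list(NIGHT.member_hours))
    if profile.zero_inflation_day > 0:
        zeros = rng.random(n) < profile.zero_inflation_day
        counts[is_day & zeros] = 0

    # nocturnal arousal bursts: per night hour, Poisson(rate) events, each a
    # contiguous 3-10 minute span of added activity
    if profile.night_burst_rate > 0:
        night_hours = np.flatnonzero(~is_day[::60])  # hour-resolution mask
        n_bursts = rng.poisson(profile.night_burst_rate, size=night_hours.size)
        for h_idx, k in zip(night_hours, n_bursts):
            for _ in range(k):
                span = int(rng.integers(3, 11))
                start = int(h_idx) * 60 + int(rng.integers(0, 60 - span + 1))
                counts[start : start + span] += int(round(profile.burst_magnitude))

    activity = counts.astype(float)
    # optional missing-data runs to exercise the cleaning path
    if na_run_rate > 0:
        n_runs = rng.poisson(na_run_rate * days)
        for _ in range(n_runs):
            span = int(rng.integers(5, 90))
            start = int(rng.integers(0, max(1, n - span)))
            activity[start : start + span] = np.nan

    timestamps = pd.date_range(start=start_date, periods=n, freq="min")
    return ActivitySeries(subject_id, profile.group, timestamps, activity)


def generate_cohort(config: CohortConfig = CohortConfig()) -> tuple[list[ActivitySeries], list[SubjectMeta]]:
    """Simulate the labelled cohort in memory, reproducibly from config.seed."""
    rng = np.random.default_rng(config.seed)
    series: list[ActivitySeries] = []
    metas: list[SubjectMeta] = []
    specs = [("condition", config.condition_profile, config.n_condition),
             ("control", config.control_profile, config.n_control)]
    for group, base_profile, count in specs:
        profile = dataclasses.replace(base_profile, group=group)
        for i in range(1, count + 1):
            sid = f"{group}_{i}"
            series.append(
                simulate_subject(profile, config.days_per_subject, rng, subject_id=sid,
                                 start_date=config.start_date, na_run_rate=config.na_run_rate)
            )
            is_cond = group == "condition"
            madrs = int(rng.integers(18, 32)) if is_cond else 0
            metas.append(
                SubjectMeta(
                    subject_id=sid, days=config.days_per_subject,
                    gender=int(rng.integers(1, 3)), age="35-39",
                    afftype="unipolar depressive" if is_cond else None,
                    melanch=2, inpatient=2, edu="11-15", marriage=1, work=1,
                    madrs1=madrs if is_cond else 0,
                    madrs2=madrs if is_cond else 0,
                )
            )
    return series, metas


def simulate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Write a simulated cohort as Depresjon-dialect files; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, metas = generate_cohort(config)
    for s in series:
        write_activity_csv(s, out_dir / f"{s.subject_id}.csv")
    rows = []
    afftype_codes = {None: "", "bipolar II": 1, "unipolar depressive": 2, "bipolar I": 3}
    for m in metas:
        rows.append({
            "number": m.subject_id, "days": m.days, "gender": m.gender, "age": m.age,
            "afftype": afftype_codes[m.afftype], "melanch": m.melanch,
            "inpatient": m.inpatient, "edu": m.edu, "marriage": m.marriage,
            "work": m.work, "madrs1": m.madrs1, "madrs2": m.madrs2,
        })
    pd.DataFrame(rows, columns=SCORES_COLUMNS).to_csv(out_dir / "scores.csv", index=False)
    return out_dir
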