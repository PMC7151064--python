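"""24 time- and frequency-domain features per one-hour activity window.

Ten time-domain statistics are computed on the 60 standardized minute values;
fourteen more on the window's one-sided periodogram (31 bins for a 60-point
transform, DC and Nyquist included once), bins[k] = |X(k)|^2 / N with X the
DFT and N = 60.  Feature indices:

====== ========================== ====== ==========================
 index  time domain                index  frequency domain
====== ========================== ====== ==========================
 0      kurtosis                   10     kurtosis
 1      mean                       11     mean
 2      median                     12     median
 3      SD (sample, n-1)           13     SD (sample, n-1)
 4      variance (population)      14     variance (population)
 5      coefficient of variation   15     coefficient of variation
 6      interquartile range        16     spectral density (total power)
 7      minimum                    17     interquartile range
 8      maximum                    18     trimmed mean
 9      trimmed mean               19     minimum
                                   20     maximum
                                   21     spectral entropy
                                   22     skewness
                                   23     spectral flatness
====== ========================== ====== ==========================

Kurtosis is non-excess (mu4/sigma^4, population moments; Gaussian -> 3) and
skewness the population third standardized moment.  The coefficient of
variation is sample SD over mean, returned as 0 when the mean or SD is zero
(degenerate-window sentinel).  The trimmed mean cuts 5% from each tail by
default.  Spectral entropy is the Shannon entropy (base 2) of the
probability-normalized periodogram; spectral flatness is the geometric over
arithmetic mean of the bins, with bins below 1e-12 floored to 1e-12 inside
the logarithm (zero bins are common in sleep windows and the bare formula is
undefined there).
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from actidep.preprocess import HourWindow, WINDOW_MINUTES

N_FEATURES = 24
N_BINS = WINDOW_MINUTES // 2 + 1  # one-sided bins of a 60-point transform
TRIM_FRACTION = 0.05
FLATNESS_EPS = 1e-12

FEATURE_NAMES = [
    "kurtosis_time", "mean_time", "median_time", "sd_time", "variance_time",
    "cv_time", "iqr_time", "min_time", "max_time", "trim_mean_time",
    "kurtosis_freq", "mean_freq", "median_freq", "sd_freq", "variance_freq",
    "cv_freq", "spectral_density", "iqr_freq", "trim_mean_freq", "min_freq",
    "max_freq", "entropy", "skewness_freq", "spectral_flatness",
]


class DegenerateWindowWarning(UserWarning):
    """A window (or its spectrum) was constant; sentinel feature values used."""


@dataclass
class PowerSpectrum:
    """One-sided periodogram ordinates for frequency indices k = 0..30."""

    bins: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_BINS,):
            raise ValueError(f"spectrum must hold {N_BINS} bins")
        if np.any(self.bins < 0):
            raise ValueError("periodogram ordinates must be non-negative")


@dataclass
class FeatureVector:
    """The 24 features of one hour window, indexed per the table above."""

    features: np.ndarray
    label: int
    subject_id: str
    hour: int
    date: datetime.date | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features")


def periodogram_matrix(values: np.ndarray) -> np.ndarray:
    """One-sided periodograms of the rows of an (n, 60) matrix."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != WINDOW_MINUTES:
        raise ValueError(f"expected (n, {WINDOW_MINUTES}) matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("window values must be finite")
    spectrum = np.fft.rfft(values, axis=1)
    return (spectrum.real**2 + spectrum.imag**2) / WINDOW_MINUTES


def periodogram(values: np.ndarray) -> PowerSpectrum:
    """One-sided periodogram of exactly 60 finite values."""
    values = np.asarray(values, dtype=float)
    if values.shape != (WINDOW_MINUTES,):
        raise ValueError(f"expected exactly {WINDOW_MINUTES} values")
    return PowerSpectrum(periodogram_matrix(values[None, :])[0])


def _moment_stats(x: np.ndarray) -> np.ndarray:
    """The shared 10-statistic block, rows of x -> (n, 10).

    Order: kurtosis, mean, median, SD, variance, CV, IQR, min, max,
    trimmed mean.
    """
    n_rows = x.shape[0]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    var_pop = x.var(axis=1)  # population variance per the feature table
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant window(s): kurtosis and CV set to 0",
            DegenerateWindowWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trigger scipy's precision-loss warning; they are
        # sentinelled to 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = scipy.stats.kurtosis(x, axis=1, fisher=False, bias=True)
        kurt = np.where(degenerate, 0.0, kurt)
        cv = np.where(degenerate | (mean == 0), 0.0, sd / np.where(mean == 0, 1.0, mean))
    q1, med, q3 = np.percentile(x, [25, 50, 75], axis=1)
    trim = scipy.stats.trim_mean(x, TRIM_FRACTION, axis=1)
    out = np.empty((n_rows, 10))
    out[:, 0] = kurt
    out[:, 1] = mean
    out[:, 2] = med
    out[:, 3] = sd
    out[:, 4] = var_pop
    out[:, 5] = cv
    out[:, 6] = q3 - q1
    out[:, 7] = x.min(axis=1)
    out[:, 8] = x.max(axis=1)
    out[:, 9] = trim
    return out


def _entropy_rows(bins: np.ndarray) -> np.ndarray:
    total = bins.sum(axis=1)
    zero = total == 0
    if zero.any():
        warnings.warn("all-zero spectrum: entropy set to 0", DegenerateWindowWarning, stacklevel=3)
    safe_total = np.where(zero, 1.0, total)
    p = bins / safe_total[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ent = -terms.sum(axis=1)
    return np.where(zero, 0.0, ent)


def _flatness_rows(bins: np.ndarray) -> np.ndarray:
    arith = bins.mean(axis=1)
    zero = arith == 0
    if zero.any():
        warnings.warn("all-zero spectrum: flatness set to 0", DegenerateWindowWarning, stacklevel=3)
    geo = np.exp(np.log(np.maximum(bins, FLATNESS_EPS)).mean(axis=1))
    flat = geo / np.where(zero, 1.0, arith)
    # the eps floor inflates the geometric mean of near-zero spectra; keep <= 1
    return np.where(zero, 0.0, np.minimum(flat, 1.0))


def shannon_entropy(spectrum: PowerSpectrum) -> float:
    """Shannon entropy (bits) of the probability-normalized spectrum."""
    return float(_entropy_rows(spectrum.bins[None, :])[0])


def spectral_flatness(spectrum: PowerSpectrum) -> float:
    """Geometric over arithmetic mean of the bins; 1 for a flat spectrum."""
    return float(_flatness_rows(spectrum.bins[None, :])[0])


def time_features(values: np.ndarray) -> np.ndarray:
    """The 10 time-domain statistics (indices 0-9) of a 60-value window."""
    values = np.asarray(values, dtype=float)
    if values.shape != (WINDOW_MINUTES,):
        raise ValueError(f"expected exactly {WINDOW_MINUTES} values")
    return _moment_stats(values[None, :])[0]


def freq_features(spectrum: PowerSpectrum) -> np.ndarray:
    """The 14 frequency-domain statistics (indices 10-23) of a spectrum."""
    return _freq_block(spectrum.bins[None, :])[0]


def _freq_block(bins: np.ndarray) -> np.ndarray:
    stats = _moment_stats(bins)
    sd = stats[:, 3]
    with np.errstate(invalid="ignore"):
        skew = scipy.stats.skew(bins, axis=1, bias=True)
    skew = np.where(sd == 0, 0.0, skew)
    out = np.empty((bins.shape[0], 14))
    out[:, 0] = stats[:, 0]   # kurtosis
    out[:, 1] = stats[:, 1]   # mean
    out[:, 2] = stats[:, 2]   # median
    out[:, 3] = stats[:, 3]   # SD
    out[:, 4] = stats[:, 4]   # variance
    out[:, 5] = stats[:, 5]   # CV
    out[:, 6] = bins.sum(axis=1)   # spectral density = total power
    out[:, 7] = stats[:, 6]   # IQR
    out[:, 8] = stats[:, 9]   # trimmed mean
    out[:, 9] = stats[:, 7]   # min (DC bin included)
    out[:, 10] = stats[:, 8]  # max
    out[:, 11] = _entropy_rows(bins)
    out[:, 12] = skew
    out[:, 13] = _flatness_rows(bins)
    return out


def compute_feature_matrix(values: np.ndarray) -> np.ndarray:
    """All 24 features for each row of an (n, 60) window matrix."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != WINDOW_MINUTES:
        raise ValueError(f"expected (n, {WINDOW_MINUTES}) matrix")
    bins = periodogram_matrix(values)
    return np.hstack([_moment_stats(values), _freq_block(bins)])


def extract_features(window: HourWindow) -> FeatureVector:
    """The full 24-feature vector of one window, label copied over."""
    feats = compute_feature_matrix(window.values[None, :])[0]
    return FeatureVector(feats, label=window.label, subject_id=window.subject_id,
                         hour=window.hour, date=window.date)


def extract_all(windows: list[HourWindow]) -> list[FeatureVector]:
    """Vectorized feature extraction over a window list."""
    if not windows:
        return []
    matrix = compute_feature_matrix(np.stack([w.values for w in windows]))
    return [
        FeatureVector(matrix[i], label=w.label, subject_id=w.subject_id, hour=w.hour, date=w.date)
        for i, w in enumerate(windows)
    ]


def feature_matrix(vectors: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into an (n, 24) design matrix and a label array."""
    X = np.stack([v.features for v in vectors])
    y = np.array([v.label for v in vectors], dtype=int)
    return X, y
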