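import cmath
import math

import numpy as np
import pytest

from actidep.features import (
    DegenerateWindowWarning,
    N_BINS,
    PowerSpectrum,
    compute_feature_matrix,
    extract_features,
    extract_all,
    freq_features,
    periodogram,
    shannon_entropy,
    spectral_flatness,
    time_features,
)
from tests.conftest import make_window


# ---------------------------------------------------------------- oracles --

def dft_periodogram_oracle(x):
    """O(N^2) direct DFT periodogram, independent of the FFT path."""
    n = len(x)
    bins = []
    for k in range(n // 2 + 1):
        X = sum(x[m] * cmath.exp(-2j * math.pi * k * m / n) for m in range(n))
        bins.append(abs(X) ** 2 / n)
    return bins


def quantile_oracle(sorted_vals, p):
    """Linear-interpolation quantile on sorted data."""
    h = (len(sorted_vals) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(sorted_vals) - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def stats_oracle(x):
    """Plain-Python recomputation of the shared 10-statistic block."""
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    cv = sd / mean if mean != 0 and sd != 0 else 0.0
    s = sorted(x)
    q1, med, q3 = (quantile_oracle(s, p) for p in (0.25, 0.5, 0.75))
    k = int(0.05 * n)
    trim = sum(s[k : n - k]) / (n - 2 * k)
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    return dict(kurtosis=kurt, mean=mean, median=med, sd=sd, variance=m2,
                cv=cv, iqr=q3 - q1, mn=min(x), mx=max(x), trim=trim, skew=skew)


# ----------------------------------------------------------- periodogram --

class TestPeriodogram:
    def test_all_zero_input(self):
        assert periodogram(np.zeros(60)).bins.tolist() == [0.0] * N_BINS

    def test_constant_input_is_dc_only(self):
        bins = periodogram(np.full(60, 3.0)).bins
        assert bins[0] == pytest.approx(60 * 9.0)
        np.testing.assert_allclose(bins[1:], 0.0, atol=1e-9)

    def test_pure_tone_concentrates_at_its_bin(self):
        n = np.arange(60)
        bins = periodogram(np.cos(2 * np.pi * 5 * n / 60)).bins
        assert np.argmax(bins) == 5

    def test_matches_direct_dft_oracle(self, rng):
        x = rng.normal(size=60)
        np.testing.assert_allclose(periodogram(x).bins, dft_periodogram_oracle(x),
                                   rtol=1e-10, atol=1e-12)

    def test_parseval_identity(self, rng):
        x = rng.normal(size=60)
        bins = periodogram(x).bins
        one_sided_sum = bins[0] + bins[-1] + 2 * bins[1:-1].sum()
        assert one_sided_sum == pytest.approx(np.sum(x**2), rel=1e-9)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            periodogram(np.zeros(59))


# ------------------------------------------------------- entropy/flatness --

class TestEntropyFlatness:
    def test_single_bin_entropy_zero(self):
        bins = np.zeros(N_BINS)
        bins[4] = 2.5
        assert shannon_entropy(PowerSpectrum(bins)) == pytest.approx(0.0)

    def test_uniform_entropy_is_log2_bins(self):
        assert shannon_entropy(PowerSpectrum(np.full(N_BINS, 0.7))) == pytest.approx(
            math.log2(N_BINS))

    def test_entropy_matches_direct_sum(self, rng):
        bins = rng.gamma(1.0, 1.0, N_BINS)
        p = bins / bins.sum()
        expected = -sum(pi * math.log2(pi) for pi in p if pi > 0)
        assert shannon_entropy(PowerSpectrum(bins)) == pytest.approx(expected, abs=1e-12)

    def test_entropy_scale_invariant(self, rng):
        bins = rng.gamma(1.0, 1.0, N_BINS)
        assert shannon_entropy(PowerSpectrum(bins * 17.3)) == pytest.approx(
            shannon_entropy(PowerSpectrum(bins)), abs=1e-12)

    def test_flatness_of_constant_spectrum_is_one(self):
        assert spectral_flatness(PowerSpectrum(np.full(N_BINS, 4.2))) == pytest.approx(1.0)

    def test_flatness_collapses_with_a_zero_bin(self):
        bins = np.full(N_BINS, 1.0)
        bins[3] = 0.0
        f = spectral_flatness(PowerSpectrum(bins))
        assert 0 < f < 0.5

    def test_flatness_matches_direct_formula(self, rng):
        bins = rng.gamma(2.0, 1.0, N_BINS) + 0.1
        expected = math.exp(np.mean(np.log(bins))) / np.mean(bins)
        assert spectral_flatness(PowerSpectrum(bins)) == pytest.approx(expected, abs=1e-12)

    def test_flatness_never_exceeds_one(self, rng):
        for _ in range(50):
            bins = rng.gamma(0.3, 1.0, N_BINS)
            assert spectral_flatness(PowerSpectrum(bins)) <= 1.0


# ------------------------------------------------------------- the block --

class TestTimeFeatures:
    def test_constant_window_sentinels(self):
        with pytest.warns(DegenerateWindowWarning):
            f = time_features(np.full(60, 3.0))
        kurt, mean, med, sd, var, cv, iqr, mn, mx, trim = f
        assert mean == med == trim == mn == mx == 3.0
        assert sd == var == iqr == 0.0
        assert kurt == cv == 0.0

    def test_gaussian_kurtosis_near_three(self, rng):
        x = rng.normal(size=100_000)
        win = x[:60]  # kurtosis itself is checked on the large sample below
        k = stats_oracle(list(x))["kurtosis"]
        se = math.sqrt(24 / len(x))
        assert abs(k - 3) < 3 * se
        assert time_features(win)[0] == pytest.approx(stats_oracle(list(win))["kurtosis"])

    def test_variance_is_population_moment(self, rng):
        x = rng.normal(size=60)
        f = time_features(x)
        assert f[4] == pytest.approx(np.mean((x - x.mean()) ** 2))
        assert f[4] == pytest.approx(f[3] ** 2 * 59 / 60)


class TestFreqFeatures:
    def test_dc_only_spectrum_of_constant_window(self):
        spec = periodogram(np.full(60, 2.0))
        f = freq_features(spec)
        assert f[10] == pytest.approx(60 * 4.0)  # max bin (index 20 overall)
        assert f[2] == pytest.approx(0.0)  # median bin (index 12 overall)

    def test_symmetric_spectrum_skewness_by_direct_moments(self, rng):
        bins = rng.gamma(2.0, 1.0, N_BINS)
        f = freq_features(PowerSpectrum(bins))
        assert f[12] == pytest.approx(stats_oracle(list(bins))["skew"], abs=1e-9)

    def test_spectral_density_is_total_power(self, rng):
        bins = rng.gamma(2.0, 1.0, N_BINS)
        assert freq_features(PowerSpectrum(bins))[6] == pytest.approx(bins.sum())

    def test_zscore_white_noise_total_power_near_n(self, rng):
        # one-sided total power of z-scored noise ~ half of sum x^2 ~ 30
        total = np.mean([
            freq_features(periodogram((lambda v: (v - v.mean()) / v.std(ddof=1))(
                rng.normal(size=60))))[6]
            for _ in range(300)
        ])
        # E[sum x^2] = 59 after z-scoring; one-sided bins carry interior
        # power once, so E[total] = (59 + E[bin0 + binNyq]) / 2 ~ 30
        assert 25 < total < 35


class TestExtractFeatures:
    def test_composition_of_time_and_freq_blocks(self, rng):
        w = make_window(rng.normal(size=60), label=1, hour=23)
        v = extract_features(w)
        np.testing.assert_allclose(v.features[:10], time_features(w.values))
        np.testing.assert_allclose(v.features[10:], freq_features(periodogram(w.values)))
        assert v.label == 1 and v.hour == 23

    def test_two_path_oracle_on_random_windows(self, rng):
        """Vectorized features equal a plain-Python recomputation from raw values."""
        wins = [make_window(rng.gamma(1.5, 20, 60)) for _ in range(100)]
        matrix = compute_feature_matrix(np.stack([w.values for w in wins]))
        for row, w in zip(matrix, wins):
            t = stats_oracle(list(w.values))
            expected_time = [t["kurtosis"], t["mean"], t["median"], t["sd"], t["variance"],
                             t["cv"], t["iqr"], t["mn"], t["mx"], t["trim"]]
            np.testing.assert_allclose(row[:10], expected_time, rtol=1e-9, atol=1e-9)
            bins = dft_periodogram_oracle(list(w.values))
            b = stats_oracle(bins)
            p = [v / sum(bins) for v in bins]
            entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
            flat = math.exp(sum(math.log(max(v, 1e-12)) for v in bins) / len(bins)) / b["mean"]
            expected_freq = [b["kurtosis"], b["mean"], b["median"], b["sd"], b["variance"],
                             b["cv"], sum(bins), b["iqr"], b["trim"], b["mn"], b["mx"],
                             entropy, b["skew"], flat]
            np.testing.assert_allclose(row[10:], expected_freq, rtol=1e-7, atol=1e-9)

    def test_deterministic_bit_for_bit(self, rng):
        w = make_window(rng.normal(size=60))
        a = extract_features(w).features
        b = extract_features(w).features
        assert (a == b).all()

    def test_extract_all_matches_single_path(self, rng):
        wins = [make_window(rng.normal(size=60), hour=h) for h in range(5)]
        batch = extract_all(wins)
        for w, v in zip(wins, batch):
            np.testing.assert_array_equal(v.features, extract_features(w).features)

    def test_all_features_finite(self, rng):
        wins = [make_window(rng.integers(0, 400, 60).astype(float)) for _ in range(50)]
        matrix = compute_feature_matrix(np.stack([w.values for w in wins]))
        assert np.isfinite(matrix).all()
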