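# Methods

## Problem and unit of analysis

The pipeline classifies one-hour actigraphy windows — 60 consecutive
per-minute activity counts from a wrist-worn accelerometer — as originating
from a depressed (condition) or healthy (control) subject.  Windows, not
subjects, are the observations: every window inherits its subject's binary
label, and the three datasets (day 8–20 h, night 21–7 h, full day) are
compared on identical terms.  Observation-level splitting means windows of
one subject can land in both train and test; this matches the analysis the
package reimplements and is a known optimism source (see Limitations).  A
subject-grouped split is not the default but can be built from the window
metadata (`subject_id` travels with every window and feature vector).

## Pre-processing

- **Equalization.** All subjects are truncated to the cohort's minimum
  record length rounded down to whole days (head kept; the choice of end is
  arbitrary and documented as such).
- **Windowing.** Windows align to clock hours (minute :00 to :59) and must
  be 60 strictly consecutive minutes; partial hours at record edges are
  skipped, and any window containing a missing value (`NA`) is dropped
  whole.  Missing data is never imputed — a zero count is real sleep,
  absence of data is not.
- **Standardization.** z = (x − x̄)/s with one global x̄ and sample SD s
  (denominator n−1) pooled over all minute values of the dataset being
  built.  By default the statistics are fitted on the 70% training portion
  only and applied to both portions, avoiding test-set leakage;
  `global_stats: all` pools over the whole dataset instead.  The split is a
  deterministic function of the label sequence and the split seed, so
  selection and classification re-derive the identical partition.
- Order of operations: segment → drop incomplete/missing windows →
  standardize.

## Features

Ten time-domain statistics on the 60 standardized values and fourteen on the
one-sided periodogram bins P(k) = |X(k)|²/60, k = 0…30 (DC and Nyquist
included once).  Conventions that matter:

- **Variance vs SD.** SD is the sample statistic (n−1); variance is the
  population second moment (1/n).  The two are therefore related by
  var = SD²·(n−1)/n, in both domains.
- **Kurtosis** is non-excess (μ₄/σ⁴, population moments; Gaussian → 3);
  **skewness** is the population third standardized moment.
- **CV** = sample SD / mean, with 0 returned when the mean or SD is zero
  (degenerate-window sentinel, warned once per batch).
- **Trimmed mean** removes ⌊0.05·n⌋ observations from each tail
  (3 of 60 minutes; 1 of 31 bins); the fraction is a module constant.
- **Spectral density** (the scalar feature) is total power Σ P(k).  The
  reduction is not uniquely pinned down by the source material; total power
  is the natural Parseval-consistent choice and is what the tests verify.
- **Spectral entropy** is Shannon entropy (base 2) of p = P/ΣP, so its
  range is [0, log₂ 31]; it is invariant to spectrum rescaling.
- **Spectral flatness** is geometric over arithmetic bin mean, with bins
  below 1e−12 floored to 1e−12 inside the logarithm only.  Zero bins are
  common in quiet sleep windows and the bare geometric mean is undefined
  there; the floor makes flatness collapse toward 0 rather than blow up.
  The ratio is clipped at 1 (the floor can otherwise push it marginally
  above for all-but-zero spectra).
- **DC is retained** in the spectrum and participates in min/median/etc.
  Standardization is global, not per-window, so window means still carry
  signal (night level vs day level) and live in the DC bin.
- The periodogram is the squared magnitude of the DFT ("real periodogram"
  reading); discarding the imaginary part before squaring is not
  implemented because a power representation must be non-negative.

Feature extraction is vectorized over an (n, 60) matrix; the single-window
API calls the same code path.  Tests verify the batch path against an
independent plain-Python recomputation (direct O(N²) DFT, loop-based
moments) on random windows.

## Forward selection

Greedy wrapper from the best single feature, adding at each step the feature
that maximizes logistic-regression accuracy on the held-out 30%; rows are
recorded for set sizes 2–10.  The LR is unpenalized (C = ∞, lbfgs, 2000
iterations; a capped-iteration fit is scored with a warning).  Ties between
candidate features go to the lowest index, making traces deterministic.
`best_k` is the size of the first recorded set achieving the trace maximum,
but the experiment table always compares nine-feature models so all three
datasets are measured under the same model size.

## Classification and validation

Random forest with the canonical defaults: 500 trees, ⌊√p⌋ candidate
features per split, unlimited depth, bootstrap n-out-of-n.  This emulates
the classical R implementation's defaults; bit-level agreement across
ecosystems is not possible and not claimed.  The positive class is 1
(condition); a tied vote predicts positive.  Five experiments: best-9 per
dataset, plus the night-selected nine features applied to day and full-day
data (does the night model generalize across the clock?).

Validation derives sensitivity TP/(TP+FN), specificity TN/(TN+FP),
prevalence (TP+FN)/n, the prevalence forms of PPV and NPV (algebraically
identical to TP/(TP+FP) and TN/(TN+FN) when prevalence comes from the same
counts — fuzz-tested to 1e−9), and accuracy.  Percent formatting is half-up
at 2 decimals.  Zero-denominator metrics are reported as NaN, never
silently as 0.

## Synthetic cohort generator

Per-minute counts are drawn from a negative binomial (shape r, so
var = μ + μ²/r) around a clipped cosinor mean
μ(t) = max(0, mesor + amplitude·cos(2π(t − acrophase·60)/1440)), with two
perturbations: daytime zero-inflation (sedentary stillness) and, in each
night hour, Poisson(rate) arousal bursts adding `burst_magnitude` counts
over a random contiguous 3–10-minute span (sleep fragmentation).  Defaults
(counts/min):

| parameter            | control | condition | rationale                          |
|----------------------|--------:|----------:|------------------------------------|
| mesor                |     115 |       135 | flattened rhythm raises the trough |
| amplitude            |     105 |        70 | blunted circadian swing            |
| acrophase            |    14 h |      14 h | mid-afternoon peak                 |
| night burst rate     |  0.3 /h |    3.0 /h | heavy sleep fragmentation          |
| burst magnitude      |     120 |       180 | arousal intensity                  |
| day zero-inflation   |    0.10 |      0.18 | psychomotor stillness bouts        |
| NB dispersion r      |     1.5 |       1.5 | strong overdispersion, both groups |

The profiles were calibrated once, jointly, to realize the qualitative
structure the analysis assumes: the *day-hour mean level is matched* across
groups (mesor + 0.58·amplitude ≈ 176 counts/min for both — daily
obligations persist regardless of condition), so the group contrast is
concentrated at night, where condition subjects combine an elevated cosinor
trough (65 vs 10 counts/min) with frequent bursts.  Under these defaults
night-window classification reaches ≈ 0.92 accuracy and day ≈ 0.75, with
full-day in between — night best, day worst.

Group profiles are deterministic: there is **no between-subject
heterogeneity** by default.  Two consequences: (a) setting the condition
profile equal to the control profile produces an exact null — windows carry
no label information whatsoever; (b) the observation-level split cannot
inflate accuracy through subject memorization, which it would on real data.
The generator is therefore a structural testbed, not a physiological model:
it does not emulate inter-individual variability, day-to-day mood dynamics,
weekday/weekend structure, device artifacts, or the marginal count
distributions of any real corpus.  Passing tests demonstrate that the
pipeline recovers a designed circadian contrast, not that the published
real-data accuracies transfer.

On the null cohort the forest still emits a minority-class prediction for
roughly a quarter of test windows (fully grown trees memorize training
noise), so its raw accuracy sits a few points *below* the majority-class
rate — the expected value for any label-independent classifier is
maj − (2·maj − 1)·r for minority-prediction rate r.  The null calibration
therefore checks label-independence directly: balanced accuracy within
0.5 ± 3 SE and no excess over the majority rate, rather than the idealized
"accuracy equals the majority rate".

## Problem sizes

The default cohort (55 subjects × 14 days) yields 18,480 full-day windows
(10,010 day / 8,470 night; the 13:11 hour ratio holds exactly on gapless
data).  The test suite runs most properties on reduced cohorts (4–9
subjects, 1–3 days) and the effect-recovery checks on the full default
cohort across 10 seeds; the acceptance script runs one full pipeline at the
default size.  Forward selection evaluates ≈ 200 logistic fits per dataset.

## Known limitations

- Window-level evaluation overstates subject-level generalization on real
  data; a leave-subject-out protocol is the honest alternative and can be
  layered on the existing metadata.
- The specificity formula follows the standard TN/(TN+FP); one published
  variant of the formula with a different denominator is inconsistent with
  its own reported values and is treated as a typographical error.
- Real-corpus reproduction (window counts, selection traces, confusion
  counts) depends on unstated equalization lengths and split seeds and is
  supported only as an integration path via `--input-dir`, not asserted by
  the test suite.
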