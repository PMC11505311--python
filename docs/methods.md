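# Methods

This note records the models, conventions and default parameters behind
`ecgbispec`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not establish.

## Signal model and preprocessing

Records are 12-lead ECG at a nominal 1000 Hz, amplitudes in mV. The
denoising chain is notch → baseline → wavelet, each stage
length-preserving:

* **Notch**: second-order IIR notch at 50 Hz, quality factor Q = 30,
  applied forward–backward (`filtfilt`) for zero phase. Q = 30 gives a
  ≈1.7 Hz −3 dB width — narrow enough to leave the 5–40 Hz ECG band
  essentially untouched (<2% attenuation at 5 Hz).
* **Baseline**: two-stage median filter, 200 ms then 600 ms windows (odd
  sample counts). The 200 ms stage steps over QRS complexes, the 600 ms
  stage over P/T waves, so the cascade tracks only sub-hertz wander; the
  estimate is subtracted.
* **Wavelet denoising**: Daubechies-4, decomposition level
  min(8, ⌊log2 n⌋ − 2, max feasible level), soft thresholding of all detail
  levels at the universal threshold σ√(2 ln n), σ estimated from the
  finest-level details as MAD/0.6745. This targets broadband muscle noise
  while keeping the beat morphology (correlation ≥ 0.99 on clean signals).

**R-peak detection** is classic Pan–Tompkins: 5–15 Hz band-pass (2nd-order
Butterworth, zero phase), derivative, squaring, 150 ms moving-window
integration, adaptive dual thresholds (running signal/noise peak estimates
with 0.125/0.875 updates), 200 ms refractory period and RR-based
search-back at 1.66× the running RR mean. Detections are refined to the
local maximum of the band-passed signal within ±50 ms. Detection runs on a
single configurable lead (default II); the detected indices segment all
leads so beats stay aligned across leads.

**Segmentation** cuts 300 + 1 + 300 = 601 samples around each R peak. The
first and last detected peaks are always discarded (their windows are the
ones most likely to be truncated or rhythm-atypical), as is any peak whose
window would leave the record; fewer than three peaks therefore yield no
beats. The 601-sample window is defined in samples, so it presumes
1000 Hz; records at other rates should be resampled to 1000 Hz first.

## Decomposition

**EMD**: standard sifting with cubic-spline envelopes through local
extrema. The beat is mirror-extended by half its length on each side before
envelope fitting to suppress end effects. A sift stops on the Cauchy
criterion Σ(h_prev − h)²/Σh_prev² < 0.2 (the classic threshold) or after
100 sifts; extraction stops at 10 IMFs or when the residual has fewer than
two extrema. Completeness — IMFs plus residual summing exactly to the
input — holds by construction and is asserted to 1e-8 relative in the
tests. IMFs are kept in extraction order, highest frequency first.

**VMD**: the constrained variational problem (minimum summed bandwidth of
analytic, frequency-shifted modes subject to reconstruction) is solved by
ADMM in the frequency domain on the mirror-extended signal: each mode is
updated by the Wiener-like quotient
u_k ← (f − Σ_{i≠k} u_i + λ/2)/(1 + 2α(ω − ω_k)²), each center frequency as
the power-weighted mean frequency of its mode, and the dual variable by
step τ. Defaults: K = 10, α = 2000, τ = 0 (no exact-reconstruction
enforcement, tolerant of residual noise), tol = 1e-7, 500 iterations
maximum. Initialization is deterministic — ω_k uniformly spaced on
(0, fs/2) — so results need no seed. Modes are returned sorted by ascending
center frequency; note this runs opposite to EMD's ordering. On noisy
beats the 1e-7 tolerance is often not reached within 500 iterations; the
result is still well-converged in practice (relative change ~1e-6) and the
ModeSet carries a `converged` flag plus a logged warning.

## Mode selection

Each mode is scored by its Pearson correlation with the beat it came from;
scores are averaged over cases to a 12-lead × 10-mode table. A "case" is a
single heartbeat (the finer-grained choice; subject-level aggregation is a
caller-side regrouping). Correlations are used signed, not absolute.
Selection is positional — the first five modes — with a consistency flag
reporting whether those five really carry the five largest means per lead;
the flag never changes the selection. Correspondence analysis of the
(nonnegative) correlation table uses the standard chi-square-metric SVD:
P = table/total, S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, principal coordinates
from mass-scaled singular vectors; total inertia equals the table's
chi-square statistic divided by its grand total (asserted against a direct
chi-square computation). Negative entries, which can occur if a mode
anti-correlates, are clamped to zero with a warning.

## Bispectrum

The direct (third-order periodogram) estimator on a single segment: mean
removal, Hann taper, zero-padding to nfft = 1024, then
B(i,j) = X(i)X(j)X*(i+j)/nfft on the quadrant 0..nfft/2 × 0..nfft/2,
zeroed outside the triangle i + j ≤ nfft/2 where the conjugate index would
leave the grid. Beats are 601 samples, so there is no sub-segment
averaging within a beat. The matrix stores complex values; amplitude
symmetry ω(i,j) = ω(j,i) and cubic amplitude scaling (|c|³ under x → c·x)
are asserted.

A single-realization amplitude is blind to phase coherence: quadratic
phase coupling (three tones at f1, f2, f1+f2 with locked phases) is
detected by averaging *complex* bispectra over an ensemble, where
incoherent phases cancel. `average_bispectrum` therefore supports both
amplitude averaging (group-level magnitude comparison of beats) and
complex averaging (coupling detection); the tests show a >50% drop of the
ensemble-mean amplitude at the coupled bin when the phase lock is broken.

## Features

Fifteen features per (beat, lead, mode); bispectral features read the
mode's amplitude matrix, the others the mode's time series.

| feature | definition | notes |
|---|---|---|
| brightness | Σ_{i,j≥F} ω / Σ ω | cutoff F = 120 Hz |
| flatness | geometric/arithmetic mean of ω | see ε note below |
| roll-off | max F with Σ_{i,j≤F} ω ≤ 0.95 Σ ω | returned in Hz |
| entropy | −Σ p log p, p = ω/Σω | natural log |
| squared entropy | −Σ q log q, q = ω²/Σω² | |
| sum log amp | Σ log ω | ε-floored |
| sum log diag | Σ_k log ω(k,k) | ε-floored |
| diag moment 1 | Σ_k k·log ω(k,k) | |
| diag moment 2 | Σ_k (k − m₁)²·log ω(k,k) | m₁ is the moment-1 value, taken literally |
| PSD peak | max of Burg AR(16) spectrum | 512-point grid on [0, fs/2] |
| ApEn | Φᵐ(r) − Φᵐ⁺¹(r), self-matches included | m = 2, r = 0.2·SD |
| FuzzyEn | ln φᵐ − ln φᵐ⁺¹, membership exp(−(d/r)ⁿ), n = 2 | mean-removed templates |
| SampEn | −ln(A/B), self-matches excluded | Chebyshev distance |
| PermEn | ordinal-pattern entropy / ln(order!) | order 3, delay 1, stable ties |
| LZC | c(n)·log₂(n)/n, LZ76 parse of median-binarized signal | |

Conventions worth recording:

* **ε floor**: log-based features floor amplitudes at ε = 1e-12 because
  the triangle complement of the stored quadrant is exactly zero. A side
  effect is that flatness (whose geometric mean shares the floor) is
  scale-invariant only on strictly positive matrices; on matrices with
  floored zeros the floor does not scale with the signal. Brightness,
  roll-off and both entropies are exactly scale-invariant.
* **Burg recursion**: implemented as the textbook lattice recursion
  (reflection coefficient from forward/backward prediction errors,
  σ²_m = σ²_{m-1}(1 − k²_m) from σ²₀ = mean(x²)). The AR coefficients
  agree with statsmodels' Burg to machine precision; the residual-variance
  normalization is pinned to the textbook form so the PSD peak has a
  single well-defined value. A noiseless sinusoid drives σ² numerically
  to (slightly below) zero; it is floored at the smallest positive double.
* **LZ76 convention**: phrases are counted when they first become
  irreproducible from the history (overlap allowed); a trailing phrase
  still reproducible when the string ends is not counted, so a constant
  string has complexity 1. Under the c·log₂(n)/n normalization random
  strings score ≈1.
* **SampEn degenerate case**: when no template matches exist at either
  length (constant or near-constant modes) the value is undefined; 0 is
  returned and the vector flagged degenerate rather than aborting.
* Entropy parameters m = 2, r = 0.2·SD, permutation order 3 are the
  standard literature defaults.
* Features are computed per beat, not averaged per subject, matching a
  beat-level classification design.

Every feature has an independent loop-level oracle in the test suite
(direct transcription of the definitions, no vectorization); implementation
and oracle agree to 1e-9 on 100 random small inputs.

## Classification

Per lead and decomposition method, the 5 selected modes × 15 features are
concatenated to a 75-column vector per beat. Stratified 10-fold
cross-validation; features standardized with training-fold statistics only
(leakage checked in a test by reproducing the fold-wise path externally).
Classifier defaults, all configurable: logistic regression (L2, C = 1),
SVM (RBF, C = 1, scale bandwidth), decision tree (Gini, unlimited depth),
random forest (100 trees), KNN (k = 5, Euclidean). Metrics per fold: ACC,
SEN, SPE, PPV, NPV (a ratio with a zero denominator is reported as NaN,
never fabricated) and AUC as the rank statistic (ties count half), equal to
the all-pairs comparison probability.

The fold unit is the heartbeat. Beat-level splitting leaks subject
identity between folds — beats of one subject appear on both sides — so
accuracies are optimistic relative to a subject-held-out design; the
grouping is configurable and subject-level splits are recommended for any
claim about generalization to new subjects. This caveat applies equally to
the synthetic experiments here.

Shapley attributions use the sampling estimator: for each instance,
marginal contributions are averaged over random feature-subset
permutations with out-of-subset features replaced by background-set draws.
The estimator satisfies local accuracy (attributions sum to
score − expected background score) and the dummy property up to
Monte-Carlo error, both asserted.

## Classifier comparison statistics

Each classifier contributes 10 fold observations of a 12-dimensional
vector (one metric across leads). One-way MANOVA uses Wilks' Λ =
|W|/|W+B| with Rao's F approximation (the statistic reduces exactly to
one-way ANOVA for one dimension, and to the Hotelling relation
T² = (n₁+n₂−2)(1−Λ)/Λ for two groups — both asserted, plus a cross-check
against statsmodels' MANOVA). Post hoc: two-sample Hotelling T² with
pooled covariance for each of the 10 classifier pairs, F =
T²(n₁+n₂−p−1)/((n₁+n₂−2)p), Bonferroni-adjusted across exactly those 10
pairs. Type-I error of both tests is calibrated by simulation in the
suite (rejection rate 0.05 ± 0.03 under the null).

Group baseline tables are compared from summary statistics alone:
pooled-variance two-sample t-tests for mean ± SD rows and Yates-corrected
chi-square tests for 2×2 count rows. The Yates correction and pooled (not
Welch) variance are deliberate: they are the variants that reproduce the
published reference p-values from rounded summaries; with summaries
rounded to 2 decimals a third-decimal disagreement can remain (one such
row is excluded from the checks for exactly that reason).

## Synthetic data generator

Each record is built from two latent source waveforms — sums of five
Gaussian bumps (P, Q, R, S, T) with fixed relative timings/widths on an RR
grid — mixed into 12 leads by a fixed 12×2 matrix with per-lead sign
variation. Defaults describe the study conditions: 1000 Hz, ~70 bpm with
±5% multiplicative uniform RR jitter, per-beat gain jitter of 3%, 0.05 mV
power-line interference at 50 Hz, 0.10 mV baseline wander at 0.25 Hz, and
0.02 mV white muscle noise. The default dataset is 20 subjects per class,
10 beats each; the pipeline-level experiments use 10+10 subjects × 20
beats × 2 leads, a scale chosen so the full chain (detection →
VMD → features → 5 classifiers × 10-fold CV) completes in minutes on one
CPU while leaving ~360 beats per lead for cross-validation.

The between-class effect has two independently switchable knobs:

* an amplitude scale on class-B beats (default 1.3×), the analogue of a
  between-group difference in bispectral amplitude magnitude (which scales
  cubically with beat amplitude); and
* a quadratic phase-coupled triple (tones at 25, 40 and 65 Hz with locked
  phases) injected with class-dependent strength (0.02 mV vs 0.10 mV).

Morphology randomness (RR grid, beat gains, coupling phases) is drawn from
a class-independent stream keyed by (seed, subject index), while noise is
keyed by (seed, class, subject index). Consequently the *null* effect
(scale 1, equal coupling strengths) produces class-conditional signals
that are identical before noise — a sharp null for calibration tests —
and generation is bit-reproducible given (seed, class, subject index).

What the generator does *not* emulate: pathology-specific
electrophysiology, realistic lead fields, rhythm disturbances,
non-stationary noise, electrode artifacts, inter-subject morphology
variability beyond the two latent sources. Passing the end-to-end tests
therefore shows the machinery is correct and sensitive to the engineered
bispectral class difference at realistic noise levels — not that the
pipeline separates real patient groups.

## Numerical conventions and degenerate inputs

0-based indexing throughout; beats cover [r−300, r+300] inclusive.
Constant signals: correlation is undefined (NaN, excluded from means with
a log entry); SampEn undefined (0 + degenerate flag); notch/median stages
pass constants through unchanged. All-zero bispectra return
brightness/flatness/entropies of 0 with the degenerate flag. Undefined
classification ratios are NaN and excluded from comparisons with a logged
warning. MANOVA raises on singular within-group scatter (suggesting
dimension reduction) rather than silently pseudo-inverting.

## Known limitations

* The 601-sample beat window presumes 1000 Hz sampling.
* Beat-level cross-validation leaks subject identity (see above).
* Single-segment bispectrum estimates are high-variance; per-beat features
  inherit that variance and rely on the classifier to average over beats.
* EMD mode count varies per beat; beats with fewer than the selected five
  modes are dropped from the feature table (with a logged count) rather
  than imputed.
* The correspondence analysis is descriptive; no inferential test is
  attached to the factor loadings.
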