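# Methods

This note documents the models, conventions and numerical choices behind
`hdsig`, and what its synthetic cohorts do and do not demonstrate.

## Problem setting

The package targets epoch-level binary classification of Huntington's disease
(HD) status from three simultaneously recorded biosignals per participant —
16-channel EEG (10–20 montage, 1 kHz), single-channel ECG (1.2 kHz) and
22-channel fNIRS (11 optodes × HbO/HbR, 31.25 Hz) — in a cohort structured as
15 symptomatic carriers (SHD), 12 pre-symptomatic carriers (PHD), 36 controls
and 6 unclassified participants. SHD/PHD map to label 1; controls and
unclassified (whose preliminary features resembled controls) map to 0.

## Preprocessing

Each recording is band-pass filtered with a zero-phase Butterworth filter
(order 5, applied forward–backward with `scipy.signal.sosfiltfilt`):
EEG 0.5–45 Hz, ECG 0.05–100 Hz, fNIRS 0.2–1.5 Hz. Order 5 was chosen so the
doubled-magnitude response meets the attenuation contract the package tests:
a 10 Hz sinusoid passes within 1 % RMS, a 60 Hz sinusoid is attenuated to
6 % (a 4th-order filter leaves 11 %), and the response at twice the upper
edge and half the lower edge is below −20 dB.

Filtered signals are cut into 5 s epochs with 1 s overlap (4 s step). A
window is emitted iff its start lies at or before `duration − step`, and a
trailing deficit is zero-padded; this is the unique convention under which a
1200 s recording yields exactly 300 epochs (the last window, starting at
1196 s, is padded by 1 s). Epochs whose peak-to-peak amplitude on any channel
exceeds a per-modality threshold (EEG 500 µV, ECG 5 mV, fNIRS disabled;
config-exposed, since no principled criterion is fixed by the problem) are
dropped, then each channel of each epoch has its own mean subtracted.
Rejection precedes normalization; normalization is per-epoch because epochs
are created first and a per-recording mean would reintroduce offsets into
padded windows.

## Feature taxonomy

Per channel and epoch (26 features for EEG/ECG channels, 23 for fNIRS):

* **Hjorth parameters.** activity = var(x); mobility = √(var(Δx)/var(x)),
  the RMS angular frequency in rad/sample; complexity =
  mobility(Δx)/mobility(x). Zero-variance signals return (0, 0, 0).
* **Statistical.** Excess kurtosis and skewness (biased moment estimators,
  0 for constant signals), coefficient of variation SD/(mean + ε) with
  ε = 10⁻¹², and mean/max of |Δx| and |Δ²x|. The CoV guard matters because
  features are computed after mean subtraction; the resulting values are
  large but finite and scale-consistent across epochs.
* **Slope.** Mean and variance of Δx·fs (units/s), plus the Higuchi fractal
  dimension: normalized curve lengths L(k) averaged over the k offsets for
  k = 1..kmax (default 10, the common EEG choice), least-squares slope of
  log L(k) vs log(1/k). Exactly 1 for a line; → 2 for white noise. A
  constant signal has all L(k) = 0 and returns NaN, imputed as 0 (with a
  logged count) before modelling — tree ensembles tolerate the sentinel.
* **Wavelet.** Single-level DWT (coif1 for EEG/fNIRS, db4 for ECG) with
  periodization boundary handling, which keeps the orthogonal transform
  energy-preserving: approximation + detail energy equals Σx² to machine
  precision. Per coefficient set: mean, SD, energy ΣC², and Shannon entropy
  −Σ pᵢ log pᵢ with pᵢ = Cᵢ²/ΣC² (0·log 0 := 0). One decomposition level
  gives exactly 8 wavelet features per channel, matching the taxonomy's
  counts (e.g. 128 = 8 × 16 for EEG).
* **Welch band powers.** Hann window, 50 % segment overlap, constant
  detrend; segment length 1 s for EEG/ECG, the full 5 s epoch for fNIRS
  (31.25 Hz over 5 s is too short to split while resolving the 0.2–0.6 Hz
  respiration band). Band power is the trapezoidal integral of the PSD over
  in-band frequencies [lo, hi). Bands: EEG δ 0.5–3.5, θ 3.5–7.5, α 7.5–13,
  β 13–30, γ 30–45 Hz; ECG 0.05–6, 6–11, 11–16, 16–20, 20–100 Hz; fNIRS
  respiration 0.2–0.6 and cardiac 0.6–1.5 Hz.

With the full montage this is 26·16 + 26·1 + 23·22 = 948 features per epoch,
decomposing into statistical(+slope) 160/10/220, Hjorth 48/3/66, wavelet
128/8/176 and PSD 80/5/44 across EEG/ECG/fNIRS. The three modalities'
epochs are aligned by index and truncated to the shortest modality's count
(mismatches beyond 5 % are an error).

## Classification

Six shallow families (Extremely Randomized Trees, Random Forest,
polynomial-kernel SVM, logistic regression, LDA, QDA) are evaluated with
patient-grouped 10-fold cross-validation: all epochs of a patient share one
fold, so subject identity can never leak across the train/test boundary.
Patients are shuffled with the split seed and dealt round-robin,
class-stratified when labels are available. Stratification matters for the
pooled metrics below: without it, each test fold's class mix is mirrored by
an opposite shift in its training prior, and pooled out-of-fold
probabilities acquire a pessimistic bias (we measured mean pooled AUC ≈ 0.33
under a pure-noise null with 20 patients; stratified, the same setup gives
0.500 with range [0.455, 0.535] over ten seeds).

Metrics (accuracy, precision, recall in percent; ROC-AUC; F1) are computed
on the pooled out-of-fold predictions — the stabler convention for a single
reported number per model — with per-fold blocks available via a flag.
ROC is a threshold sweep with trapezoidal area (numerically identical to the
Mann–Whitney rank statistic, which the tests assert to 10⁻⁹); the PR area
uses step interpolation. Scores are class-1 probabilities where the model
provides them and the decision function otherwise; the prediction threshold
is 0.5. Hyperparameter defaults mirror the common library defaults (100
trees, Gini; SVM poly degree 3, C = 1; L2 logistic regression; unshrunk
LDA/QDA); the tuned tree specs use n = 1000 estimators, and a seeded random
grid search is provided. Class imbalance (27 vs 42) is left unweighted.

## Feature statistics and importance

Per-feature significance comes from one joint OLS of the binary label on the
z-scored feature matrix plus intercept (a single multivariate fit is what
global R²/F/log-likelihood diagnostics presuppose; a marginal per-feature
mode is available). t values are β/SE with two-sided p from the t
distribution; Gaussian-error OLS conventions throughout; no
multiple-testing correction — binned counts use raw p thresholds
(p = 0 literal, < 0.001, < 0.01, < 0.05, ≥ 0.05, first match wins). When a
cohort has fewer epochs than features the joint fit is refused unless the
caller supplies a feature subset (or a seeded random `max_features` draw) —
on desk-scale cohorts significance calibration is assessed on a subset, as
the regression is otherwise unidentified.

Grouped importance fits one seeded ERT on all epochs; per-feature
importances are mean decrease in impurity normalized to sum to one. Group
means are averages of member features' importances over four groupings
(feature family, signal type, EEG channel, EEG PSD band), and the ±1 SE is
the standard error of the per-tree group means across the ensemble's trees
(a single fitted ensemble is the stated setting, so across-tree spread is
the available dispersion measure).

## Synthetic cohorts

The generator emulates the cohort's structure (counts 15/12/36/6, 1200 s,
native sampling rates) and the qualitative class contrasts the analysis
assumes: reduced low-frequency EEG amplitude in HD, less periodic HD heart
rhythm, and looser HbO/HbR coupling in HD.

* EEG channels are sums of five band-limited oscillations — narrowband
  Gaussian noise synthesized in the frequency domain with exact per-band RMS
  (δ 20, θ 15, α 10, β 5, γ 2 µV sinusoid-equivalent amplitude, a roughly
  1/f profile at physiological scale) — plus 5 µV white sensor noise. HD
  scales the δ/θ RMS by `eeg_lowband_amp_ratio` (default 0.6), so HD delta
  band power is the control's × ratio².
* ECG is a PQRST-like train of Gaussian bumps (R ≈ 1 mV) at ~1.1 Hz whose
  beat intervals jitter with SD 0.02 s (controls) vs `ecg_period_jitter_sd`
  (default 0.06 s) in HD.
* fNIRS optodes carry band-limited (0.2–1.5 Hz) slow oscillations; HbO and
  sign-inverted HbR share a common component with coupling 0.9 (controls)
  vs `fnirs_coupling_rho` (default 0.5) in HD.

Effect magnitudes are free parameters — the underlying study reports no
effect sizes — chosen so the contrasts are visible to the feature set
without being degenerate; they are the conditions under which the package's
behavioural checks run, not estimates.

The choice of *stochastic* band oscillations is deliberate. Any
deterministic per-patient waveform (fixed sinusoids with patient-specific
phases, say) makes epoch features almost constant within a patient, i.e.
patient-identifiable; grouped CV then reads patient identity as spurious
class signal, and under a null configuration the classifier's AUC and the
OLS p-values decalibrate badly. Narrowband noise has correlation time of
order the reciprocal bandwidth — far below the 4 s epoch step — so epochs
mix, and under the null (ratio 1, equal jitter, equal coupling) patients
are exchangeable: ERT pooled AUC sits near 0.5 and about 5 % of features
fall below p = 0.05.

That is also the main caveat. Real recordings *do* carry strong
patient-level idiosyncrasies (anatomy, electrode placement, skull
conductivity), within-patient correlation across epochs, artifacts
(blinks, motion, line noise) and realistic ECG morphology, none of which
the generator reproduces. Passing null-calibration here validates the
pipeline's statistical machinery, not the claim that raw OLS p-values
would be calibrated on a clinical cohort; with patient-level random
effects they would be anti-conservative.

Determinism: patient *i* of a cohort is generated from
`numpy.random.default_rng([seed, i])` — a seed-sequence key rather than
`seed + i`, so distinct (seed, index) pairs never collide — making every
patient independently reproducible and cohorts bit-identical across runs.

## Problem sizes used in tests

Desk-scale runs use the full montage (channel counts are what the
feature-space structure depends on) with 60 s recordings, EEG/ECG resampled
specs of 250/300 Hz, and 20 patients (5 SHD, 5 PHD, 10 controls), giving
300 epochs of 948 features per cohort — small enough for a complete
pipeline run in tens of seconds while preserving every structural property
of the clinic-scale configuration. Clinic-scale structure (69 patients,
1200 s, native rates) remains available via `clinic_scale_config()` /
`scale: clinic`. Null-calibration checks average three desk-scale cohorts;
the OLS calibration uses a 150-feature random subset (300 epochs cannot
identify 948 joint coefficients).

## Known limitations

* The generator's realism limits are described above; in particular,
  fNIRS coupling is a cross-channel property that per-channel features do
  not see, so `fnirs_coupling_rho` shapes the signals but not the current
  feature matrix.
* The printed-zero p-value bin depends on double-precision underflow in the
  t-distribution tail; it is exact but platform-convention-bound.
* LDA/QDA fall back to pseudo-inverse behaviour on singular within-class
  covariances (the library convention) and emit warnings that the CV driver
  suppresses.
* With fewer than ~2 patients per class per fold, grouped CV metrics are
  dominated by patient-level sampling noise; desk-scale metric values
  should be read as behavioural checks, not performance estimates.
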