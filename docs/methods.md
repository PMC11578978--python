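# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package, in the spirit of a statistical-software
methods appendix. Everything stated here is computed by the code; nothing
is asserted that the test suite or `scripts/acceptance.py` does not
verify at run time.

## 1. Synthetic cohorts

### 1.1 Feature-level generator

`simulate_feature_cohort` draws one feature vector per subject from
per-group target moments (`adhdm.moments.published_moments()` ships the
published 29 TD / 69 ADHD baseline table as defaults). Strictly positive,
right-skewed parameters — SDNN, RMSSD, PLF, PHF, LF/HF (and extended
variants), stdPAT, stdTonic, mPhasic, stdPhasic, aucPhasic, EDASymp — are
drawn log-normally with (µ, σ) solved from the target mean/SD, so the raw
moments are matched exactly in expectation; all other parameters are
Gaussian. An optional correlation matrix is applied through a Gaussian
copula; it must be positive semi-definite. Gender is Bernoulli with the
published per-group male fractions (11/29 TD, 51/69 ADHD), age uniform on
7–12 years.

The published tonic-EDA means are negative in µS, which is impossible for
a raw skin conductance level; those values were evidently detrended or
re-referenced before publication. The generator treats them as plain
numeric targets and documents the unit ambiguity rather than "fixing"
them.

A stress stage adds a per-group mean shift plus within-subject noise
(0.3 × baseline SD). The shift magnitudes are not published — only
directions and significance markers — so the defaults encode the reported
qualitative pattern (similar HR/RMSSD response in both groups; larger
vagal PHF response in TD; larger tonic-EDA, respiratory-rate and finger
temperature reactivity in ADHD; lower respiratory stability in ADHD) with
magnitudes chosen once at roughly half a baseline SD. Passing tests
therefore demonstrate that the pipeline detects planted reactivity
differences of that size, not that the real effect sizes are recovered.

`apply_missingness` reproduces the published per-parameter availability:
for each parameter × group the available n is scaled from the published
cohort size to the simulated group size and the complement is masked
uniformly at random (MCAR). Real missingness was artifact-driven and
plausibly not MCAR; this is a deliberate simplification, so imputation
performance on real data may be worse than in tests.

### 1.2 Raw-signal generator

`simulate_subject_signals` renders six channels (ECG/PPG at 1000 Hz,
respiration/EDA/temperatures at 256 Hz) over an annotated baseline +
stress recording, each stage at least 120 s so two 1-minute analysis
windows exist. The generative model is intentionally the simplest one
with controllable ground truth:

- **IBI model**: constant mean IBI (60/HR) plus two sinusoidal
  modulations — 0.1 Hz (Mayer-wave band) and the respiratory frequency —
  plus optional white jitter; beat times are obtained by integration. A
  0.25 s floor guards against non-physiological intervals.
- **ECG**: a Gaussian R-wave template (σ = 10 ms) at each beat time.
  **PPG**: raised-cosine pulses placed so that the 50 %-rise fiducial
  falls exactly at beat time + configured PAT, making the PAT round trip
  exact by construction.
- **EDA**: tonic level + linear drift + Poisson sudomotor events
  convolved with a biexponential kernel (rise 0.75 s, decay 2 s) + noise.
- **Respiration**: unit sinusoid at the configured rate;
  **temperatures**: constant site levels.

All randomness derives from the subject seed through spawned
`SeedSequence` streams; identical (spec, config) inputs give bit-identical
channels. The generator does not emulate QRS morphology variants,
baseline wander, motion artifacts beyond additive noise, or
thermoregulatory dynamics — conclusions from round-trip tests are about
the correctness of the extraction chain, not about robustness to
real-world artifact.

## 2. Feature extraction

All extractors operate on non-overlapping 1-minute windows aligned to the
stage start; the stage value is the unweighted mean of valid windows, and
a feature with no valid window is missing, never zero-filled.

- **QRS detection**: 5–25 Hz band-pass, squared derivative, 50 ms
  smoothing, peak picking with a 250 ms refractory period, fiducial
  refinement to the local band-passed extremum. On synthetic templates
  fiducials land within ±10 ms of truth. An all-zero or beat-free signal
  returns an empty, flagged series.
- **Ectopic correction**: intervals deviating > 30 % from the running
  median of five are repaired — short-interval pairs that sum back to the
  local median are merged (false detection); long gaps are split into the
  nearest multiple of the local median (missed beats). The threshold is
  configurable; the value is a conventional choice, as the original
  correction rule is cited but not reproduced in the source literature.
- **HRV spectra**: instantaneous HR (1/IBI, in Hz) resampled at 4 Hz by
  cubic spline, Welch with 60 s Hann segments and 50 % overlap. Powers
  are band integrals of this HR-series spectrum (units Hz²); published
  power units ("s⁻²") are ambiguous between HR- and IBI-series
  conventions, and the HR-series convention is used consistently. PHFn is
  on a 0–100 scale. In extended mode only the HF upper edge moves (to
  mean HR in Hz / 2); the LF band is never altered. At a mean HR of
  48 bpm the extended edge coincides with the standard 0.4 Hz and the
  two modes agree to numerical tolerance (verified); below 18 bpm the
  band would be degenerate and the features are missing.
- **PPG**: Hjorth descriptors (activity, mobility, complexity) per 5 s
  window; windows outside multiplicative bounds around the recording
  median are masked. Pulse fiducials are linear-interpolated 50 %
  foot-to-peak crossings, sub-sample accurate (±5 ms on templates).
- **PAT**: each R peak is matched to the first pulse fiducial within
  (0, 600] ms; unmatched beats are skipped, never interpolated. Means/SDs
  require at least two matches per window.
- **Respiration**: unpadded boxcar periodogram; RR is the peak frequency
  in 0.1–0.6 Hz; Pk is the percentage of in-band power within
  ±max(0.015 Hz, 1.5 bins) of the peak. The boxcar choice makes a stable
  tone (integer cycles per 60 s window) concentrate in one bin (Pk ≈
  100) while an equal two-tone mixture splits to ≈ 50, cleanly
  implementing the "> 65 % = stable window" criterion; the bin floor
  tolerates off-bin leakage.
- **EDA decomposition** solves
  min ½‖y − Kp − Bℓ − Cd‖² + α‖p‖₁ + ½γ‖ℓ‖² s.t. p ≥ 0,
  where K is the biexponential convolution operator, B a cubic B-spline
  tonic basis with knots every 10 s, C an affine term. With p ≥ 0 the ℓ1
  term is linear, so the problem is a smooth bound-constrained QP solved
  with L-BFGS-B on sparse operators at an 8 Hz working rate (the kernel
  has no energy above ~2 Hz). Hyperparameters follow the published
  convex-EDA defaults (α = 8·10⁻⁴, γ = 10⁻²), configurable. The residual
  is defined as input − tonic − phasic, so the decomposition identity is
  exact by construction; driver non-negativity is enforced by the solver
  bounds. Amplitude jumps > 0.5 µS are interpolated beforehand (the
  automated stand-in for visual artifact inspection).
- **Temperature**: jumps > 1 °C between samples are interpolated; TGrad
  is the mean successive difference of the 10-s block-mean series; TPow
  the mean squared value; TRatio the ratio of window means
  (finger/face) — note ratio-of-means, not mean-of-ratios; on the
  published TD means the two differ by < 0.01.

## 3. Cohort statistics

- **Test selection**: Shapiro–Wilk per group at α = 0.05; both normal →
  Student t; otherwise, if strictly positive, a log transform is retried;
  otherwise Mann-Whitney U. Categorical variables use χ² *without*
  continuity correction — this reproduces the published p = 0.001 for the
  11/18 vs 51/18 gender table. The recorded test always matches the
  Shapiro outcomes actually computed, and the procedure is deterministic.
- **Imputation**: the source description "multiple imputation … by the
  multivariate Maximum Likelihood method" mixes two distinct procedures;
  the default here is single EM-based conditional-mean imputation on
  z-scored features (classic EM for the MVN with missing data, including
  the conditional-covariance correction in the M step), with an optional
  multiple-draw mode (draws from the conditional normal, pooled by
  averaging). On complete data the EM estimate equals the sample moments;
  observed cells are returned bit-identical. Columns under 50 % observed
  are outside the imputation model's precondition and are excluded by the
  pipeline with a log entry (with the published availability pattern this
  affects RR and Pk when group sizes mirror the original cohort).
- **Matching**: logistic propensity of class on gender and age;
  matching operates on the log propensity. TD subjects (the minority
  class) anchor the pairs. Greedy rounds process anchors in descending
  propensity order (hardest to match first — standard greedy-PSM
  practice); in each of up to `max_ratio` (default 2) rounds every anchor
  takes the nearest still-available ADHD subject within the caliper
  (default 0.2 SD of the log propensity — a common convention; none is
  published). ADHD subjects are used without replacement; ties break on
  subject id, so matching is deterministic even when all propensities
  coincide. Anchors with no admissible match are dropped with a warning.
- **Balance check**: binomial GLM of class on gender and age over the
  matched set. A pair-clustered covariance is available
  (`cluster_by_pair=True`) but is not the default: with ~27 clusters of
  size 2–3 the sandwich estimator is strongly anti-conservative and the
  exchangeable-GEE variant is numerically unstable, so the model-based
  covariance is used.
- **VIF**: VIF_j = 1/(1−R²_j) by direct OLS of each candidate on the
  others; the largest is dropped iteratively while any exceeds the
  threshold (default 5; no threshold is published). Perfect collinearity
  yields an infinite VIF and is dropped first.

## 4. Classifier and evaluation

- **Design preparation**: RMSSD, stdTonic and mPhasic are
  log-transformed; all physiological candidates are z-scored (sample
  moments by default, explicit constants optionally). Gender and age
  enter raw — whether the original analysis z-scored them is not stated,
  and the standardization-constant mechanism supports either convention.
- **Stepwise fit**: ML logistic regression; the non-forced term with the
  largest Wald p > α is removed and the model refit until all remaining
  non-forced terms are significant; gender and age are never removed.
  Quasi-complete separation (|coef| > 50 or undefined standard errors)
  raises an error naming the offending term.
- **Default candidate set**: PAT/stdPAT (few real observations) and the
  temperature parameters (large basal group differences) are excluded, as
  are the extended-band duplicates of the standard HRV indices;
  configurable.
- **ROC/Youden**: AUC by the rank (Mann-Whitney) formulation with
  midrank tie handling; the Youden cutoff maximizes sensitivity +
  specificity − 1 over midpoints between adjacent distinct scores, ties
  broken toward the lower threshold; predictions use score ≥ cutoff. AUC
  is invariant under strictly monotone score transforms (property-tested).
- **Metrics**: the five standard metrics recompute exactly from the
  integer confusion counts; display rounding is one decimal in percent.

## 5. Problem sizes and stochastic checks

The whole-pipeline checks run at sizes chosen to make Monte-Carlo noise
small while keeping the suite quick: pipeline closure uses 200 subjects
per group over 20 seeds with independent 400-subject held-out cohorts
(mean held-out AUC > 0.85 is the pass criterion; per-seed AUCs are
typically 0.92–0.95); coefficient recovery uses 100 replicates of 400
subjects and requires ≥ 90 % CI coverage per coefficient. Labels in these
checks are Bernoulli draws of the generative model's own probabilities,
so the achievable AUC is bounded by the model's intrinsic overlap, not
by the cohort's group structure. The original study's in-sample AUC of
0.95 on 76 children is not reproducible without the original recordings;
the closure property substitutes a self-consistency claim: the design
pipeline recovers a working classifier when its own generative
assumptions hold.

## 6. Known limitations

- Feature marginals are matched per group, but the true cross-feature
  correlation structure of the original cohort is unknown; by default
  features are drawn independently (copula optional), which weakens
  multivariate effects such as the VIF step relative to real data.
- The raw-signal generator's fiducial templates are idealized; detector
  tolerances (±10 ms QRS, ±5 ms pulse) are verified on these templates
  only.
- EDA solver accuracy depends on the L-BFGS-B convergence tolerances;
  with the defaults the driver recovers planted event amplitudes within
  ~35 % and the residual RMS stays at the injected noise level.
- The published model's standardization constants are reconstructed, so
  absolute scores for real subjects may be shifted relative to the
  original implementation; rankings are unaffected by monotone shifts of
  the linear predictor only when a single predictor moves, so users with
  their own cohort should refit or supply their own constants.
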