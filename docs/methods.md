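# Methods

This note records the models implemented, the assumptions behind them,
the defaults that matter, and the design choices made where more than
one faithful reading existed.

## Data model

A `FeatureTable` is a samples × features abundancy matrix with sample
metadata (batch, age in fractional years, sex, class ∈ {control,
patient, qc}, triplicate id) and feature metadata (ion mode, m/z,
retention time, optional annotation, neutral mass, isotope
distribution, MS/MS peak list, internal-standard flag).  Missing
measurements are explicit `NaN`, never zero: an unmatched feature in
one batch is information about the matching process, not a zero
concentration.  On disk a table is two flat CSVs (samples + feature
metadata), inspectable with any tool.

## Initial transforms

Features may be log-transformed or Box–Cox transformed,
ŷ = ((y + λ₂)^λ₁ − 1)/λ₁ with λ₁ = 0.5, λ₂ = 1.  Method labels follow
the `{None,Log,BC}-{Method}` convention.  Multiplicative technical
variation becomes additive under the log, which is what both the mixed
model and the variance-based metrics assume; Box–Cox at λ₁ = 0.5 is a
weaker compromise.  The internal standards receive the same transform
as the features before latent-variable extraction (the alternative —
raw IS against transformed features — breaks the linearity the mixed
model relies on).

## Metchalizer

**Assumption.** All variation in a feature that is explainable by the
internal standards is technical.  The IS are spiked at fixed known
concentration into every sample, so their abundance tracks injection
volume, ionization drift and batch state, not biology.

**Latent variables.**  The ten IS are correlated, so they are
represented by orthogonal latent variables from a PLS2 regression of
the standardized IS matrix on one-hot batch membership.  The LV count K
is chosen from I(K) = Σ_{k≤K} Σ_{b,i} (x_ib^LVk − x̄_b^LVk)², the
cumulative within-batch dispersion of sample scores: the smallest K
reaching 75% of I(K_max).  Because PLS deflates variance in order, the
curve saturates quickly; typical selected K on simulated data is 1–3.

**Mixed model.**  Per feature, a random-intercept model with the LV
scores as fixed effects and batch as the grouping factor, estimated by
REML (statsmodels `MixedLM`).  Before fitting, samples with
within-batch |Z| > 2 (Z from that batch's per-feature mean/SD) are
removed; batches retaining fewer than 3 samples keep a zero intercept
with a warning.  Numerical handling, in order:

1. if the fixed-plus-batch-dummy OLS fit is (near) exact
   (residual variance < 1e−16 of the response variance), its
   sum-to-zero-contrast solution is used directly — this is the limit
   of the BLUPs as residual noise vanishes, where REML itself is
   degenerate;
2. otherwise REML via BFGS, retried with Powell if the random-intercept
   variance lands on the zero boundary (the L-BFGS optimizer in
   statsmodels stops there spuriously on roughly half of realistic
   features, which Powell resolves);
3. a genuinely zero variance falls back to OLS with all γ = 0.

A singular fixed-effect design raises, naming the feature.  Fits are
per feature and independent: results do not depend on feature order.

**Correction.**  corrected = y − ŷ + median(ŷ_·j).  The recentering
median is taken over all samples by default; the per-batch variant is
available (`recenter="per_batch"`) but re-adds a batch-specific
constant and therefore partially undoes the correction, so it is not
the default.  Samples excluded as outliers during fitting are still
corrected.  Internal standards pass through transformed but
uncorrected.

## Baseline normalizers

*Best-correlated IS*: per feature, within-batch Spearman correlations
with each IS averaged across batches; the best positively correlated
standard m is used as ŷ_ij = y_ij / y_im · median(y_·m).  When no IS
correlates positively the feature is left unnormalized with a warning
(dividing by an anti-correlated standard would amplify variance).
*Anchor*: per batch, division by the mean of the anchor samples (the QC
replicates by default).  *PQN*: per sample, division by the median
quotient against the median reference spectrum.

## Evaluation metrics

Six metrics score a normalized table using the QC replicates (a fixed
commercial plasma sample repeated in every batch) and, when available,
quantitative concentrations:

1. **WTR score** per feature: the ratio of within-batch to total QC
   variance.  The within-batch component is estimated as the pooled
   within-batch variance (Σ_b Σ_i (y_bi − ȳ_b)² / (N − B)) over the
   total (N−1) variance, clipped to [0, 1].  The algebraically
   equivalent population identity (σ²_tot − σ²_between)/σ²_tot with
   σ²_between the plain variance of batch means is available as
   `estimator="between"`, but as an estimator it is biased low by the
   sampling noise of the batch means — its expectation cannot exceed
   1 − 1/m for m replicates per batch even under perfect correction —
   so the pooled form is the default.
2. **QC correlations**: Spearman correlation over features for every
   unordered QC pair.
3. **Spearman score** and 4. **R² score** per quantified metabolite
   between normalized abundancies and µmol/L concentrations.
5. **QC prediction score** and 6. **batch prediction score**: PCA
   (centred, unscaled) on all features excluding standards; L1
   logistic models on the first four PCs predict QC-vs-plasma (score
   should stay near 1) and each batch one-vs-rest on plasma samples
   (score should drop toward the class prior after normalization).
   Fitted in-sample probabilities are averaged; no cross-validation
   (the scores are descriptive, not generalization estimates), with a
   fixed solver seed and C = 1 by default.

## Reference populations and Z-scores

Reference candidates are the control samples.  Before a reference set
is formed, outliers are removed by five iterations of |Z| > 3 filtering
(mean/SD recomputed each round, so masked outliers emerge).  Strategies:

- **15in / 15out**: 15 controls matched on age and sex from the
  patient's own batch / from the other batches.  Matching takes
  same-sex candidates in order of |Δage| first, relaxing to the
  opposite sex only when the same-sex pool is exhausted; ties break on
  sample id, so selection is deterministic.
- **All samples**: every control, ignoring age and sex.
- **Regression**: per feature, OLS of abundancy on
  [1, sex, sex·age, age, age², age³] (sex coded 1 = female).  Residual
  variance is age-dependent: σ̂²_i is a kernel-weighted mean of squared
  residuals with weights exp(−|ageᵢ − age_k|/(a + b·ageᵢ)), a = b = 1
  year — weights decay over about a year in infancy and over decades in
  adults, matching how metabolite reference ranges tighten at young
  ages.  The coefficient covariance is the sandwich
  (XᵀX)⁻¹Xᵀdiag(σ̂²)X(XᵀX)⁻¹, and the prediction variance
  Var[ŷ(x)] = xᵀCov x + σ̂²(age).  The Z-score divides by
  √Var[ŷ]; dividing by the variance itself (`z_scale="variance"`) is
  available but produces non-unit-variance scores, and the plotted
  SD bands of such models imply the square-root convention.  The same
  kernel parameters serve training-sample variances and patient-age
  evaluation.  Single-sex cohorts drop the sex terms and are flagged.

Patients are technical triplicates; the final Z is the triplicate mean.
p-values: the standard Welch t-test of the three replicate Z-scores
against the reference population's Z-scores for 15in/15out/All; for the
regression strategy, where the reference mean is exactly 0 with
negligible variance, the adjusted statistic t = mean(Z)/√(s²/3) is
referred to a t distribution with 2 degrees of freedom (the
triplicate's n − 1; a normal reference is available behind a flag).

**Coefficient inference.**  Robust p-values are the median over 50
refits on 90% subsamples drawn without replacement, each using the
two-tailed normal p of β̂/√Var[β̂]; per-feature seeds derive from a
master seed.  Significance tables apply Benjamini–Hochberg separately
per coefficient and ion mode, optionally gated on a linear-age effect
size (|β̂₁| as percent of the predicted abundancy at the cohort median
age per year; threshold configurable, 2%/year conventionally).

## Biomarker detection

An expected biomarker is *positive* when |Z| exceeds the threshold and
the sign matches the expected direction (p-value mode thresholds the
Welch p, with the same sign requirement).  A biomarker resolvable in
both ion modes uses the mode with the larger population-average raw
abundancy.  Sweeping the threshold (200 points over [0, 8] for Z,
logarithmic over [1e−12, 1] for p) yields a curve of detected expected
biomarkers against the mean number of positive features per patient;
the AUC is trapezoidal with the x-axis rescaled to [0, 1] by its
maximum, so AUCs are comparable across strategies and are reported as
percentages of a reference curve.  The normalization convention makes
absolute AUCs convention-dependent; only relative AUCs are meaningful
across implementations.

## Synthetic data

The generator emulates a nine-batch plasma study: 18–40 controls and
5–9 QC technical replicates per batch, patient technical triplicates,
ten internal standards.  Abundance is multiplicative:

    y = concentration(age, sex) × sample_technical × batch_factor × noise

- `sample_technical` is one log-normal scalar per sample shared by all
  features and standards (the injection-volume analogue).
- `batch_factor` is log-normal per batch × feature group (3 groups by
  default), with log-SD set from a between-batch CV of 27%; within
  technical variation defaults to a 14% CV split between the sample
  scalar (10%) and measurement noise (10%).
- Internal standards experience the technical terms scaled by a
  coupling fraction (default 0.9): the share of technical variation an
  IS actually reports.
- A configurable fraction of features (default 0.25) carries a
  polynomial age trend of random degree ≤ 3 in log space (coefficients
  drawn on scaled age so a cubic never dwarfs the baseline); a small
  fraction carries a sex effect.  Ages are log-uniform on [0.1, 80]
  years to stress the young-age regime where trends are steepest.
  Optionally the measurement-noise SD grows linearly with age
  (`age_noise_slope`) to exercise the heteroskedastic variance model.
- QC samples follow a distinct fixed concentration profile (no age/sex)
  and differ only by technical terms, like a commercial plasma pool.
- Spiked biomarkers multiply a patient triplicate's concentration of a
  chosen feature by 8× (up) or 1/8 (down) by default.

`simulate_split_batches` turns a merged table back into per-batch
tables with renamed feature ids, RT drift and m/z ppm jitter applied at
*exactly* the requested magnitude (random sign), so matcher gates can
be tested right at their thresholds; true correspondences are recorded.

What the generator does **not** emulate: chromatographic peak shapes,
adduct/isotope deconvolution, missing features (unmatched within a
batch), retention-time nonlinearity within a batch, inter-individual
biological covariance between metabolites, and storage or
batch-composition confounding.  Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
performance on any particular instrument's data.

## Matching conventions

The thresholds themselves are standard (cosine > 0.8, RT < 3%, isotope
bins < 25 points, median < 300%, < 1 ppm); three details are
convention choices, all configurable:

- RT percent difference uses the mean of the two RTs as denominator;
  the median-abundancy percent difference uses the smaller median (so
  "< 300%" admits up to a 4-fold ratio).
- A shared annotation is sufficient on its own; otherwise RT and
  median gates always apply, the cosine gate applies when both sides
  have MS/MS, the isotope gate when both have distributions, and the
  ppm gate (neutral mass, else m/z) only when MS/MS is absent.
- MS/MS cosine pairs peaks greedily by nearest m/z within 0.01 Da and
  L2-normalizes intensities.

A candidate prefilter (|Δm/z| ≤ 0.05 Da, RT within 10%) bounds the
pair search; annotation-equal pairs bypass it.  Features with two or
more passing partners on either side are excluded as ambiguous, never
guessed.

## Problem sizes and determinism

The test suite and the acceptance script run simulations at 3–9
batches, 30–110 features and up to ~2000 control samples; these sizes
give stable pass/fail behaviour for every property checked while
keeping a full run in tens of seconds on one CPU.  All stochastic
stages are seeded; the pipeline derives per-stage seeds by stable
hashing of stage names from one master seed, so adding a stage does not
reshuffle the others.

## Known limitations

- Metchalizer interprets *any* batch-level variation unexplained by the
  LVs as technical; genuine biological differences between batch
  cohorts would be removed too.  Randomizing samples over batches is a
  design prerequisite, not something the model can recover.
- Features absent from some batches cannot be corrected by the
  intercepts of batches where they were never observed; the merge keeps
  only fully matched features.
- The bootstrap-median p-value is approximately, not exactly,
  calibrated (subsamples overlap); the type-I error check in the test
  suite bounds it empirically at around the nominal level.
- In-sample prediction scores flatter strongly regularized models; they
  are comparative metrics between normalizations, not absolute
  classifier performance.
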