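# Methods

This note documents the models the package implements, the defaults it
chooses where the field protocol leaves them open, what the synthetic scene
generator does and does not emulate, and the numerical conventions a user
needs to reproduce a run exactly.

## Spectra handling

Reflectance is stored as a fraction in [0, 1] on a strictly increasing 1-nm
integer grid inside 350–2500 nm. Percent-scale exports are auto-detected
(table maximum > 1.5) and divided by 100 with a logged warning; inputs on
other grids are rejected rather than resampled, so index inputs are never
silently interpolated. Repeated scans per plot are combined by the
arithmetic mean per wavelength (idempotent on averaged data).

Noise deletion removes wavelengths inside configurable inclusive regions;
the defaults — 350–399, 1350–1480, 1800–1980, 2401–2500 nm — are the
detector-edge and atmospheric water-vapour windows typical of field
ASD-class spectroradiometers. Trimming is pure column selection: retained
values and metadata are untouched.

## Spectral reflectance indices

The registry covers every index the benchmark report references, in three
kinds: normalized differences (Ra − Rb)/(Ra + Rb), simple ratios Ra/Rb, and
explicit expressions (MTCI, SAVI2 variants, TCARI/TCARI2, MCARI, DATT, SIPI,
PRI·CI, …). Expressions are plain text compiled once with sympy; the
registry round-trips through a line-oriented text format and is user
extensible through the `ndsi(a; b)` / `sr(a; b)` constructors.

A few referenced indices have no unambiguous literature formula at their
cited bands; the registry instantiates standard forms and records the
provenance in each entry's note: WDVI = R₈₃₀ − 1.06·R₆₆₀ (soil-line slope
1.06), BI = √((R₄₆₀² + R₆₆₀²)/2) (brightness form), AI as the
double-difference (R₇₄₀ − R₆₉₁) − (R₈₈₇ − R₆₉₈), and PRI·CI as
PRI(570;530)·(R₇₆₀/R₇₀₀ − 1). Zero-denominator evaluations yield missing
values (not exceptions) so screening proceeds on degenerate spectra; an
index whose bands were trimmed produces an all-missing column plus a logged
warning.

Screening fits trait ~ index by simple least squares per column and ranks
by r² descending (ties: RMSE ascending, then name). No multiplicity
correction is applied; the number of indices tested is recorded in the
result's attrs so readers can judge the selection effect.

## Preprocessing

The canonical order is: drop rows with any missing predictor or response,
score the remainder with Local Outlier Factor (Euclidean metric on z-scored
columns) and drop scores above the threshold, then normalize inside the
model fit. LOF defaults — 20 neighbours, threshold 1.5 — are the method's
common settings, made configurable because the protocol names the method
without parameters. Outlier screening runs per modeling dataset (per
trait × stage × environment set), not on pooled data.

Normalization uses the sample (n − 1) standard deviation. Regression
pipelines z-score; classification pipelines mean-center (the only
per-family normalization detail the protocol fixes). Statistics are always
estimated on training folds and replayed on held-out folds; the leakage
test in the suite perturbs validation rows and checks that training-fold
statistics are unchanged.

## Regression

All four families share seeded 10-fold cross-validation. Hyperparameter
selection and validation metrics use the same folds (the usual chemometrics
protocol, not nested CV): for each candidate hyperparameter the pooled
out-of-fold RMSE is computed, the minimizer is kept, its out-of-fold
predictions supply the validation metrics, and the final model is refit on
all data. This mildly favours the selected hyperparameter; with 100–800
observations per cell the effect is small, and it keeps the comparison
aligned with how such benchmarks are normally reported.

- **PCR** — PCA on z-scored data, OLS on the leading scores. Because scores
  are orthogonal, predictions for every component count come from one
  decomposition (cumulative univariate projections). Count searched over
  1–20; reduced to the data rank with a warning when necessary.
- **PLSR** — NIPALS PLS1 (scikit-learn, scaling disabled; our z-scoring is
  applied first). X-scores are orthogonal, so truncated-component
  predictions reuse one fit per fold. Count searched over 1–20.
- **Ridge** — closed-form coefficient path over 100 penalties log-spaced on
  [10⁻², 10¹⁰], computed from one SVD per training fold
  (β(λ) = V·diag(s/(s² + λ))·Uᵀ(y − ȳ); intercept unpenalized via
  centering). Defined for any λ > 0 even with singular X.
- **SVR** — ε-insensitive regression, C = 1, ε = 0.1 fixed; candidate
  kernels linear / polynomial (degree 3) / RBF / sigmoid, each
  cross-validated, minimum CV RMSE kept. Kernel scale γ = 1/(2 m²) with m
  the median pairwise Euclidean distance of the (sub-sampled) training
  fold. A kernel that fails to train is skipped with a warning; the model
  errors only if all candidates fail.

Validation r² is the squared Pearson correlation between observations and
pooled out-of-fold predictions (not averaged per fold — stable at fold
sizes of n/10). Calibration metrics are reported alongside, labeled.

## Classification

Dichotomization is over the trait **range**, not quantiles: threshold =
min + f·(max − min) with f = 0.80 by default, computed on the modeling
dataset *after* preprocessing, per trait × stage × environment set. Values
exactly at the threshold are elite (Class 2 is the closed upper tail), so
the maximum observation is always Class 2 and the minimum always Class 1.
Labels are invariant to increasing affine transforms of the trait. Because
the cut is on the range, the elite share depends on the distribution's
tail mass — near 20% for uniform traits, less for the skewed scaled-Beta
traits the generator produces.

Folds are stratified by class (spread round-robin per label) so the rare
elite class reaches every fold — plain random folds risk empty-class folds
at 20% prevalence; the deviation from a plain partition is deliberate and
seeded. Within one benchmark cell all three classifiers share one fold
assignment so the comparison is paired.

- **PCA-LDA** — linear discriminant (class means, pooled covariance) on the
  leading PCA scores; PC count searched over 1–20 by macro CV error.
- **PLS-DA** — PLS1 regression of the 0/1 class indicator on mean-centered
  spectra; LV count searched over 1–20. Class assignment fits
  class-conditional Gaussians to the calibration scores and assigns by
  maximum likelihood with equal priors (toolbox-style probability rule);
  equal priors are what lets the minority elite class compete at 4:1
  imbalance. A plain argmax rule (indicator ≥ 0.5) is available by flag.
- **kNN** — Euclidean majority vote, k searched over 1–10. Deterministic
  tie rules: equal distances rank by training order (stable sort); tied
  votes go to the nearer neighbour's label.

The error rate is **1 − macro-averaged per-class prediction rate** (mean of
the two class sensitivities), with 1 − accuracy reported alongside: the two
coincide only for balanced classes, and only the macro definition makes
accuracy ≈ 0.8 compatible with error ≈ 0.4 at 80/20 prevalence, as the
benchmark report format requires.

## Synthetic scene generator

The generator exists so every stage is testable without field data; its
defaults are the study conditions it emulates: 384 genotypes × 2 replicates
under FI and WS, twelve trait × stage combinations with the published
per-regime ranges, means and SDs (LAI measured under FI only), and one
spectrum per plot per assessment stage.

**Traits.** Each trait × regime is a scaled Beta whose shape matches the
published mean and SD within the published range (values hard-clipped to the
range; clip rate logged). The Beta tails make the 80/20 range split
nontrivial — a uniform would pin elite prevalence at exactly 20%, a
degenerate special case. A per-plot shared "performance" factor with
trait-specific loadings (GY 0.8, Δ¹³C 0.7, Chl 0.6, …) induces realistic
positive cross-trait correlations; genotype values correlate across regimes
through a Gaussian copula (default r = 0.5, unreported in the field study,
configurable). Replicate noise defaults to 0.25 of the trait SD. Δ¹³C is
generated by simulating plant δ¹³C and applying
Δ¹³C = (δ¹³Cₐ − δ¹³Cₚ)/(1 + δ¹³Cₚ/1000). The air value is taken as
**−8.0 ‰**: sources sometimes quote "8.0 ‰" unsigned, but published Δ¹³C
values of 12–20 ‰ are only consistent with the conventional signed
atmospheric value and negative plant δ¹³C.

**Spectra.** Reflectance = f·vegetation + (1 − f)·soil + noise, clamped to
[0, 1]; soil is a smooth rising line, the vegetation endmember is built
parametrically: a visible region whose 670-nm absorption deepens and whose
red edge shifts right with the stage-matched chlorophyll trait, an NIR
plateau, an SWIR decline, and multiplicative Gaussian water wells at 970,
1200, 1450 and 1940 nm whose depth follows canopy water status (tied to
grain yield plus latent jitter, normalized over the pooled table so both
regimes sit on one physiological scale). The mixing fraction f follows
LAI (SM2 where LAI is unmeasured). Every feature has the form
baseline + coupling·(driver − 0.5), so a zero coupling pins the feature at
its baseline and makes the spectra exactly independent of that trait — the
suite verifies this in the strongest form (permuting the trait leaves the
spectra byte-identical). Band noise is i.i.d. Gaussian, σ = 0.004.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no radiative-transfer physics (PROSAIL-class
realism is a non-goal), no directional/illumination effects or
calibration drift, band noise is white rather than spectrally correlated,
the trait–spectrum link is low-dimensional (three drivers) where real
canopies have many, and there is no genotype × environment interaction
beyond the copula correlation. Absolute performance numbers on this scene
say nothing quantitative about field data; the qualitative contrasts
(pooling effect, regressor ordering, elite-recall differences between
classifiers) are what the scene is built to probe.

## Benchmark orchestration and problem sizes

Cell coordinates (trait, trait stage, spectra stage, environment set) map to
seeds by CRC32 of the coordinate string, so adding a method never shifts
another method's folds. The trait ↔ stage ↔ environment validity matrix is
data, not code. A failing cell is recorded as failed and the run continues.
The manifest (version, master seed, config, per-cell preprocessing counts
and fold seeds) suffices to replay a run bit-for-bit.

The shipped analyses and the test suite run on a reduced scene — 64
genotypes (512 spectra) with the trimmed grid thinned to every 4th band,
keeping all registry-referenced wavelengths — sizes chosen so the whole
suite completes in well under a minute of model fitting while the contrasts
of interest remain far from threshold. The generator and benchmark accept
the full 384-genotype, 1-nm configuration unchanged.

## Known limitations

- The registry implements the indices the benchmark report names plus the
  generic two-band families, not any full proprietary index collection.
- PLS-DA class priors, the SVR "minimization criterion", and the regression
  component-count search are under-specified in the field protocol; the
  choices here (equal priors, CV RMSE, 1–20 by CV) are documented above and
  configurable, but other software may differ in exactly these places.
- Validation metrics share folds with hyperparameter selection (see
  Regression); treat them as tuned-model CV estimates, not unbiased
  generalization estimates.
- `align` recognizes plot keys directly or with the generator's `@STAGE`
  suffix; exotic keying schemes need pre-alignment by the caller.
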