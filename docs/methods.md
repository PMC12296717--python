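# Methods

## Problem setting and model

The package targets two-class origin discrimination of one material
measured on four analytical platforms — LC-MS and GC-MS feature tables
and raw ¹H NMR / MIR spectra — followed by unsupervised validation on
samples from origins never used in modelling. All modelling operates on
per-platform blocks Xᵏ ∈ ℝ^(n×pₖ) sharing one sample index; a manifest
assigns each sample an origin label and a role, `model` (70 samples,
two origins) or `external` (14 samples, four further origins).

Standardization, feature selection and classifier fitting only ever see
model-set training rows. The split (default 70:30 of the model set,
stratified by origin; 70 samples → 49 train / 21 test), the
standardization statistics (per-feature mean and population sd of model
samples), and every selector are fitted once and applied unchanged to
test and external rows. This is enforced structurally — the fitting
functions take training data only — rather than by runtime hooks.

## Preprocessing

**NMR.** The chemical-shift axis is referenced by locating the tallest
point within ±0.05 ppm of 0.00 ppm (the TSP singlet) and translating
the axis so that apex sits at exactly 0.00 ppm. The referenced spectrum
is integrated into half-open buckets [b, b + w) of width w = 0.002 ppm
tiling [0.4, 12.0) ppm. A bucket's value is the **sum** of grid-point
intensities inside it (preserves integral proportionality on a uniform
grid; a mean convention would only rescale columns and be undone by
Z-scoring). Buckets overlapping the residual-water window 4.8–5.0 ppm
are dropped whole — no partial-bucket truncation — leaving
((12.0 − 0.4) − 0.2)/0.002 = 5700 buckets. Grid points lying exactly on
a bucket edge belong to the upper bucket (half-open convention); the
bucket centers are recorded as feature coordinates (`ppm_4.3210`).

**MIR.** Savitzky–Golay smoothing (default window 11 points, polynomial
order 3 — deliberate, exposed defaults: the smoothing strength is an
instrument-dependent choice, so both are `MirPipelineConfig` fields),
then vector normalization to unit Euclidean norm, then removal of the
windows 4000–3500, 2400–2200 and 500–400 cm⁻¹, treated as **closed**
intervals so boundary grid points are removed (a deterministic tie
rule). The order SG → VN → removal matters and is regression-tested:
normalizing before removal uses the full-spectrum norm, normalizing
after would use the truncated norm. SG edge handling fits the terminal
windows' polynomials (scipy's `mode="interp"`), which makes polynomials
of degree ≤ order exact fixed points everywhere, not just at interior
points. Axis units are wavenumbers (cm⁻¹) throughout.

**Standardization.** Z-score per feature with the population (n)
denominator — a declared convention, tested; with 49–70 fitting samples
the difference from n−1 is cosmetic. Zero-variance features (e.g. empty
spectral regions) are dropped with a warning so no NaN propagates.

## Fusion levels

- **LLDF** concatenates the standardized blocks; feature ids are
  prefixed with the block tag so provenance survives.
- **MLDF** reduces each block first. PCA and PLS-DA selectors keep the
  fewest components whose cumulative explained variance reaches 95%;
  for PLS-DA the criterion is cumulative **X**-variance (the package
  treats the two selectors symmetrically; a Y-variance criterion would
  almost always return one component for a two-class indicator), capped
  at 30 components with a warning when 95% is unreachable — typical for
  noise-dominated synthetic blocks. DT/RF selectors keep the top 40
  variables by impurity importance. Scores are projections, so
  PCA/PLS-DA-selected MLDF models have no original-variable ranking;
  only DT/RF-selected models are screenable.
- **HLDF** per block: a 100-tree forest over all variables keeps the
  top 120; a second forest **refit** on those 120 keeps the top 40
  carrying the refit importances. "Successive" selection implies the
  second fit, and the refit importances are what exists at merge time;
  `FusionConfig(hldf_refit=False)` reuses the stage-1 importances
  instead for comparison. Fused importance = (1/K) × Gini importance
  (0.25 for K = 4 blocks); the merged 160 are sorted by fused
  importance with ties broken by block order then original column
  index, and the top 40 train the final forest. Blocks narrower than a
  budget cap it with a warning.

A consequence of per-forest importance normalization worth knowing:
each fitted forest's importances sum to 1 regardless of how predictive
the block is, so a pure-noise block's stage-2 importances average
1/40 = 0.025 and the equal block weighting cannot down-rank an
uninformative block wholesale — the final 40 stay roughly balanced
across blocks even when all signal sits in one block. What the method
does guarantee, and what the tests assert, is that genuinely
informative variables rise to the very top of the merged ranking.

Classifier settings: SVM with RBF kernel; kNN with k = 3 and Euclidean
distance; MLP with hidden layers (500, 200, 10), Adam, max 300
iterations (the training budget is not otherwise specified anywhere, so
it is a fixed, seeded package choice recorded in `FusionConfig`);
decision tree with Gini impurity; random forest with 100 trees and the
out-of-bag estimate enabled; PCA and PLS-DA use 2 components. PCA is
made predictive as nearest-centroid in score space; PLS-DA regresses a
0/1 indicator and cuts at 0.5. All seeds derive from one global seed
via CRC32-keyed child seeds (platform- and stage-keyed, so adding a
block or model never perturbs another's stream).

## Evaluation

Per model: train/test accuracy; positive-class precision, recall and f1
on the test partition; ROC by descending-score threshold sweep with
tied scores contributing a single step, AUC by trapezoidal integration
(equal to Mann–Whitney concordance with ties counted half — asserted
against exhaustive pair counting). The positive class defaults to the
alphabetically first label. OOB is reported as out-of-bag **accuracy**
(higher is better) so all columns share the "close to 1 is good"
orientation; the error convention is simply 1 − OOB. Classifiers without continuous scores fall back to 0/1
predictions for the ROC, with a warning. Strategies are ranked by
(AUC, test accuracy) descending.

## Screening and external validation

The top k = 38 variables by fused importance are exported from the best
traceable ranking — the best model's own Gini ranking when its selector
keeps original variables, otherwise the HLDF merged ranking. The
external samples, carrying the model-set standardization, are
restricted to those variables and projected by a PCA fitted **on the
external samples themselves** (the held-out origins are unknown groups;
fitting on them asks "do these samples organize by origin at all?" —
projection through model-set loadings is available via
`project_external(..., fit="model")`). Separation is summarized by

  separation_index = mean between-group pairwise distance /
                     mean within-group pairwise distance

in the 2-D scores — rotation- and translation-invariant, guarded by a
tiny epsilon when within-group distances vanish. It is an
artifact-defined proxy for what is otherwise judged visually from score
plots, not a statistic with a reference distribution; it is only ever
used comparatively (screened variables vs the full concatenation on the
same samples).

## Synthetic study generator

The generator emulates the study design end to end: 70 model samples in
two origin groups (35 + 35) and 14 external samples in four groups
(4 + 4 + 3 + 3); four blocks — two tabular, two spectral.

- **Tabular blocks**: feature j has a random baseline level; exactly
  `n_informative` columns receive group-dependent mean shifts. The two
  model groups sit at ∓½ · effect_size · noise_sd, i.e. their
  separation is effect_size standard deviations. External groups draw
  independent N(0, 1) coefficients per (group, feature) on the *same*
  informative columns — the generator's stand-in for the empirical
  observation that variables separating the model origins also spread
  the held-out origins. A per-sample offset (sd `sample_effect_sd`)
  added to every column emulates batch/dilution nuisance — the stated
  reason for Z-scoring — and is what makes the full-feature external
  PCA genuinely harder than the screened one.
- **Spectral blocks**: smooth sinusoidal baseline + Gaussian peaks at
  fixed random positions + white noise. Peak shape is Gaussian for both
  NMR and MIR — the fusion logic under test is shape-agnostic and the
  Gaussian admits closed-form checks. Group effects multiply informative
  peak amplitudes: log-amplitude shifts of 0.25 · effect_size ·
  coefficient (multiplicative intensity variation, matching how MS/NMR
  intensities vary). NMR spectra always carry a reference singlet at
  0.00 ppm, a nuisance "water" hump at 4.9 ppm with wildly varying
  amplitude (removed by the bucketing exclusion), and an optional
  per-sample axis jitter that the referencing step must undo. A
  per-sample global amplitude factor plays the batch-nuisance role;
  vector normalization removes it for MIR by construction.

Ground truth (informative columns / peak positions) is written to
`truth.json` beside the data, so recovery metrics need no
re-simulation. One global seed fans out per block; identical specs give
identical output.

**What the generator does not emulate:** retention-time drift, isotope
patterns, peak overlap and crowding, correlated metabolite families,
heteroscedastic intensity-dependent noise, Lorentzian/Voigt lineshapes,
or any real covariance between platforms beyond the shared group
structure. Passing tests therefore demonstrate that the pipeline's
arithmetic, selection logic and leakage hygiene are correct and that it
recovers planted structure under idealized noise — not that it would
rank platforms or metabolites correctly on real instrument data.

## Problem sizes used by the test suite and acceptance script

The default study (`default_study_spec`) uses realistic widths: LC-MS
300 features, GC-MS 120, NMR 5700 buckets (12 601-point spectra), MIR
698 retained grid points, with 10/8/8/6 informative features per block
at effect size 2. The statistical test-suite simulations use a leaner
design chosen for the property under test: four 100-feature tabular
blocks with 2 informative features each (signal split evenly, no block
sufficient alone — the scenario fusion exists for), per-sample offset
sd 0.5, 25 paired seeds for the fusion-advantage, screening-recall and
external-separation properties and 50 seeds for the null calibration.
With dense per-block signal every single block is near ceiling at 21
test samples and the best-of-four comparison is dominated by selection
optimism, so the fusion advantage is intrinsically undetectable there;
the sparse design measures the method, not that artifact.

## Known limitations

- The model set is strictly two-class; multi-class fusion training is
  out of scope (external origins are only ever assessed unsupervised).
- Metrics are binary; no AUC-difference significance testing — models
  are ranked by inspection of the comparison table.
- Screening requires original-variable selectors; score-based MLDF
  models cannot be screened by construction.
- No peak picking, deconvolution, compound identification or vendor
  file formats; spectra enter as plain two-column text.
- The separation index compares projections of the same samples; it is
  not calibrated across data sets.
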