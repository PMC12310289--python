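# Methods

This note documents the models, numerical choices and known limits of the
`rangeshift` pipeline in enough detail to reproduce or criticise it.

## Grid model and geometry

Layers share one regular geographic grid: upper-left origin, square cells
of `res_arcmin` arcminutes, row 0 northernmost. Interpolation and
point-in-cell assignment use cell centers with half-open extents
`[origin, origin + n·res)`; a point on a cell's west or north edge belongs
to that cell. Masked cells (outside the study region) are excluded from
every sum, quantile and centroid.

Cell areas use a sphere of radius 6371.0 km:
`A(row) = R² · Δλ · (sin φ_top − sin φ_bot)`. No ellipsoid is used; at the
grain of this analysis the difference is far below decision relevance, and
the spherical tiling identity (global sum = 4πR², verified to 1e-6
relative) makes the choice auditable. Centroid shift distances are
great-circle (haversine) on the same sphere.

Raster I/O uses the ESRI ASCII grid format: single band, explicit nodata,
plain text. Bilinear resampling covers the same extent at the new
resolution; each output center takes the bilinear interpolation of the
four surrounding input centers (clamped to the outer ring at edges), and
any output cell whose stencil touches a masked input is masked — the
conservative choice for coastline cells, where interpolating across the
mask would invent values.

## Synthetic environments and virtual species

Climate layers are Gaussian random fields: white noise smoothed with a
Gaussian kernel of scale `correlation_length` (cells), standardized, then
affinely mapped to realistic magnitudes (tmin ≈ 1.6 ± 2.9 °C plus a
deterministic poleward cooling of ±`lat_gradient_degc`; tmax = tmin + 26–30
°C; pan = 674·exp(0.45·z) mm; pcv = logistic, in (0, 1)). The meridional
gradient is what lets warming scenarios move suitability poleward; without
it a warmed field is statistically exchangeable with the present one.

Land cover is a closed composition: six latent fields, each
`alpha_cov · (normalized linear map of the standardized climate fields) +
(1 − alpha_cov) · independent random field`, scaled and passed through a
softmax × 100. `alpha_cov` is the collinearity dial: 0 gives land cover
independent of climate (checked: mean |correlation| < 0.1 on a 200×200
grid), 1 makes it a deterministic function of climate.

A virtual species has suitability
`logistic(intercept + Σ β_l·z_l + Σ β_l²·z_l²)` on layers standardized
over unmasked cells. Standardizing inside the suitability function keeps
coefficients comparable across layers, which is what makes
parameter-recovery tests well-posed. Occurrences are cell-level Bernoulli
draws with probability ∝ suitability · bias^γ, scaled to an expected count
`n_target`; γ = 0 ignores effort, larger γ concentrates records where
observers go. Future layer sets perturb temperatures additively,
precipitation multiplicatively, seasonality additively with clipping into
(0, 1), and land cover on the log-percentage latents before re-applying
the softmax, so the composition stays closed. The two packaged scenario
presets ("mild", "strong") shift tmin/tmax by +1.4/+3.2 and +2.2/+4.7 °C,
scale precipitation by 0.92/0.88, and expand forest and crop at the
expense of open habitats (more strongly under "mild", whose land-use story
differs most from the present).

What the generator does *not* emulate: dispersal limitation, biotic
interactions, spatially varying observation protocols, coastlines/irregular
masks, and non-Gaussian spatial structure (fronts, orography). Passing
tests therefore demonstrate the statistical machinery is correct under the
stated data-generating process, not that any real species obeys it.

## Occurrence processing

A species is present in a cell if at least one record falls inside it;
duplicates collapse. The sampling-effort covariate is a Gaussian kernel
density of effort points (in practice, records of related taxa; in the
demo, simulated observer hubs) evaluated at cell centers in cell units and
rescaled by its maximum over the study region. The bandwidth default is 10
cells; the source analysis tool and bandwidth behind this construct are
not documented anywhere we can reproduce, so this smooth default is a
stand-in and is configurable. Pseudo-absences are drawn uniformly without
replacement from the biomes containing at least one presence, excluding
presence cells (a choice the method description leaves open; excluding
them avoids contradictory labels), capped at 10,000. One pseudo-absence
set per species is shared by all models of that species. Presences get
weight 1, pseudo-absences weight n_presence/n_pseudoabsence, which pins
the weighted prevalence at exactly 0.5.

## GLM fitting and stepwise AIC

The GLM is a weighted binomial logistic regression on linear + quadratic
terms of standardized predictors plus the (standardized) bias covariate.
The solver is iteratively reweighted least squares with a ridge of 1e-6 on
the normal equations of the standardized design and step-halving on any
deviance increase; convergence is a relative deviance change < 1e-9, cap
100 iterations. The ridge matters: presence/pseudo-absence tables are
routinely quasi-separable, where unpenalized IRLS drifts for hundreds of
iterations with diverging coefficients. On converged problems the fit
agrees with an unpenalized reference implementation to < 1e-5 in
coefficients (asserted in the tests against statsmodels). For 0/1
responses the weighted log-likelihood is −deviance/2, so AIC =
deviance + 2k.

Stepwise selection is backward–forward over the term set, treating each
linear and quadratic term as independently droppable (no hierarchy
constraint — the convention of standard stepwise implementations), with
the intercept and the bias control variable never dropped. Subset fits are
warm-started from the full-model coefficients and cached. One property of
AIC stepwise worth stating explicitly: a true-zero term is retained with
probability ≈ P(χ²₁ > 2) ≈ 0.16, so a pure-noise predictor (two terms)
escapes the reduced model entirely only ~71% of the time. That is a
property of the criterion, not a defect of the search.

## Deviance partitioning

Explained deviance is measured against the bias-only null (not the
intercept-only null): D_M = (dev_null − dev_M)/dev_null for the
stepwise-reduced climate, land-cover and combined models. With exactly two
variable sets, the incremental-improvement scheme reduces to three fitted
models and

    a = D_CL − D_L,  b = D_CL − D_C,  c = D_C + D_L − D_CL,

an exact additive partition of D_CL. Negative components (suppression, or
small stepwise artifacts) are reported as-is; truncating at zero would
hide diagnostics. Stepwise reduction can leave tiny violations of the
nesting inequality D_CL ≥ max(D_C, D_L); violations beyond 0.005 raise,
as they indicate a broken fit rather than a selection artifact.

Interpretation caveat learned from the synthetic experiments: on smooth
landscapes (long correlation lengths relative to grid size) even
climate-independent land cover shares realized spatial structure with a
climate-driven response, and that shared structure belongs genuinely in
the joint fraction c. Recovery tests of the independent fractions
therefore use short correlation lengths (2 cells on a 60×60 grid, many
effective spatial degrees of freedom); the packaged demo keeps the
smoother 8-cell landscape, where a large c is the expected, correct
answer.

## Ensemble components

* **GLM** — the stepwise-reduced model above.
* **Random forest** — 500 probability-voting trees honoring case weights,
  `min_samples_leaf = 25`. The large leaves are deliberate: fully grown
  trees memorize the Bernoulli presence labels, so their vote correlates
  with the realized coin flips instead of the underlying probability;
  leaf averaging restores calibrated suitability estimates (rank
  concordance with known truth rises from ~0.70 to ~0.93 in our checks).
  The upstream ensemble platform's forest settings are not exactly
  reproducible, so these are fixed and documented as this package's own.
* **MaxEnt-like** — L1-penalized logistic regression on linear +
  quadratic + pairwise-product features of standardized predictors, a
  maxnet-style formulation that keeps the pipeline self-contained and
  deterministic. The penalty is chosen by 5-fold cross-validated weighted
  deviance with the one-standard-error rule (strongest penalty within one
  SE of the minimum); at the plain CV minimum the lasso keeps many
  vanishing coefficients, while 1-SE zeroes ~94% of truly null features
  without losing real ones in our measurements. The CV grid spans
  C ∈ [0.01, 5]; weaker penalties invite separation blow-ups on these
  quasi-separable tables.

The ensemble is the unweighted mean of component predictions, averaged in
component-name order so it is bit-identical under permutation of the
component list. For projections the bias covariate is fixed at its
training maximum (predict "as if perfectly observed"). No cross-validation
ensembling or score weighting is applied — plain averaging is the stated
design.

## Evaluation

* **Boyce index** (default 101 windows of width 0.1× the background
  range): windows slide across the background prediction range; each
  window's P/E ratio is (fraction of presence predictions inside)/(fraction
  of background inside); the index is the Spearman correlation of P/E
  with the window midpoint. Zero-background windows are skipped, not
  imputed. If the P/E series is constant the index is defined as 0 with a
  warning. The index is exactly invariant under affine transforms of the
  predictions (windows scale with the range) and only approximately stable
  under nonlinear monotone transforms (window membership shifts) — the
  rank step is invariant, the binning is not. Its null distribution is
  wide: with 2,000/5,000 samples the mean of |Boyce| under no association
  is ≈ 0.26.
* **AUC** — Mann–Whitney concordance via ranks (ties counted ½), exact
  against brute-force pairwise enumeration.
* **TSS** — sensitivity + specificity − 1 at the 5% omission threshold,
  the linear-interpolation empirical quantile of presence predictions.
  Specificity uses the pseudo-absence/background sample; with a 0.5
  weighted prevalence and background contamination (background cells may
  be truly suitable), TSS values are structurally lower than against true
  absences.
* **Variable importance** — per variable and repetition, shuffle the
  column, re-predict, importance = 1 − max(0, Pearson r with the original
  predictions); constant predictions give importance 0 with a warning.

## Projections, range metrics, comparisons

Decoupled inputs copy the current grid and overwrite the climate set, the
land-cover set, or both from the future layer set ("clim"/"land"/"both");
everything else (including bias handling) is unchanged, which gives the
bit-exact identity tested end-to-end: a "land" projection under an
unchanged land-cover future equals the current prediction exactly.

The binarization threshold is computed once per species from the current
prediction at its presence cells and reused unchanged for all its future
projections — future maps are compared against a fixed present reference.
Area of habitat sums spherical cell areas over suitable cells. The range
centroid weights cell-center coordinates by continuous suitability only
(no cell-area multiplier, per the metric's definition); shift distance is
the great-circle distance between centroids. All metrics can be recomputed
on maps masked to currently occupied cells (`restrict_to_occupied`).

Cross-species contrasts use two-sided paired Wilcoxon signed-rank tests:
zero differences dropped (the classical convention; Pratt's is available),
exact null when the effective n ≤ 25 with no tied magnitudes, otherwise
the tie-corrected normal approximation; an all-zero difference vector is
defined as p = 1 and flagged. No multiple-testing correction is applied by
default (raw pairwise p-values are reported; a Holm option exists in the
machinery but is off). Figures-style standardized values are per-species
z-scores across the compared cells; they affect plots only, never tests.

## Pipeline and reproducibility

`run_study` drives the whole chain from a single `StudyConfig`. All
randomness derives from one root seed through named substreams
(`sha256(root:stage:species) mod 2³¹`), so a re-run with the same config
is byte-identical in every CSV; the manifest records the config hash,
seeds, failures and outputs. One species' failure never aborts the batch.

Problem sizes used by the packaged demo and the acceptance script — a
50×50 grid (5 arcmin), 3 virtual species, ~300 presence cells each, ~2,200
pseudo-absences (the 10,000 cap never binds on this grid), 2 scenarios ×
3 modes; recovery experiments use 20 replicates on 60×60 grids and the
collinearity sweep 10 replicates per `alpha_cov` level — were chosen so
the full suite and the acceptance run each complete in minutes on one CPU
while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The MaxEnt-like component approximates MaxEnt's solution path, not the
  Java implementation's feature classes (no hinge/threshold features).
* The effort-surface bandwidth and kernel are a documented stand-in; real
  effort fields are neither Gaussian nor stationary.
* The partition is defined for exactly two predictor sets; more sets need
  a different (hierarchical) scheme.
* Geographic grids only; no reprojection. Kernel distances are computed in
  cell units, which ignores meridional convergence within the study
  region.
* TSS and AUC against background samples understate accuracy relative to
  true-absence evaluation; the Boyce index is the primary calibration
  metric for exactly that reason.
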