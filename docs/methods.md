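# Methods

This note documents the models, generators and numerical conventions of
`enmtransfer`, the choices made where the design was genuinely open, and what
the synthetic experiments can and cannot say about real survey data.

## Synthetic world

The generator emulates a fire-prone, land-abandonment mountain landscape on
the Mediterranean–Eurosiberian transition, nested in a much larger region.

**Grids.** The local grid defaults to 80×80 cells of 230 m (the analysis
resolution of 16-day vegetation-index composites); the regional extent is 10×
the local extent with 10 km cells, strictly containing it. Coordinates are
planar metres; row 0 is the top row and a point maps to the cell whose
half-open interval [left, right) × [top, bottom) contains it. Experiments in
tests and the acceptance script use 30–50 cell grids so the whole suite runs
in minutes on one CPU; the survey sizes and all decision thresholds are never
scaled.

**Climate.** Monthly maximum temperature follows a temperate-oceanic
climatology (July/August maxima ≈ 27 °C, summer drought) plus a linear
regional gradient (8 °C of summer tmax across the region, so ~0.8 °C across
the local extent) and a spatially autocorrelated anomaly (Gaussian-filtered
white noise, unit variance, smoothing length 8 cells, amplitude 1.2 °C).
Minimum temperature is tmax minus a month-specific diurnal range, which
enforces tmax ≥ tmin by construction. Precipitation applies a relative
anomaly whose weight varies seasonally (wet-season months carry it ~1.6×,
dry-season ~0.4×): without that seasonal weighting the precipitation CV —
the seasonality predictor — would be spatially constant and degenerate under
standardization.

**Land cover.** A categorical map on a 4× finer sub-grid (mirroring 30 m
imagery under the 230 m analysis grid), built by thresholding one smooth
field at the quantiles of the target composition (69 % scrubland, 21 %
forest, 7 % cropland, 3 % other), which gives patch structure and exact
realized proportions. Block-counting the sub-grid yields genuinely
fractional cover at analysis resolution.

**Vegetation index.** 23 composites per year; each cell's seasonal curve is
the cover-fraction-weighted mixture of class profiles (cropland: strong early
peak; forest: productive, muted cycle; scrubland: intermediate; other: low),
plus a persistent site anomaly and per-composite noise, clipped to [−1, 1].

**Change scenario (t0 → t1).** Defaults: +1 °C on all monthly temperatures,
−10 mm on monthly precipitation, 35 % of cropland converts to scrubland and
of scrubland to forest (simultaneously, from the t0 state), and three fire
discs of radius 5 land-cover cells convert forest → scrubland and
scrubland → other based on the pre-fire state. Cells only move between the
four classes. The t1 vegetation-index year is regenerated from the t1 cover.
A zero scenario reproduces t0 exactly (bitwise), which the no-change null
experiments rely on.

**Virtual species.** Coefficients on the nine standardized local predictors
(BIO5, BIO12, BIO15; three cover fractions; three EFAs), magnitudes uniform
in [0.25, 0.75] with random signs, constrained for trait consistency: forest
preference ⇒ positive forest-fraction weight (open ⇒ negative); migrants
load positively on vegetation seasonality; Mediterranean species positively
on summer maximum temperature; specialists get 1.5× steeper responses
(narrower niches). Intercepts are uniform in [−1.0, 0.3], giving prevalences
roughly 0.2–0.6 at the 344-point calibration survey. Traits follow a
marginally balanced binary design (three index bits plus a parity bit).
The magnitude range was chosen so that true suitability surfaces have
standard deviations near 0.2–0.3 — sharp enough to be learnable from ~350
points, soft enough that Bernoulli sampling noise matters, as in real point
counts.

**Surveys.** 344 calibration points at t0; a random 204-point revisit at t1
(internal transferability); 384 fresh, calibration-disjoint points at t1
(external transferability). Locations are shared across species; detection
equals occurrence (a Bernoulli draw from true suitability) — imperfect
detection is deliberately out of scope, mirroring single-visit point-count
designs. Species enter the modelling only with strictly more than 15
calibration presences.

**Seeds.** One master seed; each stage derives a child generator from
`SeedSequence((master, crc32(stage key), ...))`, so stages are independently
reproducible and insensitive to the order in which other stages consume
randomness. Identical config + seed ⇒ bitwise-identical worlds, species,
surveys and result tables.

## Predictors

All 19 bioclimatic variables are computed (quarters = running 3-month windows
with December–January wraparound, ties broken by the earliest starting month;
sample n−1 SDs throughout; BIO15 = 100·SD(prec)/(1 + BIO12/12), the +1
shielding arid cells), though only BIO5, BIO12 and BIO15 enter models by
default — the trivariate expert choice. EFAs are the annual mean, seasonal
SD and 1-based peak-composite index (earliest composite on ties; an index
rather than a calendar date, the unit-safe choice). Fractional cover uses
exact per-class block counting — class mass is conserved to the cell, and a
non-integer resolution ratio is a hard error rather than an interpolation.
Continuous resampling defaults to bilinear (the method for the climate-grid
alignment is not dictated by anything physical; it is exposed as a switch),
categorical to nearest-neighbour. Standardization always uses
calibration-epoch (t0) statistics; projections to t1 or across scales reuse
them verbatim.

## Ensemble niche models

`EnsembleENM` fits one species on a stack of at most three layers — the
complexity cap that keeps individual and combined models comparable — via
stratified 70/30 split-sample replicates (default 30; stratification keeps
prevalence in every fold, and a single-class training fold skips that
replicate rather than crashing). The learner registry maps names to
scikit-learn estimators: `glm` (L2 logistic regression), `rf` (60 trees,
min leaf 10), `gbm` (depth 2, 100 stages, min leaf 10), optional `gam`
(spline-basis logistic), `fda` (LDA) and `ann` (one hidden layer of 8).
Tree-learner leaf sizes are deliberately conservative: members that memorize
calibration-site noise poison the internal-TT evaluation, which revisits
those very sites.

The consensus includes every algorithm × replicate member with holdout
AUC > 0.65, weighted by raw AUC (a rescaled AUC − 0.5 option exists, default
off). If no member qualifies, the single best member is used and the
fallback logged — an ensemble must exist for every species so the
hypothesis-testing design stays complete. Final projections are the
consensus of the split-sample members; nothing is refit on 100 % of the data.

Two AUC summaries coexist on the results object and differ on purpose:
`split_sample_auc` (mean holdout AUC over *all* members) is the reported
crossvalidation accuracy, while `mean_holdout_auc` (included members only)
describes the consensus. Averaging only included members conditions on the
same noisy AUC used for inclusion and inflates the estimate by ~0.02, which
would manufacture a spurious crossvalidation-vs-internal gap even in a frozen
environment.

**Combined models** re-run the full machinery with the individual ensembles'
suitability surfaces as predictors (2–3 layers, so the complexity cap holds
by construction). **Hierarchical integration** replaces the local climate
input by the direct downscaling of a regional climate ensemble: the regional
model is fitted on atlas-style data (one Bernoulli draw per regional cell
from the species' climate-marginal truth) and its response surface is
evaluated cell-wise on fine-resolution climate standardized with the
*regional* statistics. Regional-scale crossvalidation stands in for the
local crossvalidation record of the hierarchical climate model; the
individual land-cover and EFA records are approach-invariant and shared
across both approach labels.

## Evaluation and inference

AUC is the Mann–Whitney pairwise probability (midranks, ties ½). Binary
metrics (sensitivity, specificity, TSS, kappa) use the smallest max-TSS
threshold over observed scores, computed on calibration data and frozen for
both transferability regimes — re-tuning the threshold on evaluation data
would leak. Schoener's D is computed on continuous suitability surfaces
normalized over the shared unmasked support, per epoch (per-epoch matrices
are reported rather than pooled). Transferable-species counts use strict
AUC > 0.7.

The Gaussian-identity GLMs use the ML variance (RSS/n) so AIC is comparable
across fixed-effects structures, with k counting the residual variance; a
perfect fit floors σ² at 1e−12 and is flagged. All 2^m main-effect subsets
are fitted (interactions excluded), Δ < 7 defines the support set, ΣW > 0.5
consequential importance. The TRAIT factor is one trait column per run; the
pipeline loops over all four traits. The Wilcoxon signed-rank test drops
zero differences, midranks ties, and is exact (sign-assignment distribution
by integer convolution) for n ≤ 25, tie-corrected normal with continuity
correction above; contrasts are paired at the configuration level
(predictor set × approach group means), with an unpaired rank-sum
alternative, since trait groups partition species and species-level pairing
is impossible. Only p < 0.001 is called significant, and no further
multiplicity correction is applied — deliberately conservative rather than
corrected.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that the *machinery* behaves as designed under
known truth: crossvalidation overstates transferability exactly when the
environment actually changes; stacking the three driver families recovers
accuracy that no single family carries; the inference layer finds planted
effects and ignores absent ones. They do not calibrate absolute accuracy
values for real birds: virtual species have linear-logistic niches, no
spatial aggregation beyond the environment, no detection error, no
observer or phenological survey artefacts, and the two epochs are exactly
aligned (real vegetation-index years pair imperfectly with survey years).
Real-data headline numbers are therefore expected to differ; the directional
and structural claims are what transfer.

One directional claim did *not* reproduce robustly: that direct-downscaled
regional climate projections keep higher sensitivity than locally calibrated
climate models for regionally widespread species. For such species the
projected suitability over the small local extent is nearly uniform, so the
max-TSS binarization sits on a plateau and per-seed sensitivity swings
between ~0.3 and ~1.0; across seeds the two approaches are statistically on
par at the transfer evaluations. The package keeps the principled threshold
convention (each model binarizes on its own calibration data, regional for
the downscaled model) and reports the instability rather than asserting the
direction.

## Numerical conventions and edge cases

Nodata propagates through every derivation (any masked contributor masks the
output cell). Zero-variance layers are a named hard error at
standardization. Logistic arguments are clipped at ±700 before
exponentiation. Ensemble weights are convex by construction, so consensus
predictions stay within the members' range. Evaluation campaigns in which a
species is detected everywhere or nowhere leave that record's metrics as NaN
(flagged `degenerate_campaign`) rather than aborting the run; inference drops
such rows. Every output table carries the run's configuration hash, and the
inference stage refuses tables whose hash does not match the active
configuration.

## Problem sizes

Defaults target the full study design (80×80 local grid, 30 replicates,
three algorithms). The packaged experiments use reduced sizes chosen as the
smallest that leave the directional effects unambiguous: tests run 30–40
cell grids with 3–8 replicates; the acceptance script runs a six-species
50×50 experiment plus ten-seed hypothesis checks (40×40, two algorithms,
eight replicates). Each reduction is a problem-size choice only — survey
sizes (344/204/384), the >15-presence filter, the 70/30 split, the 0.65
inclusion and 0.7 transferability cuts, Δ < 7, ΣW > 0.5 and p < 0.001 are
study constants and never change.
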