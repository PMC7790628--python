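# Methods

This note documents the models, numerical choices and known limitations
behind the package, in the order the pipeline runs.

## Synthetic landscapes

The generator exists so that every estimator in the package can be
validated against known truth without any field data. It emulates a
high-Himalayan survey block, not any particular real topography.

**DEM.** Elevation is a sum of a base plane, `ridge_count` elongated
Gaussian ridge/valley functions (random position and orientation,
amplitudes 400–900 m alternating in sign, width 2.5 km) and spectrally
smoothed Gaussian noise, rescaled linearly onto the configured range
(default 2,870–6,150 m). With ridges and noise disabled the surface is
an analytic plane, which gives closed-form targets for the terrain
operators (Horn slope of `z = 0.5x` is exactly `atan(0.5)`).

**NDVI.** Expected greenness follows a piecewise-linear profile of
elevation: a forest plateau (~0.6) below ~3,950 m, a grass/shrub band
(~0.45 → 0.28) to ~4,750 m, and barren/snow (< 0.14) above ~4,900 m.
Three perturbations make NDVI a realistic *proxy* of elevation rather
than a deterministic function of it:

* *patchiness* — a smooth random field displaces the apparent elevation
  fed to the profile (default sd 500 m), so vegetation types form
  patches; vegetation-zone boundaries in steep terrain do vary by
  hundreds of meters between slopes and catchments;
* *exposure* — south-facing cells are greener by up to 0.10 (linear in
  the deviation of aspect from south);
* *observation noise* — smoothed white noise, sd 0.05.

With all three at zero NDVI is a pure function of elevation. The
patchiness default was chosen so that the elevation–NDVI correlation in
a survey frame is strong but typically below the 0.7 collinearity
threshold, as in real survey data where NDVI carries independent
information. Individual grass-band cells therefore scatter around the
band (the *expected* NDVI stays inside 0.25–0.5); tests assert the
expectation and majority membership, not per-cell membership.

**Transects.** A relief score (DEM minus its smoothed version) marks
ridges (+) and valleys (−). Each transect starts at a high-|score|
eligible cell (elevation 3,000–5,000 m by default, optional forest and
settlement-distance constraints) and greedily walks to the 8-neighbor
with the strongest same-sign relief until the target length is reached;
walks shorter than half the target are discarded. Lengths are therefore
within −50 %/+2 % of the target.

**Population.** Groups are an inhomogeneous point process: log relative
intensity is a step preference, `β_e·1[elevation ∈ band] +
β_n·1[NDVI ∈ band]` (defaults: band 4,250–4,550 m with β_e = 2.5; NDVI
0.25–0.50 with β_n = 1.0). The group count is Poisson with mean
`density × area / E[truncated group size]`; sizes are negative binomial
(mean 14.4, dispersion 1.5) truncated to [1, 113]; individuals are
adult male / adult female / subadult with probabilities 0.35/0.45/0.20,
and 15 % are relabeled unclassified by masking — so the adult-ratio
imputation can be checked against the true classes. A step (rather than
smooth) preference is used because partial-response recovery is judged
by the location of the fitted smooth's maximum.

**Survey.** Detection is per group (surveys record group sightings):
p(detect) = exp(−λ·d) truncated at 1,500 m, d the distance to the
nearest transect, optionally gated by line-of-sight from the nearest
point on the transect. Default λ = 0.0035/m, the spring-scale decay of
observed sighting distances.

**Features.** Settlements sample the lowest decile of the smoothed DEM
(valley bottoms), trails connect random settlement pairs through a
jittered midpoint, livestock points cluster within a configurable radius
of settlements.

## Terrain operators

Horn's 3×3 third-order finite difference (1-2-1 weights) for slope and
aspect; aspect is the compass bearing of steepest descent and is
converted to deviation-from-south (min(|a−180|, 360−|a−180|)) before
modeling, because raw aspect is circular. Ruggedness is the Riley index
(root of summed squared differences to the 8 neighbors). Cliff cells
have slope strictly > 45° and belong to an 8-connected patch of area
strictly > 90 m². Hydrology: priority-flood sink filling with an epsilon
(10⁻⁶ m) gradient toward the spill so D8 routing never meets a flat; D8
ties resolve to the lowest direction code; accumulation counts upstream
cells in topological order and verifies acyclicity. Border cells are
nodata for kernel operators and off-grid drains for D8. Distance
surfaces are cell-center-to-geometry Euclidean distances (vector
features) or exact distance transforms (binary rasters).

## Viewsheds and minimum density

Sight lines are sampled every half cell by bilinear interpolation, with
half-cell margins at both ends, observer eye height 1.7 m, target height
0 m, no curvature or refraction (negligible below 1.5 km). The sample
positions are a fixed function of the ray alone, so the same cell pair
always yields the same decision regardless of the batch or the buffer
radius — this makes viewshed nesting (1,000 m ⊆ 1,500 m) exact. A
transect viewshed is the union of observer-point viewsheds (observers
every cell along the line, each scanning to the buffer radius plus one
spacing) clipped to the Euclidean buffer; `assume_visible=True` skips
the sight tests for open-terrain work where visibility is effectively
complete. Manual survey-area corrections are supported as explicit
add/remove cell masks, never inferred.

Minimum density divides all individuals of observations located in
visible cells by the visible area; reported values are rounded to one
decimal, half up. Membership is cell-based (half-open cell intervals),
so in the exact-recovery study the detection truncation extends half a
cell diagonal past the buffer — "full detection" then means every group
whose cell is surveyed is seen, and the estimator equals the realized
density identically.

## Habitat selection

The used–available design follows the survey's construction exactly:
50,000 uniform candidates in the 1,500-m viewshed, 100× the observation
count sampled *without replacement* with probability ∝ exp(−λ·d);
group sizes attributed by permutation when size and distance are
uncorrelated (two-sided p ≥ 0.05), otherwise by an OLS line of size on
distance (predictions rounded to the nearest integer, floored at 1);
adults per row = identified adults + unclassified × R with R the
dataset-level adult ratio; presence weights `adults_i/Σadults × n_obs`
and pseudo-absence weights proportional to attributed adult counts,
rescaled to the same total, so both sides carry exactly `n_obs` of
weight after any filtering. Rows with zero weight (groups with no
adults) carry no likelihood information and are dropped before fitting.
Presences in the forest land-cover class are excluded by default
(detection there is assumed poor); the class comes from NDVI
calibration when calibration points are available.

The collinearity screen removes, for each pair with |r| ≥ 0.7 (a 10⁻¹²
tolerance makes the boundary inclusive under floating point), the
member later in the retain-priority list, processing pairs from the
strongest correlation down; the result depends only on the correlation
matrix and the priority.

**GAM.** Weighted binomial (logit) model: penalized B-spline smooths
(df 8, cubic) on standardized continuous covariates, linear terms for
binary covariates, fitted by penalized IRLS. The smoothing penalty is a
single shared α selected from {10⁻⁴ … 10} by penalized AIC (weighted
deviance + 2·edf). A Laplace-approximate REML criterion was evaluated
and consistently over-smoothed band-shaped preferences at survey-scale
effective sample sizes (total weight ≈ 2·n_obs ≈ 200), so AIC was
adopted as the default; α can also be fixed per term. Effective degrees
of freedom are diag[(XᵀWX+S)⁻¹XᵀWX], the covariance is the Bayesian
posterior (XᵀWX+S)⁻¹, smooth terms get Wald chi-square tests on their
edf, deviance explained is 1 − D/D₀ against the weighted null, and the
adjusted R² uses weighted residual and total sums of squares with
n − edf denominator. Prediction clamps covariates to the training range
(B-spline bases are undefined beyond their knots), so partial responses
are only meaningful over the data support; recovery studies locate the
smooth's peak over the central 2–98 % of the frame's covariate values.

## Permutation importance

Default mode permutes one column of the prediction frame (model not
refit), correlates response-scale predictions with the originals over
`n_reps` independent permutations, and reports raw = 1 − mean r and
raw/Σraw. A refit mode (re-estimating the model on the permuted frame)
is available because "randomized model" is ambiguous; the mode is
recorded in the output. A constant prediction vector yields raw 0 with
a log message. An exactly unused covariate (zero coefficients) yields
exactly raw 0.

## Recovery studies and what they show

`studies.density_recovery_trial`: 60×60-cell scenes, two transects,
complete visibility, buffer = truncation distance. Exactness under
certain detection and conservativeness under exponential decay hold by
construction of the estimator; the study verifies the implementation,
over 50 seeds.

`studies.selection_recovery_replicate`: 9×9 km scenes, 12 transects of
2.1 km, true density 120 ind/km². The density is deliberately above the
real survey's so that a ~81 km² desk-scale scene yields the survey's
presence sample (~50–120 group observations) and a model frame of
~5,000–12,000 rows; what matters statistically is the effective sample,
not the absolute density. Truth uses both the elevation and the NDVI
band, as the real animals do. Success criteria: the elevation smooth
peaks inside 4,250–4,550 m (≥ 90 % of 20 replicates) and the top
standardized importance is one of the two generating covariates
(≥ 95 %). Attribution between elevation and NDVI individually is not
always identifiable — the two are ecological proxies, and
distance-to-settlement also correlates with elevation because
settlements sit in valleys; that signal-splitting is a property of the
inference problem, not of the implementation.

These studies validate the estimators under the generator's assumptions
(independent group placement given the intensity, exponential detection,
planar geometry). They do not establish performance under spatial
autocorrelation of presences, observer heterogeneity, double counting,
or geodesic/projection effects, none of which the generator emulates.

## Problem sizes and defaults

| Parameter | Default | Notes |
|---|---|---|
| cell size | 30 m | DEM resolution of the emulated survey |
| landscape extent | 21×21 km (config), 9×9 km (replicates), 1.8×1.8 km (density trials) | desk-scale studies state their sizes explicitly |
| buffer radii | 1,000 / 1,500 m | upper/lower minimum-density bounds |
| observer height | 1.7 m | eye height; target height 0 |
| λ (sighting decay) | 0.0035 /m | spring scale; 0.0024 autumn |
| pseudo-absence pool | 50,000 | uniform in the 1,500-m viewshed |
| pseudo-absence multiplier | 100 × n_obs | sampled without replacement |
| collinearity threshold | \|r\| ≥ 0.7 | inclusive |
| GAM basis | df 8, cubic B-splines | per continuous covariate |
| α grid | 10⁻⁴…10 | shared penalty, penalized-AIC choice |
| importance repetitions | 100 (pipeline), 30 (replicate studies) | rank-stable at 30 |
| livestock buffer | 500 m | sensitivity variants re-run with other widths |
| stream threshold | 0.5 km² drainage | manual network editing is out of scope |

## Limitations

* Planar metric coordinates throughout; no projections or geodesy.
* Single-flow-direction (D8) routing only; no multi-flow dispersion.
* NDVI is the only land-cover predictor; no multispectral
  classification.
* The distance-decay of detection is assumed exponential end to end —
  it is the generating law of the simulator and the thinning law of the
  pseudo-absence design; no detection-function estimation in the
  distance-sampling sense is attempted.
* Season-specific survey areas cannot be reconstructed from published
  totals alone; the density arithmetic uses the printed count/area
  pairs as inputs.
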