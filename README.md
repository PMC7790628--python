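# bharal

Survey-density estimation and habitat-selection modeling for mountain
ungulates counted from line transects, with a fully synthetic Himalayan
landscape generator so that every estimator can be tested against known
ground truth.

The package is aimed at quantitative wildlife ecologists working with
total-count transect surveys of species such as the blue sheep
(*Pseudois nayaur*): populations spread over rugged terrain, counted by
observers walking ridgeline and valley transects, with detections
thinning with distance and visibility limited by topography.

## What it computes

**Minimum density.** The conservative density estimate is the number of
individuals counted divided by the *visible* surveyed surface:

```
D_min = (Σ individuals inside viewshed) / visible area (km²)
```

The visible surface is a line-of-sight viewshed computed on a DEM from
observer points along each transect, clipped to a distance buffer
(conventionally 1,000 m and 1,500 m, giving upper and lower bounds).
Because no detection correction is applied, `D_min` never exceeds the
true density.

**Habitat selection.** A used–available design contrasts presences with
pseudo-absences: 50,000 uniform candidates inside the 1,500-m viewshed
are thinned to 100× the number of observations with probability
∝ exp(−λ·d), where λ is the exponential decay of observed sighting
distances (MLE λ = 1/mean distance). Rows are weighted by adult counts
(unclassified individuals imputed by the dataset adult ratio) with equal
total weight on presences and pseudo-absences; covariates with
|Pearson r| ≥ 0.7 are screened; and presence/availability is modeled by
a weighted binomial GAM with penalized B-spline smooths,

```
logit P(used) = β₀ + f₁(elevation) + f₂(NDVI) + f₃(slope) + … + γ·livestock
```

**Variable importance.** Each covariate is randomly permuted 100 times;
raw importance is 1 − mean Pearson correlation between original and
permuted-input predictions, standardized to sum to one.

Terrain covariates are derived in-package: Horn slope/aspect, deviation
of aspect from south, Riley terrain ruggedness, cliff patches (slope
> 45°, area > 90 m²), priority-flood sink filling, D8 flow direction,
flow accumulation, stream extraction, Euclidean distance surfaces and
livestock presence buffers. Rasters are plain-text ESRI ASCII grids,
vectors are GeoJSON, tables are CSV.

## Worked example

```python
import numpy as np
from bharal import (LandscapeConfig, PopulationTruth, DetectionModel,
                    generate_dem, generate_ndvi, place_transects,
                    simulate_population, simulate_survey,
                    transect_viewshed, minimum_density, transect_summary)

cfg = LandscapeConfig(extent_m=(6000, 6000), seed=1)
dem = generate_dem(cfg)                      # 2,870–6,150 m, ridges+noise
ndvi = generate_ndvi(dem, cfg)               # tracks the vegetation bands
transects = place_transects(dem, 8, 2100, seed=2)
groups = simulate_population(dem, ndvi,
                             PopulationTruth(true_density_ind_per_km2=40),
                             seed=3)
obs = simulate_survey(groups, transects, dem, DetectionModel(), seed=4)

print(transect_summary(transects))
vs = {r: transect_viewshed(dem, transects, r) for r in (1000.0, 1500.0)}
for r, est in minimum_density(obs, vs, season="demo").items():
    print(f"radius {r:.0f} m: {est.individuals_counted} individuals over "
          f"{est.visible_area_km2:.1f} km² -> {est.density_rounded} ind/km²")
```

prints (seeds as above):

```
{'n_transects': 8, 'total_length_km': 16.9259…, 'mean_length_km': 2.1}
radius 1000 m: 137 individuals over 9.9 km² -> 13.8 ind/km²
radius 1500 m: 137 individuals over 12.8 km² -> 10.7 ind/km²
```

The upper bound (1,000 m buffer) exceeds the lower bound (1,500 m)
because the wider buffer adds unsurveyed area faster than additional
animals, and both sit below the configured density of 40 ind/km² — the
"minimum" property under imperfect detection (exponential sighting decay
at the default λ = 0.0035/m leaves distant groups uncounted).

The full pipeline (covariates → density → GAM → importance, with report
bundle) runs from a YAML config:

```bash
bharal run --config config.yaml
```

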