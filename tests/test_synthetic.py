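import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bharal import density as dens
from bharal import synthetic as syn
from bharal import terrain
from bharal.grid import Grid


def small_config(**kw):
    base = dict(extent_m=(3000.0, 3000.0), cell_size_m=30.0, seed=1)
    base.update(kw)
    return syn.LandscapeConfig(**base)


# ---------------------------------------------------------------------------
# configuration and DEM
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        syn.LandscapeConfig(extent_m=(1000.0, 990.0))
    with pytest.raises(ValueError, match="min < max"):
        syn.LandscapeConfig(elevation_range_m=(5000.0, 4000.0))
    with pytest.raises(ValueError, match="positive"):
        syn.LandscapeConfig(extent_m=(-300.0, 300.0))


def test_dem_deterministic_and_within_range():
    cfg = small_config(seed=9)
    a = syn.generate_dem(cfg)
    b = syn.generate_dem(cfg)
    np.testing.assert_array_equal(a.values, b.values)
    assert a.values.min() >= 2870.0 - 1e-9
    assert a.values.max() <= 6150.0 + 1e-9
    # terrain is non-trivial: both ridges and valleys exist
    assert np.ptp(a.values) > 1000


def test_dem_planar_ramp_has_analytic_slope():
    cfg = small_config(ridge_count=0, noise_amplitude_m=0.0,
                      base_gradient=(0.5, 0.0), normalize_elevation=False)
    dem = syn.generate_dem(cfg)
    slope = terrain.horn_slope(dem)
    np.testing.assert_allclose(slope.values[1:-1, 1:-1],
                               np.degrees(np.arctan(0.5)), atol=1e-6)


# ---------------------------------------------------------------------------
# NDVI
# ---------------------------------------------------------------------------

def test_ndvi_is_pure_function_of_elevation_without_noise():
    cfg = small_config(ndvi_noise_sd=0.0, ndvi_patchiness_m=0.0,
                      ndvi_aspect_amplitude=0.0)
    dem = syn.generate_dem(cfg)
    ndvi = syn.generate_ndvi(dem, cfg)
    knots = np.array([k for k, _ in cfg.ndvi_profile])
    vals = np.array([v for _, v in cfg.ndvi_profile])
    np.testing.assert_allclose(ndvi.values,
                               np.interp(dem.values, knots, vals), atol=1e-12)


def test_ndvi_class_bands_hold_with_high_probability():
    cfg = syn.LandscapeConfig(extent_m=(6000.0, 6000.0), cell_size_m=30.0,
                              seed=22)
    dem = syn.generate_dem(cfg)
    ndvi = syn.generate_ndvi(dem, cfg)
    elev, nd = dem.values, ndvi.values
    assert np.all(nd >= -1) and np.all(nd <= 1)
    high = nd[elev > 5800]
    assert high.size > 50 and np.mean(high < 0.14) > 0.9
    # grass/shrub band: expectation inside [0.25, 0.5] and a majority of
    # cells in-band (vegetation patchiness spreads individual cells)
    grass = nd[(elev > 4250) & (elev < 4400)]
    assert grass.size > 50
    assert 0.25 < grass.mean() < 0.5
    assert np.mean((grass > 0.25) & (grass < 0.5)) > 0.5


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------

def test_transect_lengths_and_determinism():
    cfg = small_config(seed=2)
    dem = syn.generate_dem(cfg)
    a = syn.place_transects(dem, 5, 900.0, seed=3)
    b = syn.place_transects(dem, 5, 900.0, seed=3)
    assert len(a) == 5
    for la, lb in zip(a.lines, b.lines):
        assert la.equals(lb)
    assert np.all(a.lengths_m >= 450.0) and np.all(a.lengths_m <= 1350.0)


def test_sixty_transects_total_near_target():
    # survey-scale check: 60 transects of target 2.1 km -> about 126 km
    cfg = syn.LandscapeConfig(extent_m=(9000.0, 9000.0), cell_size_m=30.0, seed=5)
    dem = syn.generate_dem(cfg)
    ts = syn.place_transects(dem, 60, 2100.0, seed=6)
    total_km = ts.total_length_m / 1000.0
    assert 0.8 * 126.0 <= total_km <= 1.1 * 126.0


def test_transect_constraint_band_outside_dem_errors():
    cfg = small_config()
    dem = syn.generate_dem(cfg)
    bad = syn.TransectConstraints(elevation_band=(8000.0, 9000.0))
    with pytest.raises(ValueError, match="constraints"):
        syn.place_transects(dem, 3, 600.0, constraints=bad, seed=0)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def test_population_uniform_when_selection_is_flat():
    cfg = small_config(seed=8)
    dem = syn.generate_dem(cfg)
    ndvi = syn.generate_ndvi(dem, cfg)
    truth = syn.PopulationTruth(
        true_density_ind_per_km2=2000.0,
        selection=syn.SelectionFunction(beta_elevation=0.0, beta_ndvi=0.0))
    groups = syn.simulate_population(dem, ndvi, truth, seed=13)
    # quadrat chi-square on a 5x5 partition at alpha = 0.01
    qx = np.floor(groups["x"] / 600.0).astype(int).clip(0, 4)
    qy = np.floor((3000.0 - groups["y"]) / 600.0).astype(int).clip(0, 4)
    counts = np.bincount(qy * 5 + qx, minlength=25)
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    assert stats.chi2.sf(chi2, 24) > 0.01


def test_population_expected_total_individuals():
    # density 7/km2 over ~200 km2 -> about 1,400 individuals
    cfg = syn.LandscapeConfig(extent_m=(14160.0, 14160.0), cell_size_m=30.0,
                              seed=3)
    dem = syn.generate_dem(cfg)
    ndvi = syn.generate_ndvi(dem, cfg)
    truth = syn.PopulationTruth(true_density_ind_per_km2=7.0)
    totals = [syn.simulate_population(dem, ndvi, truth, seed=s)["group_size"].sum()
              for s in (4, 5, 6)]
    assert 1400 * 0.8 <= np.mean(totals) <= 1400 * 1.2


def test_group_sizes_and_class_counts():
    cfg = small_config(seed=5)
    dem = syn.generate_dem(cfg)
    ndvi = syn.generate_ndvi(dem, cfg)
    truth = syn.PopulationTruth(true_density_ind_per_km2=400.0)
    groups = syn.simulate_population(dem, ndvi, truth, seed=6)
    assert len(groups) >= 100
    sizes = groups["group_size"]
    assert sizes.min() >= 1 and sizes.max() <= 113
    se = sizes.std() / np.sqrt(len(sizes))
    assert abs(sizes.mean() - 14.4) <= 2 * se + 0.5
    parts = groups[["n_adult_male", "n_adult_female", "n_subadult",
                    "n_unclassified"]].sum(axis=1)
    assert (parts == sizes).all()
    assert groups["n_unclassified"].sum() > 0


def test_population_requires_valid_cells():
    cfg = small_config()
    dem = syn.generate_dem(cfg)
    ndvi = syn.generate_ndvi(dem, cfg)
    with pytest.raises(ValueError, match="zero intensity"):
        syn.simulate_population(dem, ndvi, syn.PopulationTruth(), seed=0,
                                valid_mask=np.zeros(dem.shape, dtype=bool))


# ---------------------------------------------------------------------------
# survey
# ---------------------------------------------------------------------------

def survey_scene(seed=7, density=400.0):
    cfg = small_config(seed=seed)
    dem = syn.generate_dem(cfg)
    ndvi = syn.generate_ndvi(dem, cfg)
    transects = syn.place_transects(dem, 4, 900.0, seed=seed + 1)
    truth = syn.PopulationTruth(true_density_ind_per_km2=density)
    groups = syn.simulate_population(dem, ndvi, truth, seed=seed + 2)
    return dem, transects, groups


def test_survey_detects_everything_at_rate_zero():
    dem, transects, groups = survey_scene()
    det = syn.DetectionModel(rate_per_m=0.0, max_distance_m=1500.0)
    obs = syn.simulate_survey(groups, transects, dem, det, seed=1)
    import shapely
    d = shapely.distance(shapely.points(groups["x"], groups["y"]),
                         transects.union())
    assert len(obs) == int((d <= 1500.0).sum())
    np.testing.assert_allclose(np.sort(obs["distance_m"]),
                               np.sort(d[d <= 1500.0]))


def test_survey_detects_nothing_at_extreme_rate():
    dem, transects, groups = survey_scene()
    det = syn.DetectionModel(rate_per_m=5.0, max_distance_m=1500.0)
    obs = syn.simulate_survey(groups, transects, dem, det, seed=1)
    assert len(obs) == 0 or obs["distance_m"].max() < 1.0


def test_survey_requires_transects():
    dem, _, groups = survey_scene()
    with pytest.raises(ValueError, match="empty transect"):
        syn.simulate_survey(groups, syn.TransectSet([]), dem,
                            syn.DetectionModel(), seed=0)


def test_survey_line_of_sight_blocks_hidden_group():
    from shapely.geometry import LineString

    # flat terrain with a 100-m wall between the transect and one group
    g = Grid(np.zeros((21, 21)), origin=(0.0, 630.0), cell_size=30.0)
    wall = g.values.copy()
    wall[:, 10] = 100.0
    dem = g.like(wall)
    transects = syn.TransectSet([LineString([(45.0, 100.0), (45.0, 500.0)])])
    groups = pd.DataFrame({
        "group_id": [0, 1],
        "x": [550.0, 100.0], "y": [300.0, 300.0],  # behind wall / same side
        "group_size": [5, 5], "n_adult_male": [2, 2],
        "n_adult_female": [2, 2], "n_subadult": [1, 1],
        "n_unclassified": [0, 0]})
    det = syn.DetectionModel(rate_per_m=0.0, max_distance_m=1500.0,
                             require_line_of_sight=True)
    obs = syn.simulate_survey(groups, transects, dem, det, seed=0)
    assert list(obs["x"]) == [100.0]


def test_fitted_rate_recovers_generating_decay():
    from shapely.geometry import LineString

    from bharal.selection import fit_exponential_rate

    # flat terrain, one central transect, uniform group placement: the
    # availability of distances is uniform, so detected distances follow a
    # truncated exponential and the closed-form MLE recovers the rate
    dem = Grid(np.zeros((100, 100)), origin=(0.0, 3000.0), cell_size=30.0)
    transects = syn.TransectSet([LineString([(1500.0, 0.0), (1500.0, 3000.0)])])
    rng = np.random.default_rng(42)
    n = 4000
    groups = pd.DataFrame({
        "group_id": np.arange(n),
        "x": rng.uniform(0, 3000, n), "y": rng.uniform(0, 3000, n),
        "group_size": np.ones(n, dtype=int),
        "n_adult_male": np.ones(n, dtype=int),
        "n_adult_female": np.zeros(n, dtype=int),
        "n_subadult": np.zeros(n, dtype=int),
        "n_unclassified": np.zeros(n, dtype=int)})
    det = syn.DetectionModel(rate_per_m=0.0035, max_distance_m=1500.0)
    obs = syn.simulate_survey(groups, transects, dem, det, seed=12)
    assert len(obs) >= 200
    rate = fit_exponential_rate(obs["distance_m"])
    assert rate.rate_per_m == pytest.approx(0.0035, rel=0.2)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def test_features_zero_settlements_and_infinite_distances():
    cfg = small_config()
    dem = syn.generate_dem(cfg)
    feats = syn.place_features(dem, syn.FeatureConfig(n_settlements=0), seed=0)
    assert feats.settlements == [] and feats.trails == [] and feats.livestock == []
    with pytest.warns(UserWarning):
        d = terrain.distance_surface(feats.settlements, dem)
    assert np.isinf(d.values).all()


def test_features_livestock_at_settlements_with_zero_radius():
    cfg = small_config(seed=2)
    dem = syn.generate_dem(cfg)
    fc = syn.FeatureConfig(n_settlements=3, livestock_per_settlement=2,
                           livestock_cluster_radius_m=0.0)
    feats = syn.place_features(dem, fc, seed=3)
    sx = {(round(p.x, 6), round(p.y, 6)) for p in feats.settlements}
    for lp in feats.livestock:
        assert (round(lp.x, 6), round(lp.y, 6)) in sx


def test_features_deterministic_and_in_valleys():
    cfg = small_config(seed=6)
    dem = syn.generate_dem(cfg)
    a = syn.place_features(dem, seed=9)
    b = syn.place_features(dem, seed=9)
    assert all(p.equals(q) for p, q in zip(a.settlements, b.settlements))
    elev_at = dem.sample([p.x for p in a.settlements],
                         [p.y for p in a.settlements])
    # settlements sit in the lower part of the elevation distribution
    assert np.median(elev_at) < np.median(dem.values)
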