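import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from shapely.geometry import LineString

from bharal import density as dens
from bharal import selection as sel
from bharal import synthetic as syn
from bharal.grid import CovariateStack, Grid


# ---------------------------------------------------------------------------
# exponential sighting-distance rate
# ---------------------------------------------------------------------------

def test_exponential_rate_closed_form():
    assert sel.fit_exponential_rate([400.0] * 7).rate_per_m == pytest.approx(0.0025)
    # the survey's spring scale: mean distance ~285.7 m -> rate ~0.0035
    d = np.full(50, 1000.0 / 3.5)
    assert sel.fit_exponential_rate(d).rate_per_m == pytest.approx(0.0035)
    r1 = sel.fit_exponential_rate([100.0, 300.0]).rate_per_m
    r2 = sel.fit_exponential_rate([200.0, 600.0]).rate_per_m
    assert r1 == pytest.approx(2 * r2)
    with pytest.raises(ValueError):
        sel.fit_exponential_rate([])
    with pytest.raises(ValueError, match="zero"):
        sel.fit_exponential_rate([0.0, 0.0])


# ---------------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------------

def strip_viewshed(n=60, cell=30.0):
    """Rectangular viewshed with a transect along the left edge."""
    g = Grid(np.ones((n, n)), origin=(0.0, n * cell), cell_size=cell)
    vs = dens.ViewshedResult(g, radius_m=n * cell)
    x0 = g.x_coords()[0]
    ts = syn.TransectSet([LineString([(x0, 0.0), (x0, n * cell)])])
    return vs, ts


def test_pseudo_absence_counts_and_reproducibility():
    vs, ts = strip_viewshed()
    rate = sel.ExponentialRate(0.0035)
    pa = sel.generate_pseudo_absences(vs, ts, 94, rate, seed=5)
    assert len(pa) == 9400  # 100 x 94
    pb = sel.generate_pseudo_absences(vs, ts, 94, rate, seed=5)
    pd.testing.assert_frame_equal(pa, pb)
    inside = vs.visible.sample(pa["x"].to_numpy(), pa["y"].to_numpy())
    assert (inside == 1.0).all()
    with pytest.raises(ValueError, match="candidates"):
        sel.generate_pseudo_absences(vs, ts, 94, rate, n_candidates=1000)


def test_pseudo_absence_distances_follow_target_law():
    vs, ts = strip_viewshed()
    # tiny rate: sampled distances keep the candidates' uniform law
    pa = sel.generate_pseudo_absences(vs, ts, 50, sel.ExponentialRate(1e-9),
                                      n_candidates=20000, seed=6)
    ks = stats.kstest(pa["distance_m"] / pa["distance_m"].max(), "uniform")
    assert ks.pvalue > 0.01
    # moderate rate: sampled distances follow the exponential-weighted
    # candidate law (chi-square against the exact target bin masses)
    rate = 0.002
    pa, cand = sel.generate_pseudo_absences(
        vs, ts, 20, sel.ExponentialRate(rate), n_candidates=50000, seed=7,
        return_candidates=True)
    edges = np.linspace(0.0, cand["distance_m"].max() + 1.0, 9)
    observed, _ = np.histogram(pa["distance_m"], edges)
    wsum, _ = np.histogram(cand["distance_m"], edges,
                           weights=cand["weight"].to_numpy())
    expected = len(pa) * wsum / wsum.sum()
    chi2 = ((observed - expected) ** 2 / expected).sum()
    assert stats.chi2.sf(chi2, len(observed) - 1) > 0.01
    # and the decay is visible: monotone decreasing bin counts
    assert observed[0] > observed[-1]


# ---------------------------------------------------------------------------
# group sizes and weights
# ---------------------------------------------------------------------------

def obs_table(sizes, distances, males=None, females=None, sub=None, uncl=None):
    n = len(sizes)
    males = males if males is not None else [1] * n
    females = females if females is not None else [1] * n
    sub = sub if sub is not None else [0] * n
    uncl = (uncl if uncl is not None
            else [s - m - f - b for s, m, f, b in zip(sizes, males, females, sub)])
    return pd.DataFrame({
        "obs_id": range(n), "season": "spring",
        "x": np.zeros(n), "y": np.zeros(n),
        "distance_m": distances, "group_size": sizes,
        "n_adult_male": males, "n_adult_female": females,
        "n_subadult": sub, "n_unclassified": uncl})


def test_groupsize_distance_correlation_matches_manual_formula():
    rng = np.random.default_rng(8)
    for _ in range(20):
        n = int(rng.integers(5, 15))
        sizes = rng.integers(1, 40, n).astype(float)
        dist = rng.uniform(0, 1000, n)
        if np.std(sizes) == 0:
            continue
        r, p = sel.test_groupsize_distance(obs_table(sizes, dist))
        cov = np.mean((sizes - sizes.mean()) * (dist - dist.mean()))
        manual = cov / (sizes.std() * dist.std())
        assert r == pytest.approx(manual, abs=1e-12)
    near = obs_table([1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0])
    r, p = sel.test_groupsize_distance(near)
    assert r == pytest.approx(1.0) and p < 1e-6
    with pytest.raises(ValueError, match="variance"):
        sel.test_groupsize_distance(obs_table([5, 5, 5], [1.0, 2.0, 3.0]))


def test_attribute_group_sizes_permutes_when_uncorrelated():
    rng = np.random.default_rng(9)
    obs = obs_table(rng.integers(1, 30, 40), rng.uniform(0, 1000, 40))
    pa = pd.DataFrame({"x": np.zeros(500), "y": np.zeros(500),
                       "distance_m": rng.uniform(0, 1500, 500)})
    out, model = sel.attribute_group_sizes(pa, obs, seed=3)
    assert model.strategy == "permute"
    assert set(out["attributed_group_size"]).issubset(set(obs["group_size"]))


def test_attribute_group_sizes_linear_model_when_correlated():
    rng = np.random.default_rng(10)
    d = rng.uniform(0, 1000, 80)
    sizes = np.maximum(1, np.round(5 + 0.01 * d + rng.normal(0, 1, 80)))
    obs = obs_table(sizes, d)
    pa = pd.DataFrame({"x": np.zeros(10), "y": np.zeros(10),
                       "distance_m": np.linspace(0, 900, 10)})
    out, model = sel.attribute_group_sizes(pa, obs, seed=3)
    assert model.strategy == "linear"
    pred = model.intercept + model.slope * pa["distance_m"]
    expect = np.maximum(1, np.floor(pred + 0.5)).astype(int)
    assert (out["attributed_group_size"].to_numpy() == expect.to_numpy()).all()


def test_linear_group_size_arithmetic_at_reported_coefficients():
    # autumn linear model: 8.498 + 0.009 * distance
    assert sel.predicted_group_size(8.498, 0.009, 500.0) == 13
    assert sel.predicted_group_size(8.498, 0.009, 0.0) == 8
    assert sel.predicted_group_size(0.2, 0.0, 900.0) == 1  # floored at 1


def test_adult_counts_with_unclassified_imputation():
    # rows: (4M+F, 2 sub, 0 uncl) and (0, 0, 3 uncl) with dataset R = 2/3
    obs = obs_table([6, 10], [0.0, 0.0], males=[2, 2], females=[2, 2],
                    sub=[2, 2], uncl=[0, 4])
    r = sel.adult_ratio(obs)
    assert r == pytest.approx(8 / 12)
    counts = sel.adult_counts(obs)
    assert counts[0] == pytest.approx(4.0)
    assert counts[1] == pytest.approx(4 + 4 * (8 / 12))
    # an all-unclassified group of 10 at R = 0.8
    obs2 = obs_table([10, 8, 2], [0.0, 0.0, 0.0], males=[0, 4, 1],
                     females=[0, 3, 1], sub=[0, 1, 0], uncl=[10, 0, 0])
    assert sel.adult_ratio(obs2) == pytest.approx(0.9)
    obs3 = obs_table([10, 10], [0.0, 0.0], males=[0, 4], females=[0, 4],
                     sub=[0, 2], uncl=[10, 0])
    assert sel.adult_ratio(obs3) == pytest.approx(0.8)
    assert sel.adult_counts(obs3)[0] == pytest.approx(8.0)


def test_compute_weights_conservation_and_proportionality():
    w_pres, w_pa = sel.compute_weights(np.full(10, 3.0), 10, np.full(40, 2.0))
    np.testing.assert_allclose(w_pres, 1.0)
    assert w_pa.sum() == pytest.approx(10.0)
    w_pres, _ = sel.compute_weights(np.array([2.0, 6.0]), 2, np.ones(5))
    np.testing.assert_allclose(w_pres, [0.5, 1.5])
    with pytest.raises(ValueError):
        sel.compute_weights(np.zeros(3), 3, np.ones(5))


# ---------------------------------------------------------------------------
# collinearity screen
# ---------------------------------------------------------------------------

def correlated_frame(seed=0):
    rng = np.random.default_rng(seed)
    n = 400
    slope = rng.normal(0, 1, n)
    noise = rng.normal(0, 1, n)
    # tri correlated with slope at ~0.948
    tri = 0.948 * slope + np.sqrt(1 - 0.948**2) * noise
    other = rng.normal(0, 1, n)
    return pd.DataFrame({"slope_deg": slope, "tri_m": tri, "ndvi": other})


def test_screen_drops_lower_priority_member_of_collinear_pair():
    frame = correlated_frame()
    rep = sel.screen_collinearity(frame, retain_priority=["slope_deg"])
    assert "tri_m" not in rep.retained and "slope_deg" in rep.retained
    assert rep.dropped[0][0] == "tri_m" and rep.dropped[0][1] == "slope_deg"
    assert abs(rep.correlations.loc["slope_deg", "tri_m"]) > 0.9


def test_screen_boundary_exactly_at_threshold_drops():
    # construct two columns with correlation exactly 0.7
    n = 100
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, n)
    b = rng.normal(0, 1, n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= a * (a @ b) / (a @ a)   # orthogonalize
    b /= b.std()
    y = 0.7 * a + np.sqrt(1 - 0.49) * b
    frame = pd.DataFrame({"x": a, "y": y})
    r = frame.corr().loc["x", "y"]
    assert r == pytest.approx(0.7, abs=1e-12)
    rep = sel.screen_collinearity(frame, retain_priority=["x"])
    assert rep.retained == ["x"]


def test_screen_keeps_uncorrelated_variables_and_is_order_stable():
    rng = np.random.default_rng(2)
    frame = pd.DataFrame(rng.normal(0, 1, (300, 4)),
                         columns=["a", "b", "c", "d"])
    rep = sel.screen_collinearity(frame, retain_priority=["a"])
    assert rep.retained == ["a", "b", "c", "d"] and rep.dropped == []
    shuffled = correlated_frame().sample(frac=1.0, random_state=5)
    rep1 = sel.screen_collinearity(correlated_frame(), retain_priority=["slope_deg"])
    rep2 = sel.screen_collinearity(shuffled, retain_priority=["slope_deg"])
    assert rep1.retained == rep2.retained


# ---------------------------------------------------------------------------
# model frame
# ---------------------------------------------------------------------------

def tiny_stack(n=40, cell=30.0, seed=0):
    rng = np.random.default_rng(seed)
    g = Grid(np.zeros((n, n)), origin=(0.0, n * cell), cell_size=cell)
    elev = g.like(3000 + 2000 * rng.random((n, n)))
    ndvi = g.like(rng.uniform(0, 0.8, (n, n)))
    return CovariateStack({"elevation": elev, "ndvi": ndvi})


def presences_at(stack, xs, ys, sizes=None):
    n = len(xs)
    sizes = sizes if sizes is not None else [4] * n
    return pd.DataFrame({
        "obs_id": range(n), "season": "spring", "x": xs, "y": ys,
        "distance_m": np.zeros(n), "group_size": sizes,
        "n_adult_male": [2] * n, "n_adult_female": [1] * n,
        "n_subadult": [1] * n,
        "n_unclassified": [s - 4 for s in sizes]})


def test_build_model_frame_sizes_filtering_and_weights():
    stack = tiny_stack()
    tmpl = stack.template
    rng = np.random.default_rng(3)
    xs = rng.uniform(50, 1150, 20)
    ys = rng.uniform(50, 1150, 20)
    pres = presences_at(stack, xs, ys)
    pa = pd.DataFrame({"x": rng.uniform(50, 1150, 200),
                       "y": rng.uniform(50, 1150, 200),
                       "distance_m": rng.uniform(0, 500, 200),
                       "attributed_group_size": rng.integers(1, 20, 200)})
    forest = tmpl.like(np.zeros(tmpl.shape))
    frame = sel.build_model_frame(pres, pa, stack, exclude_forest=True,
                                  forest_mask=forest)
    assert frame.n == 220 and frame.n_presence == 20
    w = frame.data["weight"]
    y = frame.data["presence"]
    assert w[y == 1].sum() == pytest.approx(20.0)
    assert w[y == 0].sum() == pytest.approx(20.0)

    # forest filtering drops presences and re-conserves weights
    infor = tmpl.like(np.zeros(tmpl.shape))
    r, c = tmpl.world_to_cell(xs[:5], ys[:5])
    infor.values[r, c] = 1.0
    frame2 = sel.build_model_frame(pres, pa, stack, exclude_forest=True,
                                   forest_mask=infor)
    assert frame2.n_presence == 15 and frame2.n_dropped_forest == 5
    w2, y2 = frame2.data["weight"], frame2.data["presence"]
    assert w2[y2 == 1].sum() == pytest.approx(15.0)
    assert w2[y2 == 0].sum() == pytest.approx(15.0)

    all_forest = tmpl.like(np.ones(tmpl.shape))
    with pytest.raises(ValueError, match="no presence"):
        sel.build_model_frame(pres, pa, stack, exclude_forest=True,
                              forest_mask=all_forest)
    out = pres.copy()
    out.loc[0, "x"] = -10_000.0
    with pytest.raises(ValueError, match="extent"):
        sel.build_model_frame(out, pa, stack, exclude_forest=False)


# ---------------------------------------------------------------------------
# GAM
# ---------------------------------------------------------------------------

def simulated_frame(n=5000, signal=0.0, seed=0, band=(4250.0, 4550.0)):
    """Frame with independent covariates; presence from a band preference."""
    rng = np.random.default_rng(seed)
    elev = rng.uniform(3200, 5400, n)
    ndvi = rng.uniform(0.0, 0.8, n)
    slope = rng.uniform(0, 60, n)
    livestock = rng.integers(0, 2, n).astype(float)
    eta = -1.0 + signal * ((elev >= band[0]) & (elev < band[1]))
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    data = pd.DataFrame({"presence": y, "weight": np.ones(n),
                         "elevation": elev, "ndvi": ndvi,
                         "slope_deg": slope, "livestock_presence": livestock})
    covs = ["elevation", "ndvi", "slope_deg", "livestock_presence"]
    return sel.ModelFrame(data, covs, int(y.sum()), int((1 - y).sum()))


def test_gam_null_case_explains_nothing():
    fit = sel.fit_habitat_gam(simulated_frame(signal=0.0, seed=4))
    assert fit.deviance_explained < 0.02
    assert fit.n == 5000


def test_gam_recovers_elevation_band_preference():
    fit = sel.fit_habitat_gam(simulated_frame(signal=2.0, seed=5))
    grid = np.linspace(3300, 5300, 201)
    part = fit.partial_dependence("elevation", grid)
    peak = grid[np.argmax(part)]
    assert 4250 <= peak <= 4550
    summary = fit.summary_frame()
    elev_row = summary[summary["term"] == "s(elevation)"].iloc[0]
    assert elev_row["p"] < 0.001 and elev_row["edf"] > 1
    assert 0 <= fit.deviance_explained <= 1


def test_gam_weight_scaling_invariance():
    frame = simulated_frame(n=2000, signal=1.5, seed=6)
    fit1 = sel.fit_habitat_gam(frame, alpha=0.1)
    doubled = sel.ModelFrame(frame.data.assign(weight=2 * frame.data["weight"]),
                             frame.covariates, frame.n_presence,
                             frame.n_pseudo_absence)
    # doubling weights and the penalty together is an exact reparametrization
    fit2 = sel.fit_habitat_gam(doubled, alpha=0.2)
    np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-6)


def test_unpenalized_gam_matches_plain_glm():
    frame = simulated_frame(n=1500, signal=1.0, seed=7)
    fit = sel.fit_habitat_gam(frame, df=5, alpha=1e-10)
    design = fit._design(frame.data)
    glm = sm.GLM(frame.data["presence"].to_numpy(), design,
                 family=sm.families.Binomial(),
                 var_weights=frame.data["weight"].to_numpy()).fit()
    np.testing.assert_allclose(fit.params, glm.params, atol=1e-4)


def test_predict_selection_consistent_with_row_predictions():
    frame = simulated_frame(n=3000, signal=2.0, seed=8)
    fit = sel.fit_habitat_gam(frame)
    n = 15
    g = Grid(np.zeros((n, n)), origin=(0.0, n * 30.0), cell_size=30.0)
    rng = np.random.default_rng(9)
    stack = CovariateStack({
        "elevation": g.like(rng.uniform(3300, 5300, (n, n))),
        "ndvi": g.like(rng.uniform(0, 0.8, (n, n))),
        "slope_deg": g.like(rng.uniform(0, 60, (n, n))),
        "livestock_presence": g.like(rng.integers(0, 2, (n, n)).astype(float)),
    })
    pred = sel.predict_selection(fit, stack)
    assert np.nanmin(pred.values) >= 0 and np.nanmax(pred.values) <= 1
    df = pd.DataFrame({k: np.asarray(v.values).ravel()
                       for k, v in stack.grids.items()})
    np.testing.assert_allclose(pred.values.ravel(), fit.predict(df), atol=1e-12)
    # constant covariates -> constant prediction
    const = CovariateStack({k: g.like(np.full((n, n), df[k].iloc[0]))
                            for k in df.columns})
    cpred = sel.predict_selection(fit, const)
    assert np.ptp(cpred.values) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="lacks"):
        sel.predict_selection(fit, CovariateStack({"elevation": g}))
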