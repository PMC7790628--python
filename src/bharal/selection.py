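"""Used-available habitat-selection inference.

The design contrasts presence locations (transect sightings) with
pseudo-absences sampled inside the 1,500-m viewshed: 50,000 uniform
candidate points are thinned to 100x the number of observations with
probabilities proportional to an exponential density of the distance to
the transect, so the available sample shares the survey's sighting-
distance profile.  Pseudo-absences receive group sizes either permuted
from the observed sizes or predicted from a distance linear model
(depending on whether group size correlates with distance), rows are
weighted by adult counts with equal total weight on each side, collinear
covariates (|r| >= 0.7) are screened out, and presence/availability is
modeled by a weighted binomial GAM with penalized-spline smooths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .density import ViewshedResult
from .grid import CovariateStack, Grid
from .synthetic import TransectSet

logger = logging.getLogger("bharal")

__all__ = [
    "ExponentialRate",
    "GroupSizeModel",
    "CollinearityReport",
    "ModelFrame",
    "GamFit",
    "fit_exponential_rate",
    "generate_pseudo_absences",
    "test_groupsize_distance",
    "attribute_group_sizes",
    "adult_ratio",
    "adult_counts",
    "compute_weights",
    "screen_collinearity",
    "build_model_frame",
    "fit_habitat_gam",
    "predict_selection",
]


@dataclass
class ExponentialRate:
    """MLE of the exponential sighting-distance decay (per meter)."""

    rate_per_m: float
    season: str = ""

    def __post_init__(self) -> None:
        if not self.rate_per_m > 0:
            raise ValueError("rate must be positive")


def fit_exponential_rate(distances, season: str = "") -> ExponentialRate:
    """Closed-form exponential MLE: rate = 1 / mean(distance)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances given")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    mean = d.mean()
    if mean <= 0:
        raise ValueError("all distances are zero; rate undefined")
    return ExponentialRate(float(1.0 / mean), season)


def generate_pseudo_absences(vs1500: ViewshedResult,
                             transects: TransectSet | shapely.Geometry,
                             n_obs: int, rate: ExponentialRate,
                             n_candidates: int = 50_000, multiplier: int = 100,
                             seed: int = 0, return_candidates: bool = False):
    """Distance-weighted pseudo-absence points inside the 1,500-m viewshed.

    Uniform candidates are drawn over visible cells (uniform within the
    cell), then ``multiplier * n_obs`` of them are sampled *without
    replacement* with probability proportional to
    ``exp(-rate * distance_to_transect)``.  Deterministic per seed.
    """
    n_sample = multiplier * n_obs
    if n_sample > n_candidates:
        raise ValueError(
            f"requested {n_sample} points from only {n_candidates} candidates")
    mask = vs1500.mask
    if not mask.any():
        raise ValueError("empty viewshed")
    rng = np.random.default_rng(seed)
    grid = vs1500.visible
    cells = np.argwhere(mask)
    pick = rng.integers(len(cells), size=n_candidates)
    rows, cols = cells[pick, 0], cells[pick, 1]
    cs = grid.cell_size
    x = grid.origin[0] + (cols + rng.uniform(0, 1, n_candidates)) * cs
    y = grid.origin[1] - (rows + rng.uniform(0, 1, n_candidates)) * cs

    union = transects.union() if isinstance(transects, TransectSet) else transects
    dist = shapely.distance(shapely.points(x, y), union)
    w = np.exp(-rate.rate_per_m * dist)
    w = w / w.sum()
    take = rng.choice(n_candidates, size=n_sample, replace=False, p=w)
    out = pd.DataFrame({"x": x[take], "y": y[take], "distance_m": dist[take]})
    out.reset_index(drop=True, inplace=True)
    if return_candidates:
        cand = pd.DataFrame({"x": x, "y": y, "distance_m": dist, "weight": w})
        return out, cand
    return out


def test_groupsize_distance(obs: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of group size vs distance."""
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    size = obs["group_size"].to_numpy(dtype=float)
    dist = obs["distance_m"].to_numpy(dtype=float)
    if np.std(size) == 0 or np.std(dist) == 0:
        raise ValueError("zero variance in group size or distance")
    r, p = stats.pearsonr(size, dist)
    return float(r), float(p)


@dataclass
class GroupSizeModel:
    """How pseudo-absence group sizes were attributed."""

    strategy: str               # "permute" or "linear"
    correlation_r: float
    correlation_p: float
    intercept: float = float("nan")
    slope: float = float("nan")

    def __post_init__(self) -> None:
        if self.strategy not in {"permute", "linear"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")


def attribute_group_sizes(pa: pd.DataFrame, obs: pd.DataFrame,
                          alpha: float = 0.05, seed: int = 0
                          ) -> tuple[pd.DataFrame, GroupSizeModel]:
    """Attribute group sizes to pseudo-absence points.

    If group size does not correlate with distance (two-sided p >=
    ``alpha``) sizes are resampled with replacement from the observed
    sizes; otherwise an ordinary least-squares line of size on distance
    supplies predicted sizes, rounded to the nearest integer and floored
    at 1.
    """
    if len(obs) == 0:
        raise ValueError("empty observation table")
    r, p = test_groupsize_distance(obs)
    pa = pa.copy()
    if p >= alpha:
        rng = np.random.default_rng(seed)
        sizes = obs["group_size"].to_numpy()
        pa["attributed_group_size"] = rng.choice(sizes, size=len(pa), replace=True)
        model = GroupSizeModel("permute", r, p)
    else:
        fit = stats.linregress(obs["distance_m"].to_numpy(dtype=float),
                               obs["group_size"].to_numpy(dtype=float))
        pred = fit.intercept + fit.slope * pa["distance_m"].to_numpy(dtype=float)
        pa["attributed_group_size"] = np.maximum(
            1, np.floor(pred + 0.5).astype(int))
        model = GroupSizeModel("linear", r, p, float(fit.intercept),
                               float(fit.slope))
    logger.info("group-size attribution: %s (r=%.3f, p=%.3f)",
                model.strategy, r, p)
    return pa, model


def predicted_group_size(intercept: float, slope: float, distance_m: float) -> int:
    """Linear-model group size at a distance, rounded, floored at 1."""
    return max(1, int(np.floor(intercept + slope * distance_m + 0.5)))


def adult_ratio(obs: pd.DataFrame) -> float:
    """Dataset-level ratio of adults among all classified individuals."""
    adults = (obs["n_adult_male"] + obs["n_adult_female"]).sum()
    classified = adults + obs["n_subadult"].sum()
    if classified == 0:
        raise ValueError("no classified individuals in the dataset")
    return float(adults) / float(classified)


def adult_counts(obs: pd.DataFrame) -> np.ndarray:
    """Adults per observation, imputing unclassified individuals.

    adults_i = males_i + females_i + unclassified_i * R, with R the
    dataset-level adult ratio among classified individuals.
    """
    r = adult_ratio(obs)
    return (obs["n_adult_male"].to_numpy(dtype=float)
            + obs["n_adult_female"].to_numpy(dtype=float)
            + obs["n_unclassified"].to_numpy(dtype=float) * r)


def compute_weights(adults_presence: np.ndarray, n_obs: int,
                    pa_adults: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adult-proportional weights with equal totals on both sides.

    Presence weight_i = adults_i / sum(adults) * n_obs (so presence
    weights sum to the number of observations); pseudo-absence weights
    are proportional to attributed adult counts and rescaled to the same
    total.
    """
    adults_presence = np.asarray(adults_presence, dtype=float)
    pa_adults = np.asarray(pa_adults, dtype=float)
    tot = adults_presence.sum()
    if tot <= 0:
        raise ValueError("zero total adults among presences")
    w_pres = adults_presence / tot * n_obs
    tot_pa = pa_adults.sum()
    if tot_pa <= 0:
        raise ValueError("zero total adults among pseudo-absences")
    w_pa = pa_adults / tot_pa * n_obs
    return w_pres, w_pa


@dataclass
class CollinearityReport:
    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped, because_of, r)
    correlations: pd.DataFrame


def screen_collinearity(frame: pd.DataFrame, threshold: float = 0.7,
                        retain_priority: list[str] | None = None
                        ) -> CollinearityReport:
    """Drop one variable of every pair with |Pearson r| >= threshold.

    Offending pairs are handled from the strongest correlation down; the
    member appearing *later* in ``retain_priority`` is dropped (variables
    absent from the priority list rank after all listed ones, in column
    order).  The result depends only on the correlation matrix and the
    priority, not on row order.
    """
    cols = list(frame.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables to screen")
    if retain_priority is None:
        retain_priority = []
    rank = {v: i for i, v in enumerate(retain_priority)}
    base = len(retain_priority)
    order = {v: rank.get(v, base + i) for i, v in enumerate(cols)}
    corr = frame.corr(method="pearson")
    retained = list(cols)
    dropped: list[tuple[str, str, float]] = []
    # tiny tolerance so a correlation of exactly the threshold (up to float
    # rounding) counts as "equal to or greater"
    cut = threshold - 1e-12
    while True:
        worst = None
        worst_r = cut
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = abs(corr.loc[a, b])
                if r >= worst_r and (worst is None or r > worst_r):
                    worst, worst_r = (a, b), r
        if worst is None:
            break
        a, b = worst
        drop = b if order[a] <= order[b] else a
        keep = a if drop == b else b
        retained.remove(drop)
        dropped.append((drop, keep, float(corr.loc[a, b])))
    return CollinearityReport(retained, dropped, corr)


@dataclass
class ModelFrame:
    """Response/weights/covariates table for the selection GAM."""

    data: pd.DataFrame             # presence, weight, covariate columns
    covariates: list[str]
    n_presence: int
    n_pseudo_absence: int
    n_dropped_forest: int = 0

    @property
    def n(self) -> int:
        return len(self.data)


def build_model_frame(presences: pd.DataFrame, pseudo_absences: pd.DataFrame,
                      stack: CovariateStack, exclude_forest: bool = True,
                      forest_mask: Grid | None = None,
                      covariates: list[str] | None = None,
                      adult_ratio_value: float | None = None) -> ModelFrame:
    """Assemble the used-available model frame.

    Covariates are extracted at every point; presence rows falling in
    forest are dropped when ``exclude_forest`` (sightings there are
    assumed under-detected), and rows in nodata covariate cells (raster
    borders) are dropped with a log message.  Points outside the raster
    extent are an error.  Weights are recomputed on the filtered frame so
    that presence and pseudo-absence weights each sum to the number of
    remaining observations.  ``pseudo_absences`` must already carry
    ``attributed_group_size``.
    """
    if covariates is None:
        covariates = stack.names
    missing = [c for c in covariates if c not in stack]
    if missing:
        raise ValueError(f"covariates missing from the stack: {missing}")
    template = stack.template
    for df, label in ((presences, "presence"), (pseudo_absences, "pseudo-absence")):
        if not np.all(template.contains(df["x"].to_numpy(), df["y"].to_numpy())):
            raise ValueError(f"{label} points fall outside the raster extent")

    def extract(df: pd.DataFrame) -> pd.DataFrame:
        vals = stack.sample(df["x"].to_numpy(), df["y"].to_numpy())
        return pd.DataFrame({c: vals[c] for c in covariates})

    pres = presences.reset_index(drop=True).copy()
    if exclude_forest:
        if forest_mask is None:
            raise ValueError("exclude_forest requires a forest mask grid")
        in_forest = forest_mask.sample(pres["x"].to_numpy(),
                                       pres["y"].to_numpy()) == 1.0
        n_dropped = int(in_forest.sum())
        pres = pres.loc[~in_forest].reset_index(drop=True)
    else:
        n_dropped = 0

    pres_cov = extract(pres)
    pres_ok = ~pres_cov.isna().any(axis=1).to_numpy()
    pa = pseudo_absences.reset_index(drop=True)
    pa_cov = extract(pa)
    pa_ok = ~pa_cov.isna().any(axis=1).to_numpy()
    n_nodata = int((~pres_ok).sum() + (~pa_ok).sum())
    if n_nodata:
        logger.info("dropped %d rows in nodata covariate cells", n_nodata)
    pres, pres_cov = pres.loc[pres_ok], pres_cov.loc[pres_ok]
    pa_cov = pa_cov.loc[pa_ok]
    pa_sizes = pa.loc[pa_ok, "attributed_group_size"].to_numpy(dtype=float)
    if len(pres) == 0:
        raise ValueError("no presence observations remain after filtering")

    n_obs = len(pres)
    r = adult_ratio_value if adult_ratio_value is not None else adult_ratio(pres)
    pres_adults = (pres["n_adult_male"].to_numpy(dtype=float)
                   + pres["n_adult_female"].to_numpy(dtype=float)
                   + pres["n_unclassified"].to_numpy(dtype=float) * r)
    w_pres, w_pa = compute_weights(pres_adults, n_obs, pa_sizes * r)

    top = pres_cov.reset_index(drop=True)
    top.insert(0, "presence", 1.0)
    top.insert(1, "weight", w_pres)
    bot = pa_cov.reset_index(drop=True)
    bot.insert(0, "presence", 0.0)
    bot.insert(1, "weight", w_pa)
    data = pd.concat([top, bot], ignore_index=True)
    logger.info("model frame: %d presences (%d dropped in forest), %d pseudo-absences",
                n_obs, n_dropped, int(pa_ok.sum()))
    return ModelFrame(data, list(covariates), n_obs, int(pa_ok.sum()),
                      n_dropped)


# ---------------------------------------------------------------------------
# GAM fitting
# ---------------------------------------------------------------------------

BINARY_COVARIATES = ("livestock_presence",)
# candidate shared penalties for the grid search; the effective penalty
# scales with the total observation weight (about 2 x n_obs here), so the
# grid leans toward small values
_ALPHA_GRID = (1e-4, 1e-3, 1e-2, 0.1, 1.0, 10.0)


@dataclass
class GamFit:
    """A fitted weighted binomial habitat-selection GAM."""

    params: np.ndarray                   # intercept, linear, then basis coefs
    cov_params: np.ndarray               # Bayesian posterior covariance
    smoother: object                     # BSplines over standardized covariates
    smooth_vars: list[str]
    linear_vars: list[str]               # excludes the intercept
    standardize: dict[str, tuple[float, float]]   # var -> (mean, sd)
    bounds: dict[str, tuple[float, float]]        # var -> knot bounds (std scale)
    alpha: list[float]
    terms: pd.DataFrame = field(default_factory=pd.DataFrame)
    deviance_explained: float = float("nan")
    r2_adjusted: float = float("nan")
    n: int = 0
    converged: bool = True

    # -- design construction ------------------------------------------
    def _design(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        cols = [np.ones(n)]
        cols += [df[v].to_numpy(dtype=float) for v in self.linear_vars]
        for i, v in enumerate(self.smooth_vars):
            m, s = self.standardize[v]
            lo, hi = self.bounds[v]
            # clamp extrapolation to the training range edge
            x = np.clip((df[v].to_numpy(dtype=float) - m) / s, lo, hi)
            cols.append(self.smoother.smoothers[i].transform(x))
        return np.column_stack(cols)

    def predict_link(self, df: pd.DataFrame) -> np.ndarray:
        """Linear predictor (log-odds of selection) per row."""
        return self._design(df) @ self.params

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted selection probability (response scale) per row."""
        eta = self.predict_link(df)
        return 1.0 / (1.0 + np.exp(-eta))

    def term_slice(self, var: str) -> slice:
        """Column slice of one smooth term in the design/params."""
        i = self.smooth_vars.index(var)
        k0 = 1 + len(self.linear_vars)
        for j in range(i):
            k0 += self.smoother.smoothers[j].dim_basis
        return slice(k0, k0 + self.smoother.smoothers[i].dim_basis)

    def partial_dependence(self, var: str, values: np.ndarray) -> np.ndarray:
        """Link-scale contribution of one smooth term at given values."""
        i = self.smooth_vars.index(var)
        m, s = self.standardize[var]
        lo, hi = self.bounds[var]
        x = np.clip((np.asarray(values, dtype=float) - m) / s, lo, hi)
        basis = self.smoother.smoothers[i].transform(x)
        return basis @ self.params[self.term_slice(var)]

    def summary_frame(self) -> pd.DataFrame:
        return self.terms.copy()


def _pirls_fit(y, exog_lin, smoother, w, alpha):
    """Weighted penalized IRLS; returns params and weighted diagnostics.

    statsmodels' PIRLS accepts per-row weights but its post-fit deviance
    and edf ignore them, so the weighted deviance, effective degrees of
    freedom diag[(X'WX+S)^-1 X'WX] and posterior covariance (X'WX+S)^-1
    are recomputed here from the converged fit.
    """
    fam = sm.families.Binomial()
    model = GLMGam(y, exog=exog_lin, smoother=smoother, family=fam,
                   alpha=alpha)
    res = model.fit(maxiter=200, weights=w)
    params = np.asarray(res.params)
    mu = np.clip(np.asarray(res.fittedvalues), 1e-10, 1 - 1e-10)
    dev_w = float(fam.deviance(y, mu, var_weights=w))
    X = model.exog
    irls_w = w * fam.weights(mu)
    xtwx = X.T @ (X * irls_w[:, None])
    S = model.penal.penalty_matrix(alpha=alpha)
    vp = np.linalg.inv(xtwx + S)
    edf = np.diag(vp @ xtwx)
    converged = bool(getattr(res, "converged", True))
    return params, vp, edf, dev_w, mu, converged


def fit_habitat_gam(frame: ModelFrame, smooth_vars: list[str] | None = None,
                    linear_vars: list[str] | None = None, df: int = 8,
                    degree: int = 3, alpha="auto") -> GamFit:
    """Fit the weighted binomial (logit) habitat-selection GAM.

    Continuous covariates enter as penalized B-spline smooths on
    standardized values; binary covariates (livestock presence) enter
    linearly.  ``alpha`` is a single penalty, a per-term list, or
    ``"auto"`` for a small penalized-AIC grid search over a shared
    penalty (deviance + 2 * total edf).  Reported per smooth term:
    estimated degrees of freedom, reference df (basis dimension),
    Wald chi-square and p-value; per linear term: coefficient, SE, z, p.
    """
    data = frame.data
    if smooth_vars is None:
        smooth_vars = [c for c in frame.covariates if c not in BINARY_COVARIATES]
    if linear_vars is None:
        linear_vars = [c for c in frame.covariates if c in BINARY_COVARIATES]
    if not smooth_vars:
        raise ValueError("no continuous covariates to smooth")

    # rows with zero weight (groups with no adults) carry no likelihood
    # information and break the IRLS weighting; drop them explicitly
    wall = frame.data["weight"].to_numpy(dtype=float)
    if np.any(wall <= 0):
        logger.info("dropping %d zero-weight rows before fitting",
                    int((wall <= 0).sum()))
        data = frame.data.loc[wall > 0].reset_index(drop=True)
    y = data["presence"].to_numpy(dtype=float)
    w = data["weight"].to_numpy(dtype=float)
    standardize: dict[str, tuple[float, float]] = {}
    bounds: dict[str, tuple[float, float]] = {}
    xs = []
    knot_kwds = []
    for v in smooth_vars:
        x = data[v].to_numpy(dtype=float)
        m, s = float(x.mean()), float(x.std())
        if s == 0:
            raise ValueError(f"covariate {v!r} is constant")
        xstd = (x - m) / s
        standardize[v] = (m, s)
        lo, hi = float(xstd.min()), float(xstd.max())
        bounds[v] = (lo, hi)
        xs.append(xstd)
        knot_kwds.append({"lower_bound": lo, "upper_bound": hi})
    smoother = BSplines(np.column_stack(xs), df=[df] * len(smooth_vars),
                        degree=[degree] * len(smooth_vars),
                        variable_names=list(smooth_vars), knot_kwds=knot_kwds)
    exog_lin = np.column_stack(
        [np.ones(len(data))] + [data[v].to_numpy(dtype=float) for v in linear_vars])

    if alpha == "auto":
        best = None
        for a in _ALPHA_GRID:
            try:
                fitted = _pirls_fit(y, exog_lin, smoother, w,
                                    [a] * len(smooth_vars))
            except Exception:  # noqa: BLE001 - candidate may fail to converge
                continue
            paic = fitted[3] + 2.0 * float(np.sum(fitted[2]))
            if not np.isfinite(paic):
                continue
            if best is None or paic < best[0]:
                best = (paic, a, fitted)
        if best is None:
            raise RuntimeError("GAM did not converge for any penalty candidate")
        alpha_used = [best[1]] * len(smooth_vars)
        params, vp, edf_all, dev_w, mu, converged = best[2]
    else:
        alpha_used = ([float(alpha)] * len(smooth_vars)
                      if np.isscalar(alpha) else [float(a) for a in alpha])
        params, vp, edf_all, dev_w, mu, converged = _pirls_fit(
            y, exog_lin, smoother, w, alpha_used)

    if not converged:
        logger.warning("GAM IRLS did not fully converge")
    if np.any(mu <= 1e-8) or np.any(mu >= 1 - 1e-8):
        logger.warning("fitted probabilities at the boundary: possible separation")

    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                  var_weights=w).fit()
    dev_expl = 1.0 - dev_w / null.deviance
    edf_total = float(edf_all.sum())
    nreal = len(y)
    ybar = float(np.average(y, weights=w))
    rss = float(np.sum(w * (y - mu) ** 2))
    tss = float(np.sum(w * (y - ybar) ** 2))
    r2_adj = 1.0 - (rss / max(nreal - edf_total, 1.0)) / (tss / (nreal - 1))

    # per-term summaries (Wald tests against the posterior covariance)
    rows = []
    bse = np.sqrt(np.diag(vp))
    for j, v in enumerate(["(Intercept)"] + list(linear_vars)):
        z = params[j] / bse[j]
        rows.append({"term": v, "type": "linear", "coefficient": params[j],
                     "se": bse[j], "z": z,
                     "p": 2 * stats.norm.sf(abs(z)),
                     "edf": np.nan, "ref_df": np.nan, "chi_sq": np.nan})
    k0 = 1 + len(linear_vars)
    for i, v in enumerate(smooth_vars):
        dim = smoother.smoothers[i].dim_basis
        cols = slice(k0, k0 + dim)
        k0 += dim
        edf_term = float(edf_all[cols].sum())
        beta = params[cols]
        covinv = np.linalg.pinv(vp[cols, :][:, cols])
        chi2 = float(beta @ covinv @ beta)
        dof = max(edf_term, 1e-6)
        rows.append({"term": f"s({v})", "type": "smooth", "coefficient": np.nan,
                     "se": np.nan, "z": np.nan,
                     "p": float(stats.chi2.sf(chi2, dof)),
                     "edf": edf_term, "ref_df": float(dim), "chi_sq": chi2})
    terms = pd.DataFrame(rows)

    return GamFit(np.asarray(params), np.asarray(vp), smoother,
                  list(smooth_vars), list(linear_vars), standardize, bounds,
                  list(alpha_used), terms, float(dev_expl), float(r2_adj),
                  nreal, converged)


def predict_selection(fit: GamFit, stack: CovariateStack) -> Grid:
    """Per-cell predicted relative selection (response scale) over a stack."""
    needed = fit.smooth_vars + fit.linear_vars
    missing = [v for v in needed if v not in stack]
    if missing:
        raise ValueError(f"stack lacks covariate layers: {missing}")
    template = stack.template
    cols = {v: np.asarray(stack[v].values, dtype=float).ravel() for v in needed}
    df = pd.DataFrame(cols)
    ok = ~df.isna().any(axis=1)
    out = np.full(len(df), np.nan)
    if ok.any():
        out[ok.to_numpy()] = fit.predict(df.loc[ok])
    return template.like(out.reshape(template.shape))
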