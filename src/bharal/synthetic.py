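"""Synthetic mountain landscapes, ungulate populations, and surveys.

Everything downstream (terrain covariates, viewsheds, density estimation,
habitat-selection GAMs) is exercised on data from this module, so ground
truth is always known.  The generator mimics a high-Himalayan survey
area: a rugged DEM spanning roughly 2,870-6,150 m built from parametric
ridge functions plus spectrally smoothed noise, NDVI that tracks
elevation (forest band below ~4,000 m, grass/shrub to ~4,800 m, barren
and snow above), transects along ridge/valley lines, groups of animals
placed by a known selection function with negative-binomial group sizes
(mean ~14), and detections thinning approximately exponentially with
distance to the transect out to 1,500 m.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from scipy import ndimage
from scipy import stats as scistats
from shapely.geometry import LineString, Point

from .grid import Grid, write_ascii_grid, write_geojson

logger = logging.getLogger("bharal")

__all__ = [
    "LandscapeConfig",
    "SelectionFunction",
    "PopulationTruth",
    "DetectionModel",
    "TransectConstraints",
    "TransectSet",
    "FeatureConfig",
    "FeatureSet",
    "generate_dem",
    "generate_ndvi",
    "place_transects",
    "simulate_population",
    "simulate_survey",
    "place_features",
    "generate_calibration_points",
]

# Default NDVI-elevation profile: forest plateau below ~4,000 m, grass and
# shrub from ~4,050-4,750 m (NDVI mostly 0.25-0.5), barren/snow above
# ~4,900 m (NDVI below 0.14).
DEFAULT_NDVI_PROFILE = (
    (2870.0, 0.62),
    (3950.0, 0.58),
    (4050.0, 0.45),
    (4500.0, 0.40),
    (4750.0, 0.28),
    (4900.0, 0.12),
    (5400.0, 0.05),
    (6150.0, 0.01),
)


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    ``extent_m`` defaults to 21 x 21 km (441 km^2, the scale of one
    mountain survey block); elevations span 2,870-6,150 m.
    """

    extent_m: tuple[float, float] = (21000.0, 21000.0)
    cell_size_m: float = 30.0
    elevation_range_m: tuple[float, float] = (2870.0, 6150.0)
    ridge_count: int = 6
    ridge_width_m: float = 2500.0
    noise_amplitude_m: float = 150.0
    noise_smoothing_cells: float = 4.0
    base_gradient: tuple[float, float] = (0.0, 0.0)  # dz/dx east, dz/dy north
    normalize_elevation: bool = True
    ndvi_profile: tuple[tuple[float, float], ...] = DEFAULT_NDVI_PROFILE
    ndvi_noise_sd: float = 0.05
    ndvi_patchiness_m: float = 500.0   # sd of vegetation-band displacement
    ndvi_aspect_amplitude: float = 0.10  # south-facing greening range
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0 or self.cell_size_m <= 0:
            raise ValueError("extent and cell size must be positive")
        for dim in (w, h):
            if abs(dim / self.cell_size_m - round(dim / self.cell_size_m)) > 1e-9:
                raise ValueError("extent must be divisible by the cell size")
        lo, hi = self.elevation_range_m
        if lo >= hi:
            raise ValueError("elevation range must have min < max")

    @property
    def shape(self) -> tuple[int, int]:
        w, h = self.extent_m
        return (int(round(h / self.cell_size_m)), int(round(w / self.cell_size_m)))


@dataclass
class SelectionFunction:
    """Known habitat-selection truth: log-intensity of group placement.

    The log relative intensity of a cell is
    ``beta_elevation * 1[elevation in elevation_band] +
    beta_ndvi * 1[ndvi in ndvi_band]`` — a step preference matching how
    partial-response recovery is later judged.
    """

    elevation_band: tuple[float, float] = (4250.0, 4550.0)
    ndvi_band: tuple[float, float] = (0.25, 0.50)
    beta_elevation: float = 2.5
    beta_ndvi: float = 1.0

    def log_intensity(self, elevation: np.ndarray, ndvi: np.ndarray) -> np.ndarray:
        e0, e1 = self.elevation_band
        v0, v1 = self.ndvi_band
        s = self.beta_elevation * ((elevation >= e0) & (elevation < e1))
        s = s + self.beta_ndvi * ((ndvi >= v0) & (ndvi < v1))
        return s.astype(float)


@dataclass
class PopulationTruth:
    """Ground-truth population parameters.

    Defaults emulate the surveyed population: overall density around 7
    individuals/km^2, negative-binomial group sizes with mean 14.4
    truncated to [1, 113], a 35/45/20 adult-male/adult-female/subadult
    mix, and 15% of individuals left unclassified.
    """

    true_density_ind_per_km2: float = 7.0
    selection: SelectionFunction = field(default_factory=SelectionFunction)
    group_size_mean: float = 14.4
    group_size_dispersion: float = 1.5  # negative-binomial size parameter
    group_size_max: int = 113
    class_proportions: tuple[float, float, float] = (0.35, 0.45, 0.20)
    unclassified_fraction: float = 0.15

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.group_size_mean < 1 or self.group_size_max < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.unclassified_fraction <= 1:
            raise ValueError("unclassified fraction must be in [0, 1]")


@dataclass
class DetectionModel:
    """Per-group detection: p(detect) = exp(-rate * distance), truncated."""

    rate_per_m: float = 0.0035
    max_distance_m: float = 1500.0
    require_line_of_sight: bool = False

    def __post_init__(self) -> None:
        if self.rate_per_m < 0:
            raise ValueError("rate must be >= 0")
        if self.max_distance_m <= 0:
            raise ValueError("max distance must be positive")


@dataclass
class TransectSet:
    """Survey transect polylines in the landscape frame."""

    lines: list[LineString]

    @property
    def lengths_m(self) -> np.ndarray:
        return np.array([ln.length for ln in self.lines])

    @property
    def total_length_m(self) -> float:
        return float(self.lengths_m.sum())

    def union(self):
        return shapely.union_all(self.lines)

    def __len__(self) -> int:
        return len(self.lines)

    def save(self, path) -> None:
        write_geojson(self.lines, path,
                      [{"transect_id": i, "length_m": ln.length}
                       for i, ln in enumerate(self.lines)])


@dataclass
class TransectConstraints:
    """Eligibility constraints for transect placement (survey-design rules:
    mean elevation 3,000-5,000 m, low forest cover, near settlements)."""

    elevation_band: tuple[float, float] = (3000.0, 5000.0)
    forest_mask: Grid | None = None
    max_forest_fraction: float = 0.5
    max_settlement_distance_m: float | None = None
    settlement_distance: Grid | None = None


@dataclass
class FeatureConfig:
    n_settlements: int = 5
    n_trails: int = 6
    livestock_per_settlement: int = 8
    livestock_cluster_radius_m: float = 800.0


@dataclass
class FeatureSet:
    settlements: list[Point]
    trails: list[LineString]
    livestock: list[Point]

    def save(self, path) -> None:
        geoms = self.settlements + self.trails + self.livestock
        props = ([{"layer": "settlement"}] * len(self.settlements)
                 + [{"layer": "trail"}] * len(self.trails)
                 + [{"layer": "livestock"}] * len(self.livestock))
        write_geojson(geoms, path, props)


# ---------------------------------------------------------------------------
# DEM and NDVI
# ---------------------------------------------------------------------------

def generate_dem(config: LandscapeConfig) -> Grid:
    """Generate a DEM as plane + parametric ridges + smoothed noise.

    With ``ridge_count=0`` and ``noise_amplitude_m=0`` the surface is the
    analytic plane ``z = emin + gx*x + gy*y`` (useful for closed-form
    terrain tests).  With ``normalize_elevation=True`` (default) the
    surface is rescaled linearly onto ``elevation_range_m`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.shape
    grid = Grid(np.zeros((nrows, ncols)), origin=(0.0, float(config.extent_m[1])),
                cell_size=config.cell_size_m)
    X, Y = grid.cell_centers()
    gx, gy = config.base_gradient
    z = gx * X + gy * Y

    width, height = config.extent_m
    for k in range(config.ridge_count):
        # random ridge line through the domain; alternate ridges and valleys
        px, py = rng.uniform(0, width), rng.uniform(0, height)
        theta = rng.uniform(0, np.pi)
        nx, ny = -np.sin(theta), np.cos(theta)  # unit normal to the ridge line
        dist = (X - px) * nx + (Y - py) * ny
        amp = rng.uniform(400.0, 900.0) * (1 if k % 2 == 0 else -1)
        z = z + amp * np.exp(-(dist**2) / (2 * config.ridge_width_m**2))

    if config.noise_amplitude_m > 0:
        noise = rng.standard_normal((nrows, ncols))
        noise = ndimage.gaussian_filter(noise, config.noise_smoothing_cells)
        sd = noise.std()
        if sd > 0:
            z = z + noise * (config.noise_amplitude_m / sd)

    emin, emax = config.elevation_range_m
    if config.normalize_elevation:
        zmin, zmax = z.min(), z.max()
        if zmax - zmin < 1e-12:
            z = np.full_like(z, 0.5 * (emin + emax))
        else:
            z = emin + (z - zmin) * (emax - emin) / (zmax - zmin)
    else:
        z = emin + z
    return grid.like(z)


def _ndvi_of_elevation(elev: np.ndarray,
                       profile: tuple[tuple[float, float], ...]) -> np.ndarray:
    knots = np.array([k for k, _ in profile])
    vals = np.array([v for _, v in profile])
    return np.interp(elev, knots, vals)


def generate_ndvi(dem: Grid, config: LandscapeConfig) -> Grid:
    """NDVI tracking the elevation profile, with patchiness and exposure.

    The piecewise elevation profile sets the expected greenness of each
    vegetation band.  Band edges are displaced by a smooth random field
    (``ndvi_patchiness_m``, in meters of apparent elevation) so grass,
    shrub and barren form patches rather than perfect contour bands;
    south-facing cells are greener by up to ``ndvi_aspect_amplitude``;
    and white observation noise (``ndvi_noise_sd``, smoothed) is added.
    With all three set to 0 NDVI is a pure function of elevation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    elev = np.asarray(dem.values, dtype=float)
    apparent = elev
    if config.ndvi_patchiness_m > 0:
        shift = ndimage.gaussian_filter(rng.standard_normal(dem.shape), 5.0)
        sd = shift.std()
        if sd > 0:
            apparent = elev + shift * (config.ndvi_patchiness_m / sd)
    ndvi = _ndvi_of_elevation(apparent, config.ndvi_profile)
    if config.ndvi_aspect_amplitude > 0:
        from .terrain import horn_aspect, south_deviation

        southdev = np.asarray(south_deviation(horn_aspect(dem)).values)
        effect = config.ndvi_aspect_amplitude * (0.5 - southdev / 180.0)
        ndvi = ndvi + np.where(np.isfinite(effect), effect, 0.0)
    if config.ndvi_noise_sd > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(dem.shape), 2.0)
        sd = noise.std()
        if sd > 0:
            ndvi = ndvi + noise * (config.ndvi_noise_sd / sd)
    return dem.like(np.clip(ndvi, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Transects
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def place_transects(dem: Grid, n_transects: int, target_length_m: float,
                    constraints: TransectConstraints | None = None,
                    seed: int = 0) -> TransectSet:
    """Place transects that follow local ridge or valley lines.

    A relief score (DEM minus its smoothed version) marks ridges
    (positive) and valleys (negative).  Each transect starts on a
    high-|score| eligible cell and greedily walks to the neighbor that
    keeps the same relief sign strongest, within the elevation band,
    until the target length is reached.  Walks shorter than half the
    target are discarded and retried, so lengths land within -50%/+~2%
    of the target.
    """
    if constraints is None:
        constraints = TransectConstraints()
    rng = np.random.default_rng(seed)
    z = np.asarray(dem.values, dtype=float)
    lo, hi = constraints.elevation_band
    eligible = (z >= lo) & (z <= hi) & np.isfinite(z)
    if constraints.forest_mask is not None:
        frac = ndimage.uniform_filter(
            np.asarray(constraints.forest_mask.values, dtype=float), size=5)
        eligible &= frac < constraints.max_forest_fraction
    if (constraints.settlement_distance is not None
            and constraints.max_settlement_distance_m is not None):
        eligible &= (np.asarray(constraints.settlement_distance.values)
                     < constraints.max_settlement_distance_m)
    if not eligible.any():
        raise ValueError("no cells satisfy the transect placement constraints")

    score = z - ndimage.gaussian_filter(z, 5.0)
    abs_score = np.where(eligible, np.abs(score), -np.inf)
    # start candidates: upper quartile of |relief| among eligible cells
    thresh = np.quantile(np.abs(score)[eligible], 0.75)
    starts = np.argwhere(eligible & (np.abs(score) >= thresh))
    if len(starts) == 0:
        starts = np.argwhere(eligible)

    cs = dem.cell_size
    nr, nc = dem.shape
    lines: list[LineString] = []
    occupied = np.zeros(dem.shape, dtype=bool)
    attempts = 0
    while len(lines) < n_transects:
        attempts += 1
        if attempts > 200 * n_transects:
            raise ValueError("unable to place the requested transects")
        r, c = starts[rng.integers(len(starts))]
        if occupied[r, c]:
            continue
        sign = 1.0 if score[r, c] >= 0 else -1.0
        path = [(r, c)]
        visited = {(r, c)}
        length = 0.0
        while length < target_length_m:
            best = None
            best_val = -np.inf
            for dr, dc in _NEIGHBORS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc):
                    continue
                if (rr, cc) in visited or not eligible[rr, cc] or occupied[rr, cc]:
                    continue
                val = sign * score[rr, cc]
                if val > best_val:
                    best_val, best = val, (rr, cc)
            if best is None:
                break
            step = cs * (np.sqrt(2.0) if best[0] != r and best[1] != c else 1.0)
            length += step
            r, c = best
            path.append((r, c))
            visited.add((r, c))
        if length < 0.5 * target_length_m:
            continue
        xs = dem.origin[0] + (np.array([p[1] for p in path]) + 0.5) * cs
        ys = dem.origin[1] - (np.array([p[0] for p in path]) + 0.5) * cs
        lines.append(LineString(np.column_stack([xs, ys])))
        for p in path:
            occupied[p] = True
    return TransectSet(lines)


# ---------------------------------------------------------------------------
# Population and survey
# ---------------------------------------------------------------------------

GROUP_COLUMNS = ["group_id", "x", "y", "group_size", "n_adult_male",
                 "n_adult_female", "n_subadult", "n_unclassified"]


def _draw_group_sizes(rng: np.random.Generator, n: int,
                      truth: PopulationTruth) -> np.ndarray:
    """Negative-binomial sizes truncated to [1, group_size_max]."""
    k = truth.group_size_dispersion
    m = truth.group_size_mean
    p = k / (k + m)
    sizes = np.empty(n, dtype=int)
    todo = np.arange(n)
    while todo.size:
        draw = rng.negative_binomial(k, p, todo.size)
        ok = (draw >= 1) & (draw <= truth.group_size_max)
        sizes[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return sizes


def simulate_population(dem: Grid, ndvi: Grid, truth: PopulationTruth,
                        seed: int = 0, valid_mask: np.ndarray | None = None
                        ) -> pd.DataFrame:
    """Place animal groups by an inhomogeneous point process.

    The number of groups is Poisson with mean
    ``density * area / mean group size``; cells are drawn with
    probability proportional to ``exp(log_intensity)`` and positions are
    uniform within the cell.  Individuals get a sex/age class from the
    truth proportions, then a fraction is relabeled unclassified.
    """
    rng = np.random.default_rng(seed)
    elev = np.asarray(dem.values, dtype=float)
    nd = np.asarray(ndvi.values, dtype=float)
    valid = np.isfinite(elev) & np.isfinite(nd)
    if valid_mask is not None:
        valid &= valid_mask
    if not valid.any():
        raise ValueError("zero intensity everywhere: no valid cells")

    s = truth.selection.log_intensity(elev, nd)
    weights = np.where(valid, np.exp(s - s[valid].max()), 0.0).ravel()
    weights /= weights.sum()

    area_km2 = valid.sum() * dem.cell_area_km2
    # expected group count uses the truncated group-size mean so realized
    # individual totals are unbiased for the configured density
    k, m = truth.group_size_dispersion, truth.group_size_mean
    support = np.arange(1, truth.group_size_max + 1)
    pmf = scistats.nbinom.pmf(support, k, k / (k + m))
    trunc_mean = float((support * pmf).sum() / pmf.sum())
    expected_groups = (truth.true_density_ind_per_km2 * area_km2 / trunc_mean)
    n_groups = int(rng.poisson(expected_groups))

    idx = rng.choice(weights.size, size=n_groups, p=weights)
    rows, cols = np.unravel_index(idx, dem.shape)
    cs = dem.cell_size
    xs = dem.origin[0] + (cols + rng.uniform(0, 1, n_groups)) * cs
    ys = dem.origin[1] - (rows + rng.uniform(0, 1, n_groups)) * cs

    sizes = _draw_group_sizes(rng, n_groups, truth)
    pm, pf, ps = truth.class_proportions
    classed = rng.multinomial(1, [pm, pf, ps],
                              size=int(sizes.sum())) if n_groups else np.empty((0, 3))
    records = []
    pos = 0
    for gid in range(n_groups):
        size = int(sizes[gid])
        cls = classed[pos:pos + size]
        pos += size
        mask = rng.uniform(size=size) < truth.unclassified_fraction
        kept = cls[~mask]
        nm, nf, nsub = (int(kept[:, j].sum()) for j in range(3)) if len(kept) else (0, 0, 0)
        records.append((gid, xs[gid], ys[gid], size, nm, nf, nsub, int(mask.sum())))
    df = pd.DataFrame.from_records(records, columns=GROUP_COLUMNS)
    logger.info("simulated %d groups, %d individuals over %.1f km2",
                n_groups, int(sizes.sum()) if n_groups else 0, area_km2)
    return df


OBSERVATION_COLUMNS = ["obs_id", "season", "x", "y", "distance_m", "group_size",
                       "n_adult_male", "n_adult_female", "n_subadult",
                       "n_unclassified", "on_transect"]


def simulate_survey(groups: pd.DataFrame, transects: TransectSet, dem: Grid,
                    det: DetectionModel, seed: int = 0,
                    season: str = "spring") -> pd.DataFrame:
    """Simulate transect detections of the simulated groups.

    A group at perpendicular distance d from the nearest transect is
    detected with probability ``exp(-rate * d)`` when ``d <= max
    distance``, and (optionally) only if the nearest point on the
    transect has line-of-sight to the group.
    """
    if len(transects) == 0:
        raise ValueError("empty transect set")
    rng = np.random.default_rng(seed)
    union = transects.union()
    pts = shapely.points(groups["x"].to_numpy(), groups["y"].to_numpy())
    dist = shapely.distance(pts, union)
    p_det = np.exp(-det.rate_per_m * dist)
    detected = (dist <= det.max_distance_m) & (rng.uniform(size=len(groups)) < p_det)

    if det.require_line_of_sight and detected.any():
        from shapely.ops import nearest_points

        from .density import line_of_sight  # local import avoids a cycle
        for i in np.nonzero(detected)[0]:
            pt = pts[i]
            obs_pt = nearest_points(union, pt)[0]
            ocell = dem.world_to_cell(obs_pt.x, obs_pt.y)
            tcell = dem.world_to_cell(pt.x, pt.y)
            if not line_of_sight(dem, (int(ocell[0]), int(ocell[1])),
                                 (int(tcell[0]), int(tcell[1]))):
                detected[i] = False

    out = groups.loc[np.asarray(detected)].reset_index(drop=True).copy()
    out.insert(0, "obs_id", np.arange(len(out)))
    out.insert(1, "season", season)
    out["distance_m"] = np.asarray(dist)[np.asarray(detected)]
    out["on_transect"] = True
    out = out[OBSERVATION_COLUMNS]
    logger.info("survey detected %d of %d groups", len(out), len(groups))
    return out


# ---------------------------------------------------------------------------
# Anthropogenic features and calibration points
# ---------------------------------------------------------------------------

def place_features(dem: Grid, config: FeatureConfig | None = None,
                   seed: int = 0) -> FeatureSet:
    """Settlements in valley bottoms, trails between them, livestock nearby."""
    if config is None:
        config = FeatureConfig()
    rng = np.random.default_rng(seed)
    if config.n_settlements == 0:
        return FeatureSet([], [], [])
    z = np.asarray(dem.values, dtype=float)
    smooth = ndimage.gaussian_filter(np.where(np.isfinite(z), z, np.nanmax(z)), 3.0)
    # valley bottoms: lowest decile of the smoothed surface
    thresh = np.nanquantile(smooth, 0.10)
    cand = np.argwhere(smooth <= thresh)
    take = rng.choice(len(cand), size=min(config.n_settlements, len(cand)),
                      replace=False)
    cs = dem.cell_size
    settlements = [Point(dem.origin[0] + (c + 0.5) * cs,
                         dem.origin[1] - (r + 0.5) * cs)
                   for r, c in cand[take]]
    trails = []
    if len(settlements) >= 2:
        for _ in range(config.n_trails):
            i, j = rng.choice(len(settlements), size=2, replace=False)
            a, b = settlements[i], settlements[j]
            mid = Point(0.5 * (a.x + b.x) + rng.normal(0, 0.05 * abs(a.x - b.x) + cs),
                        0.5 * (a.y + b.y) + rng.normal(0, 0.05 * abs(a.y - b.y) + cs))
            trails.append(LineString([a, mid, b]))
    livestock = []
    for s in settlements:
        for _ in range(config.livestock_per_settlement):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, config.livestock_cluster_radius_m)
            livestock.append(Point(s.x + rad * np.cos(ang), s.y + rad * np.sin(ang)))
    return FeatureSet(settlements, trails, livestock)


# Elevation bands used to label synthetic calibration points (transition
# zones are skipped so labels are unambiguous).
_CALIBRATION_BANDS = {
    "forest": (0.0, 3900.0),
    "shrubland": (4100.0, 4400.0),
    "grassland": (4400.0, 4700.0),
    "barren": (4950.0, 1e9),
}


def generate_calibration_points(dem: Grid, ndvi: Grid, n_per_class: int = 30,
                                seed: int = 0) -> pd.DataFrame:
    """Labeled land-cover calibration points with their NDVI values.

    Labels come from the elevation band each point sits in (the same
    bands that drive the synthetic NDVI profile), mimicking
    ground-truthed validation points.
    """
    rng = np.random.default_rng(seed)
    elev = np.asarray(dem.values, dtype=float)
    rows = []
    for label, (lo, hi) in _CALIBRATION_BANDS.items():
        cand = np.argwhere((elev >= lo) & (elev < hi))
        if len(cand) == 0:
            continue
        take = rng.choice(len(cand), size=min(n_per_class, len(cand)),
                          replace=False)
        for r, c in cand[take]:
            x = dem.origin[0] + (c + 0.5) * dem.cell_size
            y = dem.origin[1] - (r + 0.5) * dem.cell_size
            rows.append({"x": x, "y": y, "landcover": label,
                         "ndvi": float(ndvi.values[r, c])})
    return pd.DataFrame(rows)


def save_truth(truth: PopulationTruth, path) -> None:
    """Write ground-truth parameters as a YAML sidecar."""
    doc = {
        "true_density_ind_per_km2": truth.true_density_ind_per_km2,
        "selection": {
            "elevation_band": list(truth.selection.elevation_band),
            "ndvi_band": list(truth.selection.ndvi_band),
            "beta_elevation": truth.selection.beta_elevation,
            "beta_ndvi": truth.selection.beta_ndvi,
        },
        "group_size": {"mean": truth.group_size_mean,
                       "dispersion": truth.group_size_dispersion,
                       "max": truth.group_size_max},
        "class_proportions": list(truth.class_proportions),
        "unclassified_fraction": truth.unclassified_fraction,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)
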