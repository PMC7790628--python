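"""Terrain covariates derived from a DEM.

Slope and aspect use Horn's third-order finite difference on the 3x3
window (weights 1-2-1); ruggedness is the Riley index (root of summed
squared elevation differences to the eight neighbors).  Hydrology follows
the classic single-flow-direction chain: priority-flood sink filling with
an epsilon gradient toward the spill, D8 steepest-descent routing, and
upstream-cell accumulation.  Cliffs are connected components of steep
slope above a minimum area.  All operators preserve the input frame and
propagate nodata (NaN).
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
import shapely
from scipy import ndimage

from .grid import Grid

__all__ = [
    "horn_slope",
    "horn_aspect",
    "south_deviation",
    "riley_tri",
    "detect_cliffs",
    "fill_sinks",
    "d8_flow_direction",
    "flow_accumulation",
    "extract_streams",
    "distance_surface",
    "livestock_presence",
]

# D8 direction codes (ArcGIS convention), paired with (drow, dcol) offsets.
# Ties between equally steep neighbors resolve to the lowest code.
D8_CODES = (1, 2, 4, 8, 16, 32, 64, 128)
D8_OFFSETS = {
    1: (0, 1),     # E
    2: (1, 1),     # SE
    4: (1, 0),     # S
    8: (1, -1),    # SW
    16: (0, -1),   # W
    32: (-1, -1),  # NW
    64: (-1, 0),   # N
    128: (-1, 1),  # NE
}
D8_OUTLET = 0  # border cell draining off-grid


def _horn_gradients(dem: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Interior dz/dx (east+) and dz/dy (south+) by Horn's kernel."""
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("Horn kernel needs a grid of at least 3x3")
    z = np.asarray(dem.values, dtype=float)
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    eight = 8.0 * dem.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / eight
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / eight
    return dzdx, dzdy


def horn_slope(dem: Grid) -> Grid:
    """Slope in degrees, [0, 90); border cells nodata."""
    dzdx, dzdy = _horn_gradients(dem)
    out = np.full(dem.shape, np.nan)
    out[1:-1, 1:-1] = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.like(out)


def horn_aspect(dem: Grid) -> Grid:
    """Downslope direction, degrees clockwise from north; flat -> nodata.

    The aspect is the compass bearing of the steepest-descent vector, so a
    plane dipping due south yields 180 and one dipping due east yields 90.
    """
    dzdx, dzdy = _horn_gradients(dem)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # downslope vector (east, north) = (-dzdx, dzdy_south)
        asp = np.degrees(np.arctan2(-dzdx, dzdy)) % 360.0
    flat = np.hypot(dzdx, dzdy) == 0
    asp[flat] = np.nan
    out = np.full(dem.shape, np.nan)
    out[1:-1, 1:-1] = asp
    return dem.like(out)


def south_deviation(aspect: Grid) -> Grid:
    """Angular deviation of the aspect from due south, in [0, 180]."""
    a = np.asarray(aspect.values, dtype=float)
    d = np.abs(a - 180.0)
    out = np.minimum(d, 360.0 - d)
    return aspect.like(out)


def riley_tri(dem: Grid) -> Grid:
    """Riley terrain ruggedness index (m); border cells nodata."""
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("TRI needs a grid of at least 3x3")
    z = np.asarray(dem.values, dtype=float)
    center = z[1:-1, 1:-1]
    ssq = np.zeros_like(center)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = z[1 + dr : z.shape[0] - 1 + dr, 1 + dc : z.shape[1] - 1 + dc]
            ssq = ssq + (nb - center) ** 2
    out = np.full(dem.shape, np.nan)
    out[1:-1, 1:-1] = np.sqrt(ssq)
    return dem.like(out)


def detect_cliffs(slope: Grid, threshold_deg: float = 45.0,
                  min_area_m2: float = 90.0) -> Grid:
    """Binary cliff grid: 8-connected steep patches above a minimum area.

    A cell is steep when its slope strictly exceeds ``threshold_deg``; a
    patch counts as cliff when its area (cells x cell size squared)
    strictly exceeds ``min_area_m2``.
    """
    s = np.asarray(slope.values, dtype=float)
    steep = np.where(np.isnan(s), False, s > threshold_deg)
    labels, nlab = ndimage.label(steep, structure=np.ones((3, 3), dtype=int))
    out = np.zeros(slope.shape, dtype=float)
    if nlab:
        sizes = np.bincount(labels.ravel())
        keep = sizes * slope.cell_size**2 > min_area_m2
        keep[0] = False
        out[keep[labels]] = 1.0
    out[np.isnan(s)] = np.nan
    return slope.like(out)


def fill_sinks(dem: Grid, epsilon: float = 1e-6) -> Grid:
    """Priority-flood depression filling.

    Raises every sink to its spill elevation plus a tiny monotone
    ``epsilon`` gradient toward the spill so that D8 routing never meets a
    flat.  Cells already draining are untouched; output >= input.
    """
    z = np.asarray(dem.values, dtype=float)
    nr, nc = z.shape
    filled = np.where(np.isnan(z), -np.inf, z).copy()
    visited = np.zeros_like(filled, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(nr):
        for c in range(nc):
            if r in (0, nr - 1) or c in (0, nc - 1):
                visited[r, c] = True
                heapq.heappush(heap, (filled[r, c], r, c))
    while heap:
        v, r, c = heapq.heappop(heap)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and not visited[rr, cc]:
                    visited[rr, cc] = True
                    filled[rr, cc] = max(filled[rr, cc], v + epsilon)
                    heapq.heappush(heap, (filled[rr, cc], rr, cc))
    filled[np.isnan(z)] = np.nan
    filled[np.isneginf(filled)] = np.nan
    return dem.like(filled)


def d8_flow_direction(dem_filled: Grid) -> Grid:
    """D8 steepest-descent direction codes on a sink-filled DEM.

    Each cell receives the code of the neighbor with the largest positive
    drop per unit distance (diagonals weighted by sqrt(2)); ties take the
    lowest code.  Border cells with no descending in-grid neighbor drain
    off-grid (code 0).  An interior cell with no descent means the DEM was
    not filled and raises ``ValueError``.
    """
    z = np.asarray(dem_filled.values, dtype=float)
    nr, nc = z.shape
    best_drop = np.full(z.shape, -np.inf)
    best_code = np.zeros(z.shape, dtype=float)
    padded = np.pad(z, 1, constant_values=np.nan)
    for code in D8_CODES:
        dr, dc = D8_OFFSETS[code]
        nb = padded[1 + dr : nr + 1 + dr, 1 + dc : nc + 1 + dc]
        dist = dem_filled.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        drop = (z - nb) / dist
        upd = np.where(np.isnan(drop), False, drop > best_drop)
        best_drop[upd] = drop[upd]
        best_code[upd] = code
    no_descent = ~(best_drop > 0)
    border = np.zeros(z.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    stuck = no_descent & ~border & ~np.isnan(z)
    if stuck.any():
        r, c = np.argwhere(stuck)[0]
        raise ValueError(f"unfilled sink or flat at cell ({r}, {c}); run fill_sinks")
    best_code[no_descent & border] = D8_OUTLET
    best_code[np.isnan(z)] = np.nan
    return dem_filled.like(best_code)


def flow_accumulation(directions: Grid) -> Grid:
    """Number of upstream cells draining through each cell (self excluded).

    Processes cells in topological order of the direction graph and raises
    ``ValueError`` on a cycle.  The conservation identity holds: summing
    accumulation+1 over outlet cells (code 0 or draining off-grid) gives
    the total number of drained cells.
    """
    codes = np.asarray(directions.values, dtype=float)
    nr, nc = codes.shape
    n = nr * nc
    valid = ~np.isnan(codes)
    down = np.full(n, -1, dtype=np.int64)  # -1: outlet / off-grid / nodata
    rr, cc = np.nonzero(valid)
    for r, c in zip(rr, cc):
        code = int(codes[r, c])
        if code == D8_OUTLET:
            continue
        dr, dc = D8_OFFSETS[code]
        r2, c2 = r + dr, c + dc
        if 0 <= r2 < nr and 0 <= c2 < nc and valid[r2, c2]:
            down[r * nc + c] = r2 * nc + c2
    indeg = np.zeros(n, dtype=np.int64)
    targets = down[down >= 0]
    np.add.at(indeg, targets, 1)
    acc = np.zeros(n, dtype=np.int64)
    queue = [i for i in range(n) if valid.flat[i] and indeg[i] == 0]
    processed = 0
    while queue:
        i = queue.pop()
        processed += 1
        j = down[i]
        if j >= 0:
            acc[j] += acc[i] + 1
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if processed != int(valid.sum()):
        raise ValueError("cycle detected in flow-direction grid")
    out = acc.reshape(nr, nc).astype(float)
    out[~valid] = np.nan
    return directions.like(out)


def extract_streams(accum: Grid, threshold_cells: int) -> Grid:
    """Binary stream grid: accumulation >= threshold (in cells)."""
    a = np.asarray(accum.values, dtype=float)
    out = np.where(a >= threshold_cells, 1.0, 0.0)
    out[np.isnan(a)] = np.nan
    return accum.like(out)


def stream_threshold_cells(drainage_km2: float, cell_size_m: float) -> int:
    """Convert a drainage-area threshold (km^2) to a cell count."""
    return max(1, int(round(drainage_km2 * 1e6 / cell_size_m**2)))


def distance_surface(features, template: Grid) -> Grid:
    """Euclidean distance (m) from each cell center to the nearest feature.

    ``features`` is either a binary Grid (distance to cells equal to 1,
    center to center) or an iterable of shapely geometries (distance to
    the geometry itself).  An empty feature set yields an all-infinite
    surface with a warning.
    """
    if isinstance(features, Grid):
        if not template.same_frame(features):
            raise ValueError("feature grid is not co-registered with template")
        mask = np.asarray(features.values, dtype=float) == 1.0
        if not mask.any():
            warnings.warn("empty feature grid: distance surface is infinite")
            return template.like(np.full(template.shape, np.inf))
        dist = ndimage.distance_transform_edt(~mask, sampling=template.cell_size)
        return template.like(dist.astype(float))
    geoms = [g for g in features if g is not None and not g.is_empty]
    if not geoms:
        warnings.warn("empty feature set: distance surface is infinite")
        return template.like(np.full(template.shape, np.inf))
    union = shapely.union_all(geoms)
    X, Y = template.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    dist = shapely.distance(pts, union).reshape(template.shape)
    return template.like(dist)


def livestock_presence(points, buffer_m: float = 500.0,
                       template: Grid | None = None) -> Grid:
    """Binary presence grid: 1 within ``buffer_m`` of any livestock point."""
    if template is None:
        raise ValueError("a template grid is required")
    dist = distance_surface(points, template)
    vals = np.asarray(dist.values, dtype=float)
    out = np.where(vals <= buffer_m, 1.0, 0.0)
    out[np.isnan(vals)] = np.nan
    return template.like(out)
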