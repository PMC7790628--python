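"""NDVI-based land-cover calibration and classification.

NDVI acts as the sole land-cover proxy: labeled calibration points give
each class an NDVI range (by quantiles), classes are compared with the
Wilcoxon rank-sum test, and rasters are classified by first-match against
a priority-ordered list of ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid

__all__ = [
    "CLASS_LABELS",
    "ClassRanges",
    "calibrate_ndvi_classes",
    "wilcoxon_rank_sum",
    "classify_ndvi",
    "UNCLASSIFIED",
]

CLASS_LABELS = (
    "grassland",
    "shrubland",
    "agricultural",
    "forest",
    "settlement",
    "barren",
    "water",
    "snow",
)

UNCLASSIFIED = -1  # raster code for NDVI outside every class range


@dataclass
class ClassRanges:
    """Per-class inclusive NDVI ranges with an overlap report."""

    ranges: dict[str, tuple[float, float]]
    overlaps: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"class {name!r}: low {lo} > high {hi}")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.ranges[name]

    def __contains__(self, name: str) -> bool:
        return name in self.ranges


def calibrate_ndvi_classes(points: pd.DataFrame,
                           quantiles: tuple[float, float] = (0.05, 0.95),
                           min_points: int = 3) -> ClassRanges:
    """Assign an NDVI range to each land-cover class from labeled points.

    ``points`` needs columns ``landcover`` (labels from ``CLASS_LABELS``)
    and ``ndvi``.  The range is the pair of configurable quantiles of the
    class's NDVI values (default [0.05, 0.95]); ``quantiles=(0, 1)``
    reduces to min/max.  The result carries a report of all pairwise
    range overlaps.
    """
    qlo, qhi = quantiles
    if not 0 <= qlo <= qhi <= 1:
        raise ValueError("quantiles must satisfy 0 <= low <= high <= 1")
    ranges: dict[str, tuple[float, float]] = {}
    for name, sub in points.groupby("landcover"):
        if name not in CLASS_LABELS:
            raise ValueError(f"unknown land-cover label {name!r}")
        vals = np.asarray(sub["ndvi"], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_points:
            raise ValueError(
                f"class {name!r} has {len(vals)} points; at least {min_points} needed")
        if np.any((vals < -1) | (vals > 1)):
            raise ValueError(f"class {name!r}: NDVI outside [-1, 1]")
        ranges[name] = (float(np.quantile(vals, qlo)), float(np.quantile(vals, qhi)))
    rows = []
    for a, b in combinations(sorted(ranges), 2):
        lo = max(ranges[a][0], ranges[b][0])
        hi = min(ranges[a][1], ranges[b][1])
        if lo <= hi:
            rows.append({"class_a": a, "class_b": b,
                         "overlap_low": lo, "overlap_high": hi})
    report = pd.DataFrame(rows, columns=["class_a", "class_b",
                                         "overlap_low", "overlap_high"])
    return ClassRanges(ranges, report)


@dataclass
class WilcoxonResult:
    statistic: float   # rank sum of the first sample (midranks for ties)
    p_value: float
    method: str        # "exact" or "normal"
    alternative: str


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon rank-sum test on two independent samples.

    The statistic is the sum of the (mid)ranks of ``x`` in the pooled
    sample.  For a combined size of at most 20 the null distribution is
    enumerated exactly over all rank subsets (ties handled through
    midranks); otherwise the normal approximation with tie correction and
    a 0.5 continuity correction is used.  The two-sided p-value is the
    doubled smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:nx].sum())

    if n <= 20:
        # Exact: every nx-subset of the pooled ranks is equally likely.
        total = comb(n, nx)
        n_le = n_ge = 0
        tol = 1e-9
        for idx in combinations(range(n), nx):
            s = ranks[list(idx)].sum()
            if s <= w + tol:
                n_le += 1
            if s >= w - tol:
                n_ge += 1
        p_le, p_ge = n_le / total, n_ge / total
        method = "exact"
    else:
        mean = nx * (n + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all observations identical
            p_le = p_ge = 1.0
        else:
            sd = np.sqrt(var)
            # continuity correction shifts the statistic toward the mean
            p_le = stats.norm.cdf((w - mean + 0.5) / sd)
            p_ge = stats.norm.sf((w - mean - 0.5) / sd)
        method = "normal"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return WilcoxonResult(w, p, method, alternative)


def classify_ndvi(ndvi: Grid, ranges: ClassRanges,
                  priority: list[str] | None = None) -> tuple[Grid, dict[int, str]]:
    """Classify an NDVI raster by first-match against priority-ordered ranges.

    Each cell takes the first class in ``priority`` whose inclusive range
    contains its NDVI; cells matching no class get ``UNCLASSIFIED`` (-1).
    Returns the integer class raster and a code -> label legend.
    """
    if priority is None:
        priority = sorted(ranges.ranges)
    unknown = [p for p in priority if p not in ranges.ranges]
    if unknown:
        raise ValueError(f"priority classes without ranges: {unknown}")
    vals = np.asarray(ndvi.values, dtype=float)
    out = np.full(ndvi.shape, float(UNCLASSIFIED))
    assigned = np.zeros(ndvi.shape, dtype=bool)
    legend = {UNCLASSIFIED: "unclassified"}
    for code, name in enumerate(priority):
        lo, hi = ranges[name]
        hit = ~assigned & (vals >= lo) & (vals <= hi)
        out[hit] = code
        assigned |= hit
        legend[code] = name
    out[np.isnan(vals)] = np.nan
    return ndvi.like(out), legend
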