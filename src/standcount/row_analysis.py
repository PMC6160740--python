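"""Crop row-line detection and seeding-uniformity statistics.

Row lines are built from the segmented objects in the vector domain:
objects are polygonised, dilated by a small buffer so within-row
neighbours fuse, fused polygons smaller than the area-median are
discarded (they are stray plants or debris off the row), and the
survivors' centroids become the row points.  Points are clustered on
their x coordinate into the known number of rows, connected along y (the
seeding direction) into polylines, and smoothed with a centered moving
average.

Three characteristics score the seeding job:

* ``CV_rs`` — coefficient of variation of the spacings between adjacent
  row lines (uniformity of row placement);
* ``E_rs``  — relative error of the mean spacing against the theoretical
  pitch T set on the seeding device;
* ``CV_su`` — coefficient of variation of the per-row estimated seedling
  totals (objects within 8.0 cm of a line count toward that row).

Spacing statistics use N-1 (the number of spacings) as divisor; per-row
count statistics use N (the number of rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString

__all__ = [
    "RowLineSet", "RowSpacingStats", "SeedlingUniformity",
    "build_row_points", "assign_row_labels", "connect_and_smooth",
    "row_spacing_stats", "seedling_uniformity",
    "DEFAULT_BUFFER_CM", "DEFAULT_ROW_ASSIGN_CM",
]

DEFAULT_BUFFER_CM = 2.0
DEFAULT_ROW_ASSIGN_CM = 8.0


@dataclass
class RowLineSet:
    """Detected row polylines, indexed 1..N left to right (increasing x).

    ``lines[i]`` is an (M, 2) array of (x, y) vertices in world cm with y
    strictly increasing.  Rows whose label attracted fewer than two points
    are degenerate: they are recorded in ``degenerate`` and excluded from
    the spacing statistics.
    """

    lines: dict[int, np.ndarray]
    degenerate: list[int] = field(default_factory=list)

    @property
    def indices(self) -> list[int]:
        return sorted(self.lines.keys())

    def linestring(self, idx: int) -> LineString:
        return LineString(self.lines[idx])

    def items(self):
        return self.lines.items()


# ---------------------------------------------------------------------------
# S1-S4: objects -> retained row points


def build_row_points(objs, buffer_cm: float = DEFAULT_BUFFER_CM) -> np.ndarray:
    """Vectorize, buffer, area-filter and reduce objects to row points.

    Objects become world-cm polygons (S1), are dilated by ``buffer_cm``
    with overlapping buffers unioned (S2), fused polygons with area below
    the median polygon area are eliminated (S3), and the survivors'
    centroids are returned as an (n, 2) array (S4).
    """
    if len(objs) == 0:
        raise ValueError("empty object set")
    polys = [objs.polygon(lbl).buffer(buffer_cm) for lbl in objs.labels]
    merged = shapely.union_all(polys)
    parts = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    areas = np.array([p.area for p in parts])
    median = float(np.median(areas))
    # ties with the median are kept; tolerance absorbs float jitter in
    # otherwise equal buffered areas
    keep = [p for p, a in zip(parts, areas) if a >= median * (1 - 1e-9)]
    return np.array([[p.centroid.x, p.centroid.y] for p in keep])


# ---------------------------------------------------------------------------
# S5-S6: row labeling


def assign_row_labels(points: np.ndarray, n_rows: int,
                      theoretical_spacing: float) -> np.ndarray:
    """Cluster point x-coordinates into ``n_rows`` groups, labels 1..N by x.

    Initial cluster centers come from the best least-squares fit of an
    N-tooth comb with pitch ``theoretical_spacing`` to the x values; a 1-D
    k-means refinement then runs until stable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    x = pts[:, 0]
    if len(x) < n_rows:
        raise ValueError(f"fewer points ({len(x)}) than rows ({n_rows})")
    if n_rows == 1:
        return np.ones(len(x), dtype=int)

    T = float(theoretical_spacing)
    # comb fit: slide an N-tooth comb of pitch T across the x range
    offsets = np.arange(x.min() - T, x.min() + T + 1e-9, T / 200.0)
    best_cost, best_centers = np.inf, None
    for off in offsets:
        teeth = off + T * np.arange(n_rows)
        d = np.abs(x[:, None] - teeth[None, :])
        cost = float((d.min(axis=1) ** 2).sum())
        if cost < best_cost:
            best_cost, best_centers = cost, teeth
    centers = best_centers.astype(float).copy()

    # 1-D k-means refinement
    assign = None
    for _ in range(200):
        new_assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for k in range(n_rows):
            sel = x[assign == k]
            if sel.size:
                centers[k] = sel.mean()
    order = np.argsort(centers)
    rank = np.empty(n_rows, dtype=int)
    rank[order] = np.arange(1, n_rows + 1)
    return rank[assign]


# ---------------------------------------------------------------------------
# S7-S8: connect and smooth


def connect_and_smooth(points: np.ndarray, labels: np.ndarray,
                       window: int = 5) -> RowLineSet:
    """Join same-label points along y into polylines and smooth their x.

    Smoothing is a centered moving average of ``window`` vertices with
    symmetrically shrinking windows at the ends (so straight lines are
    fixed points).  Labels holding fewer than two points yield degenerate
    rows, flagged and excluded from spacing statistics.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    lines: dict[int, np.ndarray] = {}
    degenerate: list[int] = []
    for lbl in sorted(set(int(v) for v in labels)):
        sel = pts[labels == lbl]
        # collapse duplicate y so vertices are strictly increasing in y
        order = np.argsort(sel[:, 1], kind="stable")
        sel = sel[order]
        ys, idx = np.unique(sel[:, 1], return_inverse=True)
        xs = np.zeros(len(ys))
        np.add.at(xs, idx, sel[:, 0])
        xs /= np.bincount(idx)
        if len(ys) < 2:
            degenerate.append(lbl)
            lines[lbl] = np.column_stack([xs, ys])
            continue
        lines[lbl] = np.column_stack([_moving_average(xs, window), ys])
    return RowLineSet(lines, degenerate)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x, dtype=float)
    n = len(x)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = x[i - h:i + h + 1].mean()
    return out


# ---------------------------------------------------------------------------
# Row characteristics


@dataclass
class RowSpacingStats:
    spacings: list[float]      # x_i, cm (adjacent-line mean distances)
    mean_spacing: float        # Xbar_rs, cm
    sd_spacing: float          # SD_rs, cm
    cv_rs: float               # percent
    e_rs: float                # percent, signed
    theoretical_spacing: float


@dataclass
class SeedlingUniformity:
    row_counts: list[float]    # u_i, estimated seedlings per row
    mean_count: float          # Xbar_su
    sd_count: float            # SD_su
    cv_su: float               # percent


def _line_x_at(verts: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.interp(y, verts[:, 1], verts[:, 0])


def row_spacing_stats(lines: RowLineSet, theoretical_spacing: float,
                      n_samples: int = 100) -> RowSpacingStats:
    """Mean/SD/CV of adjacent-row spacings and the spacing error rate.

    Each spacing x_i is the mean horizontal distance between adjacent
    lines sampled at ``n_samples`` evenly spaced y positions over their
    common y-extent.
    """
    idxs = [i for i in lines.indices if i not in lines.degenerate]
    if len(idxs) < 2:
        raise ValueError("need at least two non-degenerate row lines")
    spacings = []
    for a, b in zip(idxs[:-1], idxs[1:]):
        va, vb = lines.lines[a], lines.lines[b]
        lo = max(va[:, 1].min(), vb[:, 1].min())
        hi = min(va[:, 1].max(), vb[:, 1].max())
        if hi <= lo:
            raise ValueError(f"rows {a} and {b} have no overlapping y-extent")
        ys = np.linspace(lo, hi, n_samples)
        spacings.append(float(np.mean(_line_x_at(vb, ys) - _line_x_at(va, ys))))

    m = len(spacings)  # = N - 1
    xbar = float(np.sum(spacings) / m)
    sd = float(np.sqrt(np.sum((np.asarray(spacings) - xbar) ** 2) / m))
    cv = 100.0 * sd / xbar if xbar != 0 else float("inf")
    e_rs = 100.0 * (xbar - theoretical_spacing) / theoretical_spacing
    return RowSpacingStats(spacings, xbar, sd, cv, e_rs, theoretical_spacing)


def seedling_uniformity(centroids: np.ndarray, counts: np.ndarray,
                        lines: RowLineSet,
                        max_dist_cm: float = DEFAULT_ROW_ASSIGN_CM) -> SeedlingUniformity:
    """CV of per-row estimated seedling totals.

    Each object (centroid + estimated count) is assigned to the nearest
    row line within ``max_dist_cm`` (ties to the lower row index); objects
    farther than that from every line contribute to no row.
    """
    idxs = lines.indices
    if not idxs:
        raise ValueError("no row lines")
    centroids = np.asarray(centroids, dtype=float)
    counts = np.asarray(counts, dtype=float)
    geoms = {i: lines.linestring(i) if len(lines.lines[i]) > 1
             else shapely.Point(lines.lines[i][0]) for i in idxs}
    u = {i: 0.0 for i in idxs}
    for (cx, cy), c in zip(centroids, counts):
        p = shapely.Point(cx, cy)
        best_i, best_d = None, None
        for i in idxs:
            d = geoms[i].distance(p)
            if d <= max_dist_cm and (best_d is None or d < best_d - 1e-12):
                best_i, best_d = i, d
        if best_i is not None:
            u[best_i] += c

    vals = np.array([u[i] for i in idxs])
    n = len(vals)
    xbar = float(vals.mean())
    if xbar == 0:
        raise ValueError("zero mean per-row count")
    sd = float(np.sqrt(np.sum((vals - xbar) ** 2) / n))
    return SeedlingUniformity([float(v) for v in vals], xbar, sd, 100.0 * sd / xbar)
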