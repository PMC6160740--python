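"""Fifteen per-object shape descriptors (F1-F15).

Vector features F1-F4 come from the object's minimum enclosing rectangle
(MER); raster features F5-F15 from the pixel set itself.  Definitions
follow the object-based image analysis conventions common in remote
sensing software:

F1  MER perimeter (cm)                 F9  shape index = F15 / (4 sqrt(F6))
F2  MER area (cm^2)                    F10 length/width from moment ellipse
F3  F2 / F1 (cm)                       F11 rectangular fit in [0, 1]
F4  MER length/width (>= 1)            F12 density = sqrt(F6)/(1+sqrt(VarX+VarY))
F5  border index = F15 / (2(l+w))      F13 elliptic fit in [0, 1]
F6  pixel count                        F14 asymmetry = 1 - minor/major
F7  roundness (px)                     F15 border length (pixel-edge count)
F8  compactness = 4ab / F6

The moment ellipse has semi-axes a = 2 sqrt(lambda1), b = 2 sqrt(lambda2)
from the eigenvalues of the pixel-center covariance (population
normalisation); for degenerate objects b is floored at 0.5 px before any
ratio.  F15 counts 4-neighbor pixel edges facing background, so it is
additive over disjoint unions.  F11/F13 are membership fractions of pixel
centers against the analytic fitted rectangle/ellipse.  F7 is the radius
of the minimum enclosing circle minus the largest inscribed-disc radius
(from the Euclidean distance transform), in px.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

__all__ = [
    "ShapeFeatureVector", "min_enclosing_rectangle",
    "vector_features", "raster_features",
    "extract_features", "features_table", "FEATURE_NAMES",
]

FEATURE_NAMES = tuple(f"F{i}" for i in range(1, 16))

_MIN_MINOR_PX = 0.5  # floor of the moment-ellipse minor semi-axis


@dataclass
class ShapeFeatureVector:
    F1: float   # MER perimeter, cm
    F2: float   # MER area, cm^2
    F3: float   # area-perimeter ratio, cm
    F4: float   # MER length-width ratio
    F5: float   # border index
    F6: float   # area count, px
    F7: float   # roundness, px
    F8: float   # compactness
    F9: float   # shape index
    F10: float  # length/width (moment-based)
    F11: float  # rectangular fit
    F12: float  # density
    F13: float  # elliptic fit
    F14: float  # asymmetry
    F15: float  # border length, px edges

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# minimum enclosing rectangle


def min_enclosing_rectangle(pixels: tuple[np.ndarray, np.ndarray],
                            gsd_cm: float = 1.0,
                            mode: str = "rotated") -> tuple[float, float, float]:
    """(L, W, orientation) of the object's minimum enclosing rectangle in cm.

    ``mode='rotated'`` (default) is the minimum-area rotated rectangle over
    the convex hull of the pixel corner points; ``mode='axis'`` is the
    axis-aligned bounding box.  L >= W; orientation is the angle (radians)
    of the L side against the x axis.
    """
    rr, cc = np.asarray(pixels[0]), np.asarray(pixels[1])
    if rr.size == 0:
        raise ValueError("empty pixel set")
    if mode == "axis":
        l_px = cc.max() - cc.min() + 1.0
        w_px = rr.max() - rr.min() + 1.0
        ang = 0.0 if l_px >= w_px else np.pi / 2
        L, W = max(l_px, w_px), min(l_px, w_px)
        return (L * gsd_cm, W * gsd_cm, ang)
    if mode != "rotated":
        raise ValueError(f"unknown MER mode {mode!r}")

    corners = _pixel_corners(rr, cc)
    hull = shapely.MultiPoint(corners).convex_hull
    rect = shapely.oriented_envelope(hull)
    if rect.geom_type == "Point":
        return (gsd_cm, gsd_cm, 0.0)  # cannot occur for >= 1 pixel with corners
    xy = np.asarray(rect.exterior.coords)[:4] if rect.geom_type == "Polygon" else None
    if xy is None:
        # degenerate collinear hull: a line segment
        (x0, y0), (x1, y1) = np.asarray(rect.coords)[[0, -1]]
        L = float(np.hypot(x1 - x0, y1 - y0))
        return (L * gsd_cm, 0.0, float(np.arctan2(y1 - y0, x1 - x0)))
    e1 = np.hypot(*(xy[1] - xy[0]))
    e2 = np.hypot(*(xy[2] - xy[1]))
    if e1 >= e2:
        L, W = e1, e2
        d = xy[1] - xy[0]
    else:
        L, W = e2, e1
        d = xy[2] - xy[1]
    return (float(L) * gsd_cm, float(W) * gsd_cm, float(np.arctan2(d[1], d[0])))


def _pixel_corners(rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Corner points (x=col, y=row) of every pixel square, deduplicated."""
    x = cc[:, None] + np.array([-0.5, 0.5, 0.5, -0.5])
    y = rr[:, None] + np.array([-0.5, -0.5, 0.5, 0.5])
    pts = np.column_stack([x.ravel(), y.ravel()])
    return np.unique(pts, axis=0)


def vector_features(pixels, gsd_cm: float, mode: str = "rotated"):
    """F1..F4 from the minimum enclosing rectangle."""
    L, W, _ = min_enclosing_rectangle(pixels, gsd_cm, mode)
    W_eff = max(W, 1e-12)
    F1 = 2.0 * (L + W)
    F2 = L * W
    return F1, F2, F2 / F1, L / W_eff


# ---------------------------------------------------------------------------
# raster features


def _border_edge_count(rr: np.ndarray, cc: np.ndarray) -> int:
    """Number of 4-neighbor pixel edges between the object and background."""
    r0, c0 = rr.min(), cc.min()
    grid = np.zeros((rr.max() - r0 + 3, cc.max() - c0 + 3), dtype=bool)
    grid[rr - r0 + 1, cc - c0 + 1] = True
    n = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        n += int(np.count_nonzero(grid & ~np.roll(grid, (dr, dc), axis=(0, 1))))
    return n


def _moment_axes(rr: np.ndarray, cc: np.ndarray):
    """Centroid, principal directions and semi-axes (a >= b) of the moment ellipse."""
    x = cc.astype(float)
    y = rr.astype(float)
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)],
                    [np.mean(dx * dy), np.mean(dy * dy)]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = max(evals[0], 0.0), max(evals[1], 0.0)
    a = 2.0 * np.sqrt(lam1)
    b = 2.0 * np.sqrt(lam2)
    a = max(a, _MIN_MINOR_PX)
    b = max(b, _MIN_MINOR_PX)
    major = evecs[:, 1]  # (x, y) direction of the major axis
    minor = evecs[:, 0]
    return (mx, my), major, minor, a, b, cov


def raster_features(pixels, mer_px: tuple[float, float]) -> dict[str, float]:
    """F5..F15 from the pixel set; ``mer_px`` are the MER sides (l, w) in px."""
    rr = np.asarray(pixels[0])
    cc = np.asarray(pixels[1])
    n = rr.size
    if n == 0:
        raise ValueError("empty pixel set")

    F6 = float(n)
    F15 = float(_border_edge_count(rr, cc))
    F9 = F15 / (4.0 * np.sqrt(F6))
    l_px, w_px = mer_px
    F5 = F15 / max(2.0 * (l_px + w_px), 1e-12)

    (mx, my), major, minor, a, b, cov = _moment_axes(rr, cc)
    F10 = a / b
    F14 = 1.0 - b / a
    F8 = (2.0 * a) * (2.0 * b) / F6
    var_sum = cov[0, 0] + cov[1, 1]
    F12 = np.sqrt(F6) / (1.0 + np.sqrt(var_sum))

    # coordinates in the principal frame
    dx, dy = cc - mx, rr - my
    u = dx * major[0] + dy * major[1]
    v = dx * minor[0] + dy * minor[1]

    # rectangular fit: centroid-centered principal-axis rectangle,
    # area F6, aspect a/b  ->  sides sqrt(F6 a/b) x sqrt(F6 b/a)
    half_l = 0.5 * np.sqrt(F6 * a / b)
    half_w = 0.5 * np.sqrt(F6 * b / a)
    inside_rect = (np.abs(u) <= half_l) & (np.abs(v) <= half_w)
    F11 = float(np.count_nonzero(inside_rect)) / F6

    # elliptic fit: moment-oriented ellipse rescaled to area F6
    ae = np.sqrt(F6 * a / (np.pi * b))
    be = np.sqrt(F6 * b / (np.pi * a))
    inside_ell = (u / ae) ** 2 + (v / be) ** 2 <= 1.0
    n_in = float(np.count_nonzero(inside_ell))
    F13 = max(0.0, (2.0 * n_in - F6) / F6)

    F7 = _roundness(rr, cc)

    return {"F5": F5, "F6": F6, "F7": F7, "F8": F8, "F9": F9, "F10": F10,
            "F11": F11, "F12": float(F12), "F13": F13, "F14": F14, "F15": F15}


def _roundness(rr: np.ndarray, cc: np.ndarray) -> float:
    """Enclosing-circle radius minus largest inscribed-disc radius, in px."""
    corners = _pixel_corners(rr, cc)
    r_enc = shapely.minimum_bounding_radius(shapely.MultiPoint(corners))
    r0, c0 = rr.min(), cc.min()
    grid = np.zeros((rr.max() - r0 + 3, cc.max() - c0 + 3), dtype=bool)
    grid[rr - r0 + 1, cc - c0 + 1] = True
    edt = ndimage.distance_transform_edt(grid)
    return float(r_enc - edt.max())


# ---------------------------------------------------------------------------
# per-object extraction


def extract_features(pixels, gsd_cm: float, mer_mode: str = "rotated") -> ShapeFeatureVector:
    """All fifteen descriptors for one object pixel set."""
    L, W, _ = min_enclosing_rectangle(pixels, gsd_cm, mer_mode)
    W_eff = max(W, 1e-12)
    F1 = 2.0 * (L + W)
    F2 = L * W
    raster = raster_features(pixels, (L / gsd_cm, W / gsd_cm))
    return ShapeFeatureVector(F1=F1, F2=F2, F3=F2 / F1, F4=L / W_eff, **raster)


def features_table(objs, mer_mode: str = "rotated") -> pd.DataFrame:
    """One row per object: label, F1..F15, world-cm centroid."""
    rows = []
    for lbl in objs.labels:
        fv = extract_features(objs.pixels(lbl), objs.gsd_cm, mer_mode)
        cx, cy = objs.centroid_world(lbl)
        rows.append({"label": lbl, **fv.as_dict(),
                     "centroid_x_cm": cx, "centroid_y_cm": cy})
    cols = ["label", *FEATURE_NAMES, "centroid_x_cm", "centroid_y_cm"]
    return pd.DataFrame(rows, columns=cols)
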