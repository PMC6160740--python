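"""Vegetation/soil segmentation and object cleanup.

Pipeline order is fixed: Otsu threshold on a vegetation-index raster,
binarize, 8-connected component labeling, small-object (weed) removal,
then proximity merging of fragments.  The weed filter defaults to
1.16 cm^2, which at the nominal 0.18 cm ground sampling distance is a
36-pixel area threshold; the fragment merge joins objects no more than
1.0 cm apart (edge-to-edge, transitively).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .raster_io import BinaryMask, LabelImage
from .vegindex import VIRaster

__all__ = [
    "SeedlingObjectSet", "otsu_threshold", "binarize", "label_components",
    "remove_small_objects", "merge_nearby", "segment_image",
    "DEFAULT_MIN_AREA_CM2", "DEFAULT_MERGE_CM",
]

DEFAULT_MIN_AREA_CM2 = 1.16
DEFAULT_MERGE_CM = 1.0

_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class SeedlingObjectSet:
    """Labeled connected components surviving cleanup; the unit of counting."""

    label_image: LabelImage
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = self.label_image.data
        self._pixels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        objs = ndimage.find_objects(lab)
        for k, sl in enumerate(objs, start=1):
            if sl is None:
                continue
            sub = lab[sl]
            rr, cc = np.nonzero(sub == k)
            self._pixels[k] = (rr + sl[0].start, cc + sl[1].start)

    # -- basic accessors ---------------------------------------------------
    @property
    def labels(self) -> list[int]:
        return sorted(self._pixels.keys())

    def __len__(self) -> int:
        return len(self._pixels)

    @property
    def gsd_cm(self) -> float:
        return self.label_image.gsd_cm

    def pixels(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) arrays of the object's pixels."""
        return self._pixels[label]

    def area_px(self, label: int) -> int:
        return len(self._pixels[label][0])

    def area_cm2(self, label: int) -> float:
        return self.area_px(label) * self.gsd_cm ** 2

    def centroid_px(self, label: int) -> tuple[float, float]:
        """(col, row) centroid of pixel centers."""
        rr, cc = self._pixels[label]
        return (float(cc.mean()), float(rr.mean()))

    def centroid_world(self, label: int) -> tuple[float, float]:
        col, row = self.centroid_px(label)
        ox, oy = self.label_image.origin
        g = self.gsd_cm
        return (ox + col * g, oy + row * g)

    def polygon(self, label: int):
        """World-cm polygon of the object (union of its pixel squares)."""
        import shapely

        rr, cc = self._pixels[label]
        ox, oy = self.label_image.origin
        g = self.gsd_cm
        x0 = ox + (cc - 0.5) * g
        y0 = oy + (rr - 0.5) * g
        boxes = shapely.box(x0, y0, x0 + g, y0 + g)
        return shapely.union_all(boxes)

    def total_area_px(self) -> int:
        return sum(self.area_px(k) for k in self._pixels)


# ---------------------------------------------------------------------------
# thresholding


def otsu_threshold(vi: VIRaster) -> float:
    """Otsu's threshold of a VI raster, returned in original index units.

    The raster is linearly rescaled to 0..255 and binned into a 256-bin
    histogram; the threshold maximizing the between-class variance is found
    by exhaustive scan over the 255 candidate splits, ties broken by the
    lowest qualifying bin.  The returned value is the bin edge separating
    the two classes, mapped back to the input scale.
    """
    data = np.asarray(vi.data, dtype=np.float64).ravel()
    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:
        raise ValueError("constant raster has no Otsu threshold")

    hist, edges = np.histogram(data, bins=256, range=(vmin, vmax))
    p = hist / hist.sum()
    bin_centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(p)
    mu = np.cumsum(p * bin_centers)
    mu_total = mu[-1]
    # between-class variance for split after bin t (t = 0..254)
    w0_t = w0[:-1]
    w1_t = 1.0 - w0_t
    valid = (w0_t > 0) & (w1_t > 0)
    sigma_b = np.full(255, -np.inf)
    num = (mu_total * w0_t - mu[:-1]) ** 2
    sigma_b[valid] = num[valid] / (w0_t[valid] * w1_t[valid])
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[t + 1])


def binarize(vi: VIRaster, thr: float) -> BinaryMask:
    """Foreground where the index exceeds the threshold (vegetation is high)."""
    return BinaryMask((vi.data > thr).astype(np.uint8), vi.gsd_cm, vi.origin)


# ---------------------------------------------------------------------------
# components and cleanup


def _relabel_raster_scan(lab: np.ndarray) -> np.ndarray:
    """Relabel positive labels to 1..K in raster-scan order of first pixel."""
    flat = lab.ravel()
    nz = np.nonzero(flat)[0]
    if nz.size == 0:
        return np.zeros_like(lab, dtype=np.int32)
    first = {}
    order = []
    for idx in nz:
        v = flat[idx]
        if v not in first:
            first[v] = idx
            order.append(v)
    mapping = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    for newk, old in enumerate(order, start=1):
        mapping[old] = newk
    return mapping[lab]


def label_components(mask: BinaryMask) -> SeedlingObjectSet:
    """8-connected components labeled 1..K in raster-scan order of first pixel."""
    lab, _ = ndimage.label(mask.data, structure=_STRUCT8)
    lab = _relabel_raster_scan(lab)
    return SeedlingObjectSet(LabelImage(lab, mask.gsd_cm, mask.origin))


def remove_small_objects(objs: SeedlingObjectSet,
                         min_area_cm2: float = DEFAULT_MIN_AREA_CM2) -> SeedlingObjectSet:
    """Delete objects smaller than the area threshold (weed filter).

    The cm^2 threshold is converted to a pixel count rounded to the nearest
    integer (1.16 cm^2 at 0.18 cm GSD -> 36 px), so a 35-px object is
    removed and a 36-px object kept.
    """
    if min_area_cm2 <= 0:
        return objs
    thr_px = int(round(min_area_cm2 / objs.gsd_cm ** 2))
    lab = objs.label_image.data
    keep = np.zeros_like(lab, dtype=np.int32)
    for k in objs.labels:
        if objs.area_px(k) >= thr_px:
            rr, cc = objs.pixels(k)
            keep[rr, cc] = k
    return SeedlingObjectSet(
        LabelImage(_relabel_raster_scan(keep), objs.gsd_cm, objs.label_image.origin)
    )


def _boundary_pixels(objs: SeedlingObjectSet) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (N,2) and labels (N,) of pixels touching background (4-n)."""
    lab = objs.label_image.data
    fg = lab > 0
    eroded = ndimage.binary_erosion(fg, structure=ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
    bound = fg & ~eroded
    rr, cc = np.nonzero(bound)
    return np.column_stack([rr, cc]), lab[rr, cc]


def merge_nearby(objs: SeedlingObjectSet,
                 max_gap_cm: float = DEFAULT_MERGE_CM) -> SeedlingObjectSet:
    """Assign one label to objects within ``max_gap_cm`` of each other.

    Distance is the minimum edge-to-edge Euclidean distance between pixel
    centers of the objects' boundary pixels; merging takes the transitive
    closure, so chains of close fragments collapse into one object.  Pixel
    sets are united, not morphologically bridged.  Idempotent.
    """
    if len(objs) < 2 or max_gap_cm <= 0:
        return objs
    coords, labels = _boundary_pixels(objs)
    r_px = max_gap_cm / objs.gsd_cm
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=r_px, output_type="ndarray")

    parent = {k: k for k in objs.labels}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        la, lb = int(labels[i]), int(labels[j])
        if la != lb:
            ra, rb = find(la), find(lb)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    lab = objs.label_image.data
    out = np.zeros_like(lab, dtype=np.int32)
    for k in objs.labels:
        rr, cc = objs.pixels(k)
        out[rr, cc] = find(k)
    return SeedlingObjectSet(
        LabelImage(_relabel_raster_scan(out), objs.gsd_cm, objs.label_image.origin)
    )


# ---------------------------------------------------------------------------
# one-call pipeline


def segment_image(img, index_name: str = "ExG-ExR",
                  min_area_cm2: float = DEFAULT_MIN_AREA_CM2,
                  merge_cm: float = DEFAULT_MERGE_CM):
    """Threshold -> binarize -> label -> area-filter -> merge.

    Returns ``(objects, threshold, mask)``.
    """
    from .vegindex import compute_index

    vi = compute_index(img, index_name)
    thr = otsu_threshold(vi)
    mask = binarize(vi, thr)
    objs = label_components(mask)
    objs = remove_small_objects(objs, min_area_cm2)
    objs = merge_nearby(objs, merge_cm)
    return objs, thr, mask
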