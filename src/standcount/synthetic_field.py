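"""Synthetic plot-image generator with full ground truth.

Renders a georeferenced RGB image of a mechanically seeded plot: rows of
green rosette plants at a programmed pitch on a textured brown soil
background, with sub-filter-size weeds and optional shadow patches.  The
generator's purpose is to exercise every pipeline stage against known
truth — plant positions, per-cluster plant multiplicities, true row
centers, weed positions and the exact vegetation mask.

Field geometry defaults follow a direct-seeded rapeseed trial layout:
2.0 m x 2.5 m subplots, 8 rows at 20 cm theoretical spacing, 0.18 cm
ground sampling distance, per-object plant multiplicities right-skewed
with mean about 1.6 and mostly in 1-3.  Two growth-stage presets differ
only in leaf size, the second sized so rendered canopy cover is roughly
1.5x the first at equal plant density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_io import RGBPlotImage

__all__ = ["FieldSpec", "FieldTruth", "generate", "stage_presets",
           "easy_spec", "canopy_cover", "object_truth_counts"]


@dataclass
class FieldSpec:
    """All knobs of the synthetic field; defaults are the study conditions."""

    plot_width_m: float = 2.0
    plot_height_m: float = 2.5
    gsd_cm: float = 0.18
    n_rows: int = 8
    spacing_cm: float = 20.0          # theoretical pitch T
    row_jitter_cm: float = 1.0        # per-row x offset sd
    point_jitter_cm: float = 1.0      # per-cluster x scatter about the row line
    gap_min_cm: float = 2.0           # guaranteed along-row gap between clusters
    gap_mean_cm: float = 8.0          # mean along-row cluster gap (incl. minimum)
    multiplicity_probs: tuple = ()    # P(k plants | cluster), k = 1..len; empty = default
    k_max: int = 25
    leaf_length_cm: tuple = (1.5, 2.8)   # major-axis diameter range of one leaf
    leaf_aspect: tuple = (0.45, 0.65)    # minor/major axis ratio range
    leaves_per_plant: tuple = (2, 5)
    weed_density_per_m2: float = 2.0
    weed_length_cm: tuple = (0.5, 1.0)   # major diameter; area stays < 1.16 cm^2
    leaf_rgb: tuple = (60, 110, 50)
    leaf_jitter: int = 20
    soil_rgb: tuple = (120, 100, 80)
    soil_noise: int = 15          # luminance speckle sd (correlated across channels)
    chroma_noise: float = 3.0     # independent per-channel noise sd
    shadow: bool = False
    target_plants: int | None = None  # stop seeding once this many plants placed
    plot_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.gsd_cm <= 0:
            raise ValueError("gsd_cm must be positive")
        if (self.n_rows - 1) * self.spacing_cm >= self.plot_width_m * 100:
            raise ValueError("rows at the given pitch do not fit inside the plot")
        if self.multiplicity_probs:
            if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
                raise ValueError("multiplicity probabilities must sum to 1")

    def resolved_multiplicity(self) -> np.ndarray:
        """Cluster-size pmf over k = 1..k_max.

        Default: truncated geometric with mean about 1.6 (right-skewed,
        clusters mostly of 1-3 plants).
        """
        if self.multiplicity_probs:
            p = np.asarray(self.multiplicity_probs, dtype=float)
            if len(p) > self.k_max:
                raise ValueError("multiplicity distribution longer than k_max")
            return p
        p_geom = 1.0 / 1.6
        k = np.arange(1, self.k_max + 1)
        w = p_geom * (1 - p_geom) ** (k - 1)
        return w / w.sum()


@dataclass
class FieldTruth:
    """Ground truth accompanying a generated image."""

    plants: np.ndarray           # (n, 2) world-cm positions
    clusters: pd.DataFrame       # columns x, y, k: one row per seeded cluster
    row_x: np.ndarray            # true row center x per row (cm), left to right
    weeds: np.ndarray            # (m, 2) world-cm positions
    veg_mask: np.ndarray         # boolean vegetation raster (plants + weeds)
    plant_mask: np.ndarray       # boolean raster of plant pixels only
    seed: int | None

    @property
    def total_plants(self) -> int:
        return len(self.plants)

    def conserves_plants(self) -> bool:
        return int(self.clusters["k"].sum()) == self.total_plants


# ---------------------------------------------------------------------------
# rendering primitives


def _paint_ellipse(canvas: np.ndarray, mask: np.ndarray, cx: float, cy: float,
                   a_cm: float, b_cm: float, theta: float, color,
                   gsd: float) -> None:
    """Fill an oriented ellipse (world cm center/axes) into canvas + mask."""
    h, w = mask.shape
    r_cm = max(a_cm, b_cm)
    c0 = max(int((cx - r_cm) / gsd) - 1, 0)
    c1 = min(int((cx + r_cm) / gsd) + 2, w)
    r0 = max(int((cy - r_cm) / gsd) - 1, 0)
    r1 = min(int((cy + r_cm) / gsd) + 2, h)
    if c0 >= c1 or r0 >= r1:
        return
    cols = (np.arange(c0, c1) + 0.0) * gsd - cx
    rows = (np.arange(r0, r1) + 0.0) * gsd - cy
    dx, dy = np.meshgrid(cols, rows)
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a_cm) ** 2 + (v / b_cm) ** 2 <= 1.0
    sub = canvas[r0:r1, c0:c1]
    sub[inside] = color
    mask[r0:r1, c0:c1] |= inside


def _draw_plant(canvas, mask, x, y, spec: FieldSpec, rng) -> None:
    n_leaves = int(rng.integers(spec.leaves_per_plant[0], spec.leaves_per_plant[1] + 1))
    base = np.array(spec.leaf_rgb, dtype=float)
    for _ in range(n_leaves):
        length = rng.uniform(*spec.leaf_length_cm)
        a = length / 2.0
        b = a * rng.uniform(*spec.leaf_aspect)
        theta = rng.uniform(0, 2 * np.pi)
        # rosette: leaf extends outward from the plant center
        lx = x + 0.8 * a * np.cos(theta)
        ly = y + 0.8 * a * np.sin(theta)
        color = np.clip(base + rng.uniform(-spec.leaf_jitter, spec.leaf_jitter, 3),
                        0, 255)
        _paint_ellipse(canvas, mask, lx, ly, a, b, theta, color, spec.gsd_cm)


# ---------------------------------------------------------------------------
# generation


def generate(spec: FieldSpec, seed: int | None = None) -> tuple[RGBPlotImage, FieldTruth]:
    """Render a synthetic plot image and its ground truth.

    Deterministic under a fixed seed: the same (spec, seed) pair yields a
    byte-identical image.
    """
    rng = np.random.default_rng(seed)
    gsd = spec.gsd_cm
    w_cm = spec.plot_width_m * 100.0
    h_cm = spec.plot_height_m * 100.0
    W = int(round(w_cm / gsd))
    H = int(round(h_cm / gsd))

    # soil background: luminance speckle is correlated across channels (it
    # nearly cancels in greenness indices, as brightness texture does on
    # real soil), plus a small independent chroma component
    canvas = np.empty((H, W, 3), dtype=float)
    canvas[:] = spec.soil_rgb
    canvas += rng.normal(0.0, spec.soil_noise, size=(H, W))[:, :, None]
    if spec.shadow:
        _add_shadows(canvas, rng, gsd)

    # row geometry
    T = spec.spacing_cm
    x0 = (w_cm - (spec.n_rows - 1) * T) / 2.0
    row_x = x0 + T * np.arange(spec.n_rows) + rng.normal(0, spec.row_jitter_cm,
                                                         spec.n_rows)

    pmf = spec.resolved_multiplicity()
    k_vals = np.arange(1, len(pmf) + 1)
    margin = 4.0

    plant_mask = np.zeros((H, W), dtype=bool)
    plants, cluster_rows = [], []
    done = False
    for rx in row_x:
        y = margin + rng.exponential(max(spec.gap_mean_cm - spec.gap_min_cm, 1e-6))
        while y < h_cm - margin and not done:
            k = int(rng.choice(k_vals, p=pmf))
            if spec.target_plants is not None:
                k = min(k, spec.target_plants - len(plants))
                if k <= 0:
                    done = True
                    break
            cx = rx + rng.normal(0, spec.point_jitter_cm)
            cluster_rows.append({"x": cx, "y": y, "k": k})
            for _ in range(k):
                px = cx + rng.uniform(-1.2, 1.2)
                py = y + rng.uniform(-1.2, 1.2)
                plants.append((px, py))
                _draw_plant(canvas, plant_mask, px, py, spec, rng)
            y += spec.gap_min_cm + rng.exponential(
                max(spec.gap_mean_cm - spec.gap_min_cm, 1e-6))

    # weeds: small green blobs off the plants, below the area filter
    veg_mask = plant_mask.copy()
    n_weeds = rng.poisson(spec.weed_density_per_m2 *
                          spec.plot_width_m * spec.plot_height_m)
    weeds = []
    plant_xy = np.array(plants) if plants else np.empty((0, 2))
    for _ in range(n_weeds):
        for _attempt in range(20):
            wx = rng.uniform(2.0, w_cm - 2.0)
            wy = rng.uniform(2.0, h_cm - 2.0)
            if plant_xy.size == 0 or np.min(
                    np.hypot(plant_xy[:, 0] - wx, plant_xy[:, 1] - wy)) > 5.0:
                break
        else:
            continue
        length = rng.uniform(*spec.weed_length_cm)
        a = length / 2.0
        b = a * rng.uniform(0.5, 0.8)
        color = np.clip(np.array(spec.leaf_rgb, float) +
                        rng.uniform(-spec.leaf_jitter, spec.leaf_jitter, 3), 0, 255)
        _paint_ellipse(canvas, veg_mask, wx, wy, a, b,
                       rng.uniform(0, 2 * np.pi), color, gsd)
        weeds.append((wx, wy))

    # mild independent sensor/chroma noise over everything
    canvas += rng.normal(0.0, spec.chroma_noise, size=canvas.shape)
    canvas = np.clip(canvas, 0, 255).astype(np.uint8)

    img = RGBPlotImage(canvas[:, :, 0], canvas[:, :, 1], canvas[:, :, 2],
                       gsd_cm=gsd, origin=(0.0, 0.0), plot_id=spec.plot_id)
    truth = FieldTruth(
        plants=np.array(plants) if plants else np.empty((0, 2)),
        clusters=pd.DataFrame(cluster_rows, columns=["x", "y", "k"]),
        row_x=np.sort(row_x),
        weeds=np.array(weeds) if weeds else np.empty((0, 2)),
        veg_mask=veg_mask,
        plant_mask=plant_mask,
        seed=seed,
    )
    return img, truth


def _add_shadows(canvas: np.ndarray, rng, gsd: float) -> None:
    """Darken a few random elliptical soil patches (microtopography shadow)."""
    h, w = canvas.shape[:2]
    shade = np.ones((h, w), dtype=float)
    scratch = np.zeros((h, w, 3))
    for _ in range(int(rng.integers(3, 7))):
        cx = rng.uniform(0, w * gsd)
        cy = rng.uniform(0, h * gsd)
        a = rng.uniform(8, 25)
        b = a * rng.uniform(0.3, 0.8)
        patch = np.zeros((h, w), dtype=bool)
        _paint_ellipse(scratch, patch, cx, cy, a, b,
                       rng.uniform(0, np.pi), (0, 0, 0), gsd)
        shade[patch] *= rng.uniform(0.7, 0.85)
    canvas *= shade[:, :, None]


# ---------------------------------------------------------------------------
# presets + helpers


def stage_presets(stage: int) -> FieldSpec:
    """Growth-stage presets: stage 2 leaves sized for ~1.5x stage-1 cover."""
    if stage == 1:
        return FieldSpec(leaf_length_cm=(1.5, 2.8), plot_id="stage1")
    if stage == 2:
        # linear leaf scale sqrt(1.5): doubles as ~1.5x area at equal density
        s = np.sqrt(1.5)
        return FieldSpec(leaf_length_cm=(1.5 * s, 2.8 * s), plot_id="stage2")
    raise ValueError("stage must be 1 or 2")


def easy_spec(n_plants: int = 50) -> FieldSpec:
    """A weed-free, well-separated layout: every object is a single plant."""
    return FieldSpec(
        multiplicity_probs=(1.0,),
        weed_density_per_m2=0.0,
        gap_min_cm=14.0,
        gap_mean_cm=18.0,
        point_jitter_cm=0.5,
        target_plants=n_plants,
        plot_id="easy",
    )


def canopy_cover(truth: FieldTruth) -> float:
    """Fraction of plot pixels covered by plant canopy."""
    return float(truth.plant_mask.mean())


def object_truth_counts(objs, truth: FieldTruth,
                        max_dist_cm: float = 3.0) -> tuple[dict[int, int], int]:
    """True plant count per segmented object.

    Each planted position is assigned to the object whose pixels contain
    it, falling back to the nearest labeled pixel within ``max_dist_cm``.
    Returns ``(counts, unassigned)`` where ``counts[label]`` is the number
    of plants inside that object and ``unassigned`` counts plants that
    matched no object (e.g. removed with a fragment by the area filter).
    """
    lab = objs.label_image.data
    h, w = lab.shape
    gsd = objs.gsd_cm
    rad = max(int(np.ceil(max_dist_cm / gsd)), 1)
    counts = {l: 0 for l in objs.labels}
    unassigned = 0
    for px, py in truth.plants:
        c = int(round(px / gsd))
        r = int(round(py / gsd))
        label = lab[r, c] if (0 <= r < h and 0 <= c < w) else 0
        if label == 0:
            r0, r1 = max(r - rad, 0), min(r + rad + 1, h)
            c0, c1 = max(c - rad, 0), min(c + rad + 1, w)
            win = lab[r0:r1, c0:c1]
            rr, cc = np.nonzero(win)
            if rr.size:
                d2 = (rr + r0 - r) ** 2 + (cc + c0 - c) ** 2
                j = int(np.argmin(d2))
                if d2[j] <= (max_dist_cm / gsd) ** 2:
                    label = int(win[rr[j], cc[j]])
        if label:
            counts[label] += 1
        else:
            unassigned += 1
    return counts, unassigned
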