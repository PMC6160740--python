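"""Raster, vector and table I/O plus the pixel-to-centimeter coordinate contract.

Every physical threshold in the pipeline is expressed in centimeters and
converted to pixels through the ground sampling distance (GSD) carried by
the raster types defined here.  Conventions used throughout the package:

* pixel indices are 0-based ``(col, row)`` pairs, pixel-center registered;
* world coordinates are ``(x, y)`` in centimeters, with x increasing along
  image columns (across rows of plants) and y increasing along image rows
  (the seeding direction);
* GSDs or world files expressed in meters are converted to cm on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "RGBPlotImage", "BinaryMask", "LabelImage",
    "read_plot_image", "write_plot_image",
    "pixel_to_world", "world_to_pixel",
    "write_mask", "read_mask",
    "write_objects", "read_objects", "write_table",
    "write_row_lines",
]

# scales below this (per pixel) are taken to be meters and converted to cm
_METER_SCALE_CUTOFF = 0.01


@dataclass
class RGBPlotImage:
    """Georeferenced 3-channel 8-bit plot image."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    gsd_cm: float
    origin: tuple[float, float] = (0.0, 0.0)
    plot_id: str = ""

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("channel grids must have identical dimensions")
        if not self.gsd_cm > 0:
            raise ValueError(f"gsd_cm must be positive, got {self.gsd_cm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def as_array(self) -> np.ndarray:
        """Stack channels into an (H, W, 3) uint8 array."""
        return np.dstack([self.red, self.green, self.blue]).astype(np.uint8)


@dataclass
class BinaryMask:
    """A {0,1} raster sharing the geo-contract of its source image."""

    data: np.ndarray
    gsd_cm: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)


@dataclass
class LabelImage:
    """Integer raster: 0 = background, k > 0 = object k.

    Labels are a contiguous range 1..K immediately after connected-component
    labeling; filtering operations relabel so the range stays contiguous.
    """

    data: np.ndarray
    gsd_cm: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")


# ---------------------------------------------------------------------------
# coordinate contract


def pixel_to_world(p: tuple[float, float], img) -> tuple[float, float]:
    """Map a 0-based ``(col, row)`` pixel index to world ``(x, y)`` in cm.

    Pixel-center convention: pixel (0, 0) maps exactly onto ``img.origin``.
    """
    col, row = p
    h, w = img_shape(img)
    if not (-0.5 <= col < w - 0.5 + 1e-9 and -0.5 <= row < h - 0.5 + 1e-9):
        raise IndexError(f"pixel index {p} outside raster of shape {(h, w)}")
    ox, oy = img.origin
    return (ox + col * img.gsd_cm, oy + row * img.gsd_cm)


def world_to_pixel(xy: tuple[float, float], img) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_world`; returns fractional ``(col, row)``."""
    x, y = xy
    ox, oy = img.origin
    return ((x - ox) / img.gsd_cm, (y - oy) / img.gsd_cm)


def img_shape(img) -> tuple[int, int]:
    if hasattr(img, "shape"):
        return img.shape
    return img.data.shape


# ---------------------------------------------------------------------------
# raster reading


def read_plot_image(path, gsd_cm: float | None = None, plot_id: str = "") -> RGBPlotImage:
    """Read a 3-band 8-bit raster (GeoTIFF, or PNG with optional world file).

    The GSD is taken from the geotransform when the file carries one,
    otherwise from ``gsd_cm``.  If both are present and differ by more than
    1 % the call fails rather than guessing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr, file_gsd, origin = _read_geotiff(path)
    else:
        arr = np.asarray(Image.open(path))
        file_gsd, origin = _read_world_file(path)

    if arr.ndim != 3 or arr.shape[2] < 3:
        nbands = 1 if arr.ndim == 2 else arr.shape[2]
        raise ValueError(f"expected a 3-band raster, got {nbands} band(s)")
    arr = arr[:, :, :3].astype(np.uint8)

    if file_gsd is not None and gsd_cm is not None:
        if abs(file_gsd - gsd_cm) > 0.01 * gsd_cm:
            raise ValueError(
                f"GSD conflict: file says {file_gsd} cm, argument says {gsd_cm} cm"
            )
        gsd = file_gsd
    elif file_gsd is not None:
        gsd = file_gsd
    elif gsd_cm is not None:
        gsd = gsd_cm
    else:
        raise ValueError(f"no resolvable GSD for {path}: pass gsd_cm or supply a geotransform")

    if origin is None:
        origin = (0.0, 0.0)
    return RGBPlotImage(arr[:, :, 0], arr[:, :, 1], arr[:, :, 2],
                        gsd_cm=gsd, origin=origin, plot_id=plot_id or path.stem)


def _to_cm(scale: float) -> float:
    return scale * 100.0 if abs(scale) < _METER_SCALE_CUTOFF else scale


def _read_geotiff(path):
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        tags = page.tags
        gsd = origin = None
        if "ModelPixelScaleTag" in tags:
            sx, sy = tags["ModelPixelScaleTag"].value[:2]
            gsd = _to_cm(float(sx))
            if abs(_to_cm(float(sy)) - gsd) > 1e-9 * max(gsd, 1.0):
                raise ValueError("anisotropic pixel scale is not supported")
        if "ModelTiepointTag" in tags and gsd is not None:
            tp = tags["ModelTiepointTag"].value
            # tiepoint: raster (i, j, k) -> model (x, y, z); pixel-corner based
            i, j = float(tp[0]), float(tp[1])
            x, y = _to_cm(float(tp[3])), _to_cm(float(tp[4]))
            origin = (x - (i - 0.5) * gsd, y - (j - 0.5) * gsd)
    return arr, gsd, origin


def _read_world_file(path: Path):
    """Read an ESRI world file next to ``path`` (e.g. .pgw for .png)."""
    for wf in (path.with_suffix(path.suffix[:2] + path.suffix[-1] + "w"),
               path.with_suffix(path.suffix + "w"),
               path.with_suffix(".wld")):
        if wf.exists():
            vals = [float(v) for v in wf.read_text().split()]
            if len(vals) != 6:
                raise ValueError(f"malformed world file {wf}")
            a, d, b, e, c, f = vals
            if d != 0 or b != 0:
                raise ValueError("rotated world files are not supported")
            gsd = _to_cm(abs(a))
            if abs(_to_cm(abs(e)) - gsd) > 1e-9 * max(gsd, 1.0):
                raise ValueError("anisotropic world file is not supported")
            return gsd, (_to_cm(c), _to_cm(f))
    return None, None


def write_plot_image(img: RGBPlotImage, path) -> None:
    """Write PNG + world file, or GeoTIFF when the suffix is .tif/.tiff."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        write_geotiff(img.as_array(), path, img.gsd_cm, img.origin)
    else:
        Image.fromarray(img.as_array()).save(path)
        _write_world_file(path, img.gsd_cm, img.origin)


def _write_world_file(path: Path, gsd_cm: float, origin) -> None:
    wf = path.with_suffix(path.suffix[:2] + path.suffix[-1] + "w")
    ox, oy = origin
    wf.write_text("\n".join(f"{v:.10f}" for v in (gsd_cm, 0.0, 0.0, gsd_cm, ox, oy)) + "\n")


def write_geotiff(arr: np.ndarray, path, gsd_cm: float, origin=(0.0, 0.0)) -> None:
    """Write an array as a TIFF with ModelPixelScale/ModelTiepoint geo tags (cm units)."""
    ox, oy = origin
    extratags = [
        (33550, "d", 3, (gsd_cm, gsd_cm, 0.0)),                       # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, ox - 0.5 * gsd_cm, oy - 0.5 * gsd_cm, 0.0)),
    ]
    tifffile.imwrite(path, arr, extratags=extratags)


def write_mask(mask: BinaryMask, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        write_geotiff(mask.data.astype(np.uint8), path, mask.gsd_cm, mask.origin)
    else:
        Image.fromarray((mask.data * 255).astype(np.uint8)).save(path)
        _write_world_file(path, mask.gsd_cm, mask.origin)


def read_mask(path, gsd_cm: float | None = None) -> BinaryMask:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr, file_gsd, origin = _read_geotiff(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
        file_gsd, origin = _read_world_file(path)
    gsd = file_gsd if file_gsd is not None else gsd_cm
    if gsd is None:
        raise ValueError("no resolvable GSD for mask")
    return BinaryMask((np.asarray(arr) > 0).astype(np.uint8), gsd, origin or (0.0, 0.0))


# ---------------------------------------------------------------------------
# vector + table output


def write_objects(objs, path) -> None:
    """Write a labeled object set as a GeoJSON FeatureCollection.

    One polygon feature per object with properties ``label``, ``area_px``,
    ``area_cm2``, centroid coordinates, and any attached per-object feature
    columns.  Coordinates are world cm.
    """
    features = []
    extra = getattr(objs, "attributes", None)
    for lbl in objs.labels:
        poly = objs.polygon(lbl)
        props = {
            "label": int(lbl),
            "area_px": int(objs.area_px(lbl)),
            "area_cm2": float(objs.area_cm2(lbl)),
        }
        cx, cy = objs.centroid_world(lbl)
        props["centroid_x_cm"] = float(cx)
        props["centroid_y_cm"] = float(cy)
        if extra is not None and lbl in extra:
            props.update({k: _jsonable(v) for k, v in extra[lbl].items()})
        features.append({
            "type": "Feature",
            "geometry": _shapely_to_geojson(poly),
            "properties": props,
        })
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _shapely_to_geojson(geom) -> dict:
    import shapely.geometry

    return shapely.geometry.mapping(geom)


def read_objects(path) -> list[dict]:
    """Read back a GeoJSON object file as a list of property dicts."""
    fc = json.loads(Path(path).read_text())
    return [f["properties"] for f in fc.get("features", [])]


def write_row_lines(lines, path) -> None:
    """Write detected row polylines as GeoJSON LineStrings (world cm)."""
    features = []
    for idx, verts in lines.items() if isinstance(lines, dict) else enumerate(lines, 1):
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in verts]},
            "properties": {"row": int(idx)},
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def write_table(rows, path) -> None:
    """Write tabular output (list of dicts or DataFrame) as CSV with header."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)
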