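"""Color vegetation indices computed from raw 8-bit RGB digital numbers.

Five broadly used greenness indices are provided:

======== ===========================  =================
name     formula                      range (8-bit in)
======== ===========================  =================
ExG      2G - R - B                   [-510, 510]
ExR      1.4R - G                     [-255, 357]
ExG-ExR  3G - 2.4R - B                [-867, 765]
NGRDI    (G - R) / (G + R)            [-1, 1]
GLI      (2G - R - B) / (2G + R + B)  [-1, 1]
======== ===========================  =================

Formulas are applied to raw digital numbers (no chromatic-coordinate
normalisation).  Ratio indices return 0 where the denominator is 0, which
only occurs for pure-black pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import RGBPlotImage, write_geotiff

__all__ = ["VIRaster", "compute_index", "INDEX_NAMES", "export_index"]

INDEX_NAMES = ("ExG", "ExR", "ExG-ExR", "NGRDI", "GLI")


@dataclass
class VIRaster:
    """Single-band vegetation-index raster with the source geo-contract."""

    data: np.ndarray
    index_name: str
    gsd_cm: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float32)
    np.divide(num, den, out=out, where=den != 0)
    return out


def compute_index(img: RGBPlotImage, index_name: str) -> VIRaster:
    """Apply a vegetation-index formula element-wise to an RGB image."""
    r = img.red.astype(np.float32)
    g = img.green.astype(np.float32)
    b = img.blue.astype(np.float32)

    name = _canonical(index_name)
    if name == "ExG":
        data = 2.0 * g - r - b
    elif name == "ExR":
        data = 1.4 * r - g
    elif name == "ExG-ExR":
        data = 3.0 * g - 2.4 * r - b
    elif name == "NGRDI":
        data = _safe_ratio(g - r, g + r)
    elif name == "GLI":
        data = _safe_ratio(2.0 * g - r - b, 2.0 * g + r + b)
    else:  # pragma: no cover - _canonical already raised
        raise ValueError(index_name)
    return VIRaster(data.astype(np.float32), name, img.gsd_cm, img.origin)


def _canonical(index_name: str) -> str:
    key = index_name.strip().lower().replace("_", "-").replace(" ", "")
    table = {
        "exg": "ExG",
        "exr": "ExR",
        "exg-exr": "ExG-ExR",
        "exgexr": "ExG-ExR",
        "exgminusexr": "ExG-ExR",
        "ngrdi": "NGRDI",
        "gli": "GLI",
    }
    if key not in table:
        raise ValueError(f"unknown vegetation index {index_name!r}; choose from {INDEX_NAMES}")
    return table[key]


def export_index(vi: VIRaster, path) -> None:
    """Write a VI raster as a single-band float GeoTIFF."""
    write_geotiff(vi.data.astype(np.float32), path, vi.gsd_cm, vi.origin)
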