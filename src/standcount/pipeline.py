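"""End-to-end pipeline: segment -> features -> count -> rows -> metrics.

`run_all` ties the stages together with one config object whose defaults
are the field-study constants: ExG-ExR index, 1.16 cm^2 weed filter,
1.0 cm fragment merge, 8.0 cm row-assignment distance, and 0.05/0.10
stepwise entry/removal levels.  Any stage failure aborts with an error
naming the stage.  Every run logs the config hash, the seed and the Otsu
threshold (the pipeline's main latent variable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import count_model as cm
from . import row_analysis as ra
from . import seg_eval
from .raster_io import BinaryMask, RGBPlotImage, read_plot_image
from .segmentation import segment_image
from .shape_features import features_table

log = logging.getLogger("standcount")

__all__ = ["PipelineConfig", "StageError", "run_all"]


@dataclass
class PipelineConfig:
    index_name: str = "ExG-ExR"
    min_area_cm2: float = 1.16
    merge_cm: float = 1.0
    mer_mode: str = "rotated"
    model: str = "builtin:single"
    n_rows: int = 8
    spacing_cm: float = 20.0
    buffer_cm: float = 2.0
    smoothing_window: int = 5
    row_assign_cm: float = 8.0
    p_enter: float = 0.05
    p_remove: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_area_cm2", "merge_cm", "spacing_cm", "buffer_cm",
                     "row_assign_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_all(config: PipelineConfig, image, truth=None, model=None) -> dict:
    """Run the full pipeline on an image; returns the report dict.

    ``image`` is an RGBPlotImage or a raster path; ``truth`` (optional) is
    a synthetic-field FieldTruth, enabling the total-count error Es and
    pixel segmentation scores against the true vegetation mask; ``model``
    (optional) is a fitted CountModel overriding ``config.model``.
    """
    log.info("run_all: config %s seed %s", config.digest(), config.seed)
    if not isinstance(image, RGBPlotImage):
        image = read_plot_image(image)

    objs, thr, mask = _stage("segment")(segment_image)(
        image, config.index_name, config.min_area_cm2, config.merge_cm)
    log.info("segment: Otsu threshold %.4f (%s), %d objects",
             thr, config.index_name, len(objs))

    feats = _stage("features")(features_table)(objs, config.mer_mode)
    log.info("features: %d objects x 15 descriptors", len(feats))

    model = _stage("count")(cm.resolve_model)(model if model is not None
                                              else config.model)
    yhat = _stage("count")(cm.predict_counts)(model, feats)
    est_total = cm.round_half_away(float(yhat.sum()))
    log.info("count: estimated plot total %d", est_total)

    report = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "index_name": config.index_name,
        "otsu_threshold": float(thr),
        "n_objects": len(objs),
        "estimated_total": est_total,
        "model_features": list(model.features),
    }

    def _rows():
        pts = ra.build_row_points(objs, config.buffer_cm)
        labels = ra.assign_row_labels(pts, config.n_rows, config.spacing_cm)
        lines = ra.connect_and_smooth(pts, labels, config.smoothing_window)
        sp = ra.row_spacing_stats(lines, config.spacing_cm)
        centroids = np.array([objs.centroid_world(l) for l in objs.labels])
        su = ra.seedling_uniformity(centroids, yhat, lines, config.row_assign_cm)
        return lines, sp, su

    lines, sp, su = _stage("rows")(_rows)()
    report.update({
        "cv_rs": sp.cv_rs,
        "e_rs": sp.e_rs,
        "mean_row_spacing_cm": sp.mean_spacing,
        "cv_su": su.cv_su,
        "row_counts": su.row_counts,
        "row_spacings_cm": sp.spacings,
    })
    log.info("rows: CV_rs %.2f%%, E_rs %.2f%%, CV_su %.2f%%",
             sp.cv_rs, sp.e_rs, su.cv_su)

    if truth is not None:
        measured = int(truth.total_plants)
        val = cm.validation_metrics([measured], [est_total])
        ref = BinaryMask(truth.veg_mask.astype(np.uint8), image.gsd_cm, image.origin)
        sc = _stage("evaluate")(seg_eval.evaluate)(ref, mask)
        report.update({
            "measured_total": measured,
            "es_percent": val.es_percent[0],
            "segmentation": sc.as_dict(),
        })
        log.info("truth: measured %d, Es %.2f%%", measured, val.es_percent[0])

    report["_objects"] = objs
    report["_features"] = feats
    report["_lines"] = lines
    return report


def write_report(report: dict, json_path=None, csv_path=None) -> dict:
    """Write the scalar report as JSON and/or one-row CSV; returns scalars."""
    scalars = {k: v for k, v in report.items()
               if not k.startswith("_") and not isinstance(v, dict)}
    if "segmentation" in report:
        scalars.update({f"seg_{k}": v for k, v in report["segmentation"].items()})
    if json_path is not None:
        Path(json_path).write_text(json.dumps(scalars, indent=2, default=_json_default))
    if csv_path is not None:
        flat = {k: (json.dumps(v) if isinstance(v, list) else v)
                for k, v in scalars.items()}
        pd.DataFrame([flat]).to_csv(csv_path, index=False)
    return scalars


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))
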