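"""File formats: landmark JSON, structure masks (PNG/TIFF), reports, tables.

Conventions:

* Landmark JSON — top-level keys ``image_id``, ``pixel_spacing_mm``,
  ``laterality_convention`` and ``landmarks`` mapping names to ``[x, y]``
  (points) or ``[[x, y], ...]`` (contours/outlines).
* Masks — one 8-bit image per structure, foreground > 0, named
  ``<image_id>__<structure>.png``.
* Reports and tables — UTF-8 comma-separated CSV with dot decimals; values
  at full double precision; a ``# key: value`` metadata header (software
  version, config hash, seed) that the paired readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .geometry import CircleFit, HipMeasurements, LandmarkSet, Point2D
from .masks import STRUCTURES, MaskSet

__all__ = [
    "read_landmarks_json",
    "write_landmarks_json",
    "read_mask_set",
    "write_mask_set",
    "measurements_to_records",
    "write_report",
    "read_table_csv",
    "write_table_csv",
    "config_hash",
]

_POINT_NAMES = (
    "tuberosity_inferior_right",
    "tuberosity_inferior_left",
    "sourcil_medial_right",
    "sourcil_medial_left",
    "sourcil_lateral_right",
    "sourcil_lateral_left",
)
_CONTOUR_NAMES = (
    "femoral_head_contour_right",
    "femoral_head_contour_left",
    "foramen_outline_right",
    "foramen_outline_left",
)

REPORT_METRICS = (
    "lcea_right",
    "lcea_left",
    "aia_right",
    "aia_left",
    "foramen_width_right",
    "foramen_width_left",
    "foi",
)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_landmarks_json(path) -> LandmarkSet:
    data = json.loads(Path(path).read_text())
    lm = LandmarkSet(
        image_id=data.get("image_id", Path(path).stem),
        pixel_spacing_mm=data.get("pixel_spacing_mm"),
        laterality_convention=data.get("laterality_convention", "right_on_left"),
    )
    landmarks = data.get("landmarks", {})
    for name, val in landmarks.items():
        if name in _POINT_NAMES:
            setattr(lm, name, Point2D(float(val[0]), float(val[1])))
        elif name in _CONTOUR_NAMES:
            setattr(lm, name, [Point2D(float(x), float(y)) for x, y in val])
        else:
            raise ValueError(f"unknown landmark name {name!r} in {path}")
    return lm


def write_landmarks_json(lm: LandmarkSet, path) -> None:
    landmarks = {}
    for name in _POINT_NAMES:
        p = getattr(lm, name)
        if p is not None:
            landmarks[name] = [p.x, p.y]
    for name in _CONTOUR_NAMES:
        pts = getattr(lm, name)
        if pts is None:
            continue
        if isinstance(pts, CircleFit):
            raise ValueError("landmark JSON stores contours, not precomputed circle fits")
        landmarks[name] = [[p.x, p.y] for p in pts]
    payload = {
        "image_id": lm.image_id,
        "pixel_spacing_mm": lm.pixel_spacing_mm,
        "laterality_convention": lm.laterality_convention,
        "landmarks": landmarks,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_mask_set(masks: MaskSet, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in STRUCTURES:
        m = getattr(masks, name)
        if m is None:
            continue
        path = out_dir / f"{masks.image_id}__{name}.png"
        Image.fromarray((m.astype(np.uint8)) * 255).save(path)
        written.append(path)
    return written


def read_mask_set(mask_dir, image_id: str, pixel_spacing_mm=None, laterality_convention="right_on_left") -> MaskSet:
    mask_dir = Path(mask_dir)
    kwargs = {}
    for name in STRUCTURES:
        for ext in ("png", "tif", "tiff"):
            path = mask_dir / f"{image_id}__{name}.{ext}"
            if path.exists():
                kwargs[name] = np.asarray(Image.open(path)) > 0
                break
    if not kwargs:
        raise FileNotFoundError(f"no structure masks for image id {image_id!r} in {mask_dir}")
    return MaskSet(image_id=image_id, pixel_spacing_mm=pixel_spacing_mm, laterality_convention=laterality_convention, **kwargs)


def mask_image_ids(mask_dir) -> list[str]:
    """Image ids present in a mask directory (``<id>__<structure>.*``)."""
    ids = set()
    for path in Path(mask_dir).iterdir():
        if "__" in path.stem:
            ids.add(path.stem.rsplit("__", 1)[0])
    return sorted(ids)


def measurements_to_records(hm: HipMeasurements) -> list[dict]:
    """Flatten a measurement result into long-format report rows."""
    rows = []
    flags = "; ".join(hm.flags)
    for metric in REPORT_METRICS:
        value = getattr(hm, metric)
        if metric.startswith("foramen_width"):
            unit = hm.width_unit
        elif metric == "foi":
            unit = "ratio"
        else:
            unit = "deg"
        rows.append(
            {"image_id": hm.image_id, "metric": metric, "value": value, "unit": unit, "flags": flags}
        )
    return rows


def _metadata_lines(meta: dict) -> str:
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def standard_metadata(seed=None, config: dict | None = None) -> dict:
    return {
        "software": f"hipmetrics {__version__}",
        "config_hash": config_hash(config or {}),
        "seed": seed,
    }


def write_table_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if meta:
            fh.write(_metadata_lines(meta))
        df.to_csv(fh, index=False, float_format=None)


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_report(records: list[dict], out_path_stem, meta: dict | None = None) -> tuple[Path, Path]:
    """Write a measurement report as CSV and JSON; returns both paths."""
    stem = Path(out_path_stem)
    df = pd.DataFrame.from_records(records)
    csv_path = stem.with_suffix(".csv")
    write_table_csv(df, csv_path, meta)
    json_path = stem.with_suffix(".json")
    payload = {"metadata": meta or {}, "measurements": records}
    json_path.write_text(json.dumps(payload, indent=1, default=_json_default))
    return csv_path, json_path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
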