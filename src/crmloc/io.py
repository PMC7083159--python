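"""Readers and writers for the package's on-disk formats.

* Box annotations: CSV in either the generic dialect
  (``image_id,x,y,width,height[,confidence]``) or the RSNA-challenge
  dialect (``patientId,x,y,width,height,Target`` — Target=1 rows carry a
  box, Target=0 rows mark a normal image with empty coordinates).
  Internally boxes are 0-based half-open; the CSV (x, y, width, height)
  columns convert as ``x_max = x + width``.
* Probability tables: CSV ``image_id,p_abnormal,p_normal``.
* Relevance maps: max-scaled 16-bit PNG plus a JSON sidecar holding
  ``source_id``, the raw maximum, the map shape, and the input size, so
  raw score values are recoverable; raw maps also export to CSV.
* Images and masks: grayscale PNG (optionally DICOM for input, when
  pydicom is installed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import InputError, ParseError
from .localization import BoundingBox, Detection, GroundTruthRecord
from .saliency import RelevanceMap

__all__ = [
    "read_boxes_csv",
    "write_gt_csv",
    "write_detections_csv",
    "read_probability_csv",
    "write_probability_csv",
    "save_heatmap",
    "load_heatmap",
    "save_image_png",
    "load_image",
    "save_mask_png",
    "load_mask_png",
]

RSNA_COLUMNS = ["patientId", "x", "y", "width", "height", "Target"]
GENERIC_COLUMNS = ["image_id", "x", "y", "width", "height"]


def _row_box(row: pd.Series, rownum: int) -> BoundingBox:
    try:
        x, y, w, h = (float(row["x"]), float(row["y"]),
                      float(row["width"]), float(row["height"]))
    except (TypeError, ValueError) as exc:
        raise ParseError(f"row {rownum}: malformed box coordinates") from exc
    if w <= 0 or h <= 0:
        raise ParseError(f"row {rownum}: non-positive width/height ({w}, {h})")
    if x < 0 or y < 0:
        raise ParseError(f"row {rownum}: negative box origin ({x}, {y})")
    return BoundingBox.from_xywh(x, y, w, h)


def read_boxes_csv(
    path: str | Path,
) -> tuple[list[GroundTruthRecord], list[Detection]]:
    """Read an annotation/detection CSV, auto-detecting the dialect.

    Returns ``(ground_truth_records, detections)``: detections are
    populated only when a ``confidence`` column is present, ground-truth
    records otherwise (RSNA Target=0 rows become box-less records).
    """
    df = pd.read_csv(path, dtype={0: str})
    cols = list(df.columns)
    if cols[:6] == RSNA_COLUMNS or cols[:5] == RSNA_COLUMNS[:5]:
        id_col, rsna = "patientId", True
    elif cols[:5] == GENERIC_COLUMNS:
        id_col, rsna = "image_id", False
    else:
        raise ParseError(f"unknown annotation header: {cols}")
    has_conf = "confidence" in cols

    gts: dict[str, list[BoundingBox]] = {}
    dets: list[Detection] = []
    for i, row in df.iterrows():
        image_id = str(row[id_col])
        if rsna and int(row.get("Target", 1)) == 0:
            gts.setdefault(image_id, [])
            continue
        if not rsna and pd.isna(row["x"]):
            gts.setdefault(image_id, [])
            continue
        box = _row_box(row, i)
        if has_conf:
            dets.append(Detection(image_id=image_id, box=box,
                                  confidence=float(row["confidence"])))
        else:
            gts.setdefault(image_id, []).append(box)
    records = [GroundTruthRecord(image_id=k, boxes=tuple(v))
               for k, v in gts.items()]
    return records, dets


def write_gt_csv(
    records: Sequence[GroundTruthRecord], path: str | Path, dialect: str = "rsna"
) -> None:
    """Write ground-truth records in the RSNA or generic dialect."""
    rows = []
    for rec in records:
        if dialect == "rsna" and not rec.boxes:
            rows.append({"patientId": rec.image_id, "x": "", "y": "",
                         "width": "", "height": "", "Target": 0})
        for box in rec.boxes:
            x, y, w, h = box.to_xywh()
            if dialect == "rsna":
                rows.append({"patientId": rec.image_id, "x": x, "y": y,
                             "width": w, "height": h, "Target": 1})
            else:
                rows.append({"image_id": rec.image_id, "x": x, "y": y,
                             "width": w, "height": h})
    columns = RSNA_COLUMNS if dialect == "rsna" else GENERIC_COLUMNS
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def write_detections_csv(dets: Sequence[Detection], path: str | Path) -> None:
    rows = []
    for det in dets:
        x, y, w, h = det.box.to_xywh()
        rows.append({"image_id": det.image_id, "x": x, "y": y, "width": w,
                     "height": h, "confidence": det.confidence})
    pd.DataFrame(rows, columns=GENERIC_COLUMNS + ["confidence"]).to_csv(
        path, index=False
    )


def read_probability_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str})
    needed = {"image_id", "p_abnormal", "p_normal"}
    if not needed.issubset(df.columns):
        raise ParseError(
            f"probability table must have columns {sorted(needed)}, got {list(df.columns)}"
        )
    return df


def write_probability_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def save_heatmap(rmap: RelevanceMap, path: str | Path) -> None:
    """Write a relevance map as max-scaled 16-bit PNG + JSON sidecar."""
    path = Path(path)
    raw_max = rmap.max
    scaled = (rmap.values / raw_max * 65535.0) if raw_max > 0 else rmap.values
    Image.fromarray(scaled.astype(np.uint16)).save(path)
    sidecar = {
        "source_id": rmap.source_id,
        "raw_max": raw_max,
        "map_shape": list(rmap.shape),
        "input_size": list(rmap.input_size) if rmap.input_size else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_heatmap(path: str | Path) -> RelevanceMap:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arr = np.asarray(Image.open(path), dtype=float)
    raw_max = float(sidecar["raw_max"])
    values = arr / 65535.0 * raw_max if raw_max > 0 else arr
    size = sidecar.get("input_size")
    return RelevanceMap(
        values,
        source_id=sidecar.get("source_id", ""),
        input_size=tuple(size) if size else None,
    )


def save_image_png(image: np.ndarray, path: str | Path) -> None:
    """Save a [0, 1] grayscale image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8)).save(path)


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image (PNG/JPEG, or DICOM when pydicom is present),
    scaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover
            raise InputError("DICOM input requires the pydicom package") from exc
        arr = pydicom.dcmread(path).pixel_array.astype(float)
        hi = arr.max()
        return arr / hi if hi > 0 else arr
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return arr / 255.0


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)
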