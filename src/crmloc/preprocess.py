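"""Post-segmentation image conditioning for chest radiographs.

Given a binary lung mask, the image is cropped to the tight bounding box
accommodating the lung pixels, rescaled to a fixed 256 x 256 size
(aspect ratio not preserved), then conditioned: 3 x 3 median filter
(edge-preserving denoise, reflect border), min-max rescale to [0, 1], and
standardization with dataset-level mean/std fitted on a training split and
persisted so that train and test images share one affine normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter
from skimage.transform import resize as _sk_resize

from .exceptions import InputError, NoLungFoundError, StateError
from .localization import BoundingBox

__all__ = [
    "LungMask",
    "CropRecord",
    "Conditioner",
    "mask_to_bbox",
    "crop_and_resize",
    "OUTPUT_SIZE",
]

OUTPUT_SIZE = (256, 256)


@dataclass(frozen=True)
class LungMask:
    """Binary lung-field mask aligned to an image."""

    values: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise InputError(f"mask must be 2-D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise InputError("mask entries must be 0/1")
        object.__setattr__(self, "values", arr.astype(np.uint8))


@dataclass(frozen=True)
class CropRecord:
    """Where a conditioned image came from in original coordinates."""

    image_id: str
    box: BoundingBox
    output_size: tuple[int, int] = OUTPUT_SIZE


def mask_to_bbox(mask: LungMask) -> BoundingBox:
    """Tight half-open box over all nonzero mask pixels.

    With two disjoint lung fields this is the single box spanning both.
    Raises :class:`NoLungFoundError` on an empty mask.
    """
    rows, cols = np.nonzero(mask.values)
    if rows.size == 0:
        raise NoLungFoundError(f"mask {mask.image_id!r} has no lung pixels")
    return BoundingBox(
        x_min=int(cols.min()),
        y_min=int(rows.min()),
        x_max=int(cols.max()) + 1,
        y_max=int(rows.max()) + 1,
    )


def crop_and_resize(
    image: np.ndarray,
    box: BoundingBox,
    image_id: str = "",
    output_size: tuple[int, int] = OUTPUT_SIZE,
) -> tuple[np.ndarray, CropRecord]:
    """Crop to ``box`` and bilinearly rescale to a fixed output size."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("expected a single-channel image")
    h, w = img.shape
    x0, y0, x1, y1 = (int(box.x_min), int(box.y_min), int(box.x_max), int(box.y_max))
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise InputError(f"box {box} outside image of shape {(h, w)}")
    crop = img[y0:y1, x0:x1]
    if crop.shape == tuple(output_size):
        out = crop.copy()
    else:
        out = _sk_resize(
            crop, output_size, order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return out, CropRecord(image_id=image_id, box=box, output_size=tuple(output_size))


class Conditioner:
    """Median filter + [0,1] rescale + dataset-level standardization.

    ``fit`` computes the dataset mean and standard deviation of the
    filtered-and-rescaled training images; ``transform`` applies the full
    chain.  Statistics persist to a JSON sidecar so held-out data can be
    conditioned identically.
    """

    def __init__(self, mean: Optional[float] = None, std: Optional[float] = None):
        self.mean = mean
        self.std = std

    @property
    def fitted(self) -> bool:
        return self.mean is not None and self.std is not None

    @staticmethod
    def filter_and_rescale(image: np.ndarray) -> np.ndarray:
        """3x3 median filter (reflect border), then min-max to [0, 1].

        A constant image maps to all zeros.
        """
        img = np.asarray(image, dtype=float)
        if img.ndim != 2:
            raise InputError("expected a single-channel image")
        filt = median_filter(img, size=3, mode="reflect")
        lo, hi = filt.min(), filt.max()
        if hi > lo:
            return (filt - lo) / (hi - lo)
        return np.zeros_like(filt)

    def fit(self, images: list[np.ndarray]) -> "Conditioner":
        if len(images) == 0:
            raise InputError("need at least one training image to fit statistics")
        pix = np.concatenate(
            [self.filter_and_rescale(im).ravel() for im in images]
        )
        self.mean = float(pix.mean())
        self.std = float(pix.std()) or 1.0
        return self

    def transform(self, image: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("standardization statistics not fitted; call fit() first")
        return (self.filter_and_rescale(image) - self.mean) / self.std

    def save(self, path: str | Path) -> None:
        if not self.fitted:
            raise StateError("nothing to save: statistics not fitted")
        Path(path).write_text(json.dumps({"mean": self.mean, "std": self.std}))

    @classmethod
    def load(cls, path: str | Path) -> "Conditioner":
        data = json.loads(Path(path).read_text())
        return cls(mean=float(data["mean"]), std=float(data["std"]))
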