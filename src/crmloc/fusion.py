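"""Ensemble fusion of relevance maps from multiple models.

Different architectures produce CRMs at different spatial resolutions and
on different score scales.  The fusion pipeline makes them commensurable
and averages them:

1. upscale every map to the input-image size (bilinear);
2. optionally divide each map by its own maximum (scale normalization, so
   no model dominates by raw score magnitude alone);
3. threshold each map at a fraction (default 10%) of its own maximum, to
   suppress noisy low scores;
4. average elementwise over models;
5. display-threshold the mean at the same fraction of *its* maximum.

The ensemble map compensates for regions of interest missed by any single
model: every surviving pixel is supported by at least one model, and
consistently-highlighted regions are reinforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InputError
from .saliency import RelevanceMap, threshold_map, upscale_map

__all__ = ["EnsembleMapConfig", "ensemble_crm", "top_k_by_localization"]


@dataclass(frozen=True)
class EnsembleMapConfig:
    """Fusion settings.

    threshold_fraction : low-score cutoff as a fraction of each map's max
        (applied per map before averaging and to the mean after).
    normalize_scale : divide each map by its own max before averaging
        (zero maps stay zero).  Disable for raw-scale averaging.
    input_size : (H, W) pixels every map is upscaled to.
    """

    input_size: tuple[int, int]
    threshold_fraction: float = 0.10
    normalize_scale: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_fraction < 1.0:
            raise InputError(
                f"threshold_fraction must be in [0, 1), got {self.threshold_fraction}"
            )


def ensemble_crm(
    maps: Sequence[RelevanceMap], cfg: EnsembleMapConfig
) -> RelevanceMap:
    """Fuse relevance maps into one ensemble map (upscale, normalize,
    threshold, average, display-threshold).

    Zero maps participate as zeros — simple averaging divides by the number
    of maps, not the number of nonzero maps.  The result is permutation
    invariant and, with ``normalize_scale``, bounded in [0, 1].
    """
    if len(maps) == 0:
        raise InputError("need at least one relevance map to fuse")
    prepared = []
    for rmap in maps:
        if rmap.shape[0] > cfg.input_size[0] or rmap.shape[1] > cfg.input_size[1]:
            raise InputError(
                f"map of shape {rmap.shape} exceeds target input size {cfg.input_size}"
            )
        up = upscale_map(rmap, cfg.input_size)
        if cfg.normalize_scale and up.max > 0:
            up = RelevanceMap(up.values / up.max, source_id=up.source_id,
                              input_size=up.input_size)
        prepared.append(threshold_map(up, cfg.threshold_fraction).values)
    mean = np.mean(prepared, axis=0)
    ids = ",".join(m.source_id or "?" for m in maps)
    fused = RelevanceMap(mean, source_id=f"ensemble({ids})",
                         input_size=cfg.input_size)
    return threshold_map(fused, cfg.threshold_fraction)


def top_k_by_localization(
    models: Sequence[str],
    scores: Mapping[str, Mapping[str, float]],
    k: int,
) -> list[str]:
    """Pick the ``k`` models with the best localization scores.

    ``scores`` maps model name -> {"iou": ..., "map": ...}.  Ranking is by
    mean IoU, ties broken by mAP, then by name for determinism.  Used to
    build top-3/top-5/top-7 ensembles from a per-model evaluation table.
    """
    if k <= 0:
        raise InputError(f"k must be positive, got {k}")
    if k > len(models):
        raise InputError(f"k={k} exceeds the {len(models)} available models")
    missing = [m for m in models if m not in scores]
    if missing:
        raise InputError(f"no localization scores for models: {missing}")
    ranked = sorted(
        models,
        key=lambda name: (
            -float(scores[name]["iou"]),
            -float(scores[name].get("map", 0.0)),
            name,
        ),
    )
    return ranked[:k]
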