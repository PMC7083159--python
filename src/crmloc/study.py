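"""Desk-scale end-to-end study: train, ensemble, localize, evaluate.

Mirrors the full workflow at laptop scale: simulate a two-class synthetic
chest-image dataset, train a few tiny CNN classifiers, compute individual
and ensemble relevance maps on the held-out split, turn them into box
detections, and score classification (accuracy/AUC with Wilson intervals)
and localization (mean IoU, mAP@[0.1 0.6]).  The qualitative question it
answers is the ensemble one: does fusing relevance maps across models
localize at least as well as the best constituent model?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ensembles import ProbabilityMatrix, majority_vote, simple_average
from .fusion import EnsembleMapConfig, ensemble_crm, top_k_by_localization
from .localization import (
    Detection,
    GroundTruthRecord,
    extract_boxes,
    mean_average_precision,
    mean_image_iou,
)
from .metrics import confusion, metric_suite
from .saliency import RelevanceMap, crm_closed_form, threshold_map, upscale_map
from .synthetic import (
    SyntheticSample,
    TinyCnnAdapter,
    TinyCnnSpec,
    build_tiny_cnn,
    generate_dataset,
    train_demo,
)

__all__ = ["StudyResult", "run_localization_study", "model_heatmap_detections"]


@dataclass(frozen=True)
class StudyResult:
    """All quantities computed by :func:`run_localization_study`."""

    model_accuracy: dict[str, float]
    model_auc: dict[str, float]
    model_iou: dict[str, float]
    model_map: dict[str, float]
    ensemble_members: list[str]
    ensemble_iou: float
    ensemble_map: float
    vote_accuracy: float
    average_accuracy: float
    average_auc: float
    n_test: int
    n_abnormal_test: int


def model_heatmap_detections(
    model: TinyCnnAdapter,
    samples: Sequence[SyntheticSample],
    threshold_fraction: float = 0.10,
) -> tuple[list[Detection], dict[str, RelevanceMap]]:
    """Per-image CRM detections for one model over a sample set.

    Each image's relevance map is upscaled to image size, display-
    thresholded, and converted to box detections whose confidence is the
    in-box heatmap maximum weighted by the model's abnormal-class
    probability.  Also returns the raw (unthresholded, upscaled) maps so
    they can be reused for map fusion.
    """
    dets: list[Detection] = []
    raw_maps: dict[str, RelevanceMap] = {}
    size = samples[0].image.shape
    for sample in samples:
        stack = model.features(sample.image)
        rmap = RelevanceMap(
            crm_closed_form(stack, model.linear_head).values,
            source_id=model.source_id,
        )
        raw_maps[sample.image_id] = rmap
        shown = threshold_map(upscale_map(rmap, size), threshold_fraction)
        p_abnormal = float(model.head_forward(stack, "probability").scores[0])
        dets.extend(
            extract_boxes(shown, p_abnormal, image_id=sample.image_id)
        )
    return dets, raw_maps


def run_localization_study(
    seed: int,
    n_samples: int = 200,
    n_models: int = 3,
    epochs: int = 10,
    size: int = 64,
    top_k: int = 3,
    threshold_fraction: float = 0.10,
) -> StudyResult:
    """Run the whole desk-scale experiment, deterministically from ``seed``.

    Simulates ``n_samples`` images (half abnormal), trains ``n_models``
    tiny CNNs (distinct conv seeds) for at most ``epochs`` epochs, then on
    the held-out test split computes per-model classification metrics,
    per-model CRM localization scores, the top-``top_k`` ensemble-CRM
    localization scores, and voting/averaging prediction-ensemble metrics.
    """
    samples, _ = generate_dataset(n_samples, 0.5, seed=seed, size=size)
    spec = TinyCnnSpec(image_size=size, depth=1)
    models = [
        build_tiny_cnn(spec, seed=seed + 101 * (j + 1), source_id=f"model{j+1}")
        for j in range(n_models)
    ]
    trained, tables, splits = train_demo(models, samples, epochs=epochs, seed=seed)
    test = splits["test"]
    y_test = np.array([s.y for s in test])

    model_accuracy: dict[str, float] = {}
    model_auc: dict[str, float] = {}
    prob_mats: list[ProbabilityMatrix] = []
    for model_id, table in tables.items():
        p_abn = table["p_abnormal"].to_numpy()
        record = metric_suite(confusion(y_test, p_abn), y_test, p_abn)
        model_accuracy[model_id] = record.accuracy
        model_auc[model_id] = record.auc if record.auc is not None else float("nan")
        prob_mats.append(
            ProbabilityMatrix(
                table[["p_abnormal", "p_normal"]].to_numpy(), model_id=model_id
            )
        )

    abnormal = [s for s in test if s.y == 1]
    gts = [GroundTruthRecord(s.image_id, s.lesion_boxes) for s in abnormal]
    model_iou: dict[str, float] = {}
    model_map: dict[str, float] = {}
    raw_maps_by_model: dict[str, dict[str, RelevanceMap]] = {}
    for model in trained:
        dets, raw_maps = model_heatmap_detections(
            model, abnormal, threshold_fraction
        )
        raw_maps_by_model[model.source_id] = raw_maps
        model_iou[model.source_id] = mean_image_iou(dets, gts)
        model_map[model.source_id] = mean_average_precision(dets, gts)

    scores = {
        mid: {"iou": model_iou[mid], "map": model_map[mid]}
        for mid in model_iou
    }
    members = top_k_by_localization(list(model_iou), scores, min(top_k, n_models))
    cfg = EnsembleMapConfig(input_size=(size, size),
                            threshold_fraction=threshold_fraction)
    ens_dets: list[Detection] = []
    for sample in abnormal:
        fused = ensemble_crm(
            [raw_maps_by_model[mid][sample.image_id] for mid in members], cfg
        )
        ens_dets.extend(extract_boxes(fused, 1.0, image_id=sample.image_id))

    avg = simple_average(prob_mats)
    avg_record = metric_suite(
        confusion(y_test, avg.p_abnormal), y_test, avg.p_abnormal
    )
    vote = majority_vote(prob_mats)

    return StudyResult(
        model_accuracy=model_accuracy,
        model_auc=model_auc,
        model_iou=model_iou,
        model_map=model_map,
        ensemble_members=members,
        ensemble_iou=mean_image_iou(ens_dets, gts),
        ensemble_map=mean_average_precision(ens_dets, gts),
        vote_accuracy=float((vote == y_test).mean()),
        average_accuracy=avg_record.accuracy,
        average_auc=avg_record.auc if avg_record.auc is not None else float("nan"),
        n_test=len(test),
        n_abnormal_test=len(abnormal),
    )
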