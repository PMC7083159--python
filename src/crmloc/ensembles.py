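"""Combining class-probability outputs of several classifiers.

Four strategies for fusing per-model (abnormal, normal) probability tables
into one prediction: majority voting on thresholded labels, simple
averaging, weighted averaging with performance-based weights, and stacked
generalization — a small neural meta-learner (one hidden layer, softmax
output) trained on the concatenated base-model probabilities while the
base models stay frozen.

Probability tables are :class:`ProbabilityMatrix` objects: ``n_samples x 2``
arrays whose columns are P(abnormal), P(normal), rows summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from .exceptions import InputError

__all__ = [
    "ProbabilityMatrix",
    "WeightVector",
    "MetaLearnerSpec",
    "StackedEnsemble",
    "majority_vote",
    "simple_average",
    "weighted_average",
    "fit_stacking",
    "predict_stacking",
    "stack_inputs",
]

ABNORMAL, NORMAL = 0, 1  # column order


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-model two-class probabilities; columns (abnormal, normal)."""

    values: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.values, dtype=float))
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InputError(f"probability matrix must be n x 2, got {arr.shape}")
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise InputError("probabilities must lie in [0, 1]")
        if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-6):
            raise InputError("probability rows must sum to 1 within 1e-6")
        object.__setattr__(self, "values", arr)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def p_abnormal(self) -> np.ndarray:
        return self.values[:, ABNORMAL]

    def labels(self, threshold: float = 0.5) -> np.ndarray:
        """Binarized prediction: 1 = abnormal (P(abnormal) >= threshold)."""
        return (self.p_abnormal >= threshold).astype(int)


@dataclass(frozen=True)
class WeightVector:
    """Convex model weights (non-negative, summing to 1)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if np.any(w < 0):
            raise InputError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise InputError(f"weights must sum to 1 within 1e-6, got {w.sum()}")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class MetaLearnerSpec:
    """Stacking meta-learner shape: one hidden layer, softmax output.

    With 7 base models the input is the concatenated 14-element probability
    vector interpreted by a 14-neuron hidden layer.
    """

    n_models: int
    hidden_units: int = 14
    hidden_activation: str = "relu"

    def __post_init__(self) -> None:
        if self.n_models < 1 or self.hidden_units < 1:
            raise InputError("n_models and hidden_units must be positive")

    @property
    def input_width(self) -> int:
        return 2 * self.n_models


def _check_aligned(predictions: Sequence[ProbabilityMatrix]) -> int:
    if len(predictions) == 0:
        raise InputError("need at least one probability matrix")
    n = predictions[0].n_samples
    if any(p.n_samples != n for p in predictions):
        raise InputError("probability matrices disagree on sample count")
    return n


def majority_vote(
    predictions: Sequence[ProbabilityMatrix], threshold: float = 0.5
) -> np.ndarray:
    """Per-sample modal label over the models' thresholded votes.

    Each model votes abnormal when its P(abnormal) >= ``threshold``; the
    label with the most votes wins.  Even-count ties resolve to abnormal
    (favoring sensitivity in a triage setting).  Returns 1 = abnormal,
    0 = normal.
    """
    _check_aligned(predictions)
    votes = np.stack([p.labels(threshold) for p in predictions])  # models x n
    n_models = votes.shape[0]
    abnormal_votes = votes.sum(axis=0)
    return (2 * abnormal_votes >= n_models).astype(int)


def simple_average(predictions: Sequence[ProbabilityMatrix]) -> ProbabilityMatrix:
    """Elementwise arithmetic mean of the model probability tables."""
    _check_aligned(predictions)
    mean = np.mean([p.values for p in predictions], axis=0)
    ids = ",".join(p.model_id or "?" for p in predictions)
    return ProbabilityMatrix(mean, model_id=f"average({ids})")


def weighted_average(
    predictions: Sequence[ProbabilityMatrix], w: WeightVector
) -> ProbabilityMatrix:
    """Convex combination ``sum_j w_j P_j`` of the model tables.

    Uniform weights reduce to :func:`simple_average`; a one-hot weight
    returns that model's table.
    """
    _check_aligned(predictions)
    if len(w) != len(predictions):
        raise InputError(
            f"{len(w)} weights for {len(predictions)} models"
        )
    out = np.tensordot(w.weights, np.stack([p.values for p in predictions]), axes=1)
    ids = ",".join(p.model_id or "?" for p in predictions)
    return ProbabilityMatrix(out, model_id=f"weighted({ids})")


def stack_inputs(predictions: Sequence[ProbabilityMatrix]) -> np.ndarray:
    """Concatenate base-model probabilities into per-sample feature rows.

    Model order is preserved: row = (p1_abn, p1_norm, p2_abn, p2_norm, ...),
    the ``2 * n_models``-element input of the meta-learner.
    """
    _check_aligned(predictions)
    return np.hstack([p.values for p in predictions])


@dataclass(frozen=True)
class StackedEnsemble:
    """A trained stacking meta-learner over frozen base models."""

    spec: MetaLearnerSpec
    model: MLPClassifier


def fit_stacking(
    base_predictions_train: Sequence[ProbabilityMatrix],
    labels_train: np.ndarray,
    spec: MetaLearnerSpec | None = None,
    seed: int = 0,
) -> StackedEnsemble:
    """Train the stacking meta-learner on base-model probabilities.

    The base models are frozen: their probability tables are pure inputs.
    The meta-learner is a single-hidden-layer network trained by
    cross-entropy with early stopping on an internal held-out split;
    deterministic for a fixed ``seed``.  ``labels_train`` uses 1 = abnormal.
    """
    if spec is None:
        spec = MetaLearnerSpec(n_models=len(base_predictions_train))
    X = stack_inputs(base_predictions_train)
    if X.shape[1] != spec.input_width:
        raise InputError(
            f"stacked input width {X.shape[1]} != spec.input_width {spec.input_width}"
        )
    y = np.asarray(labels_train, dtype=int).ravel()
    if y.size != X.shape[0]:
        raise InputError("labels_train length does not match predictions")
    model = MLPClassifier(
        hidden_layer_sizes=(spec.hidden_units,),
        activation=spec.hidden_activation,
        solver="adam",
        max_iter=2000,
        early_stopping=True,
        n_iter_no_change=25,
        validation_fraction=0.15,
        random_state=int(seed),
    )
    model.fit(X, y)
    return StackedEnsemble(spec=spec, model=model)


def predict_stacking(
    meta: StackedEnsemble, base_predictions: Sequence[ProbabilityMatrix]
) -> ProbabilityMatrix:
    """Apply a trained meta-learner; rows of the output sum to 1."""
    X = stack_inputs(base_predictions)
    if X.shape[1] != meta.spec.input_width:
        raise InputError(
            f"stacked input width {X.shape[1]} != spec.input_width "
            f"{meta.spec.input_width}"
        )
    proba = meta.model.predict_proba(X)
    classes = list(meta.model.classes_)
    p_abn = proba[:, classes.index(1)]
    p_norm = proba[:, classes.index(0)]
    return ProbabilityMatrix(np.column_stack([p_abn, p_norm]), model_id="stacking")
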