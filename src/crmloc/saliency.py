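"""Class-selective relevance mapping (CRM) for CNN classifiers.

CRM scores the importance of each spatial element ``(l, m)`` of the feature
maps at the deepest convolutional layer of a trained classifier.  With
``S_c`` the score at output node ``c`` and ``S_c(l, m)`` the score after
removing that spatial element (zeroing all ``K`` channels at ``(l, m)``),
the relevance map is

    R(l, m) = sum_c (S_c - S_c(l, m))**2

summed over all ``N`` output nodes.  A large value means removing the
element moves *all* class scores substantially — the element is
class-discriminative, contributing positively to the predicted class and
negatively to the rest.

Two evaluation routes are provided:

* :func:`crm_bruteforce` — literal element-by-element removal through any
  model head; works for logit or post-softmax scores.
* :func:`crm_closed_form` — exact shortcut for global-average-pooling (GAP)
  + linear heads at the logit level, where the score change from removing
  one element is the element's own (normalized) contribution to each logit.

Post-processing helpers (:func:`upscale_map`, :func:`threshold_map`) bring
maps to image resolution and suppress low scores for display and fusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Protocol, runtime_checkable

import numpy as np
from skimage.transform import resize as _sk_resize

from .exceptions import (
    ContractViolationError,
    InputError,
    UnsupportedArchitectureError,
)

ScoreKind = Literal["logit", "probability"]

__all__ = [
    "FeatureStack",
    "ClassScores",
    "LinearHead",
    "ModelAdapter",
    "GapLinearModel",
    "RelevanceMap",
    "crm_bruteforce",
    "crm_closed_form",
    "upscale_map",
    "threshold_map",
]


@dataclass(frozen=True)
class FeatureStack:
    """Deepest-conv-layer activations, indexed ``(l, m, k)``.

    ``l`` runs over the ``u`` spatial rows, ``m`` over the ``v`` spatial
    columns and ``k`` over the ``K`` channels.  Values are unitless
    activations and must be finite.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise InputError(
                f"feature stack must be (u, v, K) with u,v,K >= 1, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InputError("feature stack contains non-finite activations")
        object.__setattr__(self, "values", arr)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class ClassScores:
    """Output-node scores ``S_c``, either raw logits or softmax probabilities."""

    scores: np.ndarray
    score_kind: ScoreKind = "logit"

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float).ravel()
        if arr.size < 2:
            raise InputError("need at least two output nodes")
        if not np.all(np.isfinite(arr)):
            raise InputError("class scores must be finite")
        if self.score_kind == "probability":
            if np.any(arr < 0) or np.any(arr > 1) or abs(arr.sum() - 1.0) > 1e-6:
                raise InputError("probability scores must lie in [0,1] and sum to 1")
        object.__setattr__(self, "scores", arr)


@dataclass(frozen=True)
class LinearHead:
    """GAP-plus-linear head descriptor.

    Logit of node ``c`` is ``(1/Z) * sum_{l,m,k} W[k, c] * f_k(l, m) + b[c]``
    with ``Z = u * v`` — i.e. global average pooling over space followed by
    a dense layer with weights ``W`` (K x N) and bias ``b`` (N).
    """

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        b = np.asarray(self.b, dtype=float).ravel()
        if W.shape[1] != b.size:
            raise InputError(f"W is {W.shape} but bias has length {b.size}")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b", b)

    @property
    def n_classes(self) -> int:
        return self.W.shape[1]

    def logits(self, stack: FeatureStack) -> np.ndarray:
        if stack.n_channels != self.W.shape[0]:
            raise ContractViolationError(
                f"stack has {stack.n_channels} channels, head expects {self.W.shape[0]}"
            )
        pooled = stack.values.mean(axis=(0, 1))  # GAP: (K,)
        return pooled @ self.W + self.b


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


@runtime_checkable
class ModelAdapter(Protocol):
    """Contract a trained classifier must satisfy for CRM computation.

    ``head_forward`` must be deterministic (stochastic layers such as
    dropout disabled at inference).  ``linear_head`` returns the GAP-linear
    descriptor when the architecture has one, else ``None``.
    """

    def features(self, image: np.ndarray) -> FeatureStack: ...

    def head_forward(
        self, stack: FeatureStack, score_kind: ScoreKind = "logit"
    ) -> ClassScores: ...

    @property
    def linear_head(self) -> Optional[LinearHead]: ...


@dataclass(frozen=True)
class GapLinearModel:
    """Minimal adapter: a bare GAP + dense-softmax head over given stacks.

    Useful for testing heads in isolation; it has no convolutional stage,
    so :meth:`features` is the identity on an already-extracted stack.
    """

    head: LinearHead
    source_id: str = "gap-linear"

    def features(self, image: np.ndarray) -> FeatureStack:
        return FeatureStack(np.asarray(image, dtype=float))

    def head_forward(
        self, stack: FeatureStack, score_kind: ScoreKind = "logit"
    ) -> ClassScores:
        z = self.head.logits(stack)
        if score_kind == "probability":
            return ClassScores(_softmax(z), "probability")
        return ClassScores(z, "logit")

    @property
    def linear_head(self) -> Optional[LinearHead]:
        return self.head


@dataclass(frozen=True)
class RelevanceMap:
    """Non-negative 2-D saliency grid, optionally upscaled to image size."""

    values: np.ndarray
    source_id: str = ""
    input_size: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InputError(f"relevance map must be 2-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise InputError("relevance map contains non-finite values")
        if np.any(arr < 0):
            raise InputError("relevance map must be non-negative")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def max(self) -> float:
        return float(self.values.max())


def crm_bruteforce(
    adapter: ModelAdapter,
    stack: FeatureStack,
    score_kind: ScoreKind = "logit",
) -> RelevanceMap:
    """CRM by literal spatial-element removal.

    For every location ``(l, m)`` all ``K`` channel activations are zeroed
    simultaneously, the head is re-evaluated, and the summed squared score
    change over all output nodes is recorded.  The stack itself is never
    mutated.  Works with any head (``score_kind="probability"`` re-evaluates
    through the softmax).
    """
    base = adapter.head_forward(stack, score_kind).scores
    u, v = stack.spatial_shape
    out = np.zeros((u, v), dtype=float)
    work = stack.values.copy()
    for l in range(u):
        for m in range(v):
            saved = work[l, m].copy()
            work[l, m] = 0.0
            removed = adapter.head_forward(FeatureStack(work), score_kind).scores
            work[l, m] = saved
            diff = base - removed
            out[l, m] = float(diff @ diff)
    return RelevanceMap(out, source_id=getattr(adapter, "source_id", "model"))


def crm_closed_form(
    stack: FeatureStack,
    W: np.ndarray | LinearHead,
    b: Optional[np.ndarray] = None,
) -> RelevanceMap:
    """CRM for a GAP-plus-linear head, without explicit removals.

    With logit scores, removing element ``(l, m)`` changes logit ``c`` by
    exactly that element's pooled contribution ``(1/Z) * sum_k W[k,c] *
    f_k(l,m)`` (the bias and all other elements cancel), so

        R(l, m) = sum_c ((1/Z) * sum_k W[k, c] * f_k(l, m))**2

    which equals :func:`crm_bruteforce` with ``score_kind="logit"`` up to
    floating-point tolerance.  Raises
    :class:`~crmloc.exceptions.UnsupportedArchitectureError` when no head
    descriptor is supplied.
    """
    if W is None:
        raise UnsupportedArchitectureError(
            "closed-form CRM needs a GAP-linear head descriptor (W, b)"
        )
    if isinstance(W, LinearHead):
        head = W
    else:
        head = LinearHead(W, np.zeros(np.atleast_2d(W).shape[1]) if b is None else b)
    if stack.n_channels != head.W.shape[0]:
        raise ContractViolationError(
            f"stack has {stack.n_channels} channels, head expects {head.W.shape[0]}"
        )
    u, v = stack.spatial_shape
    z = float(u * v)
    # contribution[l, m, c] = (1/Z) * sum_k W[k, c] * f[l, m, k]
    contrib = np.tensordot(stack.values, head.W, axes=([2], [0])) / z
    return RelevanceMap(np.sum(contrib**2, axis=2))


def upscale_map(rmap: RelevanceMap, target: tuple[int, int]) -> RelevanceMap:
    """Bilinearly upscale a relevance map to ``target = (H, W)`` pixels."""
    h, w = int(target[0]), int(target[1])
    if h <= 0 or w <= 0:
        raise InputError(f"target size must be positive, got {(h, w)}")
    if h < rmap.shape[0] or w < rmap.shape[1]:
        raise InputError(f"target {(h, w)} smaller than map {rmap.shape}")
    if (h, w) == rmap.shape:
        values = rmap.values.copy()
    else:
        values = _sk_resize(
            rmap.values,
            (h, w),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        values = np.clip(values, 0.0, None)
    return RelevanceMap(values, source_id=rmap.source_id, input_size=(h, w))


def threshold_map(rmap: RelevanceMap, fraction: float) -> RelevanceMap:
    """Zero out entries below ``fraction`` of the map's maximum.

    Used with ``fraction=0.10`` to suppress noisy low scores before and
    after ensemble fusion.  Idempotent for a fixed fraction; a zero map is
    returned unchanged.
    """
    if not 0.0 <= fraction < 1.0:
        raise InputError(f"fraction must be in [0, 1), got {fraction}")
    values = rmap.values.copy()
    cut = fraction * values.max()
    values[values < cut] = 0.0
    return RelevanceMap(values, source_id=rmap.source_id, input_size=rmap.input_size)
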