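"""Synthetic chest-like images, lung masks, lesion boxes and tiny CNNs.

Desk-scale stand-in for a weakly-supervised radiograph collection: every
image shows a brighter "body" field with two darker elliptical lung
fields; abnormal images additionally contain localized bright Gaussian
"opacity" blobs inside a lung, each with a known ground-truth bounding box
(the +/-2 sigma rectangle, covering ~95% of the blob mass).  Image-level
labels plus boxes for the abnormal subset mirror the annotation style of
the RSNA pneumonia-detection data, at a size where classifiers train on a
CPU in seconds.

The model factory builds tiny CNN classifiers as a linear stack of
depthwise-separable convolution blocks (5 x 5 kernels, ReLU, max-pooling,
kernel count doubling per section, 3 x depth blocks in three sections)
closed by global average pooling, dropout and a dense softmax layer.  The
convolutional stage is frozen at its seeded He initialization — random
convolutional features — and training fits the GAP-linear head by
softmax cross-entropy with early stopping, which is sufficient for the
synthetic task and keeps every run deterministic and fast.  The resulting
adapters expose the deepest-conv feature stack and the exact GAP-linear
head descriptor required for closed-form relevance mapping.

Everything here is a pure function of its seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import InputError, PlacementError
from .localization import BoundingBox, iou as _iou
from .preprocess import LungMask, mask_to_bbox
from .saliency import ClassScores, FeatureStack, LinearHead, ScoreKind, _softmax

__all__ = [
    "SyntheticSample",
    "TinyCnnSpec",
    "TinyCnnAdapter",
    "generate_sample",
    "generate_dataset",
    "build_tiny_cnn",
    "split_dataset",
    "train_head",
    "train_demo",
]

# minimum spatial size of intermediate feature maps; pooling stops before
# the maps would shrink below this, so the deepest layer stays mappable
MIN_FEATURE_SIZE = 4


# --------------------------------------------------------------------------
# image generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSample:
    """One generated image with label, lesion boxes, lung mask and seed."""

    image_id: str
    image: np.ndarray
    label: str  # "normal" | "abnormal"
    lesion_boxes: tuple[BoundingBox, ...]
    mask: LungMask
    seed: int

    def __post_init__(self) -> None:
        if (self.label == "normal") != (len(self.lesion_boxes) == 0):
            raise InputError("label must be normal iff there are no lesion boxes")

    @property
    def y(self) -> int:
        return 1 if self.label == "abnormal" else 0


def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def generate_sample(
    seed: int,
    size: int = 64,
    n_lesions: int = 0,
    contrast: float = 0.8,
    image_id: str = "",
) -> SyntheticSample:
    """Generate one chest-like image, deterministically from ``seed``.

    Background: body field (intensity ~0.55) with two darker elliptical
    lung fields (~0.25) and seeded smooth noise.  Each lesion is an
    additive 2-D Gaussian bright blob (peak height = ``contrast``) centered
    inside a randomly chosen lung ellipse; its ground-truth box is the
    +/-2 sigma rectangle clipped to the lung-mask bounding box.  Lesion
    boxes are placed non-overlapping; if that fails after many tries a
    :class:`~crmloc.exceptions.PlacementError` is raised.
    """
    if size < 32:
        raise InputError(f"size must be >= 32, got {size}")
    if n_lesions < 0:
        raise InputError("n_lesions must be >= 0")
    if not 0.0 < contrast <= 1.0:
        raise InputError(f"contrast must be in (0, 1], got {contrast}")
    rng = np.random.default_rng(seed)
    s = float(size)

    image = np.full((size, size), 0.55)
    lungs = []
    for side in (-1.0, 1.0):
        cx = s * (0.5 + side * (0.18 + rng.uniform(-0.0075, 0.0075)))
        cy = s * (0.47 + rng.uniform(-0.01, 0.01))
        ax = s * (0.15 + rng.uniform(-0.005, 0.005))
        ay = s * (0.28 + rng.uniform(-0.01, 0.01))
        lungs.append((cx, cy, ax, ay))
    lung_mask = np.zeros((size, size), dtype=bool)
    for cx, cy, ax, ay in lungs:
        lung_mask |= _ellipse_mask(size, cx, cy, ax, ay)
    image[lung_mask] = 0.25

    noise = rng.normal(0.0, 1.0, (size, size))
    noise = gaussian_filter(noise, sigma=s / 16.0, mode="reflect")
    std = noise.std()
    if std > 0:
        image += 0.03 * noise / std

    mask = LungMask(lung_mask.astype(np.uint8), image_id=image_id)
    mask_box = mask_to_bbox(mask)

    boxes: list[BoundingBox] = []
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(200):
            cx0, cy0, ax0, ay0 = lungs[int(rng.integers(len(lungs)))]
            # sample the center well inside the lung ellipse
            theta = rng.uniform(0.0, 2.0 * math.pi)
            r = math.sqrt(rng.uniform(0.0, 1.0)) * 0.6
            cx = cx0 + r * math.cos(theta) * ax0
            cy = cy0 + r * math.sin(theta) * ay0
            sx = rng.uniform(0.06, 0.09) * s
            sy = rng.uniform(0.06, 0.09) * s
            cand = BoundingBox(
                x_min=max(mask_box.x_min, cx - 2 * sx),
                y_min=max(mask_box.y_min, cy - 2 * sy),
                x_max=min(mask_box.x_max, cx + 2 * sx),
                y_max=min(mask_box.y_max, cy + 2 * sy),
            )
            if any(_iou(cand, other) > 0.0 for other in boxes):
                continue
            blob = contrast * np.exp(
                -(((xx - cx) ** 2) / (2 * sx**2) + ((yy - cy) ** 2) / (2 * sy**2))
            )
            image += blob
            boxes.append(cand)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place {n_lesions} non-overlapping lesions in the lungs"
            )

    image = np.clip(image, 0.0, 1.0)
    label = "abnormal" if boxes else "normal"
    return SyntheticSample(
        image_id=image_id or f"seed{seed}",
        image=image,
        label=label,
        lesion_boxes=tuple(boxes),
        mask=mask,
        seed=int(seed),
    )


def generate_dataset(
    n: int,
    abnormal_fraction: float = 0.5,
    seed: int = 0,
    size: int = 64,
    contrast: float = 0.8,
    max_lesions: int = 2,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate ``n`` samples plus an annotation manifest.

    Class counts are the rounded fractions; per-sample seeds are spawned
    from the master seed with counter-based ``SeedSequence`` children, so
    the stream is reproducible and samples are independent.  The manifest
    is a DataFrame in the challenge dialect (``patientId, x, y, width,
    height, Target``): one row per normal image (empty coordinates,
    Target=0) and one row per lesion box (Target=1).
    """
    if n < 2:
        raise InputError(f"n must be >= 2, got {n}")
    if not 0.0 < abnormal_fraction < 1.0:
        raise InputError(f"abnormal_fraction must be in (0, 1), got {abnormal_fraction}")
    n_abnormal = int(round(n * abnormal_fraction))
    n_abnormal = min(max(n_abnormal, 1), n - 1)
    labels = np.array([1] * n_abnormal + [0] * (n - n_abnormal))
    master = np.random.default_rng(seed)
    master.shuffle(labels)
    children = np.random.SeedSequence(seed).spawn(n)
    samples: list[SyntheticSample] = []
    rows: list[dict] = []
    for i, (lab, child) in enumerate(zip(labels, children)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        n_lesions = int(master.integers(1, max_lesions + 1)) if lab else 0
        sample = generate_sample(
            seed=child_seed,
            size=size,
            n_lesions=n_lesions,
            contrast=contrast,
            image_id=f"s{i:04d}",
        )
        samples.append(sample)
        if sample.label == "normal":
            rows.append(
                {"patientId": sample.image_id, "x": "", "y": "",
                 "width": "", "height": "", "Target": 0}
            )
        else:
            for box in sample.lesion_boxes:
                x, y, w, h = box.to_xywh()
                rows.append(
                    {"patientId": sample.image_id, "x": x, "y": y,
                     "width": w, "height": h, "Target": 1}
                )
    manifest = pd.DataFrame(rows, columns=["patientId", "x", "y", "width", "height", "Target"])
    return samples, manifest


def split_dataset(
    samples: Sequence[SyntheticSample],
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.2),
    seed: int = 0,
) -> dict[str, list[SyntheticSample]]:
    """Disjoint train/val/test split by sample id, seeded and shuffled."""
    if abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) <= 0:
        raise InputError(f"fractions must be positive and sum to 1, got {fractions}")
    idx = np.arange(len(samples))
    np.random.default_rng(seed).shuffle(idx)
    n_train = int(round(fractions[0] * len(samples)))
    n_val = int(round(fractions[1] * len(samples)))
    parts = {
        "train": [samples[i] for i in idx[:n_train]],
        "val": [samples[i] for i in idx[n_train:n_train + n_val]],
        "test": [samples[i] for i in idx[n_train + n_val:]],
    }
    if any(len(v) == 0 for v in parts.values()):
        raise InputError("split produced an empty part; use more samples")
    return parts


# --------------------------------------------------------------------------
# tiny CNN factory
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TinyCnnSpec:
    """Architecture rules for the tiny separable-conv classifier.

    Three sections of ``depth`` blocks each (3 x depth blocks total);
    every block is a 5 x 5 depthwise-separable convolution + ReLU followed
    by 2 x 2 max-pooling (skipped once maps would shrink below
    ``MIN_FEATURE_SIZE``); the kernel count starts at
    ``ceil(image_size / sqrt(depth))`` and doubles per section; the head is
    GAP -> dropout(0.5) -> dense softmax over 2 classes.
    """

    image_size: int = 64
    depth: int = 1
    n_classes: int = 2
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InputError(f"depth must be >= 1, got {self.depth}")
        if self.image_size < 8:
            raise InputError(f"image_size must be >= 8, got {self.image_size}")

    @property
    def kernels_initial(self) -> int:
        return int(math.ceil(self.image_size / math.sqrt(self.depth)))

    @property
    def n_blocks(self) -> int:
        return 3 * self.depth

    @property
    def section_kernels(self) -> tuple[int, ...]:
        return tuple(self.kernels_initial * (2**s) for s in range(3))


def _depthwise_conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """5x5 depthwise convolution, zero ('same') padding. x: (H, W, C)."""
    kh, kw, _ = w.shape
    ph, pw = kh // 2, kw // 2
    h, wd = x.shape[:2]
    xp = np.pad(x, ((ph, ph), (pw, pw), (0, 0)))
    out = np.zeros_like(x)
    for dy in range(kh):
        for dx in range(kw):
            out += xp[dy:dy + h, dx:dx + wd, :] * w[dy, dx, :]
    return out


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[: h2 * 2, : w2 * 2, :].reshape(h2, 2, w2, 2, c).max(axis=(1, 3))


class TinyCnnAdapter:
    """Model adapter over the tiny separable-conv network.

    Satisfies the CRM contract: ``features`` returns the deepest-conv
    stack, ``head_forward`` is the deterministic GAP + dense head (dropout
    active only inside the trainer), and ``linear_head`` exposes the exact
    (W, b) descriptor for closed-form relevance maps.
    """

    def __init__(self, spec: TinyCnnSpec, seed: int = 0, source_id: str = ""):
        self.spec = spec
        self.seed = int(seed)
        self.source_id = source_id or f"tinycnn(d{spec.depth},s{seed})"
        rng = np.random.default_rng(seed)
        self._blocks: list[tuple[np.ndarray, np.ndarray, bool]] = []
        c_in = 1
        size = spec.image_size
        for block in range(spec.n_blocks):
            c_out = spec.section_kernels[block // spec.depth]
            dw = rng.normal(0.0, math.sqrt(2.0 / 25.0), (5, 5, c_in))
            pw = rng.normal(0.0, math.sqrt(2.0 / c_in), (c_in, c_out))
            pool = size // 2 >= MIN_FEATURE_SIZE
            if pool:
                size //= 2
            self._blocks.append((dw, pw, pool))
            c_in = c_out
        self.feature_shape = (size, size, c_in)
        # near-zero head: an untrained model predicts ~uniform probabilities
        self.head = LinearHead(
            W=rng.normal(0.0, 1e-2, (c_in, spec.n_classes)),
            b=np.zeros(spec.n_classes),
        )

    @property
    def linear_head(self) -> Optional[LinearHead]:
        return self.head

    def features(self, image: np.ndarray) -> FeatureStack:
        """Deepest-conv activations for a single grayscale image."""
        x = np.asarray(image, dtype=float)
        if x.ndim != 2 or x.shape != (self.spec.image_size,) * 2:
            raise InputError(
                f"expected a {self.spec.image_size}x{self.spec.image_size} image, "
                f"got shape {x.shape}"
            )
        x = x[:, :, None]
        for dw, pw, pool in self._blocks:
            x = _depthwise_conv_same(x, dw)
            h, w, c_in = x.shape
            x = (x.reshape(h * w, c_in) @ pw).reshape(h, w, pw.shape[1])
            x = np.maximum(x, 0.0)  # ReLU
            if pool:
                x = _maxpool2(x)
        return FeatureStack(x)

    def gap_features(self, image: np.ndarray) -> np.ndarray:
        return self.features(image).values.mean(axis=(0, 1))

    def head_forward(
        self, stack: FeatureStack, score_kind: ScoreKind = "logit"
    ) -> ClassScores:
        z = self.head.logits(stack)
        if score_kind == "probability":
            return ClassScores(_softmax(z), "probability")
        return ClassScores(z, "logit")

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """(P(abnormal), P(normal)) for one image; output node 0 is abnormal."""
        scores = self.head_forward(self.features(image), "probability").scores
        return scores


def build_tiny_cnn(spec: TinyCnnSpec, seed: int = 0, source_id: str = "") -> TinyCnnAdapter:
    """Instantiate a seeded tiny CNN adapter from architecture rules."""
    return TinyCnnAdapter(spec, seed=seed, source_id=source_id)


def save_adapter(adapter: TinyCnnAdapter, path) -> None:
    """Persist a tiny CNN to ``.npz``: architecture, conv seed, head (W, b).

    The frozen convolutional weights are regenerated from the seed on load,
    so the checkpoint stays small.
    """
    np.savez(
        path,
        image_size=adapter.spec.image_size,
        depth=adapter.spec.depth,
        n_classes=adapter.spec.n_classes,
        dropout=adapter.spec.dropout,
        seed=adapter.seed,
        W=adapter.head.W,
        b=adapter.head.b,
        source_id=np.array(adapter.source_id),
    )


def load_adapter(path) -> TinyCnnAdapter:
    """Rebuild a tiny CNN from a checkpoint written by :func:`save_adapter`."""
    data = np.load(path, allow_pickle=False)
    spec = TinyCnnSpec(
        image_size=int(data["image_size"]),
        depth=int(data["depth"]),
        n_classes=int(data["n_classes"]),
        dropout=float(data["dropout"]),
    )
    adapter = TinyCnnAdapter(spec, seed=int(data["seed"]),
                             source_id=str(data["source_id"]))
    adapter.head = LinearHead(data["W"], data["b"])
    return adapter


# --------------------------------------------------------------------------
# desk-scale trainer
# --------------------------------------------------------------------------


def train_head(
    adapter: TinyCnnAdapter,
    gap_train: np.ndarray,
    y_train: np.ndarray,
    gap_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int = 10,
    seed: int = 0,
    lr: float = 0.05,
    batch_size: int = 8,
    patience: int = 5,
    weight_decay: float = 0.1,
) -> dict:
    """Fit the GAP-linear softmax head by minibatch cross-entropy descent.

    Features are standardized with training-set statistics for
    conditioning and the learned parameters are folded back onto the raw
    feature scale, so the adapter's head descriptor stays exact.  Dropout
    at the architecture's ratio is applied to the pooled features during
    training only (inverted dropout); inference is deterministic.  Early
    stopping keeps the parameters with the best validation loss.

    Output-node convention: node 0 = abnormal, node 1 = normal; ``y`` uses
    1 = abnormal.  Returns a history dict with per-epoch losses.
    """
    if epochs < 0:
        raise InputError("epochs must be >= 0")
    X = np.asarray(gap_train, dtype=float)
    y = np.asarray(y_train, dtype=int).ravel()
    Xv = np.asarray(gap_val, dtype=float)
    yv = np.asarray(y_val, dtype=int).ravel()
    if X.shape[0] == 0 or Xv.shape[0] == 0:
        raise InputError("empty training or validation split")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-8] = 1.0
    Xs, Xvs = (X - mu) / sd, (Xv - mu) / sd
    n, k = Xs.shape
    n_cls = adapter.spec.n_classes
    T = np.zeros((n, n_cls))
    T[:, 0] = y
    T[:, 1] = 1 - y
    Tv = np.zeros((Xvs.shape[0], n_cls))
    Tv[:, 0] = yv
    Tv[:, 1] = 1 - yv

    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 1e-2, (k, n_cls))
    b = np.zeros(n_cls)
    # Adam state
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    keep = 1.0 - adapter.spec.dropout

    def _softmax_rows(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _loss(Xm: np.ndarray, Tm: np.ndarray) -> float:
        p = _softmax_rows(Xm @ W + b)
        return float(-np.mean(np.sum(Tm * np.log(p + 1e-12), axis=1)))

    best = (_loss(Xvs, Tv), W.copy(), b.copy())
    history = {"train_loss": [], "val_loss": []}
    stale = 0
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb = Xs[idx]
            if keep < 1.0:
                drop = rng.random(Xb.shape) < keep
                Xb = Xb * drop / keep
            p = _softmax_rows(Xb @ W + b)
            err = (p - T[idx]) / len(idx)
            gW = Xb.T @ err + weight_decay * W
            gb = err.sum(axis=0)
            step += 1
            mW = beta1 * mW + (1 - beta1) * gW
            vW = beta2 * vW + (1 - beta2) * gW**2
            mb = beta1 * mb + (1 - beta1) * gb
            vb = beta2 * vb + (1 - beta2) * gb**2
            corr1 = 1 - beta1**step
            corr2 = 1 - beta2**step
            W -= lr * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
            b -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
        val = _loss(Xvs, Tv)
        history["train_loss"].append(_loss(Xs, T))
        history["val_loss"].append(val)
        if val < best[0] - 1e-6:
            best = (val, W.copy(), b.copy())
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    _, W, b = best
    # fold the standardization back onto the raw feature scale
    W_raw = W / sd[:, None]
    b_raw = b - mu @ W_raw
    adapter.head = LinearHead(W_raw, b_raw)
    return history


def train_demo(
    models: Sequence[TinyCnnAdapter],
    dataset: Sequence[SyntheticSample],
    epochs: int = 10,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.2),
) -> tuple[list[TinyCnnAdapter], dict[str, "pd.DataFrame"], dict[str, list[SyntheticSample]]]:
    """Train every model's head on a shared train/val/test split.

    Each model's frozen convolutional stage embeds the images once; the
    head is then fitted by cross-entropy with early stopping.  Returns the
    trained adapters, one held-out probability table per model (columns
    ``image_id, p_abnormal, p_normal`` for the test split), and the split
    itself.  Deterministic for fixed seeds.
    """
    if len(models) == 0:
        raise InputError("need at least one model")
    splits = split_dataset(dataset, fractions=fractions, seed=seed)
    y = {name: np.array([s.y for s in part]) for name, part in splits.items()}
    tables: dict[str, pd.DataFrame] = {}
    trained: list[TinyCnnAdapter] = []
    for j, model in enumerate(models):
        gap = {
            name: np.stack([model.gap_features(s.image) for s in part])
            for name, part in splits.items()
        }
        train_head(
            model,
            gap["train"], y["train"],
            gap["val"], y["val"],
            epochs=epochs,
            seed=seed + 1000 * (j + 1),
        )
        logits = gap["test"] @ model.head.W + model.head.b
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        tables[model.source_id] = pd.DataFrame(
            {
                "image_id": [s.image_id for s in splits["test"]],
                "p_abnormal": p[:, 0],
                "p_normal": p[:, 1],
            }
        )
        trained.append(model)
    return trained, tables, splits
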