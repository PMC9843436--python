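"""Pixel-level tissue segmentation with IoU evaluation.

The trainable model is a per-pixel softmax head over the fixed windowed
local-statistics feature bank (:mod:`milslide.features`) — a deliberately
small, pluggable stand-in for a full encoder-decoder, trained with the same
contract: a combination of weighted categorical cross-entropy and
Lovász-Softmax loss, fixed learning rate, fixed epoch budget with early
termination on validation loss.

Whole-slide maps are produced by stitching overlapping patch probability
maps (per-pixel averaging, then argmax), and evaluated with per-class IoU, a
mean IoU over classes present in the truth, and a weighted IoU that weights
each class by its truth pixel abundance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._opt import EPS, Adam, softmax
from .features import PIXEL_FEATURE_NAMES, pixel_features
from .types import SEG_CLASS_ORDER


# ---------------------------------------------------------------------------
# losses


def weighted_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, class_weights: np.ndarray
) -> float:
    """Mean over pixels of w_y * (-log p_y); probabilities epsilon-clamped."""
    p = probs.reshape(-1, probs.shape[-1])
    y = labels.ravel()
    py = p[np.arange(y.size), y]
    if (py <= EPS).any():
        warnings.warn("zero probability at a true-class pixel; clamped")
    return float(np.mean(class_weights[y] * -np.log(np.maximum(py, EPS))))


def lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Lovász extension of the Jaccard loss.

    ``gt_sorted`` is the 0/1 ground-truth vector sorted by decreasing error.
    """
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    out = jaccard.copy()
    out[1:] = jaccard[1:] - jaccard[:-1]
    return out


def lovasz_softmax(probs: np.ndarray, labels: np.ndarray) -> float:
    """Lovász-Softmax loss averaged over classes present in the labels."""
    p = probs.reshape(-1, probs.shape[-1])
    y = labels.ravel()
    losses = []
    for c in np.unique(y):
        fg = (y == c).astype(float)
        errors = np.abs(fg - p[:, c])
        order = np.argsort(-errors, kind="stable")
        losses.append(float(errors[order] @ lovasz_grad(fg[order])))
    return float(np.mean(losses))


def weighted_ce_plus_lovasz(
    probs: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray,
    lovasz_weight: float,
) -> float:
    """Total segmentation loss: weighted CE + lovasz_weight * Lovász-Softmax."""
    total = weighted_cross_entropy(probs, labels, class_weights)
    if lovasz_weight != 0:
        total += lovasz_weight * lovasz_softmax(probs, labels)
    return total


def _loss_grad_logits(
    probs: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray,
    lovasz_weight: float,
) -> np.ndarray:
    """Analytic gradient of the combined loss w.r.t. the pixel logits.

    The Lovász extension is piecewise linear in the per-pixel errors, so its
    gradient w.r.t. probabilities is the sorted-gradient vector routed back
    through the sort permutation; both terms are then pulled through the
    softmax Jacobian.
    """
    n, k = probs.shape
    y = labels
    # CE term directly in logit space: w_y * (p - onehot) / n
    grad_z = probs.copy()
    grad_z[np.arange(n), y] -= 1.0
    grad_z *= class_weights[y, None] / n

    if lovasz_weight != 0:
        present = np.unique(y)
        grad_p = np.zeros_like(probs)
        for c in present:
            fg = (y == c).astype(float)
            errors = np.abs(fg - probs[:, c])
            order = np.argsort(-errors, kind="stable")
            g = lovasz_grad(fg[order])
            gp = np.empty(n)
            gp[order] = g
            # error = 1 - p for foreground, p for background
            grad_p[:, c] += np.where(fg > 0, -gp, gp) / present.size
        dot = (grad_p * probs).sum(axis=1, keepdims=True)
        grad_z += lovasz_weight * probs * (grad_p - dot)
    return grad_z


# ---------------------------------------------------------------------------
# model


@dataclass
class SegTrainConfig:
    """Training contract for the pixel segmenter.

    The contract mirrors the full-scale recipe — 384-px patches, a fixed
    learning rate, 50 epochs with early termination (patience 5 epochs
    without validation-loss improvement) — but the default learning rate is
    sized for the linear per-pixel head trained here (0.05; a deep encoder-
    decoder backbone would want a far smaller step such as 0.0022).
    """

    patch_size: int = 384
    loss_weights: dict[str, float] = field(default_factory=dict)
    lovasz_weight: float = 1.0
    learning_rate: float = 0.05
    epochs: int = 50
    early_stop_patience: int = 5
    seed: int = 0
    feature_window: int = 15

    def weight_vector(self, class_order: tuple[str, ...]) -> np.ndarray:
        w = np.array([self.loss_weights.get(c, 1.0) for c in class_order])
        if (w <= 0).any():
            raise ValueError("loss weights must be positive")
        return w

    def digest(self) -> str:
        payload = json.dumps(
            {k: v for k, v in sorted(self.__dict__.items())}, sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SegmentationMap:
    """Single-channel class-index raster with its class vocabulary."""

    labels: np.ndarray
    class_order: tuple[str, ...] = SEG_CLASS_ORDER

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size and self.labels.max() >= len(self.class_order):
            raise ValueError("label value outside class_order")


class PixelSoftmaxSegmenter:
    """Per-pixel linear softmax head over windowed local-statistics features."""

    def __init__(
        self,
        class_order: tuple[str, ...] = SEG_CLASS_ORDER,
        feature_window: int = 15,
    ):
        self.class_order = tuple(class_order)
        self.feature_window = feature_window
        k, f = len(self.class_order), len(PIXEL_FEATURE_NAMES)
        self.W = np.zeros((f, k))
        self.b = np.zeros(k)

    def logits_from_features(self, feats: np.ndarray) -> np.ndarray:
        return feats @ self.W + self.b

    def predict_proba(self, pixels: np.ndarray) -> np.ndarray:
        """(H, W, K) per-pixel class probabilities for an RGB patch."""
        feats = pixel_features(pixels, window=self.feature_window)
        return softmax(self.logits_from_features(feats), axis=-1)

    def predict_labels(self, pixels: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(pixels), axis=-1)

    def checkpoint_digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.W.tobytes())
        h.update(self.b.tobytes())
        return h.hexdigest()[:16]

    def save(self, path, config: SegTrainConfig | None = None) -> None:
        np.savez(
            path,
            W=self.W,
            b=self.b,
            class_order=np.array(self.class_order),
            feature_window=self.feature_window,
            config_digest=(config.digest() if config else ""),
        )

    @classmethod
    def load(cls, path) -> "PixelSoftmaxSegmenter":
        data = np.load(path, allow_pickle=False)
        model = cls(
            class_order=tuple(str(c) for c in data["class_order"]),
            feature_window=int(data["feature_window"]),
        )
        model.W = data["W"]
        model.b = data["b"]
        return model


def _dataset_loss(
    model: PixelSoftmaxSegmenter,
    feats: list[np.ndarray],
    labels: list[np.ndarray],
    weights: np.ndarray,
    lovasz_weight: float,
) -> float:
    losses = [
        weighted_ce_plus_lovasz(
            softmax(model.logits_from_features(f), axis=-1).reshape(-1, len(weights)),
            y.ravel(),
            weights,
            lovasz_weight,
        )
        for f, y in zip(feats, labels)
    ]
    return float(np.mean(losses))


def train_segmenter(
    train_patches: list[np.ndarray],
    train_labels: list[np.ndarray],
    val_patches: list[np.ndarray],
    val_labels: list[np.ndarray],
    config: SegTrainConfig | None = None,
    class_order: tuple[str, ...] = SEG_CLASS_ORDER,
) -> tuple[PixelSoftmaxSegmenter, dict]:
    """Train the pixel segmenter; returns (model, history).

    Deterministic given ``config.seed``; keeps the best-validation-loss
    weights and stops early after ``early_stop_patience`` epochs without
    improvement.
    """
    config = config or SegTrainConfig()
    if len(train_patches) != len(train_labels):
        raise ValueError("every training patch needs a label crop")
    weights = config.weight_vector(class_order)
    seen = np.unique(np.concatenate([y.ravel() for y in train_labels]))
    for ci, name in enumerate(class_order):
        if ci not in seen:
            warnings.warn(f"class {name!r} absent from training labels; its "
                          "loss weight is idle")

    model = PixelSoftmaxSegmenter(class_order, config.feature_window)
    # feature bank is fixed: compute once
    tf = [pixel_features(p, config.feature_window) for p in train_patches]
    vf = [pixel_features(p, config.feature_window) for p in val_patches]
    if not vf:  # no held-out patches: early-stop on training loss
        vf, val_labels = tf, train_labels

    rng = np.random.default_rng(config.seed)
    model.W += rng.normal(0, 0.01, size=model.W.shape)
    opt = Adam([model.W, model.b], lr=config.learning_rate)

    k = len(class_order)
    init_val = _dataset_loss(model, vf, val_labels, weights, config.lovasz_weight)
    best_val, best = init_val, (model.W.copy(), model.b.copy())
    history = {"val_loss": [init_val], "train_loss": []}
    stall = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(tf))
        epoch_losses = []
        for i in order:
            f = tf[i].reshape(-1, f_dim := tf[i].shape[-1])
            y = train_labels[i].ravel()
            probs = softmax(f @ model.W + model.b, axis=-1)
            epoch_losses.append(
                weighted_ce_plus_lovasz(probs, y, weights, config.lovasz_weight)
            )
            gz = _loss_grad_logits(probs, y, weights, config.lovasz_weight)
            opt.step([f.T @ gz, gz.sum(axis=0)])
        history["train_loss"].append(float(np.mean(epoch_losses)))
        val = _dataset_loss(model, vf, val_labels, weights, config.lovasz_weight)
        history["val_loss"].append(val)
        if val < best_val - 1e-9:
            best_val, best = val, (model.W.copy(), model.b.copy())
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break
    model.W, model.b = best
    return model, history


# ---------------------------------------------------------------------------
# inference and metrics


def predict_slide(
    model: PixelSoftmaxSegmenter,
    slide,
    patch_size: int,
    stride: int | None = None,
) -> SegmentationMap:
    """Stitch overlapping patch probability maps into a whole-slide map.

    Probabilities are averaged per pixel over all covering patches, then
    argmaxed.  Slides smaller than a patch are edge-padded and cropped back.
    """
    pixels = slide.pixels if hasattr(slide, "pixels") else np.asarray(slide)
    stride = stride or patch_size
    h, w = pixels.shape[:2]
    ph, pw = max(h, patch_size), max(w, patch_size)
    if (ph, pw) != (h, w):
        pixels = np.pad(
            pixels, ((0, ph - h), (0, pw - w), (0, 0)), mode="edge"
        )
    k = len(model.class_order)
    acc = np.zeros((ph, pw, k))
    cnt = np.zeros((ph, pw, 1))
    rows = sorted({min(r, ph - patch_size) for r in range(0, ph, stride)})
    cols = sorted({min(c, pw - patch_size) for c in range(0, pw, stride)})
    for r in rows:
        for c in cols:
            probs = model.predict_proba(pixels[r : r + patch_size, c : c + patch_size])
            acc[r : r + patch_size, c : c + patch_size] += probs
            cnt[r : r + patch_size, c : c + patch_size] += 1.0
    labels = np.argmax(acc / cnt, axis=-1)[:h, :w]
    return SegmentationMap(labels=labels, class_order=model.class_order)


def tissue_percentages(seg_map: SegmentationMap) -> dict[str, float]:
    """Percent of non-background pixels per tissue class (sums to 100)."""
    labels = seg_map.labels
    tissue = labels != 0
    total = int(tissue.sum())
    out = {}
    if total == 0:
        warnings.warn("all-background map: tissue percentages undefined")
        return {c: 0.0 for c in seg_map.class_order[1:]}
    for ci, name in enumerate(seg_map.class_order):
        if ci == 0:
            continue
        out[name] = 100.0 * float((labels == ci).sum()) / total
    return out


def iou_scores(
    pred: np.ndarray | SegmentationMap,
    truth: np.ndarray | SegmentationMap,
) -> tuple[dict[int, float], float, float]:
    """Per-class IoU, mean IoU, and truth-abundance-weighted IoU.

    Mean IoU averages over classes present in the truth; the weighted IoU is
    the convex combination of per-class IoUs with weights equal to each
    class's truth pixel fraction.  Classes absent from both maps are
    excluded.
    """
    p = (pred.labels if isinstance(pred, SegmentationMap) else np.asarray(pred)).ravel()
    t = (
        truth.labels if isinstance(truth, SegmentationMap) else np.asarray(truth)
    ).ravel()
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    per_class: dict[int, float] = {}
    present = np.unique(t)
    for c in np.union1d(present, np.unique(p)):
        inter = int(((p == c) & (t == c)).sum())
        union = int(((p == c) | (t == c)).sum())
        if union > 0:
            per_class[int(c)] = inter / union
    ious = np.array([per_class[int(c)] for c in present])
    fracs = np.array([(t == c).mean() for c in present])
    mean_iou = float(ious.mean()) if ious.size else float("nan")
    weighted_iou = float((fracs / fracs.sum()) @ ious) if ious.size else float("nan")
    return per_class, mean_iou, weighted_iou
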