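"""Patch classification with multiple-instance-learning losses, and the
slide-, core-, and patient-level aggregation rules.

Two MIL loss variants implement the bag-level supervision idea that not
every patch of a labeled slide carries the label's phenotype:

* ``topk`` — per class in the batch, rank samples by their true-class score
  and keep the top ``keep_fraction`` (default 70%); cross-entropy is
  averaged over kept samples per class, then over classes;
* ``meansd`` — skip samples whose true-class score falls below
  ``mean - sd_multiplier * sd`` of the batch's true-class scores.

Slide-level calls use the positive ratio: the fraction of a slide's patches
whose argmax prediction is the positive class, thresholded (boundary
inclusive).  TMA cores are called by simple patch-vote majority and patients
by the per-class geometric mean across their cores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._opt import EPS, Adam, one_hot, softmax
from .features import patch_feature_matrix
from .types import PatchPrediction, SlidePrediction


# ---------------------------------------------------------------------------
# MIL losses


@dataclass
class MILLossConfig:
    """Which MIL variant to use and its constants."""

    variant: str = "topk"  # "topk" | "meansd"
    keep_fraction: float = 0.7
    sd_multiplier: float = 1.0
    batch_size: int = 144

    def __post_init__(self) -> None:
        if self.variant not in ("topk", "meansd"):
            raise ValueError(f"unknown MIL variant {self.variant!r}")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")


def _mil_weights(
    probs: np.ndarray, labels: np.ndarray, config: MILLossConfig
) -> np.ndarray:
    """Per-sample loss weights realizing the MIL selection rule.

    Weights sum so that the weighted cross-entropy equals the variant's
    definition (per-class mean over kept samples, then mean over classes,
    for topk; plain mean over kept samples for meansd).
    """
    n = len(labels)
    true_scores = probs[np.arange(n), labels]
    w = np.zeros(n)
    if config.variant == "topk":
        present = np.unique(labels)
        for c in present:
            idx = np.flatnonzero(labels == c)
            n_keep = math.ceil(config.keep_fraction * idx.size)
            if n_keep == 0:
                raise ValueError("MIL keep count is zero")
            order = np.argsort(-true_scores[idx], kind="stable")
            kept = idx[order[:n_keep]]
            w[kept] = 1.0 / (n_keep * present.size)
    else:  # meansd
        if n < 2:
            raise ValueError("meansd MIL needs batch size >= 2")
        mu, sd = true_scores.mean(), true_scores.std()
        keep = true_scores >= mu - config.sd_multiplier * sd
        if not keep.any():
            warnings.warn("meansd MIL skipped every sample; using full batch")
            keep = np.ones(n, dtype=bool)
        w[keep] = 1.0 / keep.sum()
    return w


def _weighted_ce(probs: np.ndarray, labels: np.ndarray, w: np.ndarray) -> float:
    py = probs[np.arange(len(labels)), labels]
    return float(w @ -np.log(np.maximum(py, EPS)))


def mil_topk_loss(
    probs: np.ndarray, labels: np.ndarray, config: MILLossConfig | None = None
) -> float:
    """Top-k MIL loss: average CE over the top ``keep_fraction`` of each
    class's samples ranked by true-class score, then average over classes."""
    config = config or MILLossConfig(variant="topk")
    w = _mil_weights(probs, labels, MILLossConfig("topk", config.keep_fraction,
                                                  config.sd_multiplier,
                                                  config.batch_size))
    return _weighted_ce(probs, labels, w)


def mil_meansd_skip_loss(
    probs: np.ndarray, labels: np.ndarray, config: MILLossConfig | None = None
) -> float:
    """Mean/SD skip MIL loss: CE averaged over samples whose true-class score
    is at least ``mean - sd_multiplier * sd`` of the batch's scores."""
    config = config or MILLossConfig(variant="meansd")
    w = _mil_weights(probs, labels, MILLossConfig("meansd", config.keep_fraction,
                                                  config.sd_multiplier,
                                                  config.batch_size))
    return _weighted_ce(probs, labels, w)


# ---------------------------------------------------------------------------
# patch classifier


@dataclass
class ClassifierTrainConfig:
    """Training contract for the patch classifier head."""

    mil: MILLossConfig = field(default_factory=MILLossConfig)
    learning_rate: float = 0.01
    epochs: int = 80
    hidden_units: int = 24
    early_stop_patience: int = 10
    seed: int = 0


class PatchMLPClassifier:
    """One-hidden-layer softmax classifier over the patch feature bank."""

    def __init__(self, n_features: int, n_classes: int, hidden_units: int,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.W1 = rng.normal(0, 0.3, size=(n_features, hidden_units))
        self.b1 = np.zeros(hidden_units)
        self.W2 = rng.normal(0, 0.3, size=(hidden_units, n_classes))
        self.b2 = np.zeros(n_classes)
        self.mu = np.zeros(n_features)
        self.sigma = np.ones(n_features)

    def set_normalization(self, X: np.ndarray) -> None:
        self.mu = X.mean(axis=0)
        self.sigma = np.maximum(X.std(axis=0), 1e-6)

    def _forward(self, X: np.ndarray):
        Z = (X - self.mu) / self.sigma
        A = np.tanh(Z @ self.W1 + self.b1)
        return Z, A, softmax(A @ self.W2 + self.b2, axis=-1)

    def predict_proba_features(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(X))[2]

    def predict_proba(self, patches) -> np.ndarray:
        """(N, K) class probabilities for Patch objects or pixel arrays."""
        return self.predict_proba_features(patch_feature_matrix(patches))

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]


def train_patch_classifier(
    train_patches,
    train_labels: np.ndarray,
    val_patches,
    val_labels: np.ndarray,
    config: ClassifierTrainConfig | None = None,
    n_classes: int | None = None,
) -> tuple[PatchMLPClassifier, dict]:
    """Train a patch classifier with the configured MIL loss.

    ``train_patches``/``val_patches`` may be Patch objects, pixel arrays, or
    precomputed feature matrices.  Deterministic given ``config.seed``; the
    best validation-loss weights are kept, with early termination.
    """
    config = config or ClassifierTrainConfig()
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    if np.unique(train_labels).size < 2:
        raise ValueError("training set contains a single class")
    n_classes = n_classes or int(max(train_labels.max(), val_labels.max()) + 1)

    X = (np.asarray(train_patches)
         if isinstance(train_patches, np.ndarray) and np.asarray(train_patches).ndim == 2
         else patch_feature_matrix(train_patches))
    Xv = (np.asarray(val_patches)
          if isinstance(val_patches, np.ndarray) and np.asarray(val_patches).ndim == 2
          else patch_feature_matrix(val_patches))
    if len(Xv) == 0:  # no held-out patches: early-stop on training loss
        Xv, val_labels = X, train_labels

    model = PatchMLPClassifier(X.shape[1], n_classes, config.hidden_units,
                               seed=config.seed)
    model.set_normalization(X)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    Y = one_hot(train_labels, n_classes)

    def val_loss() -> float:
        probs = model.predict_proba_features(Xv)
        py = probs[np.arange(len(val_labels)), val_labels]
        return float(np.mean(-np.log(np.maximum(py, EPS))))

    best_val = val_loss()
    best = [p.copy() for p in model.params]
    history = {"val_loss": [best_val]}
    stall = 0
    bs = config.mil.batch_size
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        for start in range(0, len(X), bs):
            idx = order[start : start + bs]
            if np.unique(train_labels[idx]).size < 1 or idx.size < 2:
                continue
            Z, A, probs = model._forward(X[idx])
            w = _mil_weights(probs, train_labels[idx], config.mil)
            gz = (probs - Y[idx]) * w[:, None]
            gW2 = A.T @ gz
            gb2 = gz.sum(axis=0)
            ga = gz @ model.W2.T * (1 - A * A)
            opt.step([Z.T @ ga, ga.sum(axis=0), gW2, gb2])
        val = val_loss()
        history["val_loss"].append(val)
        if val < best_val - 1e-9:
            best_val, best = val, [p.copy() for p in model.params]
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break
    for p, bp in zip(model.params, best):
        p[...] = bp
    return model, history


class EnsembleClassifier:
    """Average the probability outputs of several classifiers."""

    def __init__(self, models):
        if not models:
            raise ValueError("empty ensemble")
        self.models = list(models)

    def predict_proba_features(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba_features(X) for m in self.models], axis=0)

    def predict_proba(self, patches) -> np.ndarray:
        return np.mean([m.predict_proba(patches) for m in self.models], axis=0)


def ensemble_select_and_average(models, val_metrics, k_select: int):
    """Keep the ``k_select`` models with the best validation metric and
    average their outputs.  Ties at the boundary keep the lower index."""
    if len(models) < k_select:
        raise ValueError("fewer models than k_select")
    order = np.argsort(-np.asarray(val_metrics, dtype=float), kind="stable")
    return EnsembleClassifier([models[i] for i in order[:k_select]])


# ---------------------------------------------------------------------------
# slide-level aggregation


def _to_prob_array(preds) -> np.ndarray:
    if isinstance(preds, np.ndarray):
        return np.atleast_2d(preds)
    return np.array([
        p.scores if isinstance(p, PatchPrediction) else np.asarray(p) for p in preds
    ])


def positive_ratio(
    preds, positive_class: int, slide_id: str = "slide"
) -> SlidePrediction:
    """Fraction of patches whose argmax prediction is the positive class."""
    probs = _to_prob_array(preds)
    if probs.shape[0] == 0:
        raise ValueError("no patches")
    n_pos = int((np.argmax(probs, axis=1) == positive_class).sum())
    return SlidePrediction(
        slide_id=slide_id,
        n_patches=probs.shape[0],
        n_positive=n_pos,
        positive_ratio=n_pos / probs.shape[0],
    )


def classify_by_ratio(ratios, threshold: float) -> np.ndarray:
    """Call positive iff ratio >= threshold (boundary inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold outside [0, 1]")
    arr = np.asarray(
        [r.positive_ratio if isinstance(r, SlidePrediction) else r
         for r in np.atleast_1d(ratios)],
        dtype=float,
    )
    return arr >= threshold


def gm_score(ratios: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """sqrt(sensitivity x specificity) of the >=-threshold rule."""
    ratios = np.asarray(ratios, dtype=float)
    labels = np.asarray(labels).astype(bool)
    calls = ratios >= threshold
    sens = calls[labels].mean() if labels.any() else float("nan")
    spec = (~calls[~labels]).mean() if (~labels).any() else float("nan")
    return math.sqrt(sens * spec)


def threshold_by_geometric_mean(ratios, labels) -> float:
    """Positive-ratio threshold maximizing sqrt(sensitivity x specificity).

    Candidates are the midpoints of consecutive sorted unique validation
    ratios; ties prefer the smallest threshold.  Both classes must be
    present, and the ratios must not be all identical.
    """
    ratios = np.asarray(
        [r.positive_ratio if isinstance(r, SlidePrediction) else r
         for r in np.atleast_1d(ratios)],
        dtype=float,
    )
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(ratios)
    if uniq.size < 2:
        raise ValueError("degenerate ratios: no candidate thresholds")
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    scores = np.array([gm_score(ratios, labels, t) for t in candidates])
    return float(candidates[int(np.argmax(scores))])  # argmax takes first max


# ---------------------------------------------------------------------------
# TMA aggregation


@dataclass
class CoreCall:
    """Vote-majority call for one TMA core."""

    class_index: int
    votes: np.ndarray
    mean_scores: np.ndarray


def tma_core_predict(preds) -> CoreCall:
    """Call a TMA core by simple majority of patch argmax votes.

    A vote tie is broken by the class with the higher mean probability.
    """
    probs = _to_prob_array(preds)
    if probs.shape[0] == 0:
        raise ValueError("core has no patches")
    k = probs.shape[1]
    votes = np.bincount(np.argmax(probs, axis=1), minlength=k)
    mean_scores = probs.mean(axis=0)
    top = np.flatnonzero(votes == votes.max())
    winner = int(top[np.argmax(mean_scores[top])]) if top.size > 1 else int(top[0])
    return CoreCall(class_index=winner, votes=votes, mean_scores=mean_scores)


def patient_consensus_geomean(core_scores) -> tuple[int, np.ndarray]:
    """Consensus patient call: per-class geometric mean across cores.

    Works for any core count; a single-core patient's call is that core's
    argmax.  Zero probabilities are epsilon-floored before the log.
    """
    scores = _to_prob_array(core_scores)
    if scores.shape[0] == 0:
        raise ValueError("patient has no cores")
    if (scores <= 0).any():
        warnings.warn("zero core probability floored before geometric mean")
    logs = np.log(np.maximum(scores, EPS))
    geo = np.exp(logs.mean(axis=0))
    return int(np.argmax(geo)), geo
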