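"""Classification and agreement statistics.

Thin, contract-stating wrappers over scikit-learn and scipy for the metrics
used throughout the pipeline's evaluations — confusion matrices,
micro/macro F1, the multiclass Matthews correlation coefficient, ROC AUC,
sensitivity/specificity — plus exact (Clopper-Pearson) binomial confidence
intervals and the duplicate-core agreement report.  Display percentages are
rounded half-up to integers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from .types import BinomialAgreement, ConfusionMatrix


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def confusion_and_f1(
    truth, predictions, class_order: tuple[str, ...] | None = None
) -> tuple[ConfusionMatrix, float, float]:
    """Confusion matrix (rows truth, cols prediction), micro F1, macro F1.

    Micro F1 pools counts over classes (== accuracy for single-label
    evaluation); macro F1 is the unweighted mean of per-class F1 over
    classes that occur in truth or predictions (absent classes are excluded
    with a log message).
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.shape != predictions.shape:
        raise ValueError("truth and predictions must have equal length")
    if class_order is None:
        labels = np.unique(np.concatenate([truth, predictions]))
        class_order = tuple(str(c) for c in labels)
    else:
        labels = np.arange(len(class_order))
        occurring = np.unique(np.concatenate([truth, predictions]))
        absent = set(labels) - set(occurring)
        if absent:
            warnings.warn(
                f"classes {sorted(absent)} absent from truth and predictions; "
                "excluded from macro F1"
            )
        labels = np.array(sorted(set(labels) & set(occurring)))
    counts = _sk_confusion(truth, predictions, labels=labels)
    micro = float(f1_score(truth, predictions, labels=labels, average="micro"))
    macro = float(f1_score(truth, predictions, labels=labels, average="macro"))
    return ConfusionMatrix(counts=counts, class_order=class_order), micro, macro


def mcc(confusion: ConfusionMatrix | np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (covariance form).

    Returns 0 when a marginal is degenerate (all one truth class or all one
    predicted class).
    """
    C = confusion.counts if isinstance(confusion, ConfusionMatrix) else np.asarray(confusion)
    C = C.astype(float)
    n = C.sum()
    t = C.sum(axis=1)  # truth marginal
    p = C.sum(axis=0)  # prediction marginal
    cov_tp = np.trace(C) * n - t @ p
    cov_tt = n * n - t @ t
    cov_pp = n * n - p @ p
    if cov_tt == 0 or cov_pp == 0:
        return 0.0
    return float(cov_tp / math.sqrt(cov_tt * cov_pp))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve for binary labels.

    Equals the probability a random positive outranks a random negative,
    with ties counting one half.
    """
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def sensitivity_specificity(
    confusion: ConfusionMatrix | np.ndarray, positive_class: int = 1
) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) of the binary reduction of a confusion
    matrix; an empty denominator yields None for that entry."""
    C = confusion.counts if isinstance(confusion, ConfusionMatrix) else np.asarray(confusion)
    tp = C[positive_class, positive_class]
    fn = C[positive_class].sum() - tp
    mask = np.ones(len(C), dtype=bool)
    mask[positive_class] = False
    tn = C[np.ix_(mask, mask)].sum()
    fp = C[mask, positive_class].sum()
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    return sens, spec


def clopper_pearson_ci(
    successes: int, trials: int, level: float = 0.95
) -> BinomialAgreement:
    """Exact binomial confidence interval from Beta quantiles (in percent)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    alpha = 1 - level
    lo = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return BinomialAgreement(
        successes=successes,
        trials=trials,
        point_pct=100.0 * successes / trials,
        ci_low_pct=100.0 * lo,
        ci_high_pct=100.0 * hi,
    )


@dataclass
class DuplicateAgreementReport:
    """Agreement statistics for duplicate-core TMA patients.

    ``intra_patient`` — over multi-core patients, do the model's core calls
    agree with each other; ``matched_vs_reference`` — among patients with
    internally matching calls, does the call agree with the reference label;
    ``consensus_vs_reference`` — does the consensus call agree with the
    reference, over all patients.
    """

    intra_patient: BinomialAgreement | None
    matched_vs_reference: BinomialAgreement | None
    consensus_vs_reference: BinomialAgreement


def duplicate_agreement(
    core_calls: dict[str, list],
    consensus_calls: dict[str, object],
    reference_labels: dict[str, object],
    level: float = 0.95,
) -> DuplicateAgreementReport:
    """Duplicate-core agreement report with exact binomial intervals.

    ``core_calls`` maps patient -> per-core calls, ``consensus_calls`` maps
    patient -> consensus call, ``reference_labels`` maps patient ->
    pathologist label.  Patients with one core are skipped for the
    intra-patient rate; if no patient has >= 2 cores that rate is None.
    """
    multi = {p: calls for p, calls in core_calls.items() if len(calls) >= 2}
    intra = None
    matched = None
    if multi:
        matches = {p: len(set(calls)) == 1 for p, calls in multi.items()}
        intra = clopper_pearson_ci(sum(matches.values()), len(matches), level)
        agree_ref = [
            core_calls[p][0] == reference_labels[p]
            for p, ok in matches.items()
            if ok
        ]
        if agree_ref:
            matched = clopper_pearson_ci(sum(agree_ref), len(agree_ref), level)
    cons = [
        consensus_calls[p] == reference_labels[p] for p in consensus_calls
    ]
    consensus = clopper_pearson_ci(sum(cons), len(cons), level)
    return DuplicateAgreementReport(intra, matched, consensus)
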