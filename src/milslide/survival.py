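"""Survival branch: Cox-head training, hazard ensembling, log-rank tests,
Kaplan-Meier estimation, the 12-year censoring rule, and the constrained
two-cutoff risk-group search.

The hazard model scores each subject in [-1, 1]: a linear Cox head over the
patch feature bank is averaged across the subject's patches and squashed by
tanh, and trained with the negative log partial likelihood (Breslow ties).
The cutoff search scans a fixed lattice of (C_L, C_H) pairs — C_L in
[-0.9, 0.5) and C_H in (C_L, 0.95], both at step 0.05, built by integer
indexing to avoid float drift — keeps pairs satisfying four constraints
(low-vs-intermediate and intermediate-vs-high log-rank p < 0.2; every group
holds 10-50% of subjects), and returns the survivor with the smallest
3-group log-rank p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._opt import Adam
from .features import patch_feature_matrix
from .types import KMCurve, RiskGroupCutoffs, SurvivalRecord


# ---------------------------------------------------------------------------
# partitioning


@dataclass
class TertilePartition:
    """Records split into three EFS-length groups with train/val ids."""

    groups: list[list[SurvivalRecord]]
    train_ids: list[list[str]]
    val_ids: list[list[str]]


def tertile_partition(
    records: Sequence[SurvivalRecord],
    train_fraction: float = 71 / 88,
    seed: int = 0,
) -> TertilePartition:
    """Split records into shortest/intermediate/longest-time thirds.

    Group sizes are near-equal (n=264 -> 88/88/88); within each group a
    seeded shuffle assigns ``train_fraction`` of subjects to training and
    the rest to validation (88 -> 71/17 at the default fraction).
    """
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records")
    order = np.argsort([r.time for r in records], kind="stable")
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    rng = np.random.default_rng(seed)
    groups, train_ids, val_ids = [], [], []
    start = 0
    for size in sizes:
        grp = [records[i] for i in order[start : start + size]]
        start += size
        n_train = int(round(train_fraction * size))
        perm = rng.permutation(size)
        groups.append(grp)
        train_ids.append([grp[i].subject_id for i in sorted(perm[:n_train])])
        val_ids.append([grp[i].subject_id for i in sorted(perm[n_train:])])
    return TertilePartition(groups, train_ids, val_ids)


def stratified_batches(
    group_of: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Batch index lists with (near-)equal counts per group per batch."""
    groups = [np.flatnonzero(group_of == g) for g in np.unique(group_of)]
    for g in groups:
        rng.shuffle(g)
    per = max(1, batch_size // len(groups))
    n_batches = max(1, min(len(g) for g in groups) // per)
    batches = []
    for b in range(n_batches):
        idx = np.concatenate([g[b * per : (b + 1) * per] for g in groups])
        batches.append(idx)
    return batches


# ---------------------------------------------------------------------------
# Cox partial likelihood


def cox_partial_likelihood_loss(
    hazards: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Negative log partial likelihood with Breslow tie handling.

    ``L = -sum_{i: event} [h_i - log sum_{j: t_j >= t_i} exp(h_j)]``;
    defined as 0 when the batch has no events.
    """
    h = np.asarray(hazards, dtype=float)
    if not np.isfinite(h).all():
        raise ValueError("non-finite hazards")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if e.sum() == 0:
        return 0.0
    loss = 0.0
    for i in np.flatnonzero(e == 1):
        risk = h[t >= t[i]]
        loss -= h[i] - np.log(np.exp(risk - risk.max()).sum()) - risk.max()
    return float(loss)


def _cox_grad(h: np.ndarray, t: np.ndarray, e: np.ndarray) -> np.ndarray:
    """d(neg log partial likelihood)/d hazard, Breslow ties."""
    n = len(h)
    grad = -e.astype(float)
    exph = np.exp(h - h.max())
    for i in np.flatnonzero(e == 1):
        in_risk = t >= t[i]
        denom = exph[in_risk].sum()
        grad[in_risk] += exph[in_risk] / denom
    return grad


# ---------------------------------------------------------------------------
# hazard model


@dataclass
class SurvTrainConfig:
    """Training contract for the Cox patch-hazard head."""

    learning_rate: float = 0.05
    iterations: int = 300
    batch_size: int = 0  # 0 = full batch
    seed: int = 0


class CoxPatchHazardModel:
    """Linear Cox head on patch features; subject hazard = tanh(mean score)."""

    def __init__(self, n_features: int):
        self.w = np.zeros(n_features)
        self.b = 0.0
        self.mu = np.zeros(n_features)
        self.sigma = np.ones(n_features)

    def set_normalization(self, X: np.ndarray) -> None:
        self.mu = X.mean(axis=0)
        self.sigma = np.maximum(X.std(axis=0), 1e-6)

    def subject_hazard_from_features(self, mean_features: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(mean_features) - self.mu) / self.sigma
        return np.tanh(Z @ self.w + self.b)

    def predict_hazard(self, patches) -> float:
        """Hazard in [-1, 1] for one subject's patches."""
        feats = patch_feature_matrix(patches)
        return float(self.subject_hazard_from_features(feats.mean(axis=0))[0])


def subject_feature_matrix(patches_per_subject: Sequence) -> np.ndarray:
    """Mean patch-feature vector per subject."""
    return np.asarray(
        [patch_feature_matrix(p).mean(axis=0) for p in patches_per_subject]
    )


def train_survival_model(
    patches_per_subject: Sequence,
    records: Sequence[SurvivalRecord],
    config: SurvTrainConfig | None = None,
    group_of: np.ndarray | None = None,
) -> CoxPatchHazardModel:
    """Fit the Cox patch-hazard head; deterministic given ``config.seed``.

    ``patches_per_subject`` holds each subject's patches (or a precomputed
    subject x feature matrix).  Subjects with zero patches are excluded with
    a warning.  When ``group_of`` (EFS tertile index per subject) and a
    batch size are given, batches are stratified with equal per-group
    counts.
    """
    config = config or SurvTrainConfig()
    if isinstance(patches_per_subject, np.ndarray) and patches_per_subject.ndim == 2:
        X = patches_per_subject.astype(float)
        keep = np.ones(len(X), dtype=bool)
    else:
        keep = np.array([len(p) > 0 for p in patches_per_subject])
        if not keep.all():
            warnings.warn(f"excluding {(~keep).sum()} subject(s) with no patches")
        X = subject_feature_matrix(
            [p for p, k in zip(patches_per_subject, keep) if k]
        )
    recs = [r for r, k in zip(records, keep) if k]
    t = np.array([r.time for r in recs])
    e = np.array([r.event for r in recs])

    model = CoxPatchHazardModel(X.shape[1])
    model.set_normalization(X)
    Z = (X - model.mu) / model.sigma
    opt = Adam([model.w], lr=config.learning_rate)
    b_holder = np.array([model.b])
    opt_b = Adam([b_holder], lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    for it in range(config.iterations):
        if config.batch_size and group_of is not None:
            batches = stratified_batches(group_of[keep], config.batch_size, rng)
        else:
            batches = [np.arange(len(Z))]
        for idx in batches:
            s = Z[idx] @ model.w + b_holder[0]
            h = np.tanh(s)
            dh = _cox_grad(h, t[idx], e[idx])
            ds = dh * (1 - h * h)
            opt.step([Z[idx].T @ ds / len(idx)])
            opt_b.step([np.array([ds.sum() / len(idx)])])
    model.b = float(b_holder[0])
    return model


def ensemble_hazard(fold_predictions: np.ndarray) -> np.ndarray:
    """Mean of available per-fold hazards (NaN = not predicted), clipped.

    ``fold_predictions`` is (n_folds, n_subjects); every subject must be
    predicted by at least one fold.
    """
    preds = np.asarray(fold_predictions, dtype=float)
    if np.isnan(preds).all(axis=0).any():
        raise ValueError("subject with no fold prediction")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(preds, axis=0)
    return np.clip(mean, -1.0, 1.0)


# ---------------------------------------------------------------------------
# log-rank machinery


def log_rank_test(groups: Sequence[Sequence[SurvivalRecord]]) -> tuple[float, float]:
    """Standard k-sample log-rank test; returns (chi-square statistic, p).

    With no events anywhere the statistic is 0 and p = 1 by convention.
    """
    k = len(groups)
    if k < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    times = np.concatenate([[r.time for r in g] for g in groups])
    events = np.concatenate([[r.event for r in g] for g in groups]).astype(int)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    return _log_rank_arrays(times, events, labels, k)


def _log_rank_arrays(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray, k: int
) -> tuple[float, float]:
    if events.sum() == 0:
        return 0.0, 1.0
    event_times = np.unique(times[events == 1])
    n_t = event_times.size
    # per-group at-risk counts and event counts at each distinct event time
    n_jt = np.empty((n_t, k))
    d_jt = np.empty((n_t, k))
    for j in range(k):
        tj = np.sort(times[labels == j])
        n_jt[:, j] = tj.size - np.searchsorted(tj, event_times, side="left")
        ej = times[(labels == j) & (events == 1)]
        d_jt[:, j] = (ej[None, :] == event_times[:, None]).sum(axis=1)
    n_at = n_jt.sum(axis=1)
    d_at = d_jt.sum(axis=1)
    observed = d_jt.sum(axis=0)
    frac = n_jt / n_at[:, None]
    expected = (d_at[:, None] * frac).sum(axis=0)
    # hypergeometric variance-covariance, summed over event times
    scale = np.where(n_at > 1, d_at * (n_at - d_at) / np.maximum(n_at - 1, 1), 0.0)
    var = np.einsum("t,tj,jl->jl", scale, frac, np.eye(k)) - np.einsum(
        "t,tj,tl->jl", scale, frac, frac
    )
    diff = (observed - expected)[: k - 1]
    vsub = var[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(vsub) @ diff)
    stat = max(stat, 0.0)
    return stat, float(chi2.sf(stat, k - 1))


# ---------------------------------------------------------------------------
# cutoff search


#: integer lattice of the search: C = (-90 + 5*i) / 100
_C_MIN_IDX, _C_LOW_MAX_IDX, _C_HIGH_MAX_IDX = 0, 27, 37


def c_low_values() -> np.ndarray:
    """The 28 admissible low-intermediate cutoffs: [-0.9, 0.5) step 0.05."""
    return np.array([(-90 + 5 * i) / 100 for i in range(_C_MIN_IDX, _C_LOW_MAX_IDX + 1)])


def cutoff_grid() -> list[RiskGroupCutoffs]:
    """All 658 (C_L, C_H) lattice pairs with C_H in (C_L, 0.95]."""
    pairs = []
    for i in range(_C_MIN_IDX, _C_LOW_MAX_IDX + 1):
        for j in range(i + 1, _C_HIGH_MAX_IDX + 1):
            pairs.append(RiskGroupCutoffs((-90 + 5 * i) / 100, (-90 + 5 * j) / 100))
    return pairs


@dataclass
class CutoffSearchResult:
    """Best constrained cutoff pair plus the full grid ledger."""

    best: RiskGroupCutoffs | None
    p_multivariate: float | None
    p_low_int: float | None
    p_int_high: float | None
    ledger: pd.DataFrame = field(repr=False, default=None)

    @property
    def found(self) -> bool:
        return self.best is not None


def cutoff_search(
    records: Sequence[SurvivalRecord],
    hazards: Sequence[float] | None = None,
    pairwise_p_max: float = 0.2,
    min_group_fraction: float = 0.1,
    max_group_fraction: float = 0.5,
) -> CutoffSearchResult:
    """Exhaustive constrained search for the three-group hazard cutoffs.

    Every lattice pair is evaluated and logged; pairs violating any of the
    four constraints are rejected with a reason.  Among survivors the pair
    with the smallest 3-group log-rank p wins; exact p ties prefer smaller
    C_L, then smaller C_H (the enumeration order).
    """
    if hazards is None:
        hazards = [r.hazard for r in records]
        if any(h is None for h in hazards):
            raise ValueError("records lack hazards")
    h = np.asarray(hazards, dtype=float)
    if h.min() < -1 or h.max() > 1:
        raise ValueError("hazards outside [-1, 1]")
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 subjects")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=int)

    rows = []
    best_row = None
    for pair in cutoff_grid():
        groups = pair.assign(h)
        counts = np.bincount(groups, minlength=3)
        row = {
            "C_L": pair.c_low,
            "C_H": pair.c_high,
            "n_low": counts[0],
            "n_int": counts[1],
            "n_high": counts[2],
            "p_multi": np.nan,
            "p_LI": np.nan,
            "p_IH": np.nan,
            "pass": False,
            "reason": "",
        }
        if counts.min() < min_group_fraction * n:
            row["reason"] = "group below 10% of samples"
        elif counts.max() > max_group_fraction * n:
            row["reason"] = "group above 50% of samples"
        else:
            low, inter, high = (groups == 0, groups == 1, groups == 2)
            _, p_li = _log_rank_arrays(
                times[low | inter], events[low | inter],
                (groups[low | inter] == 1).astype(int), 2,
            )
            _, p_ih = _log_rank_arrays(
                times[inter | high], events[inter | high],
                (groups[inter | high] == 2).astype(int), 2,
            )
            row["p_LI"], row["p_IH"] = p_li, p_ih
            if p_li >= pairwise_p_max:
                row["reason"] = "low-vs-intermediate p >= 0.2"
            elif p_ih >= pairwise_p_max:
                row["reason"] = "intermediate-vs-high p >= 0.2"
            else:
                _, p_multi = _log_rank_arrays(times, events, groups, 3)
                row["p_multi"] = p_multi
                row["pass"] = True
                if best_row is None or p_multi < best_row["p_multi"]:
                    best_row = row
        rows.append(row)

    ledger = pd.DataFrame(rows)
    if best_row is None:
        return CutoffSearchResult(None, None, None, None, ledger)
    return CutoffSearchResult(
        RiskGroupCutoffs(best_row["C_L"], best_row["C_H"]),
        best_row["p_multi"], best_row["p_LI"], best_row["p_IH"], ledger,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and censoring


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival curve (censored subjects leave the risk set
    without a step)."""
    if len(records) == 0:
        raise ValueError("no records")
    from lifelines import KaplanMeierFitter

    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([(t >= u).sum() for u in times])
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def censor_at(
    records: Sequence[SurvivalRecord], horizon_years: float = 12.0
) -> list[SurvivalRecord]:
    """Administratively censor every record at the follow-up horizon.

    Any record extending beyond the horizon — including an event observed
    after it — becomes censored at the horizon; records at or before the
    horizon are unchanged.
    """
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    out = []
    for r in records:
        if r.time > horizon_years:
            out.append(replace(r, time=horizon_years, event=0))
        else:
            out.append(r)
    return out


def concordance(records: Sequence[SurvivalRecord], hazards=None) -> float:
    """Harrell's C-index of hazard scores (higher hazard, earlier event)."""
    from lifelines.utils import concordance_index

    if hazards is None:
        hazards = [r.hazard for r in records]
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    return float(concordance_index(t, -np.asarray(hazards, dtype=float), e))
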