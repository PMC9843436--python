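"""Configuration-driven orchestration of the end-to-end experiments.

``run_experiment`` reproduces each experiment shape on a synthetic cohort:
generate -> tile -> balance -> train -> predict -> aggregate -> evaluate,
with k-fold layouts, a run manifest proving train/test separation, and all
randomness derived from one seed.  Task presets mirror the study designs:

==========  =====================================================
task        shape
==========  =====================================================
segmentation  train pixel segmenter, stitched whole-slide IoU
fusion        3-class MIL (top-70%) patch model, best-3-of-k
              ensemble, slide-level calls
tp53          binary patch model (plain weighted CE), positive
              ratio threshold 0.2
ras           mean/SD-skip MIL, 66% tumor-area patch filter,
              threshold 0.1
myod1         x5 augmentation recipe for the mutant class,
              geometric-mean threshold from validation ratios
survival      EFS tertiles, k-fold Cox-head ensemble hazards,
              12-year censoring, constrained cutoff search
==========  =====================================================
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evalstats, mil, segment, survival as surv
from .augment import RECIPE_MUTANT, balance_classes
from .synthcohort import (
    CohortSlide,
    SurvivalParams,
    SyntheticCohortSpec,
    cohort_table,
    generate_cohort,
)
from .tiling import extract_patches, otsu_foreground
from .types import CLASS_INDEX

TASKS = ("segmentation", "fusion", "tp53", "ras", "myod1", "survival")

#: positive-ratio thresholds and loss variants per mutation task
TASK_THRESHOLDS = {"tp53": 0.2, "ras": 0.1, "myod1": None}  # None: geometric mean


@dataclass
class ExperimentConfig:
    """One experiment: task, fold layout, cohort size, and seed."""

    task: str
    folds: int = 3
    repeats: int = 1
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_slides: int = 24
    slide_px: int = 160
    patch_size: int = 32
    patches_per_slide: int = 25
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.folds < 1:
            raise ValueError("folds must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FoldAssignment:
    train: list[str]
    val: list[str]
    test: list[str]

    def audit(self) -> None:
        """Raise if any sample leaks between train/val and test."""
        tv = set(self.train) | set(self.val)
        if tv & set(self.test):
            raise AssertionError("train/val and test overlap")
        if set(self.train) & set(self.val):
            raise AssertionError("train and val overlap")


def make_folds(
    sample_ids, labels, config: ExperimentConfig
) -> list[FoldAssignment]:
    """Deterministic class-stratified fold assignments.

    With ``folds > 1`` the test sets are disjoint chunks across folds (each
    ~1/folds of every class); with ``folds == 1`` the test fraction comes
    from ``split_fractions``.  The remaining samples are split train/val at
    the configured ratio.
    """
    sample_ids = list(sample_ids)
    labels = list(labels)
    rng = np.random.default_rng(config.seed)
    by_class: dict = {}
    for sid, lab in zip(sample_ids, labels):
        by_class.setdefault(lab, []).append(sid)
    tr_f, va_f, te_f = config.split_fractions
    folds = []
    shuffled = {
        lab: [ids[i] for i in rng.permutation(len(ids))]
        for lab, ids in sorted(by_class.items(), key=lambda kv: str(kv[0]))
    }
    if config.folds > 1:
        for ids in shuffled.values():
            if len(ids) < config.folds:
                raise ValueError("class with fewer samples than folds")
    for f in range(config.folds):
        train, val, test = [], [], []
        for ids in shuffled.values():
            n = len(ids)
            if config.folds > 1:
                lo = round(f * n / config.folds)
                hi = round((f + 1) * n / config.folds)
            else:
                lo, hi = 0, round(te_f * n)
            test_ids = ids[lo:hi]
            rest = ids[:lo] + ids[hi:]
            n_val = round(va_f / (tr_f + va_f) * len(rest))
            if va_f > 0 and n_val == 0 and len(rest) >= 2:
                n_val = 1
            val.extend(rest[:n_val])
            train.extend(rest[n_val:])
            test.extend(test_ids)
        fold = FoldAssignment(train=train, val=val, test=test)
        fold.audit()
        folds.append(fold)
    return folds


@dataclass
class RunManifest:
    """Record of one experiment run: config digest, folds, metrics."""

    config_digest: str
    task: str
    folds: list[FoldAssignment]
    metrics: dict
    artifacts: dict = field(default_factory=dict)

    def audit(self) -> None:
        for fold in self.folds:
            fold.audit()

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_digest": self.config_digest,
                "task": self.task,
                "folds": [asdict(f) for f in self.folds],
                "metrics": self.metrics,
                "artifacts": self.artifacts,
            },
            indent=2,
            default=float,
        )


# ---------------------------------------------------------------------------
# cohort + patch assembly per task


def _cohort_for_task(config: ExperimentConfig) -> list[CohortSlide]:
    if config.task == "segmentation":
        balance = {"FP_like": 0.5, "FN_like": 0.5}
        prevalence = 0.0
    elif config.task == "fusion":
        balance = {"FP_like": 0.34, "FN_like": 0.33, "normal": 0.33}
        prevalence = 0.0
    elif config.task == "survival":
        balance = {"FN_like": 1.0}
        prevalence = 1.0
    else:  # mutation tasks
        balance = {"FN_like": 1.0}
        prevalence = 0.5
    spec = SyntheticCohortSpec(
        n_slides=config.n_slides,
        class_balance=balance,
        mutant_prevalence=prevalence,
        mutant_fraction_distribution=(
            ("uniform", 0.05, 0.8) if config.task == "survival" else ("uniform", 0.3, 0.7)
        ),
        survival=SurvivalParams(
            baseline_rate=0.2,
            log_hazard_coefficient=3.0 if config.task == "survival" else 0.0,
            censoring_rate=0.05,
        ),
        seed=config.seed,
        slide_px=config.slide_px,
    )
    return generate_cohort(spec)


def _slide_patches(
    cs: CohortSlide, config: ExperimentConfig, min_tumor: float = 0.0, seed: int = 0
):
    mask = otsu_foreground(cs.slide)
    return extract_patches(
        cs.slide,
        mask,
        size_px=config.patch_size,
        n_patches=config.patches_per_slide,
        min_tissue_fraction=0.5,
        min_tumor_fraction=min_tumor,
        labelmap=cs.labels if min_tumor > 0 else None,
        seed=seed,
    )


def _metric_mean(per_fold: list[dict]) -> dict:
    out = {}
    for key in per_fold[0]:
        vals = [f[key] for f in per_fold if f[key] is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


# ---------------------------------------------------------------------------
# task runners


def _run_segmentation(cohort, folds, config) -> dict:
    from .types import SEG_CLASS_ORDER

    by_id = {c.slide.slide_id: c for c in cohort}
    per_fold = []
    for fi, fold in enumerate(folds):
        def patch_set(ids):
            pixels, labels = [], []
            for sid in ids:
                cs = by_id[sid]
                for p in _slide_patches(cs, config, seed=config.seed + 17 * fi):
                    r, c = p.top_left
                    pixels.append(p.pixels)
                    labels.append(
                        np.minimum(
                            cs.labels[r : r + p.size_px, c : c + p.size_px],
                            len(SEG_CLASS_ORDER) - 1,
                        )
                    )
            return pixels, labels

        tr_px, tr_lab = patch_set(fold.train)
        va_px, va_lab = patch_set(fold.val)
        seg_cfg = segment.SegTrainConfig(
            patch_size=config.patch_size, epochs=config.epochs,
            seed=config.seed + fi,
        )
        model, _ = segment.train_segmenter(tr_px, tr_lab, va_px, va_lab, seg_cfg)
        mean_ious, weighted_ious, accs = [], [], []
        for sid in fold.test:
            cs = by_id[sid]
            pred = segment.predict_slide(
                model, cs.slide, patch_size=config.patch_size,
                stride=config.patch_size // 2,
            )
            truth = np.minimum(cs.labels, len(SEG_CLASS_ORDER) - 1)
            _, mean_iou, weighted_iou = segment.iou_scores(pred.labels, truth)
            mean_ious.append(mean_iou)
            weighted_ious.append(weighted_iou)
            accs.append(float((pred.labels == truth).mean()))
        per_fold.append(
            {
                "mean_iou": float(np.mean(mean_ious)),
                "weighted_iou": float(np.mean(weighted_ious)),
                "pixel_accuracy": float(np.mean(accs)),
            }
        )
    return _metric_mean(per_fold)


def _run_fusion(cohort, folds, config) -> dict:
    by_id = {c.slide.slide_id: c for c in cohort}
    class_of = {c.slide.slide_id: c.class_name for c in cohort}
    names = ("FP_like", "FN_like", "normal")
    models, metrics_val, per_fold = [], [], []
    for fi, fold in enumerate(folds):
        def assemble(ids, seed):
            per_class = {n: [] for n in names}
            for sid in ids:
                cs = by_id[sid]
                for p in _slide_patches(cs, config, seed=seed):
                    per_class[cs.class_name].append(p.pixels)
            return per_class

        per_class = assemble(fold.train, config.seed + 31 * fi)
        balanced = balance_classes(per_class, seed=config.seed + fi)
        X, y = [], []
        for ci, name in enumerate(names):
            X.extend(balanced[name])
            y.extend([ci] * len(balanced[name]))
        val_pc = assemble(fold.val, config.seed + 31 * fi + 1)
        Xv, yv = [], []
        for ci, name in enumerate(names):
            Xv.extend(val_pc[name])
            yv.extend([ci] * len(val_pc[name]))
        cfg = mil.ClassifierTrainConfig(
            mil=mil.MILLossConfig(variant="topk", keep_fraction=0.7, batch_size=144),
            epochs=config.epochs, seed=config.seed + fi,
        )
        model, _ = mil.train_patch_classifier(X, np.array(y), Xv, np.array(yv), cfg)
        probs_v = model.predict_proba(Xv)
        bal_acc = float(
            np.mean([
                (np.argmax(probs_v[np.array(yv) == c], axis=1) == c).mean()
                for c in np.unique(yv)
            ])
        )
        models.append(model)
        metrics_val.append(bal_acc)

    k_sel = max(1, min(3, len(models)))
    ensemble = mil.ensemble_select_and_average(models, metrics_val, k_sel)
    # evaluate slide-level calls on the union of fold test sets
    truths, calls, fp_scores = [], [], []
    for fold in folds:
        for sid in fold.test:
            cs = by_id[sid]
            patches = _slide_patches(cs, config, seed=config.seed + 7)
            if not patches:
                continue
            probs = ensemble.predict_proba([p.pixels for p in patches])
            mean_probs = probs.mean(axis=0)
            truths.append(names.index(class_of[sid]))
            calls.append(int(np.argmax(np.bincount(np.argmax(probs, axis=1),
                                                   minlength=3))))
            fp_scores.append(float(mean_probs[0]))
    cm, micro, macro = evalstats.confusion_and_f1(truths, calls, names)
    auc = (
        evalstats.roc_auc(fp_scores, [t == 0 for t in truths])
        if len(set(t == 0 for t in truths)) == 2
        else None
    )
    return {
        "slide_auc_fp": auc,
        "slide_accuracy": float(np.mean(np.array(truths) == np.array(calls))),
        "micro_f1": micro,
        "macro_f1": macro,
        "mcc": evalstats.mcc(cm),
    }


def _run_mutation(cohort, folds, config) -> dict:
    task = config.task
    min_tumor = 0.66 if task == "ras" else 0.0
    variant = mil.MILLossConfig(variant="meansd") if task == "ras" else (
        mil.MILLossConfig(variant="topk", keep_fraction=1.0)
    )
    by_id = {c.slide.slide_id: c for c in cohort}
    per_fold = []
    for fi, fold in enumerate(folds):
        def slide_sets(ids, seed):
            out = {}
            for sid in ids:
                cs = by_id[sid]
                out[sid] = _slide_patches(cs, config, min_tumor=min_tumor, seed=seed)
            return out

        train_p = slide_sets(fold.train, config.seed + 11 * fi)
        val_p = slide_sets(fold.val, config.seed + 11 * fi + 1)
        test_p = slide_sets(fold.test, config.seed + 11 * fi + 2)

        per_class = {"wild": [], "mutant": []}
        for sid, patches in train_p.items():
            key = "mutant" if by_id[sid].mutant else "wild"
            per_class[key].extend(p.pixels for p in patches)
        if not per_class["wild"] or not per_class["mutant"]:
            warnings.warn(f"fold {fi}: a class has no training slides; skipped")
            continue
        recipes = {"mutant": RECIPE_MUTANT} if task == "myod1" else None
        balanced = balance_classes(per_class, per_class_recipe=recipes,
                                   seed=config.seed + fi)
        X = balanced["wild"] + balanced["mutant"]
        y = np.array([0] * len(balanced["wild"]) + [1] * len(balanced["mutant"]))
        Xv, yv = [], []
        for sid, patches in val_p.items():
            Xv.extend(p.pixels for p in patches)
            yv.extend([by_id[sid].mutant] * len(patches))
        cfg = mil.ClassifierTrainConfig(
            mil=variant, epochs=config.epochs, seed=config.seed + fi
        )
        model, _ = mil.train_patch_classifier(X, y, Xv, np.array(yv), cfg)

        def ratios_of(slide_sets_):
            ids, ratios, labels = [], [], []
            for sid, patches in slide_sets_.items():
                if not patches:
                    continue
                probs = model.predict_proba([p.pixels for p in patches])
                ids.append(sid)
                ratios.append(mil.positive_ratio(probs, 1, sid).positive_ratio)
                labels.append(by_id[sid].mutant)
            return ids, np.array(ratios), np.array(labels)

        threshold = TASK_THRESHOLDS[task]
        if threshold is None:  # geometric-mean threshold from validation ratios
            _, vr, vl = ratios_of(val_p)
            try:
                threshold = mil.threshold_by_geometric_mean(vr, vl)
            except ValueError:
                threshold = 0.5
        _, ratios, labels = ratios_of(test_p)
        if np.unique(labels).size < 2:
            warnings.warn(f"fold {fi}: single-class test set; skipped")
            continue
        calls = mil.classify_by_ratio(ratios, threshold)
        cm, micro, _ = evalstats.confusion_and_f1(
            labels.astype(int), calls.astype(int), ("wild", "mutant")
        )
        counts = np.zeros((2, 2), dtype=int)
        for t, c in zip(labels.astype(int), calls.astype(int)):
            counts[t, c] += 1
        sens, spec = evalstats.sensitivity_specificity(counts, positive_class=1)
        per_fold.append(
            {
                "threshold": float(threshold),
                "sensitivity": sens,
                "specificity": spec,
                "slide_auc": evalstats.roc_auc(ratios, labels),
                "accuracy": micro,
            }
        )
    if not per_fold:
        raise RuntimeError("no evaluable folds")
    return _metric_mean(per_fold)


def _run_survival(cohort, folds, config) -> dict:
    records = [c.record for c in cohort]
    records = surv.censor_at(records, horizon_years=12.0)
    ids = [r.subject_id for r in records]
    rec_of = dict(zip(ids, records))
    by_id = {c.slide.slide_id: c for c in cohort}
    part = surv.tertile_partition(records, seed=config.seed)
    group_of = {}
    for gi, grp in enumerate(part.groups):
        for r in grp:
            group_of[r.subject_id] = gi

    patch_feats = {}
    for sid in ids:
        patches = _slide_patches(by_id[sid], config, seed=config.seed + 3)
        if patches:
            patch_feats[sid] = [p.pixels for p in patches]
    fold_preds = np.full((len(folds) * config.repeats, len(ids)), np.nan)
    row = 0
    for rep in range(config.repeats):
        for fi, fold in enumerate(folds):
            train_ids = [s for s in fold.train + fold.val if s in patch_feats]
            test_ids = [s for s in fold.test if s in patch_feats]
            model = surv.train_survival_model(
                [patch_feats[s] for s in train_ids],
                [rec_of[s] for s in train_ids],
                surv.SurvTrainConfig(seed=config.seed + 97 * rep + fi,
                                     iterations=150),
                group_of=np.array([group_of[s] for s in train_ids]),
            )
            for s in test_ids:
                fold_preds[row, ids.index(s)] = model.predict_hazard(
                    patch_feats[s]
                )
            row += 1
    covered = ~np.isnan(fold_preds).all(axis=0)
    hazards = surv.ensemble_hazard(fold_preds[:, covered])
    eval_records = [r for r, c in zip(records, covered) if c]
    cindex = surv.concordance(eval_records, hazards)
    result = surv.cutoff_search(eval_records, hazards)
    out = {
        "concordance": cindex,
        "cutoff_found": float(result.found),
        "c_low": result.best.c_low if result.found else None,
        "c_high": result.best.c_high if result.found else None,
        "p_multivariate": result.p_multivariate,
    }
    return out


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> RunManifest:
    """Execute one experiment end to end on a synthetic cohort.

    Deterministic given ``config.seed``; writes the manifest, cohort table,
    and metrics under ``out_dir`` when given.
    """
    cohort = _cohort_for_task(config)
    ids = [c.slide.slide_id for c in cohort]
    strat = [c.class_name if config.task in ("segmentation", "fusion")
             else c.mutant for c in cohort]
    folds = make_folds(ids, strat, config)
    runner = {
        "segmentation": _run_segmentation,
        "fusion": _run_fusion,
        "tp53": _run_mutation,
        "ras": _run_mutation,
        "myod1": _run_mutation,
        "survival": _run_survival,
    }[config.task]
    try:
        metrics = runner(cohort, folds, config)
    except Exception as err:  # abort with stage name and digest
        raise RuntimeError(
            f"stage {config.task!r} failed (config {config.digest()}): {err}"
        ) from err
    manifest = RunManifest(
        config_digest=config.digest(), task=config.task, folds=folds,
        metrics=metrics,
    )
    manifest.audit()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort_table(cohort).to_csv(out_dir / "cohort.csv", index=False)
        (out_dir / "manifest.json").write_text(manifest.to_json())
        manifest.artifacts = {
            "cohort": str(out_dir / "cohort.csv"),
            "manifest": str(out_dir / "manifest.json"),
        }
    return manifest
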