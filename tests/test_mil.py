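"""MIL losses, classifier recovery, and slide/core/patient aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milslide import mil
from milslide.mil import (
    ClassifierTrainConfig,
    MILLossConfig,
    classify_by_ratio,
    ensemble_select_and_average,
    mil_meansd_skip_loss,
    mil_topk_loss,
    patient_consensus_geomean,
    positive_ratio,
    threshold_by_geometric_mean,
    tma_core_predict,
    train_patch_classifier,
)
from milslide.types import PatchPrediction


def plain_ce(probs, labels):
    return float(np.mean(-np.log(probs[np.arange(len(labels)), labels])))


class TestTopkLoss:
    def test_identical_scores_equals_plain_ce(self):
        probs = np.full((10, 2), 0.5)
        labels = np.array([0] * 5 + [1] * 5)
        assert mil_topk_loss(probs, labels) == pytest.approx(plain_ce(probs, labels))

    def test_keep_fraction_one_is_unweighted_ce_per_class_mean(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), 30)
        labels = np.array([0] * 10 + [1] * 10 + [2] * 10)
        cfg = MILLossConfig(variant="topk", keep_fraction=1.0)
        # equal class counts: per-class mean of CE == plain mean CE
        assert mil_topk_loss(probs, labels, cfg) == pytest.approx(
            plain_ce(probs, labels)
        )

    def test_exactly_ceil_of_fraction_contributes(self):
        # 10 samples of one class, keep 0.7 -> exactly 7 in the gradient mask
        probs = np.stack([np.linspace(0.1, 0.9, 10), 1 - np.linspace(0.1, 0.9, 10)], 1)
        labels = np.zeros(10, dtype=int)
        w = mil._mil_weights(probs, labels, MILLossConfig("topk", 0.7))
        assert (w > 0).sum() == 7
        # the kept samples are those with the highest true-class score
        assert set(np.flatnonzero(w > 0)) == set(range(3, 10))

    def test_keep_count_never_zero(self):
        probs = np.array([[0.9, 0.1]])
        w = mil._mil_weights(probs, np.array([0]), MILLossConfig("topk", 0.01))
        assert (w > 0).sum() == 1


class TestMeanSdLoss:
    def test_equal_scores_nothing_skipped(self):
        probs = np.full((6, 2), 0.5)
        labels = np.array([0, 1] * 3)
        assert mil_meansd_skip_loss(probs, labels) == pytest.approx(
            plain_ce(probs, labels)
        )

    def test_low_scoring_sample_skipped(self):
        # scores {0.9,0.9,0.9,0.1}: mean 0.7, sd ~0.346 -> cutoff ~0.354
        probs = np.array([[0.9, 0.1]] * 3 + [[0.1, 0.9]])
        labels = np.zeros(4, dtype=int)
        w = mil._mil_weights(probs, labels, MILLossConfig("meansd"))
        assert w[3] == 0 and (w[:3] > 0).all()

    def test_huge_sd_multiplier_keeps_everything(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(2), 20)
        labels = rng.integers(0, 2, 20)
        cfg = MILLossConfig(variant="meansd", sd_multiplier=1e9)
        assert mil_meansd_skip_loss(probs, labels, cfg) == pytest.approx(
            plain_ce(probs, labels)
        )

    def test_all_skipped_falls_back_to_full_batch(self):
        # negative multiplier puts the cutoff above every score
        probs = np.array([[0.5, 0.5], [0.6, 0.4]])
        labels = np.array([0, 0])
        cfg = MILLossConfig(variant="meansd", sd_multiplier=-10.0)
        with pytest.warns(UserWarning, match="full batch"):
            loss = mil_meansd_skip_loss(probs, labels, cfg)
        assert loss == pytest.approx(plain_ce(probs, labels))


@pytest.fixture(scope="module")
def data(three_class_patches):
    names, train, val, test = three_class_patches
    X, y = [], []
    for i, c in enumerate(names):
        X += train[c]
        y += [i] * len(train[c])
    Xv, yv = [], []
    for i, c in enumerate(names):
        Xv += val[c]
        yv += [i] * len(val[c])
    return names, X, np.array(y), Xv, np.array(yv), test


class TestTrainClassifier:

    def test_high_margin_accuracy(self, data):
        names, X, y, Xv, yv, test = data
        model, _ = train_patch_classifier(X, y, Xv, yv)
        accs = []
        for i, c in enumerate(names):
            pred = np.argmax(model.predict_proba(test[c]), axis=1)
            accs.append((pred == i).mean())
        assert np.mean(accs) >= 0.9

    def test_same_seed_identical_predictions(self, data):
        _, X, y, Xv, yv, test = data
        cfg = ClassifierTrainConfig(epochs=10, seed=5)
        m1, _ = train_patch_classifier(X, y, Xv, yv, cfg)
        m2, _ = train_patch_classifier(X, y, Xv, yv, cfg)
        sample = test["FP_like"][:10]
        assert np.array_equal(m1.predict_proba(sample), m2.predict_proba(sample))

    def test_label_permutation_gives_chance_accuracy(self, data):
        # with train and held-out labels both permuted, the held-out labels
        # are independent of the features, so accuracy concentrates at 1/3
        _, X, y, Xv, yv, _ = data
        rng = np.random.default_rng(0)
        yv_perm = rng.permutation(yv)
        model, _ = train_patch_classifier(X, rng.permutation(y), Xv, yv_perm)
        pred = np.argmax(model.predict_proba(Xv), axis=1)
        assert (pred == yv_perm).mean() == pytest.approx(1 / 3, abs=0.1)

    def test_single_class_training_rejected(self, data):
        _, X, y, Xv, yv, _ = data
        with pytest.raises(ValueError, match="single class"):
            train_patch_classifier(X, np.zeros_like(y), Xv, yv)

    def test_meansd_variant_also_learns(self, data):
        names, X, y, Xv, yv, test = data
        cfg = ClassifierTrainConfig(mil=MILLossConfig(variant="meansd"), epochs=40)
        model, _ = train_patch_classifier(X, y, Xv, yv, cfg)
        accs = [
            (np.argmax(model.predict_proba(test[c]), axis=1) == i).mean()
            for i, c in enumerate(names)
        ]
        assert np.mean(accs) >= 0.85


class TestEnsemble:
    class Stub:
        def __init__(self, probs):
            self.probs = np.asarray(probs, dtype=float)

        def predict_proba_features(self, X):
            return np.tile(self.probs, (len(np.atleast_2d(X)), 1))

    def test_identical_models_equal_single(self):
        stubs = [self.Stub([0.7, 0.3])] * 5
        ens = ensemble_select_and_average(stubs, [0.9] * 5, 3)
        out = ens.predict_proba_features(np.zeros((2, 4)))
        assert np.allclose(out, [0.7, 0.3])

    def test_select_all_is_plain_average(self):
        stubs = [self.Stub([0.8, 0.2]), self.Stub([0.6, 0.4])]
        ens = ensemble_select_and_average(stubs, [0.5, 0.6], 2)
        assert np.allclose(ens.predict_proba_features(np.zeros((1, 4))), [0.7, 0.3])

    def test_selection_keeps_best_k(self):
        stubs = [self.Stub([1.0, 0.0]), self.Stub([0.0, 1.0]), self.Stub([0.5, 0.5])]
        ens = ensemble_select_and_average(stubs, [0.2, 0.9, 0.8], 2)
        assert np.allclose(ens.predict_proba_features(np.zeros((1, 4))), [0.25, 0.75])

    def test_tie_prefers_lower_index(self):
        stubs = [self.Stub([1.0, 0.0]), self.Stub([0.0, 1.0])]
        ens = ensemble_select_and_average(stubs, [0.5, 0.5], 1)
        assert np.allclose(ens.predict_proba_features(np.zeros((1, 4))), [1.0, 0.0])


class TestPositiveRatio:
    def test_worked_example_300_of_1000(self):
        probs = np.zeros((1000, 2))
        probs[:300, 1] = 1.0
        probs[300:, 0] = 1.0
        sp = positive_ratio(probs, positive_class=1)
        assert sp.positive_ratio == pytest.approx(0.3)
        assert sp.n_positive == 300 and sp.n_patches == 1000

    def test_no_positive_patches(self):
        probs = np.tile([0.9, 0.1], (50, 1))
        assert positive_ratio(probs, 1).positive_ratio == 0.0

    def test_all_positive(self):
        probs = np.tile([0.1, 0.9], (50, 1))
        assert positive_ratio(probs, 1).positive_ratio == 1.0

    def test_zero_patches_rejected(self):
        with pytest.raises(ValueError, match="no patches"):
            positive_ratio(np.zeros((0, 2)), 1)

    def test_invariant_to_ordering_and_duplication(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(2), 40)
        base = positive_ratio(probs, 1).positive_ratio
        shuffled = positive_ratio(probs[rng.permutation(40)], 1).positive_ratio
        doubled = positive_ratio(np.vstack([probs, probs]), 1).positive_ratio
        assert base == shuffled == doubled

    def test_accepts_patch_predictions(self):
        preds = [PatchPrediction(np.array([0.2, 0.8]))] * 3
        assert positive_ratio(preds, 1).positive_ratio == 1.0


class TestClassifyByRatio:
    def test_worked_example_threshold_0p2(self):
        assert classify_by_ratio(0.3, 0.2).item() is True

    def test_zero_ratio_negative(self):
        assert not classify_by_ratio(0.0, 0.043574).item()

    def test_boundary_inclusive(self):
        assert classify_by_ratio(0.2, 0.2).item() is True

    @settings(max_examples=50, deadline=None)
    @given(
        ratio=st.floats(0, 1),
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
    )
    def test_monotone_in_threshold(self, ratio, t1, t2):
        lo, hi = sorted((t1, t2))
        if classify_by_ratio(ratio, hi).item():
            assert classify_by_ratio(ratio, lo).item()


class TestGeometricMeanThreshold:
    def test_separable_case_gap_threshold(self):
        ratios = np.array([0.0, 0.05, 0.1, 0.5, 0.7, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        t = threshold_by_geometric_mean(ratios, labels)
        assert 0.1 < t <= 0.5
        assert mil.gm_score(ratios, labels, t) == pytest.approx(1.0)

    def test_ties_prefer_smallest_threshold(self):
        # candidates 0.15 and 0.35 both score gm = sqrt(0.5); smaller wins
        ratios = np.array([0.1, 0.2, 0.3, 0.4])
        labels = np.array([0, 1, 0, 1])
        assert threshold_by_geometric_mean(ratios, labels) == pytest.approx(0.15)

    def test_null_labels_gm_near_half(self):
        rng = np.random.default_rng(3)
        ratios = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        t = threshold_by_geometric_mean(ratios, labels)
        assert mil.gm_score(ratios, labels, t) == pytest.approx(0.55, abs=0.12)

    def test_matches_exhaustive_search_on_small_set(self):
        rng = np.random.default_rng(4)
        ratios = np.round(rng.uniform(0, 1, 10), 3)
        labels = rng.integers(0, 2, 10)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        t = threshold_by_geometric_mean(ratios, labels)
        # brute force over a dense threshold grid
        grid = np.linspace(0, 1, 2001)
        best = max(mil.gm_score(ratios, labels, g) for g in grid)
        assert mil.gm_score(ratios, labels, t) == pytest.approx(best, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            threshold_by_geometric_mean([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            threshold_by_geometric_mean([0.5, 0.5], [0, 1])


class TestTMAAggregation:
    def test_majority_vote(self):
        probs = np.array([[0.2, 0.8]] * 7 + [[0.8, 0.2]] * 3)
        assert tma_core_predict(probs).class_index == 1

    def test_tie_broken_by_mean_probability(self):
        probs = np.array([[0.55, 0.45]] * 5 + [[0.45, 0.55]] * 5)
        call = tma_core_predict(probs)
        assert call.votes[0] == call.votes[1] == 5
        assert call.class_index == 0  # mean prob favors class 0

    def test_vote_equals_histogram_argmax(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(3), 31)
        call = tma_core_predict(probs)
        hist = np.bincount(np.argmax(probs, axis=1), minlength=3)
        assert np.array_equal(call.votes, hist)
        if (hist == hist.max()).sum() == 1:
            assert call.class_index == int(np.argmax(hist))

    def test_consensus_identical_cores(self):
        cores = np.array([[0.6, 0.4], [0.6, 0.4]])
        call, _ = patient_consensus_geomean(cores)
        assert call == 0

    def test_consensus_geometric_mean_example(self):
        cores = np.array([[0.6, 0.4], [0.2, 0.8]])
        call, geo = patient_consensus_geomean(cores)
        assert geo[0] == pytest.approx(np.sqrt(0.12))
        assert geo[1] == pytest.approx(np.sqrt(0.32))
        assert call == 1

    def test_single_core_patient_uses_core_argmax(self):
        call, _ = patient_consensus_geomean(np.array([[0.3, 0.7]]))
        assert call == 1

    def test_consensus_consistency_when_cores_agree(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            cores = rng.dirichlet(np.ones(3), 4)
            argmaxes = set(np.argmax(cores, axis=1))
            if len(argmaxes) == 1:
                call, _ = patient_consensus_geomean(cores)
                assert call == argmaxes.pop()

    def test_zero_probability_floored_with_warning(self):
        cores = np.array([[0.0, 1.0], [0.5, 0.5]])
        with pytest.warns(UserWarning, match="floored"):
            call, _ = patient_consensus_geomean(cores)
        assert call == 1
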