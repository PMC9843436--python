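"""Cox loss, log-rank oracle agreement, cutoff search, KM, censoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milslide import survival as surv
from milslide.survival import (
    CutoffSearchResult,
    c_low_values,
    censor_at,
    cox_partial_likelihood_loss,
    cutoff_grid,
    cutoff_search,
    ensemble_hazard,
    km_estimate,
    log_rank_test,
    tertile_partition,
)
from milslide.types import RiskGroupCutoffs, SurvivalRecord


def recs(times, events, prefix="s"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestTertilePartition:
    def test_264_cases_split_88_88_88_71_17(self):
        rng = np.random.default_rng(0)
        records = recs(rng.exponential(5, 264) + 0.01, rng.integers(0, 2, 264))
        part = tertile_partition(records, seed=1)
        assert [len(g) for g in part.groups] == [88, 88, 88]
        assert [len(t) for t in part.train_ids] == [71, 71, 71]
        assert [len(v) for v in part.val_ids] == [17, 17, 17]

    def test_nine_records_3_3_3(self):
        records = recs(range(1, 10), [1] * 9)
        part = tertile_partition(records, seed=0)
        assert [len(g) for g in part.groups] == [3, 3, 3]

    def test_groups_are_empirical_tertiles(self):
        rng = np.random.default_rng(2)
        times = rng.uniform(0.1, 20, 30)
        records = recs(times, [1] * 30)
        part = tertile_partition(records, seed=0)
        sorted_times = np.sort(times)
        got = [sorted(r.time for r in g) for g in part.groups]
        assert got[0] == list(sorted_times[:10])
        assert got[1] == list(sorted_times[10:20])
        assert got[2] == list(sorted_times[20:])

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            tertile_partition(recs([1, 2], [1, 1]))


class TestCoxLoss:
    def test_two_subjects_equal_hazards_log2(self):
        # one event first, equal hazards: -[h - log(e^h + e^h)] = log 2
        loss = cox_partial_likelihood_loss([0.3, 0.3], [1.0, 2.0], [1, 0])
        assert loss == pytest.approx(np.log(2))

    def test_no_events_zero(self):
        assert cox_partial_likelihood_loss([0.1, -0.2], [1, 2], [0, 0]) == 0.0

    def test_ties_match_brute_force_breslow(self):
        h = np.array([0.5, -0.3, 0.1, 0.1, -0.7])
        t = np.array([2.0, 2.0, 3.0, 1.0, 3.0])
        e = np.array([1, 1, 0, 1, 1])
        # independent brute force: direct risk-set summation
        expected = 0.0
        for i in range(5):
            if e[i]:
                risk = np.exp(h[t >= t[i]]).sum()
                expected -= h[i] - np.log(risk)
        assert cox_partial_likelihood_loss(h, t, e) == pytest.approx(expected)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        h = rng.normal(0, 0.5, 20)
        t = rng.exponential(5, 20) + 0.01
        e = rng.integers(0, 2, 20)
        a = cox_partial_likelihood_loss(h, t, e)
        b = cox_partial_likelihood_loss(h + 3.7, t, e)
        assert a == pytest.approx(b)

    def test_non_finite_hazards_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            cox_partial_likelihood_loss([np.nan, 0.1], [1, 2], [1, 0])


class TestTrainSurvivalModel:
    def _cohort_features(self, coef, n, seed):
        from milslide.synthcohort import (
            SurvivalParams,
            SyntheticCohortSpec,
            generate_cohort,
        )
        from milslide import tiling

        spec = SyntheticCohortSpec(
            n_slides=n,
            class_balance={"FN_like": 1.0},
            mutant_prevalence=1.0,
            mutant_fraction_distribution=("uniform", 0.05, 0.8),
            survival=SurvivalParams(log_hazard_coefficient=coef),
            seed=seed,
        )
        cohort = generate_cohort(spec)
        feats, records = [], []
        for c in cohort:
            mask = tiling.otsu_foreground(c.slide)
            ps = tiling.extract_patches(
                c.slide, mask, 32, n_patches=20, min_tissue_fraction=0.5, seed=seed
            )
            feats.append([p.pixels for p in ps])
            records.append(c.record)
        return feats, records

    def _heldout_cindex(self, coef, seed=0, n=120):
        feats, records = self._cohort_features(coef, n, seed)
        idx = np.random.default_rng(seed).permutation(n)
        tr, te = idx[: n // 2], idx[n // 2 :]
        model = surv.train_survival_model(
            [feats[i] for i in tr],
            [records[i] for i in tr],
            surv.SurvTrainConfig(seed=seed, iterations=150),
        )
        hazards = [model.predict_hazard(feats[i]) for i in te]
        return surv.concordance([records[i] for i in te], hazards)

    def test_planted_effect_recovered(self):
        assert self._heldout_cindex(coef=1.5) >= 0.7

    def test_null_coefficient_chance_concordance(self):
        assert self._heldout_cindex(coef=0.0) == pytest.approx(0.5, abs=0.1)

    def test_same_seed_identical_hazards(self):
        feats, records = self._cohort_features(1.5, 20, seed=3)
        cfg = surv.SurvTrainConfig(seed=3, iterations=50)
        m1 = surv.train_survival_model(feats, records, cfg)
        m2 = surv.train_survival_model(feats, records, cfg)
        h1 = [m1.predict_hazard(f) for f in feats]
        h2 = [m2.predict_hazard(f) for f in feats]
        assert h1 == h2

    def test_hazards_bounded(self):
        feats, records = self._cohort_features(3.0, 20, seed=4)
        model = surv.train_survival_model(
            feats, records, surv.SurvTrainConfig(seed=4, iterations=100)
        )
        for f in feats:
            assert -1.0 <= model.predict_hazard(f) <= 1.0

    def test_empty_subject_excluded_with_warning(self):
        feats, records = self._cohort_features(1.5, 10, seed=5)
        feats[3] = []
        with pytest.warns(UserWarning, match="no patches"):
            surv.train_survival_model(
                feats, records, surv.SurvTrainConfig(seed=5, iterations=10)
            )


class TestEnsembleHazard:
    def test_identical_predictions(self):
        preds = np.full((20, 5), 0.4)
        assert np.allclose(ensemble_hazard(preds), 0.4)

    def test_symmetric_predictions_cancel(self):
        preds = np.array([[-1.0], [1.0]])
        assert ensemble_hazard(preds) == pytest.approx(0.0)

    def test_matches_oracle_mean(self):
        rng = np.random.default_rng(0)
        preds = rng.uniform(-1, 1, (20, 7))
        assert np.allclose(ensemble_hazard(preds), preds.mean(axis=0))

    def test_nan_rows_ignored(self):
        preds = np.array([[0.2, np.nan], [0.4, 0.6]])
        assert np.allclose(ensemble_hazard(preds), [0.3, 0.6])

    def test_uncovered_subject_rejected(self):
        with pytest.raises(ValueError, match="no fold prediction"):
            ensemble_hazard(np.array([[0.1, np.nan], [0.2, np.nan]]))


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = recs([1, 2, 3, 4], [1, 0, 1, 1])
        stat, p = log_rank_test([g, recs([1, 2, 3, 4], [1, 0, 1, 1], "t")])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_group_fixture(self):
        # groups A: (1,3,5,7+), B: (2,4+,6,8); hand risk-set table gives
        # O_A = 3, E_A = 2.261905, Var = 1.217120 -> chi2 = 0.447601
        a = recs([1, 3, 5, 7], [1, 1, 1, 0], "a")
        b = recs([2, 4, 6, 8], [1, 0, 1, 1], "b")
        stat, p = log_rank_test([a, b])
        assert stat == pytest.approx(0.4476013, abs=1e-6)
        assert p == pytest.approx(0.5034763, abs=1e-6)

    def test_agrees_with_lifelines_on_random_fixture(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(1)
        times = rng.exponential(5, 60) + 0.01
        events = rng.integers(0, 2, 60)
        labels = rng.integers(0, 3, 60)
        groups = [
            recs(times[labels == g], events[labels == g], f"g{g}") for g in range(3)
        ]
        stat, p = log_rank_test(groups)
        ref = multivariate_logrank_test(times, labels, events)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_three_identical_groups_zero(self):
        g = recs([1, 2, 3, 5], [1, 1, 0, 1])
        stat, _ = log_rank_test([g, g, g])
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_no_events_anywhere(self):
        stat, p = log_rank_test([recs([1, 2], [0, 0]), recs([3, 4], [0, 0], "t")])
        assert stat == 0.0 and p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank_test([recs([1], [1]), []])


def planted_three_group(seed, n=120, centers=(-0.5, 0.0, 0.5), noise=0.1):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 3, size=n)
    hazards = np.clip(np.array(centers)[g] + rng.normal(0, noise, n), -1, 1)
    rates = np.array([0.05, 0.2, 0.8])[g]
    t_event = rng.exponential(1 / rates)
    t_cens = np.minimum(rng.exponential(1 / 0.05, n), 20.0)
    times = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    events = (t_event <= t_cens).astype(int)
    return recs(times, events), hazards


class TestCutoffSearch:
    def test_grid_has_28_c_low_values_and_658_pairs(self):
        assert len(c_low_values()) == 28
        assert len(cutoff_grid()) == 658
        # exhaustive verification of the lattice bounds
        for pair in cutoff_grid():
            assert -0.9 <= pair.c_low < 0.5
            assert pair.c_low < pair.c_high <= 0.95

    def test_planted_groups_recovered(self):
        records, hazards = planted_three_group(0)
        result = cutoff_search(records, hazards)
        assert result.found
        # recovered cutoffs bracket the planted gaps (-0.25 and 0.25)
        assert -0.5 < result.best.c_low < 0.0
        assert 0.0 < result.best.c_high < 0.5
        assert result.p_multivariate < 0.01
        assert result.p_low_int < 0.2 and result.p_int_high < 0.2

    def test_recovery_across_seeds(self):
        hits = sum(
            cutoff_search(*planted_three_group(seed)).p_multivariate is not None
            and cutoff_search(*planted_three_group(seed)).p_multivariate < 0.01
            for seed in range(10)
        )
        assert hits >= 8

    def test_constraint_forcing_returns_empty(self):
        # hazards concentrated so one group always exceeds 50% of samples
        rng = np.random.default_rng(5)
        records = recs(rng.exponential(5, 40) + 0.01, rng.integers(0, 2, 40))
        hazards = np.full(40, 0.975)  # above every C_H
        result = cutoff_search(records, hazards)
        assert not result.found
        assert (~result.ledger["pass"]).all()
        assert (result.ledger["reason"] == "group below 10% of samples").any()

    def test_ledger_covers_full_grid(self):
        records, hazards = planted_three_group(1)
        result = cutoff_search(records, hazards)
        assert len(result.ledger) == 658
        assert set(result.ledger.columns) >= {
            "C_L", "C_H", "n_low", "n_int", "n_high", "p_multi", "p_LI",
            "p_IH", "pass", "reason",
        }

    def test_invariant_to_subject_ordering(self):
        records, hazards = planted_three_group(2)
        result1 = cutoff_search(records, hazards)
        perm = np.random.default_rng(0).permutation(len(records))
        result2 = cutoff_search([records[i] for i in perm], hazards[perm])
        assert result1.best.c_low == result2.best.c_low
        assert result1.best.c_high == result2.best.c_high
        assert result1.p_multivariate == pytest.approx(result2.p_multivariate)

    def test_group_assignment_monotone_in_hazard(self):
        pair = RiskGroupCutoffs(-0.1, 0.4)
        h = np.sort(np.random.default_rng(1).uniform(-1, 1, 100))
        groups = pair.assign(h)
        assert (np.diff(groups) >= 0).all()


class TestKM:
    def test_no_censoring_empirical_survivor(self):
        curve = km_estimate(recs([1, 2, 3, 4], [1, 1, 1, 1]))
        idx = np.searchsorted(curve.times, [1, 2, 3, 4])
        assert np.allclose(curve.survival[idx], [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_survival_one(self):
        curve = km_estimate(recs([1, 2, 3], [0, 0, 0]))
        assert (curve.survival == 1.0).all()

    def test_hand_computed_product_limit_table(self):
        # times 1,2+,3,4+,5,6 events 1,0,1,0,1,1:
        # S(1)=5/6, S(3)=5/6*3/4=0.625, S(5)=0.3125, S(6)=0
        curve = km_estimate(recs([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1]))
        lookup = dict(zip(curve.times, curve.survival))
        assert lookup[1.0] == pytest.approx(5 / 6)
        assert lookup[3.0] == pytest.approx(0.625)
        assert lookup[5.0] == pytest.approx(0.3125)
        assert lookup[6.0] == pytest.approx(0.0)

    def test_survival_non_increasing_from_one(self):
        rng = np.random.default_rng(3)
        curve = km_estimate(
            recs(rng.exponential(5, 50) + 0.01, rng.integers(0, 2, 50))
        )
        assert curve.survival[0] <= 1.0 + 1e-12
        assert (np.diff(curve.survival) <= 1e-12).all()


class TestCensorAt:
    def test_event_beyond_horizon_censored(self):
        # death at day 4835 (~13.25 yr) with no earlier event -> 12 yr, censored
        (out,) = censor_at([SurvivalRecord("s", 4835 / 365.25, 1)], 12.0)
        assert out.time == 12.0 and out.event == 0

    def test_event_within_horizon_unchanged(self):
        (out,) = censor_at([SurvivalRecord("s", 5.0, 1)], 12.0)
        assert out.time == 5.0 and out.event == 1

    def test_censored_within_horizon_unchanged(self):
        (out,) = censor_at([SurvivalRecord("s", 10.0, 0)], 12.0)
        assert out.time == 10.0 and out.event == 0

    @settings(max_examples=50, deadline=None)
    @given(
        time=st.floats(0.01, 30),
        event=st.integers(0, 1),
        horizon=st.floats(1, 15),
    )
    def test_never_beyond_horizon_and_idempotent(self, time, event, horizon):
        (once,) = censor_at([SurvivalRecord("s", time, event)], horizon)
        (twice,) = censor_at([once], horizon)
        assert once.time <= horizon or once.time == time
        assert (once.time, once.event) == (twice.time, twice.event)
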