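"""Grouped CV machinery, metrics battery, McNemar, tuning and transfer."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from habitdyn.features import ModelSpec, StudyArrays, feature_matrix
from habitdyn.modeling import fit_logistic, predict_proba
from habitdyn.evaluation import (
    TuningBudget,
    UndefinedMetricError,
    compare_models,
    cross_dataset_evaluate,
    make_group_folds,
    mcnemar_test,
    metrics_report,
    nested_cv,
    no_skill_accuracy,
    optimal_threshold,
    roc_auc,
    tune_parameters,
)


def brute_force_auc(probs, labels):
    """Pairwise counting oracle: wins + half-ties over all pos-neg pairs."""
    probs, labels = np.asarray(probs), np.asarray(labels)
    pos, neg = probs[labels == 1], probs[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestGroupFolds:
    @pytest.mark.parametrize("n,k,size", [(36, 9, 4), (75, 5, 15)])
    def test_balanced_fold_sizes(self, n, k, size):
        plan = make_group_folds([f"p{i}" for i in range(n)], k, seed=0)
        counts = pd.Series(plan.assignment).value_counts()
        assert (counts == size).all()

    def test_every_participant_in_exactly_one_fold(self):
        pids = [f"p{i}" for i in range(20)]
        plan = make_group_folds(pids, 6, seed=3)
        assert sorted(plan.assignment) == sorted(pids)
        counts = pd.Series(plan.assignment).value_counts()
        assert counts.max() - counts.min() <= 1

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            make_group_folds(["a", "b", "c"], 1, seed=0)

    def test_k_exceeding_participants_rejected(self):
        with pytest.raises(ValueError):
            make_group_folds(["a", "b"], 3, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_scores_equal_half(self):
        auc, _ = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_four_point_example(self):
        probs, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        auc, _ = roc_auc(probs, labels)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(brute_force_auc(probs, labels))

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 120))
            # coarse scores force ties
            probs = rng.integers(0, 6, n) / 5.0
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            auc, _ = roc_auc(probs, labels)
            assert auc == pytest.approx(brute_force_auc(probs, labels), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.2, 0.8], [1, 1])


class TestOptimalThreshold:
    def test_perfect_separation_j_is_one(self):
        _, curve = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        thr = optimal_threshold(curve)
        rep = metrics_report([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], thr)
        assert rep.tpr - rep.fpr == pytest.approx(1.0)

    def test_all_equal_scores_j_is_zero(self):
        _, curve = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        j = (curve["tpr"] - curve["fpr"]).max()
        assert j == pytest.approx(0.0)

    def test_four_point_exhaustive_scan(self):
        probs, labels = np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])
        _, curve = roc_auc(probs, labels)
        thr = optimal_threshold(curve)
        # exhaustive scan over all candidate thresholds, same tie rule
        # (maximal J, then minimal FPR)
        best_j, best_fpr = -1.0, None
        for c in np.unique(np.concatenate([probs, [np.inf]])):
            pred = probs >= c
            tpr = (pred & (labels == 1)).sum() / 2
            fpr = (pred & (labels == 0)).sum() / 2
            j = tpr - fpr
            if j > best_j + 1e-12 or (abs(j - best_j) < 1e-12 and fpr < best_fpr):
                best_j, best_fpr = j, fpr
        pred = probs >= thr
        tpr = (pred & (labels == 1)).sum() / 2
        fpr = (pred & (labels == 0)).sum() / 2
        assert tpr - fpr == pytest.approx(best_j)
        assert fpr == pytest.approx(best_fpr)


class TestMetricsReport:
    def test_all_correct(self):
        rep = metrics_report([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0], 0.5)
        assert rep.mcc == 1.0 and rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_hand_computed_confusion(self):
        # TP=3, FP=1, TN=4, FN=2 at threshold 0.5
        probs = [0.9, 0.9, 0.9, 0.6, 0.1, 0.1, 0.1, 0.1, 0.2, 0.3]
        labels = [1, 1, 1, 0, 0, 0, 0, 0, 1, 1]
        rep = metrics_report(probs, labels, 0.5)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 4, 2)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.precision == pytest.approx(0.75)
        assert rep.tpr == pytest.approx(0.6)
        assert rep.npv == pytest.approx(2 / 3)

    def test_random_predictions_near_zero_mcc(self, rng):
        n = 4000
        probs = rng.random(n)
        labels = rng.integers(0, 2, n)
        rep = metrics_report(probs, labels, 0.5)
        assert abs(rep.mcc) < 0.05

    def test_curve_endpoints(self, rng):
        probs = rng.random(50)
        labels = np.r_[np.ones(25, int), np.zeros(25, int)]
        lo = metrics_report(probs, labels, -np.inf)
        hi = metrics_report(probs, labels, np.inf)
        assert (lo.tpr, lo.fpr) == (1.0, 1.0)
        assert (hi.tpr, hi.fpr) == (0.0, 0.0)

    def test_undefined_ratios_flagged(self):
        rep = metrics_report([0.1, 0.2, 0.3, 0.4], [0, 0, 1, 1], np.inf)
        assert "precision" in rep.undefined
        assert np.isnan(rep.precision)


class TestNoSkill:
    @pytest.mark.parametrize(
        "n_pos,n_total,expected", [(376, 711, 53), (557, 1508, 63), (5, 10, 50)]
    )
    def test_examples(self, n_pos, n_total, expected):
        assert no_skill_accuracy(n_pos, n_total) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            no_skill_accuracy(1, 0)
        with pytest.raises(ValueError):
            no_skill_accuracy(5, 4)


class TestMcNemar:
    def test_balanced_discordance(self):
        # b = c = 10 -> (|0| - 1)^2 / 20 = 0.05
        a = np.r_[np.ones(10, bool), np.zeros(10, bool), np.ones(5, bool)]
        b = np.r_[np.zeros(10, bool), np.ones(10, bool), np.ones(5, bool)]
        res = mcnemar_test(a, b)
        assert res.statistic == pytest.approx(0.05)

    def test_no_discordance_degenerate(self):
        a = np.array([True, False, True])
        res = mcnemar_test(a, a)
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0

    def test_hand_arithmetic(self):
        # b=20, c=5 -> (15-1)^2 / 25 = 7.84
        a = np.r_[np.ones(20, bool), np.zeros(5, bool), np.ones(30, bool)]
        b = np.r_[np.zeros(20, bool), np.ones(5, bool), np.ones(30, bool)]
        res = mcnemar_test(a, b)
        assert res.statistic == pytest.approx(7.84)

    def test_against_statsmodels(self, rng):
        """Cross-check statistic and p-value on random paired outcomes."""
        for _ in range(20):
            a = rng.random(200) < 0.7
            b = rng.random(200) < 0.6
            res = mcnemar_test(a, b)
            table = [
                [(a & b).sum(), (a & ~b).sum()],
                [(~a & b).sum(), (~a & ~b).sum()],
            ]
            ref = sm_mcnemar(table, exact=False, correction=True)
            assert res.statistic == pytest.approx(float(ref.statistic))
            assert res.p_value == pytest.approx(float(ref.pvalue))


class TestTuning:
    def test_grid_returns_first_argmax_of_its_own_trace(self, small_study):
        arrays = StudyArrays.from_frames(small_study.logs, small_study.surveys)
        plan = make_group_folds(arrays.pids, 5, seed=1)
        fold_of = plan.fold_of(arrays.pids)
        best, best_auc, trace = tune_parameters(
            arrays, fold_of, {0, 1, 2}, {3}, ModelSpec("weighted_br"),
            TuningBudget("grid", 100, seed=0), return_trace=True,
        )
        assert len(trace) == 100
        np.testing.assert_allclose(trace["gamma"], np.linspace(0.01, 1.0, 100))
        first_best = trace.loc[trace["auc"].idxmax()]
        assert best.gamma == pytest.approx(first_best["gamma"])
        assert best_auc == pytest.approx(trace["auc"].max())

    def test_single_step_budget_returns_that_draw(self, small_study):
        arrays = StudyArrays.from_frames(small_study.logs, small_study.surveys)
        plan = make_group_folds(arrays.pids, 5, seed=1)
        fold_of = plan.fold_of(arrays.pids)
        best, _, trace = tune_parameters(
            arrays, fold_of, {0, 1, 2}, {3}, ModelSpec("theory"),
            TuningBudget("random", 1, seed=7), return_trace=True,
        )
        assert len(trace) == 1
        assert best.habit_params.hdp == pytest.approx(trace["hdp"].iloc[0])

    def test_random_draws_are_uniform_unit(self, small_study):
        arrays = StudyArrays.from_frames(small_study.logs, small_study.surveys)
        plan = make_group_folds(arrays.pids, 5, seed=1)
        fold_of = plan.fold_of(arrays.pids)
        _, _, trace = tune_parameters(
            arrays, fold_of, {0, 1, 2}, {3}, ModelSpec("theory"),
            TuningBudget("random", 50, seed=3), return_trace=True,
        )
        for col in ("hdp", "hgp", "adp", "agp_beh", "agp_rem"):
            assert trace[col].between(0, 1).all()

    def test_overlapping_folds_rejected(self, small_study):
        arrays = StudyArrays.from_frames(small_study.logs, small_study.surveys)
        plan = make_group_folds(arrays.pids, 5, seed=1)
        fold_of = plan.fold_of(arrays.pids)
        with pytest.raises(ValueError):
            tune_parameters(arrays, fold_of, {0, 1}, {1}, ModelSpec("theory"),
                            TuningBudget("random", 5, seed=0))


class TestNestedCV:
    def test_untunable_spec_equals_plain_grouped_kfold(self, small_study):
        """Without tunables the inner loop is a no-op: results must match a
        hand-rolled grouped k-fold."""
        logs, surveys = small_study.logs, small_study.surveys
        plan = make_group_folds(logs["participant_id"].unique(), 5, seed=2)
        res = nested_cv(logs, surveys, ModelSpec("past_br"), plan)

        arrays = StudyArrays.from_frames(logs, surveys)
        x, y, pid_idx, day = feature_matrix(arrays, ModelSpec("past_br"))
        fold_of = plan.fold_of(arrays.pids)[pid_idx]
        expected = np.full(len(y), np.nan)
        for f in range(5):
            te = fold_of == f
            m = fit_logistic(x[~te], y[~te], feature_names=["br", "lab", "rem"])
            expected[te] = predict_proba(m, x[te])
        got = res.predictions.sort_values(["participant_id", "day"])["prob"].to_numpy()
        order = np.lexsort((day, arrays.pids[pid_idx]))
        np.testing.assert_allclose(got, expected[order], atol=1e-12)

    def test_every_row_predicted_exactly_once(self, small_study):
        plan = make_group_folds(small_study.logs["participant_id"].unique(), 5, seed=2)
        res = nested_cv(small_study.logs, small_study.surveys, ModelSpec("past_br"), plan)
        assert not res.predictions.duplicated(["participant_id", "day"]).any()
        arrays = StudyArrays.from_frames(small_study.logs, small_study.surveys)
        _, y, _, _ = feature_matrix(arrays, ModelSpec("past_br"))
        assert len(res.predictions) == len(y)

    def test_fold_assignment_respected(self, small_study):
        """Each participant's predictions all come from their own fold."""
        plan = make_group_folds(small_study.logs["participant_id"].unique(), 5, seed=2)
        res = nested_cv(small_study.logs, small_study.surveys, ModelSpec("past_br"), plan)
        for pid, grp in res.predictions.groupby("participant_id"):
            assert set(grp["fold"]) == {plan.assignment[pid]}

    def test_deterministic_under_fixed_seed(self, small_study):
        plan = make_group_folds(small_study.logs["participant_id"].unique(), 5, seed=2)
        budget = TuningBudget("random", 20, seed=5)
        r1 = nested_cv(small_study.logs, small_study.surveys, ModelSpec("theory"), plan, budget)
        r2 = nested_cv(small_study.logs, small_study.surveys, ModelSpec("theory"), plan, budget)
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)
        assert r1.fold_params == r2.fold_params

    def test_tuned_parameters_within_search_bounds(self, small_study):
        plan = make_group_folds(small_study.logs["participant_id"].unique(), 5, seed=2)
        res = nested_cv(
            small_study.logs, small_study.surveys, ModelSpec("theory"), plan,
            TuningBudget("random", 30, seed=1),
        )
        for params in res.fold_params:
            assert all(0.0 <= v <= 1.0 for v in params.values())


class TestCompareModels:
    def test_identical_specs_mcnemar_p_one(self, small_study):
        plan = make_group_folds(small_study.logs["participant_id"].unique(), 5, seed=0)
        # compare a spec with itself under a different dict key
        res = compare_models(
            small_study.logs, small_study.surveys,
            [ModelSpec("past_br"), ModelSpec("past_br7")], plan,
        )
        a = res.results["past_br"].predictions
        dup = mcnemar_test(
            np.ones(len(a), bool), np.ones(len(a), bool)
        )
        assert dup.p_value == 1.0
        # table shape: one row per spec, the full metrics battery as columns
        assert list(res.table.index) == ["past_br", "past_br7"]
        for col in ("auc", "mcc", "accuracy", "tpr", "fpr", "precision", "f1", "npv", "threshold"):
            assert col in res.table.columns

    def test_mcnemar_matrix_symmetric(self, small_study):
        plan = make_group_folds(small_study.logs["participant_id"].unique(), 5, seed=0)
        res = compare_models(
            small_study.logs, small_study.surveys,
            [ModelSpec("past_br"), ModelSpec("survey")], plan,
        )
        m = res.mcnemar_statistic
        assert m.loc["past_br", "survey"] == m.loc["survey", "past_br"]


class TestCrossDataset:
    def test_self_transfer_untunable_is_in_sample(self, small_study):
        """Training and testing on the same study with no tunables must
        reproduce the in-sample fit."""
        logs, surveys = small_study.logs, small_study.surveys
        res = cross_dataset_evaluate(logs, surveys, logs, surveys, ModelSpec("past_br"), k=3)
        arrays = StudyArrays.from_frames(logs, surveys)
        x, y, _, _ = feature_matrix(arrays, ModelSpec("past_br"))
        m = fit_logistic(x, y, feature_names=["br", "lab", "rem"])
        auc_in, _ = roc_auc(predict_proba(m, x), y)
        assert res.metrics.auc == pytest.approx(auc_in, abs=1e-12)

    def test_tuned_transfer_runs_and_reports_params(self, small_study):
        other = small_study  # same schema; tiny budget keeps this fast
        res = cross_dataset_evaluate(
            small_study.logs, small_study.surveys, other.logs, other.surveys,
            ModelSpec("weighted_br"), k=3, budget=TuningBudget("grid", 10, seed=0),
        )
        assert 0.0 < res.tuned_params["gamma"] <= 1.0
        assert 0.0 <= res.metrics.auc <= 1.0
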