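"""Fold plans, SVM wrapper, feature ranking, greedy selection, consensus and
the nested cross-validation driver."""

import math

import numpy as np
import pytest

from midecode.classify import (
    ClassifierParams,
    EvalResult,
    consensus_select,
    evaluate_feature_set,
    greedy_select,
    make_fold_plan,
    nested_classify,
    rank_features,
    train_linear_svm,
)
from midecode.spectral import FeatureTable

from conftest import separable_features


def trial_structured_labels(n_trials_a=25, n_trials_b=25):
    cond = np.array(["A"] * n_trials_a * 6 + ["B"] * n_trials_b * 6)
    trial = np.repeat(np.arange(n_trials_a + n_trials_b), 6)
    return cond, trial


class TestFoldPlan:
    def test_balanced_partition_of_25_trials(self):
        cond, trial = trial_structured_labels()
        plan = make_fold_plan(cond, trial, k=3, seed=0)
        sizes = sorted(len(f) for f in plan.folds)
        # per condition {9,8,8} trials -> 54/48/48 segments per member
        per_cond = [
            sorted((cond[f] == c).sum() for f in plan.folds) for c in ("A", "B")
        ]
        assert per_cond == [[48, 48, 54], [48, 48, 54]]
        assert sizes == [96, 96, 108]

    def test_partition_covers_every_segment_once(self):
        cond, trial = trial_structured_labels(10, 10)
        plan = make_fold_plan(cond, trial, k=5, seed=1)
        allidx = np.sort(np.concatenate(plan.folds))
        assert np.array_equal(allidx, np.arange(cond.size))

    def test_subsegments_stay_with_their_trial(self):
        cond, trial = trial_structured_labels()
        plan = make_fold_plan(cond, trial, k=5, seed=2)
        plan.assert_no_leakage()
        for f in plan.folds:
            for t in set(trial[f].tolist()):
                assert (trial[f] == t).sum() == 6

    def test_too_few_trials_rejected(self):
        cond, trial = trial_structured_labels(2, 5)
        with pytest.raises(ValueError):
            make_fold_plan(cond, trial, k=3, seed=0)

    def test_fuzzed_plans_never_leak_trials(self):
        """Grouped-fold audit across 10,000 random geometries."""
        rng = np.random.default_rng(99)
        for _ in range(10_000):
            na, nb = rng.integers(5, 26, size=2)
            k = int(rng.integers(2, 6))
            cond, trial = trial_structured_labels(int(na), int(nb))
            plan = make_fold_plan(cond, trial, k=k, seed=int(rng.integers(2**31)))
            plan.assert_no_leakage()
            assert sum(len(f) for f in plan.folds) == cond.size


class TestLinearSVM:
    def test_separable_clouds_zero_training_error(self):
        X, y = separable_features(shift=5.0)[:2]
        model = train_linear_svm(X, y)
        assert (model.predict(X) == y).all()

    def test_symmetric_classes_have_zero_bias(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((50, 2)) + [3.0, 0.0]
        X = np.vstack([a, -a])
        y = np.array(["p"] * 50 + ["q"] * 50)
        model = train_linear_svm(X, y, standardize=False)
        assert abs(model.named_steps["svm"].intercept_[0]) < 1e-6

    def test_label_flip_negates_decision_values(self):
        X, y = separable_features(shift=1.0, seed=3)[:2]
        d1 = train_linear_svm(X, y).decision_function(X)
        flipped = np.where(y == "A", "B", "A")
        d2 = train_linear_svm(X, flipped).decision_function(X)
        # up to the solver's numerical tolerance
        assert np.allclose(d1, -d2, atol=5e-2)
        confident = np.abs(d1) > 0.1
        assert np.all(np.sign(d1[confident]) == -np.sign(d2[confident]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.zeros((10, 2)), np.array(["A"] * 10))


class TestRankFeatures:
    def test_planted_shift_ranks_first(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 100))
            y = np.array(["A"] * 20 + ["B"] * 20)
            X[y == "A", 17] += 3.0
            hits += rank_features(X, y)[0] == 17
        assert hits >= 198

    def test_null_pvalues_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 1000))
        y = np.array(["A"] * 30 + ["B"] * 30)
        # recompute p-values the way the ranking does, then KS-test them
        from scipy.stats import ttest_ind

        p = ttest_ind(X[y == "A"], X[y == "B"], axis=0).pvalue
        assert kstest(p, "uniform").pvalue > 0.01
        # and the ranking must order by those p-values
        order = rank_features(X, y)
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_constant_feature_ranked_last(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 5))
        X[:, 2] = 7.0
        y = np.array(["A"] * 15 + ["B"] * 15)
        assert rank_features(X, y)[-1] == 2


class TestEvaluateFeatureSet:
    def test_perfectly_separating_feature(self):
        X, y, trial = separable_features(shift=10.0)
        plan = make_fold_plan(y, trial, k=5, seed=0, layer="inner")
        res = evaluate_feature_set(X, y, [0], plan, pos_label="A")
        assert res.accuracy == 1.0

    def test_accuracy_accounting_identity(self):
        X, y, trial = separable_features(shift=0.5, seed=5)
        plan = make_fold_plan(y, trial, k=5, seed=1)
        res = evaluate_feature_set(X, y, [0, 1], plan, pos_label="A")
        assert res.correct == res.correct_pos + res.correct_neg
        assert res.n == res.n_pos + res.n_neg
        lhs = res.accuracy * res.n
        rhs = res.sensitivity * res.n_pos + res.specificity * res.n_neg
        assert lhs == pytest.approx(rhs)

    def test_permuted_labels_near_chance(self):
        accs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X, y, trial = separable_features(n_trials=10, shift=2.0, seed=seed)
            perm = rng.permutation(20)  # permute labels at trial level
            y = np.array(["A", "B"])[np.repeat(perm < 10, 6).astype(int)]
            plan = make_fold_plan(y, trial, k=5, seed=seed)
            accs.append(evaluate_feature_set(X, y, [0, 1, 2], plan, "A").accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_empty_feature_set_rejected(self):
        X, y, trial = separable_features()
        plan = make_fold_plan(y, trial, k=5, seed=0)
        with pytest.raises(ValueError):
            evaluate_feature_set(X, y, [], plan, "A")


def make_stub_evaluator(rng, n_pos=90, n_neg=90):
    """Random-outcome evaluator for fuzzing the greedy control flow."""

    def eval_fn(feats):
        cp = int(rng.integers(0, n_pos + 1))
        cn = int(rng.integers(0, n_neg + 1))
        return EvalResult(cp + cn, n_pos + n_neg, cp, n_pos, cn, n_neg)

    return eval_fn


class TestGreedySelect:
    def test_informative_feature_found_among_noise(self):
        """The planted feature is always selected; tie-accepting greedy
        acceptance lets harmless noise features accumulate up to the cap."""
        found = 0
        for seed in range(20):
            X, y, trial = separable_features(
                n_trials=10, n_features=200, shift=0.0, seed=seed
            )
            X[y == "A", 0] += 3.0  # single informative feature
            plan = make_fold_plan(y, trial, k=5, seed=seed)
            ranking = rank_features(X, y)

            def eval_fn(feats):
                return evaluate_feature_set(X, y, feats, plan, "A")

            res = greedy_select(ranking, eval_fn)
            found += 0 in res.selected
            assert len(res.selected) <= 30
            # accepted additions never reduced pooled accuracy
            assert res.final.accuracy >= res.trace[0]["accuracy"]
        assert found == 20

    def test_streak_limit_is_at_least_100(self):
        # 500 features -> 10% = 50 < 100, so the limit is 100 candidates
        rng = np.random.default_rng(0)
        always_reject = lambda feats: EvalResult(0, 180, 0, 90, 0, 90)

        def eval_fn(feats):
            if len(feats) == 1:
                return EvalResult(120, 180, 60, 90, 60, 90)
            return always_reject(feats)

        res = greedy_select(np.arange(500), eval_fn)
        assert len(res.trace) == 1 + 100 + 1  # seed + limit + the breaking one

    def test_cap_and_constraints_fuzz(self):
        """10,000 random-outcome runs never exceed the 30-feature cap and
        never accept an accuracy-decreasing candidate."""
        rng = np.random.default_rng(123)
        for _ in range(10_000):
            n_feat = int(rng.integers(2, 60))
            res = greedy_select(np.arange(n_feat), make_stub_evaluator(rng))
            assert len(res.selected) <= 30
            best = -1
            for step in res.trace:
                acc_count = round(step["accuracy"] * 180)
                if step["accepted"]:
                    assert acc_count >= best
                    best = max(best, acc_count)


class TestConsensusSelect:
    def test_identical_runs_identical_consensus(self):
        runs = [(3, 1, 4)] * 5
        cons, counts, mean_len = consensus_select(runs, {1: 0, 3: 1, 4: 2})
        assert set(cons) == {1, 3, 4}
        assert counts == {1: 5, 3: 5, 4: 5}
        assert mean_len == 3.0

    def test_disjoint_runs_fall_back_and_trim_to_31(self):
        runs = [tuple(range(i * 10, i * 10 + 10)) for i in range(5)]
        rank = {f: f for run in runs for f in run}
        cons, counts, mean_len = consensus_select(runs, rank)
        assert all(c == 1 for c in counts.values())
        assert len(cons) == 31
        assert set(cons) == set(range(31))  # tie-break by rank

    def test_majority_feature_only(self):
        runs = [(1,), (1,), (1,), (1, 2), (1,)]
        cons, _, _ = consensus_select(runs, {1: 0, 2: 1})
        assert cons == (1,)

    def test_requires_five_runs(self):
        with pytest.raises(ValueError):
            consensus_select([(1,)] * 4, {})


def as_table(X):
    import pandas as pd

    idx = pd.DataFrame({"channel": ["ch"] * X.shape[1], "band": range(X.shape[1])})
    return FeatureTable(values=X, index_map=idx, feature_kind="FFT")


class TestNestedClassify:
    def test_pooled_test_count_covers_every_segment(self):
        X, y, trial = separable_features(shift=3.0, seed=7)
        out = nested_classify(as_table(X), y, trial, ("A", "B"), seed=0)
        assert out.n == 300  # 25+25 trials x 6 sub-segments
        assert out.h0 == out.correct_pos + out.correct_neg
        assert 0 <= out.h0 <= out.n
        assert out.accuracy > 0.9

    def test_deterministic_given_seed(self):
        X, y, trial = separable_features(shift=0.8, seed=8)
        a = nested_classify(as_table(X), y, trial, ("A", "B"), seed=5)
        b = nested_classify(as_table(X), y, trial, ("A", "B"), seed=5)
        assert a.h0 == b.h0
        assert a.selections[0].consensus == b.selections[0].consensus

    def test_consensus_caps_respected(self):
        X, y, trial = separable_features(n_features=40, shift=0.3, seed=9)
        out = nested_classify(as_table(X), y, trial, ("A", "B"), seed=1)
        for sel in out.selections:
            assert len(sel.consensus) <= 31
            for run in sel.runs:
                assert len(run) <= 30

    def test_outer_plan_has_no_trial_leakage(self):
        X, y, trial = separable_features(shift=1.0, seed=10)
        out = nested_classify(as_table(X), y, trial, ("A", "B"), seed=2)
        out.outer_plan.assert_no_leakage()

    def test_wrong_condition_set_rejected(self):
        X, y, trial = separable_features()
        with pytest.raises(ValueError):
            nested_classify(as_table(X), y, trial, ("A", "C"), seed=0)
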