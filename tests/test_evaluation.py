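import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sbcskelm.evaluation import (
    ConfusionCounts,
    CVPlan,
    confusion,
    fold_summary,
    friedman_mean_ranks,
    metrics,
    run_cv_experiment,
    stratified_kfold,
    wilcoxon_signed_rank,
)
from sbcskelm.optimizer import OptimizerSettings


class TestConfusion:
    def test_counts(self):
        y_true = ["p", "p", "n", "n", "p"]
        y_pred = ["p", "n", "n", "p", "p"]
        c = confusion(y_true, y_pred, positive_class="p")
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)
        assert c.total == 5

    def test_unknown_positive_class(self):
        with pytest.raises(ValueError):
            confusion(["a", "b"], ["a", "b"], positive_class="z")

    def test_rejects_multiclass(self):
        with pytest.raises(ValueError):
            confusion(["a", "b", "c"], ["a", "b", "c"], positive_class="a")


class TestMetrics:
    def test_known_values(self):
        m = metrics(ConfusionCounts(tp=8, fp=2, fn=1, tn=9))
        assert m.accuracy == pytest.approx(17 / 20)
        assert m.precision == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(8 / 9)
        assert m.f_measure == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))
        num = 8 * 9 - 2 * 1
        den = np.sqrt(10 * 9 * 11 * 10)
        assert m.mcc == pytest.approx(num / den)

    def test_perfect(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert m.accuracy == m.precision == m.sensitivity == m.f_measure == m.mcc == 1.0

    def test_zero_denominator_conventions(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
        assert m.precision == 0.0 and m.sensitivity == 0.0
        assert m.f_measure == 0.0 and m.mcc == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestStratifiedKFold:
    def test_partition_and_stratification(self):
        y = np.repeat(["a", "b"], [40, 20])
        folds = stratified_kfold(y, 10, seed=4)
        assert len(folds) == 10
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(60))
        for _, te in folds:
            labels = y[te]
            assert np.sum(labels == "a") == 4 and np.sum(labels == "b") == 2

    def test_seed_changes_assignment(self):
        y = np.repeat(["a", "b"], 30)
        f1 = stratified_kfold(y, 5, seed=1)
        f2 = stratified_kfold(y, 5, seed=2)
        assert any(not np.array_equal(a[1], b[1]) for a, b in zip(f1, f2))

    def test_too_few_per_class(self):
        with pytest.raises(ValueError):
            stratified_kfold(["a"] * 3 + ["b"] * 50, 5, seed=0)


class TestFoldSummary:
    def test_mean_and_sample_std(self):
        mean, std = fold_summary([1.0, 2.0, 3.0, 4.0])
        assert mean == pytest.approx(2.5)
        assert std == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_single_value(self):
        assert fold_summary([3.0]) == (3.0, 0.0)


class TestWilcoxon:
    def test_exact_matches_enumeration_n10(self, rng):
        """Exact DP p-value equals brute-force enumeration of all 2^10
        sign assignments."""
        a = rng.normal(size=10)
        b = a + rng.normal(0.4, 0.6, size=10)
        res = wilcoxon_signed_rank(a, b)
        d = a - b
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=len(d))
        ]
        ws = np.array(ws)
        lower = np.mean(ws <= w_obs + 1e-9)
        upper = np.mean(ws >= w_obs - 1e-9)
        p_enum = min(1.0, 2 * min(lower, upper))
        assert res.p == pytest.approx(p_enum, abs=1e-12)

    def test_matches_scipy_exact_no_ties(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        res = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_clear_shift_detected(self):
        a = np.arange(10, dtype=float)
        b = a + 1.0
        res = wilcoxon_signed_rank(a, b)
        assert res.p == pytest.approx(2 / 1024)
        assert res.verdict == "+"

    def test_all_zero_differences(self):
        a = np.ones(8)
        res = wilcoxon_signed_rank(a, a)
        assert res.verdict == "=" and res.p == 1.0 and res.n_effective == 0

    def test_large_n_normal_approx_close_to_scipy(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(0.3, 1.0, size=40)
        res = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, correction=True, mode="approx")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_short(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [2.0, 1.0])


class TestFriedman:
    def test_known_ranking(self):
        # alg1 always best, alg3 always worst (lower is better)
        df = pd.DataFrame(
            {"alg1": [1.0, 1.0, 1.0], "alg2": [2.0, 2.0, 2.0], "alg3": [3.0, 3.0, 3.0]}
        )
        res = friedman_mean_ranks(df)
        assert res.mean_ranks["alg1"] == 1.0
        assert res.mean_ranks["alg3"] == 3.0
        assert res.ordering == ["alg1", "alg2", "alg3"]

    def test_ties_average_ranks(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [2.0, 2.0]})
        res = friedman_mean_ranks(df)
        assert res.mean_ranks["a"] == pytest.approx(1.5)
        assert res.mean_ranks["c"] == pytest.approx(3.0)

    def test_statistic_matches_scipy(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        res = friedman_mean_ranks(df)
        stat, p = stats.friedmanchisquare(df["a"], df["b"], df["c"])
        assert res.statistic == pytest.approx(stat)
        assert res.p == pytest.approx(p)

    def test_higher_is_better_flips(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        res = friedman_mean_ranks(df, lower_is_better=False)
        assert res.ordering[0] == "b"

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            friedman_mean_ranks(pd.DataFrame({"a": [1.0, 2.0]}))


class TestRunCVExperiment:
    def test_smoke_and_shapes(self, rng):
        # Small, clearly separable problem with a tiny search budget.
        n = 25
        X = np.vstack([rng.normal(0, 1, (n, 5)), rng.normal(2.5, 1, (n, 5))])
        y = np.repeat(["lo", "hi"], n)
        res = run_cv_experiment(
            X,
            y,
            optimizer_settings=OptimizerSettings(population_size=6, max_evaluations=40),
            plan=CVPlan(k=5, repeats=1, seed=0),
            positive_class="hi",
        )
        assert len(res.per_fold) == 5
        assert set(res.summary.index) == {"avg", "std"}
        assert res.feature_counts.sum() >= 5  # at least one feature per fold
        assert (res.feature_counts <= 5).all()
        assert res.summary.loc["avg", "accuracy"] > 0.7

    def test_reproducible(self, rng):
        n = 15
        X = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(2, 1, (n, 4))])
        y = np.repeat(["lo", "hi"], n)
        kwargs = dict(
            optimizer_settings=OptimizerSettings(population_size=6, max_evaluations=30),
            plan=CVPlan(k=3, repeats=1, seed=9),
            positive_class="hi",
        )
        r1 = run_cv_experiment(X, y, **kwargs)
        r2 = run_cv_experiment(X, y, **kwargs)
        pd.testing.assert_frame_equal(r1.per_fold, r2.per_fold)
        pd.testing.assert_series_equal(r1.feature_counts, r2.feature_counts)
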