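import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnarank.classifiers import ClassifierConfig, train
from srnarank.evaluation import (
    bh_fdr,
    friedman_test,
    permutation_importance,
    posthoc,
    pr_curve,
    precision_at_recall,
    rank_models,
    roc_auc,
    run_matrix,
    sens_spec_curve,
)

from conftest import separable_table

# ---------------------------------------------------------------------------
# Brute-force confusion-matrix oracles


def brute_curves(scores, labels):
    """Per-threshold (recall, precision, sensitivity, specificity) computed
    by explicit confusion matrices at every distinct score."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    P, N = labels.sum(), len(labels) - labels.sum()
    rows = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        tn = int(np.sum(~pred & (labels == 0)))
        rows.append((tp / P, tp / (tp + fp), tp / P, tn / N))
    return rows


def brute_auprc(scores, labels):
    rows = brute_curves(scores, labels)
    area, prev_recall = 0.0, 0.0
    for recall, precision, _, _ in rows:
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


def brute_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_instance(rng, n_max=50):
    n = int(rng.integers(4, n_max))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n - 1))] = 1
    rng.shuffle(labels)
    # coarse grid forces plenty of ties
    scores = rng.choice(np.linspace(0, 1, 7), size=n)
    return scores, labels


class TestPrCurve:
    def test_perfect_ranking(self):
        assert pr_curve([0.9, 0.1], [1, 0]).auprc == 1.0

    def test_alternating_example(self):
        c = pr_curve([0.8, 0.7, 0.6, 0.5], [1, 0, 1, 0])
        assert c.auprc == pytest.approx(5 / 6)

    def test_all_tied_scores_collapse_to_prevalence(self):
        c = pr_curve([0.5] * 6, [1, 0, 0, 1, 0, 0])
        assert len(c.recall) == 1
        assert c.recall[0] == 1.0
        assert c.auprc == pytest.approx(c.prevalence) == pytest.approx(1 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.2, 0.4], [1, 1])

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(0)
        for _ in range(300):
            scores, labels = random_instance(rng)
            c = pr_curve(scores, labels)
            assert c.auprc == pytest.approx(brute_auprc(scores, labels), abs=1e-12)
            assert c.auprc == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )


class TestRocAuc:
    def test_perfect_and_antiperfect(self):
        assert roc_auc([0.9, 0.1], [1, 0]) == 1.0
        assert roc_auc([0.1, 0.9], [1, 0]) == 0.0

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            scores, labels = random_instance(rng, n_max=30)
            assert roc_auc(scores, labels) == pytest.approx(
                brute_auc(scores, labels), abs=1e-12
            )


class TestSensSpec:
    def test_perfect_ranking_reaches_1_1(self):
        df = sens_spec_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ((df["sensitivity"] == 1) & (df["specificity"] == 1)).any()

    def test_all_tied_scores_give_1_0(self):
        df = sens_spec_curve([0.5] * 4, [1, 0, 1, 0])
        assert len(df) == 1
        assert (df.iloc[0]["sensitivity"], df.iloc[0]["specificity"]) == (1.0, 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            scores, labels = random_instance(rng, n_max=30)
            df = sens_spec_curve(scores, labels)
            brute = brute_curves(scores, labels)
            got = list(zip(df["sensitivity"], df["specificity"]))
            exp = [(r[2], r[3]) for r in brute]
            assert got == pytest.approx(exp)


class TestPrecisionAtRecall:
    def test_perfect_curve(self):
        c = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert precision_at_recall(c, 0.1) == 1.0

    def test_all_tied_returns_prevalence(self):
        c = pr_curve([0.5] * 10, [1] * 4 + [0] * 6)
        assert precision_at_recall(c, 0.4) == pytest.approx(0.4)

    def test_matches_threshold_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            scores, labels = random_instance(rng, n_max=25)
            c = pr_curve(scores, labels)
            for r in (0.1, 0.4, 0.9):
                rows = brute_curves(scores, labels)
                exp = next(p for rec, p, _, _ in rows if rec >= r)
                assert precision_at_recall(c, r) == pytest.approx(exp)

    def test_invalid_target_rejected(self):
        c = pr_curve([0.9, 0.1], [1, 0])
        with pytest.raises(ValueError):
            precision_at_recall(c, 0.0)


class TestRankModels:
    def test_both_tie_conventions(self):
        values = pd.DataFrame({"t1": [0.9, 0.9, 0.7]}, index=["a", "b", "c"])
        rm = rank_models(values)
        assert list(rm.competition["t1"]) == [1, 1, 3]
        assert list(rm.average["t1"]) == [1.5, 1.5, 3]

    def test_strictly_decreasing_column(self):
        values = pd.DataFrame({"t1": [0.9, 0.8, 0.7]})
        assert list(rank_models(values).competition["t1"]) == [1, 2, 3]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.random((5, 4)))
        rm = rank_models(values)
        perm = rng.permutation(5)
        rm_p = rank_models(values.iloc[perm].reset_index(drop=True))
        np.testing.assert_array_equal(
            rm.competition.to_numpy()[perm], rm_p.competition.to_numpy()
        )

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            rank_models(pd.DataFrame({"t": [np.nan, 1.0, 0.5]}))


def brute_friedman(R):
    """Independent re-implementation from column sums."""
    k, N = R.shape
    Rj = R.sum(axis=1)
    return 12.0 / (N * k * (k + 1)) * np.sum(Rj**2) - 3.0 * N * (k + 1)


class TestFriedman:
    def test_perfectly_consistent_ranks(self):
        # every dataset ranks the three models identically (1, 2, 3)
        R = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
        res = friedman_test(R)
        assert res.statistic == pytest.approx(10.0)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(10.0, 2)))

    def test_all_models_tied(self):
        R = np.full((3, 4), 2.0)
        assert friedman_test(R).statistic == pytest.approx(0.0)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k, N = int(rng.integers(3, 6)), int(rng.integers(2, 8))
            vals = rng.random((k, N))
            R = np.column_stack(
                [stats.rankdata(-vals[:, j]) for j in range(N)]
            )
            assert friedman_test(R).statistic == pytest.approx(
                brute_friedman(R), abs=1e-12
            )

    def test_matches_scipy_on_tie_free_values(self):
        rng = np.random.default_rng(6)
        vals = rng.random((4, 6))
        R = np.column_stack([stats.rankdata(-vals[:, j]) for j in range(6)])
        ours = friedman_test(R).statistic
        scipy_stat, _ = stats.friedmanchisquare(*[vals[i] for i in range(4)])
        assert ours == pytest.approx(scipy_stat, abs=1e-12)

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            friedman_test(np.array([[1.0, 2.0], [2.0, 1.0]]))  # k=2


class TestPosthoc:
    def _values(self, seed=7, k=5, N=5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.random((k, N)), index=[f"m{i}" for i in range(k)]
        )

    def test_identical_models_not_distinguished(self):
        vals = self._values()
        vals.iloc[1] = vals.iloc[0]  # model m1 duplicates m0
        for method in ("nemenyi", "quade", "conover"):
            res = posthoc(vals, method)
            assert res.pairwise.loc["m0", "m1"] == pytest.approx(1.0)

    def test_nemenyi_critical_difference_matches_quantile(self):
        res = posthoc(self._values(), "nemenyi")
        k, N = 5, 5
        q = stats.studentized_range.ppf(0.95, k, np.inf)
        assert res.extras["critical_difference"] == pytest.approx(
            q / np.sqrt(2) * np.sqrt(k * (k + 1) / (6 * N))
        )

    @pytest.mark.parametrize("method", ["quade", "conover"])
    def test_adjusted_never_below_raw(self, method):
        res = posthoc(self._values(seed=8), method)
        assert (res.adjusted.to_numpy() >= res.pairwise.to_numpy() - 1e-12).all()

    def test_pairwise_matrices_symmetric_with_unit_diagonal(self):
        for method in ("nemenyi", "quade", "conover"):
            res = posthoc(self._values(seed=9), method)
            P = res.pairwise.to_numpy()
            np.testing.assert_allclose(P, P.T)
            np.testing.assert_allclose(np.diag(P), 1.0)

    def test_requires_three_models(self):
        with pytest.raises(ValueError):
            posthoc(self._values(k=2), "nemenyi")


class TestBhFdr:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_sorted_input_gives_monotone_output(self):
        rng = np.random.default_rng(10)
        p = np.sort(rng.random(20))
        adj = bh_fdr(p)
        assert (np.diff(adj) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 30)))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPermutationImportance:
    def test_constant_feature_has_no_importance(self):
        data = separable_table(n=120, seed=12)
        data.features["energy"] = 5.0
        model = train(ClassifierConfig("RF", {"n_trees": 50}), data, seed=0)
        imp = permutation_importance(model, data, n_repeats=10, seed=0)
        assert abs(imp["energy"]) < 0.01

    def test_planted_signal_features_rank_top_two(self):
        data = separable_table(
            n=120, seed=13, informative=("distLeftORF", "distRightORF")
        )
        model = train(ClassifierConfig("RF", {"n_trees": 100}), data, seed=0)
        imp = permutation_importance(model, data, n_repeats=5, seed=0)
        top2 = set(imp.sort_values(ascending=False).index[:2])
        assert top2 == {"distLeftORF", "distRightORF"}

    def test_invariant_to_duplicating_rows(self):
        data = separable_table(n=80, seed=14)
        dup = separable_table(n=80, seed=14)
        dup.features = pd.concat([dup.features] * 2, ignore_index=True)
        dup.labels = np.concatenate([dup.labels] * 2)
        m1 = train(ClassifierConfig("RF", {"n_trees": 80}), data, seed=0)
        m2 = train(ClassifierConfig("RF", {"n_trees": 80}), dup, seed=0)
        i1 = permutation_importance(m1, data, n_repeats=5, seed=0)
        i2 = permutation_importance(m2, dup, n_repeats=5, seed=0)
        # same ordering of the two planted features vs the rest
        assert set(i1.sort_values(ascending=False).index[:2]) == set(
            i2.sort_values(ascending=False).index[:2]
        )

    def test_non_rf_model_rejected(self):
        data = separable_table(n=40, seed=15)
        model = train(ClassifierConfig("LR"), data, seed=0)
        with pytest.raises(ValueError, match="RF"):
            permutation_importance(model, data)


class TestRunMatrix:
    def test_shapes_and_model_count(self):
        train_sets = {
            "A": separable_table(n=40, seed=16),
            "B": separable_table(n=40, seed=17),
        }
        test_sets = {"T": separable_table(n=40, seed=18)}
        fams = [ClassifierConfig("RF", {"n_trees": 10}), ClassifierConfig("LR")]
        runs, summary, ranks = run_matrix(train_sets, test_sets, fams, n_runs=2, seed=0)
        assert len(runs) == 2 * 2 * 2 * 1
        assert ranks.values.shape == (4, 1)  # 2 families x 2 train sets

    def test_shared_seed_gives_zero_sd(self):
        train_sets = {"A": separable_table(n=40, seed=19)}
        test_sets = {"T": separable_table(n=40, seed=20)}
        _, summary, _ = run_matrix(
            train_sets, test_sets, [ClassifierConfig("RF", {"n_trees": 10})],
            n_runs=2, seeds=[7, 7],
        )
        assert (summary["std"] == 0).all()
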