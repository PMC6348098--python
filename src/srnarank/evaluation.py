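"""Performance assessment: PR/ROC curves, winner-gets-all ranks,
Friedman + post-hoc model comparison, FDR correction, and out-of-bag
permutation importance.

AUPRC is the primary metric: with heavily unbalanced test sets (a handful
of bona fide sRNAs against hundreds of random loci) precision-recall
summaries are far more informative than ROC, and precision directly
estimates the fraction of wet-lab validation experiments that would
succeed. The PR curve uses the step-wise (right-continuous) convention:
AUPRC = sum of precision x recall-increment over descending score
thresholds, with tied scores entering together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import TrainedModel, predict_proba, train
from .dataset_builder import LabeledDataset

# ---------------------------------------------------------------------------
# Threshold sweeps


def _sweep(scores, labels):
    """Cumulative TP/FP at each distinct descending score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    P = int(labels.sum())
    N = len(labels) - P
    if P == 0 or N == 0:
        raise ValueError("labels must contain at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where a new (lower) distinct score starts next — threshold points
    last_of_group = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([last_of_group, [len(s) - 1]])
    tp = np.cumsum(y)[idx]
    fp = (idx + 1) - tp
    return tp, fp, P, N, s[idx]


@dataclass
class PRCurve:
    """Precision-recall curve points (descending thresholds) and area."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auprc: float
    prevalence: float

    @property
    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "recall": self.recall,
                "precision": self.precision,
            }
        )


def pr_curve(scores, labels) -> PRCurve:
    """Precision-recall curve with step-wise AUPRC."""
    tp, fp, P, N, thr = _sweep(scores, labels)
    recall = tp / P
    precision = tp / (tp + fp)
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    auprc = float(np.sum(precision * d_recall))
    return PRCurve(
        recall=recall,
        precision=precision,
        thresholds=thr,
        auprc=auprc,
        prevalence=P / (P + N),
    )


def roc_auc(scores, labels) -> float:
    """Mann-Whitney probability that a random positive outscores a random
    negative (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def sens_spec_curve(scores, labels) -> pd.DataFrame:
    """(threshold, sensitivity, specificity) under the same sweep as pr_curve."""
    tp, fp, P, N, thr = _sweep(scores, labels)
    return pd.DataFrame(
        {"threshold": thr, "sensitivity": tp / P, "specificity": (N - fp) / N}
    )


def precision_at_recall(curve: PRCurve, r: float) -> float:
    """Precision at the smallest achieved recall >= r (step-wise convention)."""
    if not (0 < r <= 1):
        raise ValueError("target recall must be in (0, 1]")
    idx = int(np.searchsorted(curve.recall, r, side="left"))
    idx = min(idx, len(curve.recall) - 1)
    return float(curve.precision[idx])


# ---------------------------------------------------------------------------
# Winner-gets-all ranking and rank tests


@dataclass
class RankMatrix:
    """AUPRC values (models x test sets) with two tie conventions of ranks.

    ``competition``: ties share the minimum rank (1 = best) — the
    winner-gets-all reporting convention. ``average``: ties share the mean
    rank — the convention the Friedman statistic is defined on.
    """

    values: pd.DataFrame
    competition: pd.DataFrame
    average: pd.DataFrame


def rank_models(values: pd.DataFrame) -> RankMatrix:
    """Rank models (rows) within each test set (column), descending."""
    vals = values.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("AUPRC matrix contains non-finite entries")
    comp = np.column_stack(
        [stats.rankdata(-vals[:, j], method="min") for j in range(vals.shape[1])]
    )
    avg = np.column_stack(
        [stats.rankdata(-vals[:, j], method="average") for j in range(vals.shape[1])]
    )
    return RankMatrix(
        values=values,
        competition=pd.DataFrame(comp, index=values.index, columns=values.columns),
        average=pd.DataFrame(avg, index=values.index, columns=values.columns),
    )


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    adjusted: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def friedman_test(ranks: pd.DataFrame | np.ndarray) -> TestResult:
    """Friedman chi-square over a k models x N datasets average-rank matrix.

    chi2_F = 12N / (k(k+1)) * (sum_j Rbar_j^2 - k(k+1)^2 / 4), compared to
    a chi-square distribution with k - 1 degrees of freedom.
    """
    R = np.asarray(ranks, dtype=float)
    if R.ndim != 2:
        raise ValueError("rank matrix must be 2-D (models x datasets)")
    k, N = R.shape
    if k < 3 or N < 2:
        raise ValueError("Friedman test needs >= 3 models and >= 2 datasets")
    col_sums = R.sum(axis=0)
    expected = k * (k + 1) / 2
    if not np.allclose(col_sums, expected):
        raise ValueError("each dataset column must contain ranks summing to k(k+1)/2")
    rbar = R.mean(axis=1)
    chi2 = 12.0 * N / (k * (k + 1)) * (np.sum(rbar**2) - k * (k + 1) ** 2 / 4.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return TestResult(method="friedman", statistic=float(chi2), p_value=p)


def _pairwise_frame(stat: np.ndarray, names) -> pd.DataFrame:
    return pd.DataFrame(stat, index=names, columns=names)


def posthoc(values: pd.DataFrame, method: str, alpha: float = 0.05) -> TestResult:
    """Pairwise post-hoc comparisons over a models x test-sets value matrix.

    ``nemenyi``: studentized-range test on mean Friedman ranks, with the
    critical difference CD = q_alpha sqrt(k(k+1)/(6N)) reported in
    ``extras``. ``quade``: Quade's range-weighted rank test with pairwise
    t statistics on (N-1)(k-1) df. ``conover``: Conover's t-type
    comparisons conditioned on the Friedman statistic. Quade and Conover
    p-values are additionally Benjamini-Hochberg adjusted (Nemenyi p's are
    already familywise).
    """
    vals = values.to_numpy(dtype=float)
    k, N = vals.shape
    if k < 3:
        raise ValueError("post-hoc comparisons need >= 3 models")
    names = list(values.index)
    # within-dataset ranks, ties averaged (rank 1 = best AUPRC)
    R = np.column_stack(
        [stats.rankdata(-vals[:, j], method="average") for j in range(N)]
    )

    if method == "nemenyi":
        rbar = R.mean(axis=1)
        se = np.sqrt(k * (k + 1) / (6.0 * N))
        q = np.abs(rbar[:, None] - rbar[None, :]) / se
        p = stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf)
        np.fill_diagonal(p, 1.0)
        cd = float(stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2.0) * se)
        stat = float(np.nanmax(q))
        return TestResult(
            method="nemenyi",
            statistic=stat,
            p_value=float(np.min(p + np.eye(k))),
            pairwise=_pairwise_frame(p, names),
            extras={"critical_difference": cd, "mean_ranks": rbar},
        )

    if method == "quade":
        # ranks of the within-dataset value ranges, weighting informative datasets
        ranges = vals.max(axis=0) - vals.min(axis=0)
        Q = stats.rankdata(ranges, method="average")
        S = Q[None, :] * (R - (k + 1) / 2.0)
        Sj = S.sum(axis=1)
        A = float(np.sum(S**2))
        B = float(np.sum(Sj**2) / N)
        df = (N - 1) * (k - 1)
        if A == B:
            p = np.zeros((k, k))  # perfect agreement between blocks
            np.fill_diagonal(p, 1.0)
            t = np.full((k, k), np.inf)
        else:
            denom = np.sqrt(2.0 * N * (A - B) / df)
            t = np.abs(Sj[:, None] - Sj[None, :]) / denom
            p = 2.0 * stats.t.sf(t, df)
            np.fill_diagonal(p, 1.0)
        raw = _pairwise_frame(p, names)
        return TestResult(
            method="quade",
            statistic=float(np.nanmax(np.where(np.isfinite(t), t, 0.0))),
            p_value=float(p.min() if k > 1 else 1.0),
            pairwise=raw,
            adjusted=_bh_adjust_pairwise(raw),
        )

    if method == "conover":
        Rj = R.sum(axis=1)
        A1 = float(np.sum(R**2))
        C1 = N * k * (k + 1) ** 2 / 4.0
        if A1 == C1:
            raise ValueError("degenerate rank matrix (all ranks identical)")
        T = (k - 1) * float(np.sum((Rj - N * (k + 1) / 2.0) ** 2)) / (A1 - C1)
        df = (N - 1) * (k - 1)
        scale = 2.0 * N * (A1 - C1) / df * (1.0 - T / (N * (k - 1)))
        if scale <= 0:
            p = np.zeros((k, k))
            np.fill_diagonal(p, 1.0)
            t = np.full((k, k), np.inf)
        else:
            denom = np.sqrt(scale)
            t = np.abs(Rj[:, None] - Rj[None, :]) / denom
            p = 2.0 * stats.t.sf(t, df)
            np.fill_diagonal(p, 1.0)
        raw = _pairwise_frame(p, names)
        return TestResult(
            method="conover",
            statistic=float(T),
            p_value=float(p.min()),
            pairwise=raw,
            adjusted=_bh_adjust_pairwise(raw),
        )

    raise ValueError(f"unknown post-hoc method {method!r}")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i}(p_(j) * m / j), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _bh_adjust_pairwise(raw: pd.DataFrame) -> pd.DataFrame:
    k = raw.shape[0]
    iu = np.triu_indices(k, 1)
    flat = raw.to_numpy()[iu]
    adj_flat = bh_fdr(flat)
    adj = np.ones((k, k))
    adj[iu] = adj_flat
    adj[(iu[1], iu[0])] = adj_flat
    return pd.DataFrame(adj, index=raw.index, columns=raw.columns)


# ---------------------------------------------------------------------------
# Out-of-bag permutation importance (mean decrease in accuracy)


def permutation_importance(
    model: TrainedModel,
    data: LabeledDataset,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Per-feature mean decrease in out-of-bag accuracy of a random forest.

    For each tree, accuracy on its out-of-bag samples is compared with the
    accuracy after permuting one feature column among those samples; the
    drop, averaged over trees and repeats, is the importance. Only RF
    models carry the out-of-bag bookkeeping this requires.
    """
    if model.config.family != "RF":
        raise ValueError("permutation importance requires an RF model")
    forest = model.estimator
    X = data.X.to_numpy(dtype=float)
    y = data.y
    n = len(y)
    rng = np.random.default_rng(seed)
    n_features = X.shape[1]
    drops = np.zeros(n_features)
    counts = 0
    for tree, sample_idx in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), np.unique(sample_idx))
        if len(oob) == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        base = np.mean(tree.predict(X_oob) == y_oob)
        for f in range(n_features):
            for _ in range(n_repeats):
                Xp = X_oob.copy()
                Xp[:, f] = Xp[rng.permutation(len(oob)), f]
                drops[f] += base - np.mean(tree.predict(Xp) == y_oob)
        counts += 1
    if counts == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return pd.Series(drops / (counts * n_repeats), index=model.feature_schema)


# ---------------------------------------------------------------------------
# Train x test evaluation matrix


def run_matrix(
    train_sets: dict[str, LabeledDataset],
    test_sets: dict[str, LabeledDataset],
    families,
    n_runs: int = 5,
    seed: int = 0,
    seeds: list[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, RankMatrix]:
    """Train every family on every training set, evaluate on every test set.

    ``n_runs`` independently seeded fits per (family, training set) pair
    quantify model stability (``seeds`` overrides the per-run seeds; with
    identical seeds the per-cell sd is 0). Returns the long per-run AUPRC
    table, a summary (mean/median/sd per model x test set) and the
    winner-gets-all rank matrix built from mean AUPRC.
    """
    from .classifiers import ClassifierConfig

    if seeds is None:
        seeds = [seed + run for run in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("seeds must have length n_runs")
    records = []
    for family in families:
        cfg = ClassifierConfig(family) if isinstance(family, str) else family
        fam_name = cfg.family
        for train_name, train_data in train_sets.items():
            for run in range(n_runs):
                model = train(cfg, train_data, seed=seeds[run])
                for test_name, test_data in test_sets.items():
                    scores = predict_proba(model, test_data.features)
                    auprc = pr_curve(scores, test_data.y).auprc
                    records.append(
                        {
                            "family": fam_name,
                            "train": train_name,
                            "test": test_name,
                            "run": run,
                            "auprc": auprc,
                        }
                    )
    runs = pd.DataFrame(records)
    summary = (
        runs.groupby(["family", "train", "test"])["auprc"]
        .agg(["mean", "median", "std"])
        .reset_index()
    )
    mean_wide = summary.pivot_table(
        index=["family", "train"], columns="test", values="mean"
    )
    mean_wide.index = [f"{f}-{t}" for f, t in mean_wide.index]
    ranks = rank_models(mean_wide)
    return runs, summary, ranks
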