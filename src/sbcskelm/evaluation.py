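"""Classification metrics, repeated stratified k-fold CV and
nonparametric algorithm comparison.

Metrics follow the usual confusion-matrix definitions (accuracy,
precision, sensitivity, F-measure with equal precision/recall weight,
and the Matthews correlation coefficient). Zero-denominator cases take
the standard conventions: precision with TP+FP = 0 is 0, sensitivity
with TP+FN = 0 is 0, F with P+R = 0 is 0, and MCC with any zero factor
is 0.

The Wilcoxon signed-rank test is exact for n <= 25 retained pairs
(distribution of the positive-rank sum computed by dynamic programming
over doubled mid-ranks, which handles ties exactly under the
sign-permutation null) and uses the tie-corrected normal approximation
with continuity correction above that. Zero differences are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .feature_selection import (
    FitnessWeights,
    FSProblem,
    minmax_scale_train_test,
    run_binary_fs,
)
from .kelm import KernelSettings, kelm_predict, kelm_train
from .optimizer import OptimizerSettings

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVPlan",
    "CVResult",
    "confusion",
    "metrics",
    "stratified_kfold",
    "fold_summary",
    "run_cv_experiment",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "FriedmanResult",
    "friedman_mean_ranks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    f_measure: float
    mcc: float


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Count TP/FP/FN/TN for a binary task with a declared positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    if positive_class not in labels:
        raise ValueError(f"positive_class {positive_class!r} not among labels {labels}")
    if labels.shape[0] > 2:
        raise ValueError("confusion counts are defined for binary labels")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five scalar metrics from confusion counts."""
    if c.total <= 0:
        raise ValueError("empty confusion table")
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    acc = (tp + tn) / c.total
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(acc, prec, sens, f, mcc)


def stratified_kfold(labels, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified partition; per-fold class counts are within 1
    of proportionality. Errors if any class has fewer than k samples."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} samples (min is {counts.min()})")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    return list(splitter.split(np.zeros(labels.shape[0]), labels))


def fold_summary(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


@dataclass(frozen=True)
class CVPlan:
    k: int = 10
    repeats: int = 10
    stratified: bool = True
    seed: int = 0


@dataclass
class CVResult:
    """Per-fold metrics, Avg/Std summary and feature-selection counts."""

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    feature_counts: pd.Series


def run_cv_experiment(
    X,
    y,
    *,
    optimizer_settings: OptimizerSettings,
    kernel_settings: KernelSettings | None = None,
    weights: FitnessWeights | None = None,
    plan: CVPlan | None = None,
    positive_class=None,
) -> CVResult:
    """Repeated stratified k-fold wrapper-selection experiment.

    Per fold: run binary feature selection on the training partition,
    train a KELM on the selected (min-max scaled) columns and score the
    held-out fold; feature-selection counts accumulate over all
    k * repeats runs.
    """
    plan = plan or CVPlan()
    kernel_settings = kernel_settings or KernelSettings()
    weights = weights or FitnessWeights()
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    if positive_class is None:
        positive_class = np.unique(y)[0]

    rows = []
    counts = np.zeros(X.shape[1], dtype=int)
    for rep in range(plan.repeats):
        rep_seed = int(np.random.SeedSequence([plan.seed, rep]).generate_state(1)[0] % 2**31)
        folds = stratified_kfold(y, plan.k, rep_seed)
        for fold_idx, (tr, te) in enumerate(folds):
            fold_seed = int(
                np.random.SeedSequence([plan.seed, rep, fold_idx]).generate_state(1)[0]
                % 2**31
            )
            problem = FSProblem(
                X[tr], y[tr], kernel_settings, weights, seed=fold_seed,
                feature_names=feature_names,
            )
            fs_settings = OptimizerSettings(
                **{**optimizer_settings.__dict__, "seed": fold_seed}
            )
            result = run_binary_fs(problem, fs_settings)
            sel = result.mask.indices()
            counts[sel] += 1

            X_tr, X_te = minmax_scale_train_test(X[tr][:, sel], X[te][:, sel])
            model = kelm_train(X_tr, y[tr], kernel_settings)
            pred, _ = kelm_predict(model, X_te)
            rep_metrics = metrics(confusion(y[te], pred, positive_class))
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold_idx,
                    "n_selected": result.mask.selected_count,
                    "accuracy": rep_metrics.accuracy,
                    "sensitivity": rep_metrics.sensitivity,
                    "mcc": rep_metrics.mcc,
                    "f_measure": rep_metrics.f_measure,
                }
            )

    per_fold = pd.DataFrame(rows)
    metric_cols = ["accuracy", "sensitivity", "mcc", "f_measure"]
    summary = pd.DataFrame(
        {col: fold_summary(per_fold[col]) for col in metric_cols},
        index=["avg", "std"],
    )
    feature_counts = pd.Series(counts, index=feature_names, name="times_selected")
    return CVResult(per_fold=per_fold, summary=summary, feature_counts=feature_counts)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # positive-rank sum W+
    p: float
    verdict: str  # '+', '-' or '=' at the declared significance level
    n_effective: int


def _exact_signed_rank_p(doubled_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Exact two-sided p for the positive-rank sum under the sign-flip null.

    Dynamic programming over the distribution of the (doubled, hence
    integer) positive-rank sum across all 2^n sign assignments.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    lower = dist[: w_plus_doubled + 1].sum()
    upper = dist[w_plus_doubled:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(a, b, alpha: float = 0.05) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test with a '+/-/=' verdict.

    The verdict is read for lower-is-better pairs: '+' means ``a`` is
    significantly smaller than ``b`` at level ``alpha``, '-' the
    reverse, '=' no significant difference (or all differences zero).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.shape[0] < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    n = d.shape[0]
    if n == 0:
        return WilcoxonResult(statistic=0.0, p=1.0, verdict="=", n_effective=0)

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        doubled = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p = _exact_signed_rank_p(doubled, w2)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))

    if p >= alpha:
        verdict = "="
    else:
        verdict = "+" if np.median(a - b) < 0 else "-"
    return WilcoxonResult(statistic=w_plus, p=p, verdict=verdict, n_effective=n)


@dataclass
class FriedmanResult:
    mean_ranks: pd.Series  # per algorithm, lower is better
    ordering: list[str]
    statistic: float
    p: float
    per_problem_ranks: pd.DataFrame = field(repr=False, default=None)


def friedman_mean_ranks(results: pd.DataFrame, lower_is_better: bool = True) -> FriedmanResult:
    """Friedman mean ranks of algorithms (columns) across problems (rows).

    Ties take average ranks. Also reports the Friedman chi-square
    statistic and its p-value.
    """
    if isinstance(results, np.ndarray):
        results = pd.DataFrame(
            results, columns=[f"alg{i}" for i in range(results.shape[1])]
        )
    if results.shape[0] < 1 or results.shape[1] < 2:
        raise ValueError("need >= 1 problem and >= 2 algorithms")
    values = results.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite entries in results matrix")
    signed = values if lower_is_better else -values
    ranks = np.apply_along_axis(stats.rankdata, 1, signed)
    per_problem = pd.DataFrame(ranks, index=results.index, columns=results.columns)
    mean_ranks = per_problem.mean(axis=0)
    ordering = list(mean_ranks.sort_values(kind="stable").index)
    try:
        statistic, p = stats.friedmanchisquare(*[values[:, j] for j in range(values.shape[1])])
    except ValueError:  # e.g. identical columns
        statistic, p = 0.0, 1.0
    return FriedmanResult(
        mean_ranks=mean_ranks,
        ordering=ordering,
        statistic=float(statistic),
        p=float(p),
        per_problem_ranks=per_problem,
    )
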