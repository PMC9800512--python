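"""Binary wrapper feature selection (bSBCS-KELM).

The continuous optimizer searches [0, 1]^|D|; each evaluation maps the
position to a 0/1 feature mask through the steep sigmoid transfer
s(x) = 1 / (1 + e^(-2x)) (bit d is 1 iff s(x_d) >= rand_d), then scores
the mask with

    fitness = alpha * error + beta * |R| / |D|

where ``error`` is the classification error of a KELM trained on the
masked columns under an inner stratified holdout, |R| the number of
selected features and |D| the total. With alpha = 0.99, beta = 0.01 the
error term dominates and subset size acts as a small tie-breaker. The
empty mask is assigned the worst fitness 1.0 without training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold, train_test_split

from .kelm import KernelSettings, kelm_predict, kelm_train
from .optimizer import ConvergenceTrace, OptimizerSettings, SearchSpace, run_optimizer

__all__ = [
    "FitnessWeights",
    "FeatureMask",
    "FSProblem",
    "FSResult",
    "transfer_sigmoid",
    "binarize",
    "fs_fitness",
    "run_binary_fs",
    "minmax_scale_train_test",
]


def transfer_sigmoid(x):
    """Steep sigmoid transfer 1 / (1 + e^(-2x)), elementwise."""
    return expit(2.0 * np.asarray(x, dtype=float))


def binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic threshold: bit_d = 1 iff sigmoid(x_d) >= rand_d."""
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    return (transfer_sigmoid(position) >= rng.random(position.shape)).astype(int)


@dataclass(frozen=True)
class FitnessWeights:
    """Error weight alpha and subset-size weight beta (alpha + beta = 1)."""

    alpha: float = 0.99
    beta: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")


@dataclass
class FeatureMask:
    """0/1 inclusion vector over dataset columns."""

    bits: np.ndarray

    @property
    def selected_count(self) -> int:
        return int(np.sum(self.bits))

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def minmax_scale_train_test(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max scale both partitions using training-column statistics only.

    Constant training columns map to zero. Binary 0/1 columns pass
    through unchanged whenever both levels occur in the training split.
    """
    lo = X_train.min(axis=0)
    hi = X_train.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled_train = np.where(hi > lo, (X_train - lo) / span, 0.0)
    scaled_test = np.where(hi > lo, (X_test - lo) / span, 0.0)
    return scaled_train, scaled_test


class FSProblem:
    """A wrapper-selection task: data, classifier settings and fitness plan.

    The inner error estimate for the fitness is either a single
    stratified 80/20 holdout of the supplied (training) data
    (``inner_eval='holdout'``; fastest) or a stratified 5-fold inner
    cross-validation (``inner_eval='cv5'``, the default; every sample
    is scored once, so the error estimate has far finer granularity,
    which small cohorts need for the subset-size penalty to bite).
    Either plan is fixed once per problem seed. Continuous columns are
    min-max scaled on inner-train statistics — the RBF kernel is
    scale-sensitive.
    """

    def __init__(
        self,
        X,
        y,
        kernel_settings: KernelSettings | None = None,
        weights: FitnessWeights | None = None,
        seed: int = 0,
        inner_eval: str = "cv5",
        holdout_fraction: float = 0.2,
        feature_names: list[str] | None = None,
    ):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        classes, counts = np.unique(y, return_counts=True)
        if classes.shape[0] < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        self.n_features = X.shape[1]
        self.feature_names = feature_names or [f"f{i}" for i in range(self.n_features)]
        self.kernel_settings = kernel_settings or KernelSettings()
        self.weights = weights or FitnessWeights()
        self.seed = int(seed)
        if inner_eval not in ("holdout", "cv5"):
            raise ValueError("inner_eval must be 'holdout' or 'cv5'")
        self.inner_eval = inner_eval

        # Pre-split (and pre-scale) once so every fitness call sees the
        # same inner plan; only the mask varies during the search.
        self._splits: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        if inner_eval == "holdout":
            X_tr, X_ho, y_tr, y_ho = train_test_split(
                X, y, test_size=holdout_fraction, stratify=y,
                random_state=self.seed % 2**31,
            )
            X_tr, X_ho = minmax_scale_train_test(X_tr, X_ho)
            self._splits.append((X_tr, y_tr, X_ho, y_ho))
        else:
            if counts.min() < 5:
                raise ValueError("inner 5-fold CV needs >= 5 samples per class")
            skf = StratifiedKFold(n_splits=5, shuffle=True,
                                  random_state=self.seed % 2**31)
            for tr, te in skf.split(X, y):
                X_tr, X_te = minmax_scale_train_test(X[tr], X[te])
                self._splits.append((X_tr, y[tr], X_te, y[te]))


def fs_fitness(mask: np.ndarray, problem: FSProblem) -> tuple[float, float]:
    """Score a mask: returns (fitness, inner error rate).

    The empty mask scores 1.0 without training. A degenerate inner
    split (single-class training partition) contributes error 1.
    """
    mask = np.asarray(mask).astype(bool)
    n_sel = int(mask.sum())
    if n_sel == 0:
        return 1.0, 1.0
    wrong = 0
    total = 0
    for X_tr, y_tr, X_te, y_te in problem._splits:
        try:
            model = kelm_train(X_tr[:, mask], y_tr, problem.kernel_settings)
            pred, _ = kelm_predict(model, X_te[:, mask])
            wrong += int(np.sum(pred != y_te))
        except ValueError:  # degenerate split, e.g. single-class train part
            wrong += len(y_te)
        total += len(y_te)
    error = wrong / total
    w = problem.weights
    return w.alpha * error + w.beta * n_sel / problem.n_features, error


@dataclass
class FSResult:
    """Best mask found, with its fitness, inner error and search trace."""

    mask: FeatureMask
    fitness: float
    inner_error: float
    trace: ConvergenceTrace
    feature_names: list[str] = field(default_factory=list)

    def selected_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.mask.indices()]


def run_binary_fs(problem: FSProblem, settings: OptimizerSettings) -> FSResult:
    """Search [0, 1]^|D| with the chosen variant, scoring binarized masks.

    The all-features mask is evaluated once up front as a baseline, so
    the reported result is never worse than using every feature. The
    reported mask is the one realised at the best evaluation (a fresh
    rand vector is drawn per evaluation, so re-binarizing the best
    position could differ).
    """
    space = SearchSpace.cube(problem.n_features, 0.0, 1.0)
    bin_rng = np.random.default_rng(
        np.random.SeedSequence([problem.seed, settings.seed, 0x5E1EC7])
    )

    record = {"fitness": np.inf, "mask": None, "error": 1.0}

    def note(mask: np.ndarray, fitness: float, error: float) -> None:
        if fitness < record["fitness"]:
            record.update(fitness=fitness, mask=mask.copy(), error=error)

    all_features = np.ones(problem.n_features, dtype=int)
    base_fit, base_err = fs_fitness(all_features, problem)
    note(all_features, base_fit, base_err)

    def objective(position: np.ndarray) -> float:
        mask = binarize(position, bin_rng)
        fitness, error = fs_fitness(mask, problem)
        note(mask, fitness, error)
        return fitness

    _, trace = run_optimizer(objective, space, settings)
    return FSResult(
        mask=FeatureMask(record["mask"]),
        fitness=float(record["fitness"]),
        inner_error=float(record["error"]),
        trace=trace,
        feature_names=problem.feature_names,
    )
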