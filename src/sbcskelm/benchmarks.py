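"""Classic analytic benchmark functions and a comparison harness.

The harness mirrors the shape of a standard metaheuristic comparison
protocol: a factorial grid of (function, algorithm variant, seed) runs,
AVG/STD aggregation over seeds, pairwise Wilcoxon '+/-/=' verdicts
against a reference algorithm, and Friedman mean ranks across
functions. The function set is the textbook analytic suite (sphere,
rosenbrock, rastrigin, ackley, griewank, schwefel-2.26) at configurable
dimension; shifted/rotated competition suites that require external
data files are deliberately not included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .evaluation import friedman_mean_ranks, wilcoxon_signed_rank
from .optimizer import OptimizerSettings, SearchSpace, run_optimizer

__all__ = [
    "BenchmarkFunction",
    "classic_suite",
    "BenchmarkResult",
    "run_benchmark",
    "star_discrepancy",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    dim: int
    space: SearchSpace
    objective: Callable[[np.ndarray], float]
    optimum_position: np.ndarray
    optimum_value: float


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2 * np.pi * x)))


def _ackley(x: np.ndarray) -> float:
    n = x.size
    return float(
        -20.0 * math.exp(-0.2 * math.sqrt(np.sum(x * x) / n))
        - math.exp(np.sum(np.cos(2 * np.pi * x)) / n)
        + 20.0
        + math.e
    )


def _griewank(x: np.ndarray) -> float:
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _schwefel_term(t: float) -> float:
    return -t * math.sin(math.sqrt(abs(t)))


# The schwefel-2.26 minimiser, refined numerically so the registry's
# optimum value is exact to solver precision (the textbook 420.9687 is
# only 4-decimal accurate).
_SCHWEFEL_XSTAR = minimize_scalar(
    _schwefel_term, bounds=(420.0, 422.0), method="bounded",
    options={"xatol": 1e-13},
).x


def _schwefel226(x: np.ndarray) -> float:
    return float(
        -np.sum(x * np.sin(np.sqrt(np.abs(x))))
        - x.size * _schwefel_term(_SCHWEFEL_XSTAR)
    )


_SUITE: dict[str, tuple[Callable, float, float, float]] = {
    # name: (objective, lower, upper, optimum coordinate)
    "sphere": (_sphere, -100.0, 100.0, 0.0),
    "rosenbrock": (_rosenbrock, -30.0, 30.0, 1.0),
    "rastrigin": (_rastrigin, -5.12, 5.12, 0.0),
    "ackley": (_ackley, -32.0, 32.0, 0.0),
    "griewank": (_griewank, -600.0, 600.0, 0.0),
    "schwefel226": (_schwefel226, -500.0, 500.0, float(_SCHWEFEL_XSTAR)),
}


def classic_suite(dim: int = 10, names: Sequence[str] | None = None) -> dict[str, BenchmarkFunction]:
    """Registry of the classic analytic functions at the given dimension."""
    names = list(names) if names is not None else list(_SUITE)
    registry = {}
    for name in names:
        if name not in _SUITE:
            raise KeyError(f"unknown benchmark function {name!r}; known: {list(_SUITE)}")
        obj, lo, hi, xstar = _SUITE[name]
        pos = np.full(dim, xstar)
        registry[name] = BenchmarkFunction(
            name=name,
            dim=dim,
            space=SearchSpace.cube(dim, lo, hi),
            objective=obj,
            optimum_position=pos,
            optimum_value=float(obj(pos)),
        )
    return registry


@dataclass
class BenchmarkResult:
    """Long-form run table plus the derived comparison tables."""

    runs: pd.DataFrame  # columns: function, algorithm, seed, best_fitness
    avg: pd.DataFrame  # functions x algorithms mean final fitness
    std: pd.DataFrame
    wilcoxon: pd.DataFrame  # per (function, algorithm): verdict vs reference
    friedman: "pd.Series"  # mean rank per algorithm (lower is better)
    reference: str


def _cell_seed(root_seed: int, fi: int, ai: int, si: int) -> int:
    seq = np.random.SeedSequence([int(root_seed), fi, ai, si])
    return int(seq.generate_state(1)[0] % 2**31)


def run_benchmark(
    algorithms: Sequence[str],
    functions: dict[str, BenchmarkFunction],
    settings: OptimizerSettings,
    seeds: Sequence[int] | int,
    reference: str | None = None,
) -> BenchmarkResult:
    """Full factorial (function x algorithm x seed) comparison.

    Each cell derives its own seed from (root seed, indices), so any
    cell is reproducible in isolation. ``reference`` (default: the
    first algorithm) anchors the pairwise Wilcoxon verdicts, read as
    '+' when the reference achieves significantly lower final fitness.
    """
    if isinstance(seeds, int):
        seeds = list(range(seeds))
    algorithms = list(algorithms)
    if not algorithms or not functions or not seeds:
        raise ValueError("need at least one algorithm, function and seed")
    reference = reference or algorithms[0]
    if reference not in algorithms:
        raise ValueError("reference must be among the algorithms")

    rows = []
    for fi, (fname, fn) in enumerate(functions.items()):
        for ai, alg in enumerate(algorithms):
            for si, seed in enumerate(seeds):
                cell = OptimizerSettings(
                    **{**settings.__dict__, "variant": alg,
                       "seed": _cell_seed(settings.seed, fi, ai, int(seed))}
                )
                try:
                    best, _ = run_optimizer(fn.objective, fn.space, cell)
                except Exception as exc:  # annotate with cell context
                    raise RuntimeError(
                        f"benchmark cell failed: function={fname} algorithm={alg} seed={seed}"
                    ) from exc
                rows.append(
                    {"function": fname, "algorithm": alg, "seed": seed,
                     "best_fitness": best.fitness}
                )
    runs = pd.DataFrame(rows)
    avg = runs.pivot_table(index="function", columns="algorithm",
                           values="best_fitness", aggfunc="mean")
    std = runs.pivot_table(index="function", columns="algorithm",
                           values="best_fitness", aggfunc=lambda v: np.std(v, ddof=1))
    avg = avg[algorithms].loc[list(functions)]
    std = std[algorithms].loc[list(functions)]

    verdicts = []
    for fname in functions:
        sub = runs[runs["function"] == fname]
        ref_vals = sub[sub["algorithm"] == reference].sort_values("seed")["best_fitness"].to_numpy()
        row = {"function": fname}
        for alg in algorithms:
            if alg == reference:
                row[alg] = "~"
                continue
            other = sub[sub["algorithm"] == alg].sort_values("seed")["best_fitness"].to_numpy()
            if len(seeds) >= 5:
                row[alg] = wilcoxon_signed_rank(ref_vals, other).verdict
            else:  # too few paired runs for the signed-rank test
                row[alg] = "~"
        verdicts.append(row)
    wilcoxon = pd.DataFrame(verdicts).set_index("function")

    friedman = friedman_mean_ranks(avg, lower_is_better=True).mean_ranks
    return BenchmarkResult(
        runs=runs, avg=avg, std=std, wilcoxon=wilcoxon,
        friedman=friedman, reference=reference,
    )


def star_discrepancy(points: np.ndarray) -> float:
    """Brute-box estimate of the star discrepancy of points in [0, 1]^d.

    Scans anchored boxes [0, a) whose corners run over the grid of
    observed coordinate values (plus 1), taking the worst gap between
    the empirical fraction inside the closed/open box and the box
    volume. Exact for modest n and d = 2; an estimate in general.
    """
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    if d != 2:
        raise ValueError("the brute-box scan is implemented for d = 2")
    xs = np.unique(np.append(pts[:, 0], 1.0))
    ys = np.unique(np.append(pts[:, 1], 1.0))
    worst = 0.0
    for a in xs:
        inside_x_closed = pts[:, 0] <= a
        inside_x_open = pts[:, 0] < a
        for b in ys:
            vol = a * b
            closed = np.sum(inside_x_closed & (pts[:, 1] <= b)) / n
            open_ = np.sum(inside_x_open & (pts[:, 1] < b)) / n
            worst = max(worst, closed - vol, vol - open_)
    return float(worst)
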