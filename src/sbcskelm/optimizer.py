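"""Cuckoo search and its Sobol/black-hole enhanced variants.

Implements continuous global minimisation with four variants:

``CS``
    Classic cuckoo search: uniform-random initialisation, Lévy-flight
    updates and probabilistic nest abandonment.
``SCS``
    CS with the initial population drawn from a scrambled Sobol
    low-discrepancy sequence instead of uniform pseudo-random points.
``BCS``
    CS augmented with the multiverse "wormhole" (black-hole) operator,
    active in the second half of the iteration budget, which teleports
    coordinates into the neighbourhood of the current best solution.
``SBCS``
    Both enhancements combined.

All randomness flows from a single root seed through
:class:`numpy.random.SeedSequence` sub-streams, so runs are bit
reproducible. The best-so-far solution is elitist: it is never lost by
any operator, and every operator uses greedy replacement (a nest only
adopts a proposal with strictly better fitness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "SearchSpace",
    "Candidate",
    "OptimizerSettings",
    "ConvergenceTrace",
    "VARIANTS",
    "sobol_init",
    "levy_step",
    "cs_levy_update",
    "cs_abandon",
    "wep_tdr",
    "wormhole_perturb",
    "run_optimizer",
]

VARIANTS = ("CS", "SCS", "BCS", "SBCS")

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box constraint for the decision vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not np.all(lower < upper):
            raise ValueError("degenerate search space: require lower < upper elementwise")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    @classmethod
    def cube(cls, dim: int, lower: float, upper: float) -> "SearchSpace":
        return cls(np.full(dim, float(lower)), np.full(dim, float(upper)))


@dataclass
class Candidate:
    """A nest: a feasible position with its (lower-is-better) fitness."""

    position: np.ndarray
    fitness: float = math.inf

    def copy(self) -> "Candidate":
        return Candidate(self.position.copy(), self.fitness)


@dataclass
class OptimizerSettings:
    """Tunable knobs for all variants.

    ``discovery_prob`` is the host-discovery probability Pa of cuckoo
    search (0.25 in the original algorithm). ``levy_exponent`` is the
    tail index of the Lévy step law, ``step_factor`` the usual 0.01
    scale of the directional Lévy step. ``wep_min``/``wep_max`` bound
    the linearly ramped wormhole existence probability and
    ``tdr_exponent`` shapes the decaying travelling distance rate.
    """

    population_size: int = 30
    max_evaluations: int = 10_000
    discovery_prob: float = 0.25
    levy_exponent: float = 1.5
    step_factor: float = 0.01
    wep_min: float = 0.2
    wep_max: float = 1.0
    tdr_exponent: float = 6.0
    variant: str = "SBCS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.discovery_prob <= 1.0:
            raise ValueError("discovery_prob must lie in [0, 1]")
        if not 0.0 < self.levy_exponent <= 2.0:
            raise ValueError("levy_exponent must lie in (0, 2]")
        if self.step_factor < 0:
            raise ValueError("step_factor must be >= 0")
        if not self.wep_min < self.wep_max:
            raise ValueError("require wep_min < wep_max")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_evaluations < self.population_size:
            raise ValueError("max_evaluations must cover at least the initial population")


@dataclass
class ConvergenceTrace:
    """Best-so-far fitness recorded against evaluations consumed."""

    evaluations_used: list[int] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)

    def record(self, evaluations: int, fitness: float) -> None:
        self.evaluations_used.append(int(evaluations))
        self.best_fitness.append(float(fitness))


class _Evaluator:
    """Budget-counting objective wrapper; non-finite values become +inf."""

    def __init__(self, objective: Objective, budget: int):
        self._objective = objective
        self.budget = int(budget)
        self.count = 0
        self.any_finite = False

    @property
    def remaining(self) -> int:
        return self.budget - self.count

    def __call__(self, position: np.ndarray) -> float:
        if self.remaining <= 0:
            raise RuntimeError("evaluation budget exhausted")
        self.count += 1
        value = float(self._objective(position))
        if not math.isfinite(value):
            return math.inf
        self.any_finite = True
        return value


def sobol_init(
    space: SearchSpace, n: int, seed: int, *, scramble: bool = True
) -> np.ndarray:
    """Draw ``n`` initial positions from a base-2 Sobol sequence.

    Points are mapped affinely from the unit cube onto the search box,
    x = x_min + K * (x_max - x_min). With ``scramble=False`` the raw
    direction-number sequence is returned (first 1-D points
    0, 0.5, 0.75, 0.25, ...); with scrambling the seed selects the
    permutation, keeping runs reproducible while decorrelating restarts.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    sampler = qmc.Sobol(d=space.dim, scramble=scramble, rng=int(seed))
    # Draw the next power of two and slice: keeps the balance properties
    # scipy warns about, without changing the first n points.
    m = 1 << max(0, (n - 1).bit_length())
    unit = sampler.random(m)[:n]
    return space.lower + unit * space.width


def levy_step(beta: float, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step vector with tail index ``beta`` (Mantegna).

    sigma_u = [Gamma(1+b) sin(pi b/2) / (Gamma((1+b)/2) b 2^((b-1)/2))]^(1/b),
    step = u / |v|^(1/b) with u ~ N(0, sigma_u^2), v ~ N(0, 1).
    """
    if not 0.0 < beta <= 2.0:
        raise ValueError("beta must lie in (0, 2]")
    sigma_u = (
        math.gamma(1.0 + beta)
        * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return u / np.abs(v) ** (1.0 / beta)


def _greedy(
    swarm: list[Candidate],
    proposals: Sequence[np.ndarray | None],
    evaluator: _Evaluator,
) -> list[Candidate]:
    """Evaluate proposals and replace nests only on strict improvement.

    ``None`` (or an unchanged position) skips evaluation, and proposals
    beyond the remaining budget keep the incumbent.
    """
    out = []
    for cand, prop in zip(swarm, proposals):
        if prop is None or np.array_equal(prop, cand.position) or evaluator.remaining <= 0:
            out.append(cand)
            continue
        fit = evaluator(prop)
        if fit < cand.fitness:
            out.append(Candidate(prop, fit))
        else:
            out.append(cand)
    return out


def cs_levy_update(
    swarm: list[Candidate],
    best: Candidate,
    space: SearchSpace,
    settings: OptimizerSettings,
    rng: np.random.Generator,
    evaluator: _Evaluator,
) -> list[Candidate]:
    """Lévy-flight proposal for each nest, greedily accepted.

    Uses the directional convention step = step_factor * levy ⊗
    (x_i - x_best); the current best therefore proposes itself and is
    not re-evaluated.
    """
    proposals: list[np.ndarray | None] = []
    for cand in swarm:
        step = settings.step_factor * levy_step(
            settings.levy_exponent, space.dim, rng
        ) * (cand.position - best.position)
        if not np.any(step):
            proposals.append(None)
        else:
            proposals.append(space.clip(cand.position + step))
    return _greedy(swarm, proposals, evaluator)


def cs_abandon(
    swarm: list[Candidate],
    pa: float,
    space: SearchSpace,
    rng: np.random.Generator,
    evaluator: _Evaluator,
) -> list[Candidate]:
    """Abandon nests with probability ``pa`` via a biased random walk.

    A discovered nest moves by r ⊗ (x_k - x_j) where x_k, x_j are two
    distinct permutations of the population and r ~ U(0,1) per
    dimension; proposals are clipped and greedily accepted.
    """
    n = len(swarm)
    if n < 2:
        raise ValueError("abandonment needs at least 2 nests")
    positions = np.array([c.position for c in swarm])
    perm_k = positions[rng.permutation(n)]
    perm_j = positions[rng.permutation(n)]
    fire = rng.random(n) < pa
    r = rng.random(positions.shape)
    proposals: list[np.ndarray | None] = []
    for i in range(n):
        if not fire[i]:
            proposals.append(None)
        else:
            proposals.append(space.clip(positions[i] + r[i] * (perm_k[i] - perm_j[i])))
    return _greedy(swarm, proposals, evaluator)


def wep_tdr(l: int, L: int, settings: OptimizerSettings) -> tuple[float, float]:
    """Wormhole existence probability and travelling distance rate.

    WEP ramps linearly from wep_min to wep_max over the iterations;
    TDR = 1 - (l/L)^(1/p) decays from 1 to 0 with p = tdr_exponent.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0 <= l <= L:
        raise ValueError("require 0 <= l <= L")
    wep = settings.wep_min + l * (settings.wep_max - settings.wep_min) / L
    p = settings.tdr_exponent
    tdr = 1.0 - (l ** (1.0 / p)) / (L ** (1.0 / p))
    return wep, tdr


def wormhole_perturb(
    position: np.ndarray,
    best_position: np.ndarray,
    space: SearchSpace,
    wep: float,
    tdr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Teleport coordinates toward the best solution through wormholes.

    Per dimension j, with probability WEP the coordinate becomes
    X_j ± TDR * ((b_u,j - b_l,j) * r4 + b_l,j) (sign from r3 < 0.5,
    formula adopted exactly as printed); otherwise it is unchanged.
    The result is clipped to the search box.
    """
    d = space.dim
    r2 = rng.random(d)
    r3 = rng.random(d)
    r4 = rng.random(d)
    offset = tdr * (space.width * r4 + space.lower)
    teleported = np.where(r3 < 0.5, best_position + offset, best_position - offset)
    new = np.where(r2 < wep, teleported, position)
    return space.clip(new)


def _best_of(swarm: list[Candidate]) -> Candidate:
    return min(swarm, key=lambda c: c.fitness)


def run_optimizer(
    objective: Objective,
    space: SearchSpace,
    settings: OptimizerSettings,
) -> tuple[Candidate, ConvergenceTrace]:
    """Minimise ``objective`` over ``space`` with the selected variant.

    Returns the elitist best candidate and its convergence trace
    (best-so-far fitness vs evaluations consumed). Terminates when the
    evaluation budget is spent or the iteration cap
    MaxIter = max_evaluations // population_size is reached.
    """
    root = np.random.SeedSequence(settings.seed)
    ss_init, ss_loop = root.spawn(2)
    rng = np.random.default_rng(ss_loop)
    evaluator = _Evaluator(objective, settings.max_evaluations)

    n = settings.population_size
    if settings.variant in ("SCS", "SBCS"):
        init = sobol_init(space, n, int(ss_init.generate_state(1)[0] % 2**31))
    else:
        init_rng = np.random.default_rng(ss_init)
        init = space.lower + init_rng.random((n, space.dim)) * space.width

    swarm = [Candidate(init[i], evaluator(init[i])) for i in range(n)]
    best = _best_of(swarm).copy()
    trace = ConvergenceTrace()
    trace.record(evaluator.count, best.fitness)

    max_iter = max(1, settings.max_evaluations // n)
    wormhole_active = settings.variant in ("BCS", "SBCS")

    t = 1
    while evaluator.remaining > 0 and t <= max_iter:
        if wormhole_active and t > max_iter / 2:
            wep, tdr = wep_tdr(min(t, max_iter), max_iter, settings)
            proposals = [
                wormhole_perturb(c.position, best.position, space, wep, tdr, rng)
                for c in swarm
            ]
            swarm = _greedy(swarm, proposals, evaluator)
            best = min(best, _best_of(swarm), key=lambda c: c.fitness).copy()

        swarm = cs_levy_update(swarm, best, space, settings, rng, evaluator)
        best = min(best, _best_of(swarm), key=lambda c: c.fitness).copy()

        if evaluator.remaining > 0:
            swarm = cs_abandon(swarm, settings.discovery_prob, space, rng, evaluator)
            best = min(best, _best_of(swarm), key=lambda c: c.fitness).copy()

        trace.record(evaluator.count, best.fitness)
        t += 1

    if not evaluator.any_finite:
        raise RuntimeError("objective returned no finite value over the full budget")
    return best, trace
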