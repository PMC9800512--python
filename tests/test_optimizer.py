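import math

import numpy as np
import pytest

from sbcskelm.optimizer import (
    Candidate,
    OptimizerSettings,
    SearchSpace,
    VARIANTS,
    cs_abandon,
    cs_levy_update,
    levy_step,
    run_optimizer,
    sobol_init,
    wep_tdr,
    wormhole_perturb,
)
from sbcskelm.optimizer import _Evaluator


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestSearchSpace:
    def test_cube(self):
        space = SearchSpace.cube(3, -2.0, 5.0)
        assert space.dim == 3
        assert np.allclose(space.width, 7.0)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_clip(self):
        space = SearchSpace.cube(2, 0.0, 1.0)
        assert np.allclose(space.clip(np.array([-1.0, 2.0])), [0.0, 1.0])


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"discovery_prob": 1.5},
            {"levy_exponent": 0.0},
            {"levy_exponent": 2.5},
            {"step_factor": -0.1},
            {"wep_min": 0.9, "wep_max": 0.2},
            {"variant": "XYZ"},
            {"population_size": 1},
            {"population_size": 30, "max_evaluations": 10},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            OptimizerSettings(**kwargs)


class TestSobolInit:
    def test_unscrambled_first_points_1d(self):
        space = SearchSpace.cube(1, 0.0, 1.0)
        pts = sobol_init(space, 4, seed=0, scramble=False).ravel()
        assert np.allclose(pts, [0.0, 0.5, 0.75, 0.25])

    def test_points_inside_box(self):
        space = SearchSpace.cube(5, -3.0, 7.0)
        pts = sobol_init(space, 33, seed=3)
        assert pts.shape == (33, 5)
        assert np.all(pts >= -3.0) and np.all(pts <= 7.0)

    def test_seed_reproducible(self):
        space = SearchSpace.cube(4, 0.0, 1.0)
        a = sobol_init(space, 16, seed=9)
        b = sobol_init(space, 16, seed=9)
        c = sobol_init(space, 16, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            sobol_init(SearchSpace.cube(2, 0, 1), 0, seed=0)


class TestLevyStep:
    def test_heavy_tail(self, rng):
        # A Levy(1.5) sample of this size essentially always contains
        # steps far beyond the Gaussian range.
        steps = levy_step(1.5, 20_000, rng)
        assert np.max(np.abs(steps)) > 10.0

    def test_median_scale_moderate(self, rng):
        steps = levy_step(1.5, 20_000, rng)
        assert 0.05 < np.median(np.abs(steps)) < 5.0

    def test_invalid_beta(self, rng):
        with pytest.raises(ValueError):
            levy_step(2.5, 3, rng)


class TestWepTdr:
    def test_endpoints(self):
        s = OptimizerSettings()
        wep0, tdr0 = wep_tdr(0, 100, s)
        wepL, tdrL = wep_tdr(100, 100, s)
        assert wep0 == pytest.approx(0.2)
        assert tdr0 == pytest.approx(1.0)
        assert wepL == pytest.approx(1.0)
        assert tdrL == pytest.approx(0.0)

    def test_monotone(self):
        s = OptimizerSettings()
        vals = [wep_tdr(l, 50, s) for l in range(51)]
        weps = [v[0] for v in vals]
        tdrs = [v[1] for v in vals]
        assert all(a <= b for a, b in zip(weps, weps[1:]))
        assert all(a >= b for a, b in zip(tdrs, tdrs[1:]))

    def test_bounds_checked(self):
        s = OptimizerSettings()
        with pytest.raises(ValueError):
            wep_tdr(5, 4, s)


class TestWormhole:
    def test_wep_zero_is_identity(self, rng):
        space = SearchSpace.cube(6, -1.0, 1.0)
        x = rng.uniform(-1, 1, 6)
        out = wormhole_perturb(x, np.zeros(6), space, wep=0.0, tdr=0.5, rng=rng)
        assert np.array_equal(out, x)

    def test_wep_one_tdr_zero_collapses_to_best(self, rng):
        space = SearchSpace.cube(6, -1.0, 1.0)
        x = rng.uniform(-1, 1, 6)
        best = rng.uniform(-1, 1, 6)
        out = wormhole_perturb(x, best, space, wep=1.0, tdr=0.0, rng=rng)
        assert np.allclose(out, best)

    def test_result_in_box(self, rng):
        space = SearchSpace.cube(4, 0.0, 1.0)
        out = wormhole_perturb(
            rng.random(4), rng.random(4), space, wep=1.0, tdr=1.0, rng=rng
        )
        assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestOperators:
    def _swarm(self, rng, space, n=6):
        pts = space.lower + rng.random((n, space.dim)) * space.width
        return [Candidate(p, sphere(p)) for p in pts]

    def test_levy_update_never_worsens(self, rng):
        space = SearchSpace.cube(3, -5.0, 5.0)
        swarm = self._swarm(rng, space)
        best = min(swarm, key=lambda c: c.fitness)
        ev = _Evaluator(sphere, 1000)
        new = cs_levy_update(swarm, best, space, OptimizerSettings(), rng, ev)
        for old, upd in zip(swarm, new):
            assert upd.fitness <= old.fitness

    def test_levy_update_best_self_proposal_skipped(self, rng):
        space = SearchSpace.cube(3, -5.0, 5.0)
        swarm = self._swarm(rng, space)
        best = min(swarm, key=lambda c: c.fitness)
        ev = _Evaluator(sphere, 1000)
        cs_levy_update(swarm, best, space, OptimizerSettings(), rng, ev)
        # the best nest proposes a zero step and must not burn budget
        assert ev.count == len(swarm) - 1

    def test_abandon_never_worsens_and_respects_pa(self, rng):
        space = SearchSpace.cube(3, -5.0, 5.0)
        swarm = self._swarm(rng, space, n=10)
        ev = _Evaluator(sphere, 1000)
        new = cs_abandon(swarm, 0.25, space, rng, ev)
        for old, upd in zip(swarm, new):
            assert upd.fitness <= old.fitness
        ev2 = _Evaluator(sphere, 1000)
        unchanged = cs_abandon(swarm, 0.0, space, rng, ev2)
        assert ev2.count == 0
        assert all(np.array_equal(a.position, b.position) for a, b in zip(swarm, unchanged))


class TestRunOptimizer:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_converges_on_sphere(self, variant):
        space = SearchSpace.cube(2, -5.0, 5.0)
        settings = OptimizerSettings(
            population_size=20, max_evaluations=5000, variant=variant, seed=7
        )
        best, trace = run_optimizer(sphere, space, settings)
        assert best.fitness < 1e-3

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_trace_monotone_nonincreasing(self, variant):
        space = SearchSpace.cube(5, -10.0, 10.0)
        settings = OptimizerSettings(
            population_size=15, max_evaluations=2000, variant=variant, seed=11
        )
        _, trace = run_optimizer(sphere, space, settings)
        bf = trace.best_fitness
        assert all(a >= b for a, b in zip(bf, bf[1:]))

    def test_budget_respected_exactly(self):
        calls = {"n": 0}

        def counting(x):
            calls["n"] += 1
            return sphere(x)

        settings = OptimizerSettings(
            population_size=10, max_evaluations=500, variant="SBCS", seed=1
        )
        run_optimizer(counting, SearchSpace.cube(3, -1, 1), settings)
        assert calls["n"] <= 500

    def test_seed_reproducible(self):
        space = SearchSpace.cube(4, -2.0, 2.0)
        s = OptimizerSettings(population_size=10, max_evaluations=800, seed=42)
        b1, t1 = run_optimizer(sphere, space, s)
        b2, t2 = run_optimizer(sphere, space, s)
        assert b1.fitness == b2.fitness
        assert np.array_equal(b1.position, b2.position)
        assert t1.best_fitness == t2.best_fitness

    def test_best_within_bounds(self):
        space = SearchSpace.cube(3, 1.0, 2.0)
        s = OptimizerSettings(population_size=10, max_evaluations=500, seed=3)
        best, _ = run_optimizer(sphere, space, s)
        assert np.all(best.position >= 1.0) and np.all(best.position <= 2.0)

    def test_nonfinite_objective_mapped_to_inf(self):
        def holey(x):
            return math.nan if x[0] > 0 else sphere(x)

        space = SearchSpace.cube(2, -1.0, 1.0)
        s = OptimizerSettings(population_size=8, max_evaluations=400, seed=5)
        best, _ = run_optimizer(holey, space, s)
        assert math.isfinite(best.fitness)

    def test_all_nan_objective_raises(self):
        s = OptimizerSettings(population_size=5, max_evaluations=50, seed=0)
        with pytest.raises(RuntimeError):
            run_optimizer(lambda x: math.nan, SearchSpace.cube(2, 0, 1), s)
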