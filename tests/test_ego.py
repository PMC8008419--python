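"""Loop mechanics: initial design, budget, pooling, restart, comparator, diagnostics."""

import numpy as np
import pytest

from ssdopt import (
    Constraint,
    EGOConfig,
    FeasibilityRule,
    ProblemSpec,
    SolutionSpace,
    diagnostics,
    dominated_hypervolume,
    extract_approximation_set,
    nondominated_filter,
    resume,
    run_ego,
    run_fixed_design,
    sobol_initial_design,
    spawn_rng,
)
from ssdopt.ego import RunState, _evaluate_point


class CountingSimulator:
    """Bernoulli simulator that counts every replicate drawn."""

    hypotheses = frozenset({"null", "alternative"})

    def __init__(self, p=0.05):
        self.p = p
        self.calls = 0

    def simulate_once(self, x, hypothesis, rng):
        self.calls += 1
        return int(rng.random() < self.p)


def _toy_problem(thresholds=(0.1,)):
    space = SolutionSpace(
        ("k", "n"), np.array([10.0, 100.0]), np.array([100.0, 500.0]),
        np.array([True, True]),
    )
    return ProblemSpec(
        space=space,
        objectives=[lambda x: 2 * x[1], lambda x: 2 * x[0]],
        objective_names=("total_n", "total_k"),
        constraints=[
            Constraint("oc", "alternative", thr, complement=False) for thr in thresholds
        ],
    )


class TestSobolInitialDesign:
    def test_unit_square_quadrant_balance(self):
        space = SolutionSpace(("a", "b"), np.zeros(2), np.ones(2))
        pts = np.array(sobol_initial_design(space, 8, seed=1))
        quadrant = (pts[:, 0] >= 0.5).astype(int) * 2 + (pts[:, 1] >= 0.5).astype(int)
        counts = np.bincount(quadrant, minlength=4)
        np.testing.assert_array_equal(counts, [2, 2, 2, 2])

    def test_cluster_box_gives_distinct_integer_pairs(self):
        space = _toy_problem().space
        pts = sobol_initial_design(space, 20, seed=2)
        assert len(pts) == 20
        keys = {tuple(p) for p in pts}
        assert len(keys) == 20
        for p in pts:
            assert space.contains(p)
            assert p[0] == int(p[0]) and p[1] == int(p[1])

    def test_same_seed_reproduces_the_design(self):
        space = _toy_problem().space
        a = sobol_initial_design(space, 12, seed=7)
        b = sobol_initial_design(space, 12, seed=7)
        np.testing.assert_array_equal(np.array(a), np.array(b))

    def test_zero_width_dimension_rejected(self):
        with pytest.raises(ValueError):
            SolutionSpace(("a",), np.array([1.0]), np.array([1.0]))


class TestBudgetAndPooling:
    def test_budget_conservation(self, small_ego_config):
        problem = _toy_problem()
        sim = CountingSimulator()
        state = run_ego(problem, sim, small_ego_config)
        expected = (10 + 4) * small_ego_config.n_per_eval * 1
        assert sim.calls == expected
        assert state.total_simulations == expected

    def test_duplicate_evaluation_pools_replicates(self):
        problem = _toy_problem()
        sim = CountingSimulator(p=0.5)
        state = RunState(problem=problem, config=EGOConfig(n_per_eval=50, root_seed=1))
        x = np.array([20.0, 200.0])
        _evaluate_point(state, sim, x, iteration=0)
        first = state.evaluations[problem.space.key(x)]["oc"]
        _evaluate_point(state, sim, x, iteration=1)
        pooled = state.evaluations[problem.space.key(x)]["oc"]
        assert first.n_samples == 50 and pooled.n_samples == 100
        assert pooled.std_error < first.std_error or first.estimate in (0.0, 1.0)
        assert len(state.log) == 2


class TestApproximationSetExtraction:
    def test_all_points_infeasible_gives_empty_set(self, small_ego_config):
        problem = _toy_problem(thresholds=(0.001,))  # OC ~ 0.05 >> 0.001
        sim = CountingSimulator(p=0.4)
        state = run_ego(problem, sim, small_ego_config)
        aset = extract_approximation_set(state)
        assert len(aset) == 0
        assert dominated_hypervolume(aset, problem.reference_point()) == 0.0

    def test_feasible_problem_returns_nondominated_set(self, small_ego_config):
        problem = _toy_problem(thresholds=(0.5,))
        sim = CountingSimulator(p=0.05)
        state = run_ego(problem, sim, small_ego_config)
        aset = extract_approximation_set(state)
        assert len(aset) >= 1
        objs = aset.objective_array
        refiltered = nondominated_filter(list(zip(aset.designs, objs)))
        assert len(refiltered) == len(aset)

    def test_zero_iterations_uses_only_the_initial_design(self):
        problem = _toy_problem(thresholds=(0.5,))
        sim = CountingSimulator(p=0.05)
        cfg = EGOConfig(iterations=0, initial_design_size=8, n_per_eval=30, root_seed=2)
        state = run_ego(problem, sim, cfg)
        assert state.eval_counter == 8
        aset = extract_approximation_set(state)
        assert len(aset) >= 1


class TestRestart:
    def test_resumed_run_matches_uninterrupted_run(self, tmp_path):
        problem = _toy_problem(thresholds=(0.5,))
        ck = str(tmp_path / "ck.json")

        def make_cfg(iters):
            from ssdopt import PSOSettings

            return EGOConfig(
                iterations=iters, initial_design_size=8, n_per_eval=30,
                root_seed=5, pso=PSOSettings(10, 20), gp_restarts=3,
                checkpoint_path=ck,
            )

        full = run_ego(problem, CountingSimulator(p=0.1), make_cfg(4))
        partial = run_ego(problem, CountingSimulator(p=0.1), make_cfg(2))
        resumed = resume(ck, problem, CountingSimulator(p=0.1), 2)
        def strip(rows):
            return [{k: v for k, v in r.items() if k != "wall_time"} for r in rows]

        assert strip(resumed.log) == strip(full.log)
        assert resumed.eval_counter == full.eval_counter


class TestFixedDesign:
    def test_interval_filter_examples(self):
        # survivor: 0.04 + 1.96 * 0.0196 = 0.078 < 0.1; casualty: estimate 0.11
        problem = _toy_problem(thresholds=(0.1,))
        good, _ = run_fixed_design(problem, CountingSimulator(p=0.02), 10, 400, root_seed=3)
        assert len(good) >= 1
        bad, log = run_fixed_design(problem, CountingSimulator(p=0.2), 10, 400, root_seed=3)
        assert len(bad) == 0
        assert not log["retained"].any()

    def test_borderline_estimate_above_nominal_discarded(self):
        problem = _toy_problem(thresholds=(0.1,))

        class FixedRate:
            hypotheses = frozenset({"alternative"})

            def simulate_batch(self, x, h, n, rng):
                out = np.zeros(n, dtype=int)
                out[: int(0.11 * n)] = 1  # estimate exactly 0.11
                return out

            def simulate_once(self, x, h, rng):
                return 0

        aset, log = run_fixed_design(problem, FixedRate(), 5, 100, root_seed=1)
        assert len(aset) == 0


class TestDiagnostics:
    def test_empty_history_gives_empty_report(self):
        state = RunState(problem=_toy_problem(), config=EGOConfig())
        report = diagnostics(state)
        assert len(report) == 0
        assert "z" in report.columns

    def test_well_specified_run_rarely_flags(self, small_ego_config):
        problem = _toy_problem(thresholds=(0.5,))
        state = run_ego(problem, CountingSimulator(p=0.2), small_ego_config)
        report = diagnostics(state)
        assert len(report) == small_ego_config.iterations
        assert report["flag"].mean() <= 0.5
        # acquisition trace travels with the diagnostics rows
        assert {"ei", "feasibility_probability"} <= set(report.columns)
        assert (report["feasibility_probability"] >= 0).all()

    def test_mis_scaled_surrogate_raises_flags(self):
        # a surrogate claiming near-zero uncertainty far from the truth
        problem = _toy_problem(thresholds=(0.5,))
        state = RunState(problem=problem, config=EGOConfig())
        state.prediction_log = [
            {
                "iteration": 1, "constraint": "oc", "predicted_mean": 0.9,
                "predicted_sd": 1e-4, "observed": 0.2, "observed_se": 0.04,
                "duplicate": False,
            }
        ]
        report = diagnostics(state)
        assert report["flag"].all()


class TestHypervolumeTrajectory:
    def test_feasible_pool_hypervolume_nondecreasing_in_hindsight(self, small_ego_config):
        problem = _toy_problem(thresholds=(0.5,))
        state = run_ego(problem, CountingSimulator(p=0.1), small_ego_config)
        rule = FeasibilityRule(state.config.quantile_level)
        keys = list(state.evaluations)
        ref = problem.reference_point()
        hvs = []
        for upto in range(1, len(keys) + 1):
            sub = keys[:upto]
            feas = []
            for k in sub:
                x = state.points[k]
                ok = True
                for con in problem.constraints:
                    m, s = state.models[con.name].predict(x[None, :], return_std=True)
                    if m[0] - con.threshold + rule.z * s[0] > 0:
                        ok = False
                if ok:
                    feas.append((x, problem.objective_vector(x)))
            hvs.append(dominated_hypervolume(nondominated_filter(feas), ref))
        assert np.all(np.diff(hvs) >= -1e-9)
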