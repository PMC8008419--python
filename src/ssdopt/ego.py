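"""Efficient global optimisation for simulation-based sample size determination.

The loop: evaluate an initial Sobol space-filling design of the constraint
operating characteristics by Monte Carlo; then repeatedly (i) fit one GP
surrogate per constraint to all estimates so far, (ii) find the design
maximising constrained expected hypervolume improvement by particle
swarm, (iii) round integer dimensions, evaluate the proposal (pooling
replicates if it re-proposes a known design), and (iv) refresh the
approximation set of mutually nondominated, currently-deemed-feasible
designs.  Also provides the fixed space-filling comparator, run
diagnostics, and checkpoint/resume.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, qmc

from .acquisition import FeasibilityRule, PSOSettings, feasibility_quantile, maximize_ei
from .gp import GaussianProcess
from .mc import MCEstimate, estimate_oc, mc_standard_error, pool_estimates, spawn_rng
from .pareto import (
    ApproximationSet,
    default_reference_point,
    dominated_hypervolume,
    nondominated_filter,
)
from .space import SolutionSpace

__all__ = [
    "Constraint",
    "ProblemSpec",
    "EGOConfig",
    "RunState",
    "sobol_initial_design",
    "run_ego",
    "resume",
    "extract_approximation_set",
    "run_fixed_design",
    "diagnostics",
    "approximation_set_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Constraint:
    """A simulation-estimated operating-characteristic constraint OC(x) <= threshold.

    ``complement=True`` means the OC is 1 minus the rejection rate the
    simulator produces (e.g. type II error from a power simulation under
    the alternative); the MC standard error is unchanged.
    """

    name: str
    hypothesis: str
    threshold: float
    complement: bool = False


@dataclass(frozen=True)
class ProblemSpec:
    """Bundles the design box, cheap objectives, and expensive constraints."""

    space: SolutionSpace
    objectives: list
    objective_names: tuple[str, ...]
    constraints: list
    ref_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.objectives) < 1 or len(self.constraints) < 1:
            raise ValueError("need at least one objective and one constraint")
        if len(self.objective_names) != len(self.objectives):
            raise ValueError("objective_names length mismatch")

    def objective_vector(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.array([f(x) for f in self.objectives], dtype=float)

    def reference_point(self) -> np.ndarray:
        """Configured reference point, or the default box-corner rule."""
        if self.ref_point is not None:
            return np.asarray(self.ref_point, dtype=float)
        corners = np.array(
            np.meshgrid(*zip(self.space.lower, self.space.upper))
        ).T.reshape(-1, self.space.dim)
        worst = np.max([self.objective_vector(c) for c in corners], axis=0)
        return default_reference_point(worst)


@dataclass(frozen=True)
class EGOConfig:
    """Run configuration: budget split, MC sample size, feasibility rule, seeds.

    ``initial_design_size`` defaults to 10 points per design dimension,
    capped so the initial phase uses at most half the total budget.
    """

    iterations: int = 30
    initial_design_size: int | None = None
    n_per_eval: int = 100
    quantile_level: float = 0.9
    root_seed: int = 0
    pso: PSOSettings = field(default_factory=PSOSettings)
    gp_restarts: int = 10
    checkpoint_path: str | None = None

    def resolved_initial_size(self, dim: int) -> int:
        if self.initial_design_size is not None:
            e = int(self.initial_design_size)
        else:
            e = 10 * dim
            total = e + self.iterations
            if self.iterations > 0 and e > total / 2:
                e = max(2, (e + self.iterations) // 2)
        if e < 2:
            raise ValueError("initial design size must be >= 2")
        return e

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "initial_design_size": self.initial_design_size,
            "n_per_eval": self.n_per_eval,
            "quantile_level": self.quantile_level,
            "root_seed": self.root_seed,
            "pso": {
                "swarm_size": self.pso.swarm_size,
                "iterations": self.pso.iterations,
                "inertia": self.pso.inertia,
                "cognitive": self.pso.cognitive,
                "social": self.pso.social,
            },
            "gp_restarts": self.gp_restarts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EGOConfig":
        d = dict(d)
        pso = d.pop("pso", {})
        return cls(pso=PSOSettings(**pso), **d)


@dataclass
class RunState:
    """Everything accumulated during a run; serialisable and resumable."""

    problem: ProblemSpec
    config: EGOConfig
    evaluations: dict = field(default_factory=dict)  # key -> {cname: MCEstimate}
    points: dict = field(default_factory=dict)  # key -> design array
    log: list = field(default_factory=list)  # per (evaluation, constraint) rows
    prediction_log: list = field(default_factory=list)  # diagnostics rows
    iteration: int = 0
    eval_counter: int = 0
    models: dict = field(default_factory=dict)
    total_simulations: int = 0

    def log_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.log)

    def rule(self) -> FeasibilityRule:
        return FeasibilityRule(self.config.quantile_level)

    # -- checkpointing ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "iteration": self.iteration,
            "eval_counter": self.eval_counter,
            "total_simulations": self.total_simulations,
            "log": self.log,
            "prediction_log": self.prediction_log,
            "models": {name: gp.to_dict() for name, gp in self.models.items()},
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str, problem: ProblemSpec) -> "RunState":
        with open(path) as fh:
            d = json.load(fh)
        state = cls(problem=problem, config=EGOConfig.from_dict(d["config"]))
        state.iteration = d["iteration"]
        state.eval_counter = d["eval_counter"]
        state.total_simulations = d["total_simulations"]
        state.log = d["log"]
        state.prediction_log = d["prediction_log"]
        design_cols = list(problem.space.names)
        by_key: dict = {}
        for row in state.log:
            x = np.array([row[c] for c in design_cols], dtype=float)
            key = problem.space.key(x)
            est = MCEstimate(
                row["estimate"], row["n_samples"], row["successes"], row["std_error"]
            )
            by_key.setdefault(key, {})
            cname = row["constraint"]
            if cname in by_key[key]:
                by_key[key][cname] = pool_estimates([by_key[key][cname], est])
            else:
                by_key[key][cname] = est
            state.points[key] = x
        state.evaluations = by_key
        state.models = {
            name: GaussianProcess.from_dict(m) for name, m in d.get("models", {}).items()
        }
        return state


def sobol_initial_design(
    space: SolutionSpace, size: int, seed
) -> list[np.ndarray]:
    """A Sobol space-filling design scaled to the box.

    Integer dimensions are rounded half-up; designs colliding after
    rounding are replaced with subsequent elements of the sequence, so the
    result holds ``size`` distinct points.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sampler = qmc.Sobol(space.dim, scramble=True, seed=seed)
        points: list[np.ndarray] = []
        seen: set = set()
        attempts = 0
        while len(points) < size and attempts < 100 * size + 1000:
            u = sampler.random(1)[0]
            x = space.round_point(space.unscale(u))
            key = space.key(x)
            attempts += 1
            if key in seen:
                continue
            seen.add(key)
            points.append(x)
    if len(points) < size:
        raise ValueError(
            f"could not place {size} distinct designs in the box after rounding"
        )
    return points


def _evaluate_point(
    state: RunState, sim, x: np.ndarray, iteration: int
) -> dict[str, MCEstimate]:
    """Evaluate every constraint OC at a design, logging and pooling."""
    problem, config = state.problem, state.config
    key = problem.space.key(x)
    state.points.setdefault(key, problem.space.round_point(x))
    per_constraint = state.evaluations.setdefault(key, {})
    new_batch: dict[str, MCEstimate] = {}
    for c_idx, con in enumerate(problem.constraints):
        rng = spawn_rng(config.root_seed, state.eval_counter, c_idx)
        t0 = time.perf_counter()
        raw = estimate_oc(sim, state.points[key], con.hypothesis, config.n_per_eval, rng)
        est = raw.complement if con.complement else raw
        new_batch[con.name] = est
        state.total_simulations += config.n_per_eval
        if con.name in per_constraint:
            per_constraint[con.name] = pool_estimates([per_constraint[con.name], est])
        else:
            per_constraint[con.name] = est
        row = {name: float(v) for name, v in zip(problem.space.names, state.points[key])}
        row.update(
            constraint=con.name,
            hypothesis=con.hypothesis,
            n_samples=est.n_samples,
            successes=est.successes,
            estimate=est.estimate,
            std_error=est.std_error,
            iteration=iteration,
            wall_time=time.perf_counter() - t0,
        )
        state.log.append(row)
    state.eval_counter += 1
    return new_batch


def _fit_models(state: RunState, iteration: int) -> None:
    problem, config = state.problem, state.config
    keys = list(state.evaluations.keys())
    X = np.array([state.points[k] for k in keys])
    for con in problem.constraints:
        y = np.array([state.evaluations[k][con.name].estimate for k in keys])
        noise = np.array(
            [state.evaluations[k][con.name].std_error ** 2 for k in keys]
        )
        gp = GaussianProcess(
            bounds=(problem.space.lower, problem.space.upper),
            n_restarts=config.gp_restarts,
            random_state=(config.root_seed * 1000003 + iteration) % (2**31),
        )
        state.models[con.name] = gp.fit(X, y, noise_var=noise)


def extract_approximation_set(state: RunState, rule: FeasibilityRule | None = None) -> ApproximationSet:
    """Nondominated subset of the currently-deemed-feasible evaluated designs.

    Feasibility is recomputed for every evaluated point under the current
    GPs: q_j(x) = (m_j(x) - threshold_j) + Phi^-1(p) s_j(x) <= 0 for all j.
    New data can therefore evict a previously included design.
    """
    rule = rule or state.rule()
    problem = state.problem
    if not state.models:
        raise ValueError("no fitted surrogate models in the run state")
    keys = list(state.evaluations.keys())
    X = np.array([state.points[k] for k in keys])
    feasible = np.ones(len(keys), dtype=bool)
    for con in problem.constraints:
        m, s = state.models[con.name].predict(X, return_std=True)
        q = feasibility_quantile(m - con.threshold, s, rule)
        feasible &= q <= 0.0
    pool = [
        (state.points[k], problem.objective_vector(state.points[k]))
        for k, ok in zip(keys, feasible)
        if ok
    ]
    return nondominated_filter(pool)


def run_ego(problem: ProblemSpec, sim, config: EGOConfig) -> RunState:
    """Run the full surrogate-assisted optimisation loop.

    Total simulation budget is (E + iterations) * N per constraint, spent
    exactly; duplicate proposals pool their replicates with the earlier
    evaluation of the same design (their GP noise entry shrinks).
    """
    state = RunState(problem=problem, config=config)
    e_size = config.resolved_initial_size(problem.space.dim)
    budget = (e_size + config.iterations) * config.n_per_eval * len(problem.constraints)
    logger.info(
        "EGO run: E=%d initial + %d iterations, N=%d per evaluation, "
        "%d constraint(s); total budget %d simulations",
        e_size, config.iterations, config.n_per_eval, len(problem.constraints), budget,
    )
    design = sobol_initial_design(
        problem.space, e_size, seed=spawn_rng(config.root_seed, 900_000_000)
    )
    for x in design:
        _evaluate_point(state, sim, x, iteration=0)
    _checkpoint(state)
    return _iterate(state, sim, config.iterations)


def resume(checkpoint_path: str, problem: ProblemSpec, sim, iterations: int) -> RunState:
    """Continue a checkpointed run for ``iterations`` further loop steps.

    Because every random stream is keyed by (root seed, evaluation or
    iteration index), a resumed run reproduces the evaluations an
    uninterrupted run would have made.
    """
    state = RunState.load(checkpoint_path, problem)
    state.config = replace(state.config, checkpoint_path=checkpoint_path)
    return _iterate(state, sim, iterations)


def _iterate(state: RunState, sim, iterations: int) -> RunState:
    problem, config = state.problem, state.config
    rule = state.rule()
    ref = problem.reference_point()
    for _ in range(iterations):
        state.iteration += 1
        _fit_models(state, state.iteration)
        current = extract_approximation_set(state, rule)
        models = [state.models[c.name] for c in problem.constraints]
        thresholds = [c.threshold for c in problem.constraints]
        x_cont, ei_value, feas_probs = maximize_ei(
            models,
            thresholds,
            current,
            ref,
            rule,
            problem.space,
            problem.objective_vector,
            config.n_per_eval,
            spawn_rng(config.root_seed, 800_000_000, state.iteration),
            settings=config.pso,
            return_details=True,
        )
        x_new = problem.space.round_point(x_cont)
        duplicate = problem.space.key(x_new) in state.evaluations
        preds = {
            c.name: state.models[c.name].predict(x_new[None, :], return_std=True)
            for c in problem.constraints
        }
        try:
            new_batch = _evaluate_point(state, sim, x_new, iteration=state.iteration)
        except Exception:
            _checkpoint(state)
            raise
        for c_idx, con in enumerate(problem.constraints):
            m, s = preds[con.name]
            obs = new_batch[con.name]
            state.prediction_log.append(
                {
                    "iteration": state.iteration,
                    "constraint": con.name,
                    "predicted_mean": float(m[0]),
                    "predicted_sd": float(s[0]),
                    "observed": obs.estimate,
                    "observed_se": obs.std_error,
                    "duplicate": bool(duplicate),
                    "ei": float(ei_value),
                    "feasibility_probability": feas_probs[c_idx],
                }
            )
        _checkpoint(state)
    _fit_models(state, state.iteration + 1)
    _checkpoint(state)
    return state


def _checkpoint(state: RunState) -> None:
    if state.config.checkpoint_path:
        state.save(state.config.checkpoint_path)


def run_fixed_design(
    problem: ProblemSpec,
    sim,
    n_points: int,
    n_per_eval: int = 100,
    confidence_level: float = 0.95,
    root_seed: int = 0,
) -> tuple[ApproximationSet, pd.DataFrame]:
    """The fixed space-filling comparator.

    Evaluates one Sobol batch; a design survives if, for every constraint,
    the MC confidence interval (estimate +/- z omega at the given two-sided
    level) lies entirely below the nominal threshold.  Returns the
    nondominated subset of survivors and the evaluation log.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    z = float(norm.ppf(0.5 + confidence_level / 2.0))
    design = sobol_initial_design(
        problem.space, n_points, seed=spawn_rng(root_seed, 700_000_000)
    )
    rows = []
    survivors = []
    for i, x in enumerate(design):
        keep = True
        row = {name: float(v) for name, v in zip(problem.space.names, x)}
        for c_idx, con in enumerate(problem.constraints):
            rng = spawn_rng(root_seed, i, c_idx)
            raw = estimate_oc(sim, x, con.hypothesis, n_per_eval, rng)
            est = raw.complement if con.complement else raw
            row[f"{con.name}_estimate"] = est.estimate
            row[f"{con.name}_se"] = est.std_error
            if not est.estimate + z * est.std_error < con.threshold:
                keep = False
        row["retained"] = keep
        rows.append(row)
        if keep:
            survivors.append((x, problem.objective_vector(x)))
    return nondominated_filter(survivors), pd.DataFrame(rows)


def diagnostics(state: RunState) -> pd.DataFrame:
    """Standardised prediction errors of the surrogates, per iteration.

    z = (observed - predicted mean) / sqrt(s^2 + omega^2); |z| > 3 flags a
    surprising evaluation (possible surrogate misfit).  Empty if no
    post-initial evaluation has happened yet.
    """
    if not state.prediction_log:
        return pd.DataFrame(
            columns=[
                "iteration", "constraint", "predicted_mean", "predicted_sd",
                "observed", "observed_se", "z", "flag",
            ]
        )
    df = pd.DataFrame(state.prediction_log)
    denom = np.sqrt(df["predicted_sd"] ** 2 + df["observed_se"] ** 2)
    df["z"] = (df["observed"] - df["predicted_mean"]) / denom
    df["flag"] = df["z"].abs() > 3.0
    return df


def approximation_set_table(state: RunState, aset: ApproximationSet | None = None) -> pd.DataFrame:
    """Approximation set as a table: design, objectives, constraint estimates."""
    aset = aset if aset is not None else extract_approximation_set(state)
    problem = state.problem
    rows = []
    for x, y in aset:
        row = {name: float(v) for name, v in zip(problem.space.names, x)}
        row.update({name: float(v) for name, v in zip(problem.objective_names, y)})
        key = problem.space.key(x)
        for con in problem.constraints:
            est = state.evaluations[key][con.name]
            row[f"{con.name}_estimate"] = est.estimate
            row[f"{con.name}_se"] = est.std_error
            row[f"{con.name}_n"] = est.n_samples
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and len(problem.objective_names):
        df = df.sort_values(list(problem.objective_names)[0]).reset_index(drop=True)
    return df


def hypervolume_of(state: RunState, aset: ApproximationSet | None = None) -> float:
    aset = aset if aset is not None else extract_approximation_set(state)
    return dominated_hypervolume(aset, state.problem.reference_point())
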