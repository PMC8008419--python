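"""Benchmark the optimiser against the fixed space-filling comparator.

Only available for the analytic cluster-RCT problem, whose closed-form
power supplies the truth: per repeat we record the dominated hypervolume
of each method's approximation set, its size, and the proportion of its
designs whose *true* type II error respects the nominal constraint.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .ego import EGOConfig, ProblemSpec, extract_approximation_set, run_ego, run_fixed_design
from .pareto import dominated_hypervolume
from .problems.cluster import ClusterTrialParams, cluster_power_analytic, cluster_true_pareto

__all__ = ["benchmark_cluster"]

logger = logging.getLogger(__name__)


def _validity(aset, params: ClusterTrialParams) -> float:
    if len(aset) == 0:
        return float("nan")
    designs = np.array([x for x, _ in aset])
    beta = 1.0 - cluster_power_analytic(designs, params)
    return float(np.mean(beta <= params.nominal_type2))


def benchmark_cluster(
    problem: ProblemSpec,
    sim,
    config: EGOConfig,
    n_repeats: int = 20,
    fixed_sizes: tuple[int, ...] = (50,),
) -> pd.DataFrame:
    """Repeat EGO and fixed designs under equal per-evaluation budgets.

    Returns one row per (method, repeat) with the dominated hypervolume,
    approximation-set size and true-validity proportion, all scored
    against the analytic power oracle and a common reference point.
    """
    params = sim.params
    if not isinstance(params, ClusterTrialParams):
        raise ValueError("benchmark requires the analytic cluster problem")
    ref = problem.reference_point()
    true_set = cluster_true_pareto(problem.space, params)
    true_hv = dominated_hypervolume(true_set, ref)
    rows = []
    for rep in range(n_repeats):
        cfg = replace(config, root_seed=config.root_seed + rep, checkpoint_path=None)
        state = run_ego(problem, sim, cfg)
        aset = extract_approximation_set(state)
        rows.append(
            {
                "method": "ego",
                "repeat": rep,
                "evaluations": cfg.resolved_initial_size(problem.space.dim)
                + cfg.iterations,
                "hypervolume": dominated_hypervolume(aset, ref),
                "set_size": len(aset),
                "valid_proportion": _validity(aset, params),
                "true_pareto_hypervolume": true_hv,
            }
        )
        for size in fixed_sizes:
            fset, _ = run_fixed_design(
                problem,
                sim,
                n_points=size,
                n_per_eval=cfg.n_per_eval,
                root_seed=cfg.root_seed,
            )
            rows.append(
                {
                    "method": f"fixed_{size}",
                    "repeat": rep,
                    "evaluations": size,
                    "hypervolume": dominated_hypervolume(fset, ref),
                    "set_size": len(fset),
                    "valid_proportion": _validity(fset, params),
                    "true_pareto_hypervolume": true_hv,
                }
            )
    return pd.DataFrame(rows)
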