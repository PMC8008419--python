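"""Two-arm cluster randomised trial with a closed-form power oracle.

Outcome of participant i in cluster j:  y_ij = b0 + b1*t_i + u_j + e_i,
with u_j ~ N(0, sigma_B^2) and e_i ~ N(0, sigma_W^2).  The analysis is a
one-sided two-sample t-test on the k cluster means per arm, each with
variance sigma_B^2 + sigma_W^2/m for cluster size m = n/k.  Because that
test depends on the data only through the cluster means, power is
available in closed form (noncentral t), making this problem the truth
oracle for benchmarking the optimiser: design parameters (k, n) per arm,
objectives (2n, 2k), constraint type II error <= beta*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..pareto import ApproximationSet, nondominated_filter
from ..space import SolutionSpace

__all__ = [
    "ClusterTrialParams",
    "ClusterTrialSimulator",
    "cluster_power_analytic",
    "cluster_trial_simulate_once",
    "cluster_true_pareto",
    "default_cluster_space",
    "make_cluster_problem",
]


@dataclass(frozen=True)
class ClusterTrialParams:
    """Nuisance parameters, effect and nominal levels of the cluster RCT.

    Defaults: unit total variance split 0.95/0.05 (ICC 0.05), one-sided
    alpha 0.025, nominal type II error 0.1, and a standardised minimal
    clinically important difference of 0.3.
    """

    within_var: float = 0.95
    between_var: float = 0.05
    effect: float = 0.3
    alpha_one_sided: float = 0.025
    nominal_type2: float = 0.1

    def __post_init__(self) -> None:
        if self.within_var <= 0 or self.between_var <= 0:
            raise ValueError("variance components must be positive")
        if not 0 < self.alpha_one_sided < 0.5:
            raise ValueError("alpha_one_sided must lie in (0, 0.5)")


def _cluster_sizes(n: int, k: int) -> np.ndarray:
    """Split n participants over k clusters as evenly as possible."""
    base, extra = divmod(int(n), int(k))
    return np.array([base + 1] * extra + [base] * (k - extra))


def cluster_power_analytic(design, params: ClusterTrialParams):
    """Closed-form power of the cluster-means t-test.

    ``design`` is (k, n) per arm (arrays broadcast).  Cluster means have
    variance sigma_B^2 + sigma_W^2/m with m = n/k (real-valued), so the
    test statistic is noncentral t with df = 2k-2 and noncentrality
    delta / sqrt(2 (sigma_B^2 + sigma_W^2/m) / k).
    """
    design = np.asarray(design, dtype=float)
    k = design[..., 0]
    n = design[..., 1]
    if np.any(k < 2):
        raise ValueError("need at least 2 clusters per arm")
    m = n / k
    var_cm = params.between_var + params.within_var / m
    ncp = params.effect / np.sqrt(2.0 * var_cm / k)
    df = 2.0 * k - 2.0
    tcrit = stats.t.ppf(1.0 - params.alpha_one_sided, df)
    return stats.nct.sf(tcrit, df, ncp)


def _t_test_cluster_means(means_a: np.ndarray, means_b: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorised one-sided pooled t-test, rows = replicates."""
    k = means_a.shape[-1]
    diff = means_b.mean(axis=-1) - means_a.mean(axis=-1)
    va = means_a.var(axis=-1, ddof=1)
    vb = means_b.var(axis=-1, ddof=1)
    sp2 = (va + vb) / 2.0
    tstat = diff / np.sqrt(2.0 * sp2 / k)
    tcrit = stats.t.ppf(1.0 - alpha, 2 * k - 2)
    return (tstat > tcrit).astype(np.int64)


class ClusterTrialSimulator:
    """Reject-indicator simulator for the cluster RCT.

    Cluster means are drawn from their exact aggregated distribution
    N(mu_arm, sigma_B^2 + sigma_W^2/m_j) with balanced integer cluster
    sizes m_j — identical in law to drawing u_j and every e_i and
    averaging, but fast enough for 1e4-replicate calibration runs.
    """

    hypotheses = frozenset({"null", "alternative"})

    def __init__(self, params: ClusterTrialParams = ClusterTrialParams()):
        self.params = params

    def _design(self, x) -> tuple[int, int]:
        k, n = int(round(x[0])), int(round(x[1]))
        if k < 2 or n < k:
            raise ValueError(f"invalid cluster design (k={k}, n={n})")
        return k, n

    def simulate_batch(
        self, x, hypothesis: str, n_samples: int, rng: np.random.Generator
    ) -> np.ndarray:
        k, n = self._design(x)
        p = self.params
        delta = p.effect if hypothesis == "alternative" else 0.0
        sd_cm = np.sqrt(p.between_var + p.within_var / _cluster_sizes(n, k))
        means_ctrl = rng.standard_normal((n_samples, k)) * sd_cm
        means_trt = rng.standard_normal((n_samples, k)) * sd_cm + delta
        return _t_test_cluster_means(means_ctrl, means_trt, p.alpha_one_sided)

    def simulate_once(self, x, hypothesis: str, rng: np.random.Generator) -> int:
        return int(self.simulate_batch(x, hypothesis, 1, rng)[0])


def cluster_trial_simulate_once(design, params, hypothesis, rng) -> int:
    """One replicate of the cluster trial: simulate, test, return 1 iff rejected."""
    return ClusterTrialSimulator(params).simulate_once(design, hypothesis, rng)


def default_cluster_space() -> SolutionSpace:
    return SolutionSpace(
        names=("k", "n"),
        lower=np.array([10.0, 100.0]),
        upper=np.array([100.0, 500.0]),
        integer=np.array([True, True]),
    )


def cluster_true_pareto(
    space: SolutionSpace, params: ClusterTrialParams
) -> ApproximationSet:
    """True Pareto set by exhaustive integer search over (k, n).

    Keeps designs whose analytic type II error is at most the nominal
    level and returns the nondominated subset under objectives (2n, 2k).
    """
    ks = np.arange(int(space.lower[0]), int(space.upper[0]) + 1)
    ns = np.arange(int(space.lower[1]), int(space.upper[1]) + 1)
    kk, nn = np.meshgrid(ks, ns, indexing="ij")
    grid = np.stack([kk, nn], axis=-1).reshape(-1, 2)
    grid = grid[grid[:, 1] >= grid[:, 0]]  # need n >= k
    power = cluster_power_analytic(grid, params)
    feasible = grid[1.0 - power <= params.nominal_type2]
    # Only the smallest feasible n per k can be nondominated.
    best: dict[int, int] = {}
    for k, n in feasible:
        if k not in best or n < best[k]:
            best[int(k)] = int(n)
    points = [
        (np.array([k, n], dtype=float), np.array([2.0 * n, 2.0 * k]))
        for k, n in sorted(best.items())
    ]
    return nondominated_filter(points)


def make_cluster_problem(
    params: ClusterTrialParams = ClusterTrialParams(),
    space: SolutionSpace | None = None,
):
    """The cluster RCT as a (ProblemSpec, simulator) pair."""
    from ..ego import Constraint, ProblemSpec

    space = space or default_cluster_space()
    problem = ProblemSpec(
        space=space,
        objectives=[lambda x: 2.0 * x[1], lambda x: 2.0 * x[0]],
        objective_names=("total_participants", "total_clusters"),
        constraints=[
            Constraint(
                name="type2_error",
                hypothesis="alternative",
                threshold=params.nominal_type2,
                complement=True,  # OC = 1 - P(reject) under the alternative
            )
        ],
    )
    return problem, ClusterTrialSimulator(params)
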