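"""Two-endpoint multilevel pilot trial with partially nested and crossed clustering.

Response of participant i for endpoint r in {F, D} (fatigue, disability):

    y_ir = b0r + b1r t_i + u_{therapist(i), r} t_i + v_{doctor(i), r} + e_ir

Therapists exist only in the intervention arm (partially nested: the
random therapist effect is switched on by t_i); doctors treat patients
in both arms (crossed).  Endpoint correlation enters through bivariate
normal therapist effects, doctor effects and residuals with correlations
rho_T, rho_D, rho_W and common marginal variances per level.

Each endpoint is analysed with its own univariate Gaussian mixed model
(deliberately ignoring the cross-endpoint correlation, as a real analysis
would), fitted by maximum likelihood, and a one-sided likelihood ratio
test of the treatment effect.  The trial is declared positive if either
endpoint is significant at the nominal level a — inflating the familywise
type I error, which is why a itself is a design parameter.

Design parameters: n1 (intervention-arm patients), k (therapists),
r = n0/n1 (allocation ratio), j (doctors), a (nominal one-sided level).
Objectives: total patients n1 + n0, k, j.  Constraints: type II error
<= 0.1 under H1 (b1 = 1.10 on both endpoints), familywise type I error
<= 0.2 under the global null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import norm

from ..space import SolutionSpace

__all__ = [
    "MultilevelTrialParams",
    "MultilevelDesign",
    "MultilevelTrialSimulator",
    "multilevel_simulate_dataset",
    "lmm_loglikelihood",
    "fit_lmm_ml",
    "lmm_fit_and_lrt",
    "multilevel_reject_once",
    "standardised_effect",
    "control_vpc",
    "therapist_vpc",
    "doctor_vpc",
    "default_multilevel_space",
    "make_pace_problem",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MultilevelTrialParams:
    """Nuisance parameters and effects of the two-endpoint multilevel trial.

    Defaults give a control-arm VPC of sigma_D^2/(sigma_D^2+sigma_W^2) = 0.1,
    a therapist VPC of 0.05 in the intervention arm, all cross-endpoint
    correlations 0.9, and a treatment effect of 1.10 on both endpoints
    (standardised effect 0.56 against the intervention-arm total SD).
    """

    effect: tuple[float, float] = (1.10, 1.10)
    intercept: tuple[float, float] = (0.0, 0.0)
    therapist_var: float = 0.19
    doctor_var: float = 0.37
    residual_var: float = 3.29
    rho_w: float = 0.9
    rho_t: float = 0.9
    rho_d: float = 0.9

    def __post_init__(self) -> None:
        if self.residual_var <= 0:
            raise ValueError("residual_var must be positive")
        if self.therapist_var < 0 or self.doctor_var < 0:
            raise ValueError("variance components must be nonnegative")
        for rho in (self.rho_w, self.rho_t, self.rho_d):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class MultilevelDesign:
    """A candidate design; n0 is derived as round-half-up(r * n1)."""

    n1: int
    k: int
    r: float
    j: int
    a: float

    @property
    def n0(self) -> int:
        return int(np.floor(self.r * self.n1 + 0.5))

    @property
    def total_n(self) -> int:
        return self.n1 + self.n0

    @classmethod
    def from_array(cls, x) -> "MultilevelDesign":
        return cls(
            n1=int(round(x[0])), k=int(round(x[1])), r=float(x[2]),
            j=int(round(x[3])), a=float(x[4]),
        )


def standardised_effect(params: MultilevelTrialParams) -> float:
    """Treatment effect standardised by the intervention-arm total SD."""
    total = params.therapist_var + params.doctor_var + params.residual_var
    return float(params.effect[0] / np.sqrt(total))


def control_vpc(params: MultilevelTrialParams) -> float:
    """Share of control-arm variance attributable to doctors."""
    return float(params.doctor_var / (params.doctor_var + params.residual_var))


def therapist_vpc(params: MultilevelTrialParams) -> float:
    total = params.therapist_var + params.doctor_var + params.residual_var
    return float(params.therapist_var / total)


def doctor_vpc(params: MultilevelTrialParams) -> float:
    total = params.therapist_var + params.doctor_var + params.residual_var
    return float(params.doctor_var / total)


def _bivariate(rng, n, var, rho):
    """n draws of a bivariate normal with common marginal variance and corr rho."""
    if var == 0.0:
        return np.zeros((n, 2))
    cov = var * np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    return rng.standard_normal((n, 2)) @ L.T


def multilevel_simulate_dataset(
    design: MultilevelDesign,
    params: MultilevelTrialParams,
    hypothesis: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one trial dataset.

    Intervention patients are allocated round-robin to the k therapists
    and, independently round-robin, to the j doctors (cross-classified);
    control patients round-robin to the j doctors only.  Columns:
    patient, arm, therapist (-1 in the control arm), doctor, y_F, y_D.
    """
    n1, n0, k, j = design.n1, design.n0, design.k, design.j
    if n1 < k:
        raise ValueError(f"empty therapist cells: n1={n1} < k={k}")
    if n1 + n0 < j:
        raise ValueError(f"empty doctor cells: n1+n0={n1 + n0} < j={j}")
    n = n1 + n0
    arm = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    therapist = np.concatenate([np.arange(n1) % k, np.full(n0, -1)])
    doctor = np.concatenate([np.arange(n1) % j, np.arange(n0) % j])

    u = _bivariate(rng, k, params.therapist_var, params.rho_t)
    v = _bivariate(rng, j, params.doctor_var, params.rho_d)
    e = _bivariate(rng, n, params.residual_var, params.rho_w)

    beta1 = np.asarray(params.effect) if hypothesis == "alternative" else np.zeros(2)
    beta0 = np.asarray(params.intercept)
    t = arm[:, None]
    u_rows = np.where(t.astype(bool), u[np.maximum(therapist, 0)], 0.0)
    y = beta0[None, :] + beta1[None, :] * t + u_rows * t + v[doctor] + e
    return pd.DataFrame(
        {
            "patient": np.arange(n),
            "arm": arm,
            "therapist": therapist,
            "doctor": doctor,
            "y_F": y[:, 0],
            "y_D": y[:, 1],
        }
    )


# ----------------------------------------------------------------------
# Univariate working-model fitter (maximum likelihood)
# ----------------------------------------------------------------------


class _LMMData:
    """Precomputed cross-products for the profile likelihood.

    The marginal covariance is V = sigma_W^2 W with
    W = I + phi_T Z_T Z_T' + phi_D Z_D Z_D' (phi = variance ratio), and
    all W-weighted quantities reduce, via the Woodbury identity, to the
    (k+j)-dimensional capacitance matrix M = I + Ztilde' Ztilde.
    """

    def __init__(self, y, t, therapist, doctor, include_effect):
        n = len(y)
        k = int(therapist.max()) + 1 if np.any(therapist >= 0) else 0
        jj = int(doctor.max()) + 1
        ZT = np.zeros((n, k))
        rows = np.nonzero((therapist >= 0) & (t == 1))[0]
        ZT[rows, therapist[rows]] = 1.0
        ZD = np.zeros((n, jj))
        ZD[np.arange(n), doctor] = 1.0
        X = np.column_stack([np.ones(n), t]) if include_effect else np.ones((n, 1))
        self.n, self.k, self.j = n, k, jj
        self.X, self.y = X, np.asarray(y, dtype=float)
        Z = np.hstack([ZT, ZD])
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ self.y
        self.XtX = X.T @ X
        self.Xty = X.T @ self.y
        self.yty = float(self.y @ self.y)

    def profile_nll(self, log_phi: np.ndarray) -> tuple[float, np.ndarray, float]:
        """Negative profile log-likelihood at variance ratios exp(log_phi).

        Fixed effects and sigma_W^2 are profiled out by GLS.  Returns
        (nll, beta_hat, sigma_w2_hat).
        """
        nll, _, beta, sigma_w2 = self._nll_grad(log_phi, want_grad=False)
        return nll, beta, sigma_w2

    def profile_nll_grad(self, log_phi: np.ndarray) -> tuple[float, np.ndarray]:
        """(nll, gradient wrt log phi); the gradient uses the envelope
        theorem over the GLS-profiled beta and sigma_W^2."""
        nll, grad, _, _ = self._nll_grad(log_phi, want_grad=True)
        return nll, grad

    def _nll_grad(self, log_phi: np.ndarray, want_grad: bool):
        phi = np.exp(np.clip(log_phi, -40.0, 40.0))
        k, jj, n = self.k, self.j, self.n
        s = np.concatenate(
            [np.full(k, np.sqrt(phi[0])), np.full(jj, np.sqrt(phi[1]))]
        )
        M = np.eye(k + jj) + s[:, None] * self.ZtZ * s[None, :]
        L = np.linalg.cholesky(M)
        logdetW = 2.0 * np.sum(np.log(np.diag(L)))
        sZtX = s[:, None] * self.ZtX
        sZty = s * self.Zty
        rhs = np.column_stack([sZtX, sZty])
        sol = linalg.cho_solve((L, True), rhs)
        XtWiX = self.XtX - sZtX.T @ sol[:, :-1]
        XtWiy = self.Xty - sZtX.T @ sol[:, -1]
        ytWiy = self.yty - sZty @ sol[:, -1]
        beta = linalg.solve(XtWiX, XtWiy, assume_a="pos")
        rss = float(ytWiy - beta @ XtWiy)
        sigma_w2 = max(rss / n, 1e-12)
        nll = 0.5 * n * np.log(2.0 * np.pi * sigma_w2) + 0.5 * logdetW + 0.5 * n
        if not want_grad:
            return float(nll), None, beta, sigma_w2
        # Z' W^-1 r and the diagonal blocks of Z' W^-1 Z, in capacitance space.
        Ztr = self.Zty - self.ZtX @ beta
        ZWr = Ztr - (self.ZtZ * s[None, :]) @ linalg.cho_solve((L, True), s * Ztr)
        T = self.ZtZ - (self.ZtZ * s[None, :]) @ linalg.cho_solve(
            (L, True), s[:, None] * self.ZtZ
        )
        grad = np.empty(2)
        for a, sl in enumerate((slice(0, k), slice(k, k + jj))):
            quad = float(ZWr[sl] @ ZWr[sl])
            tr = float(np.trace(T[sl, sl]))
            grad[a] = phi[a] * (-quad / (2.0 * sigma_w2) + 0.5 * tr)
        return float(nll), grad, beta, sigma_w2


def lmm_loglikelihood(
    y, t, therapist, doctor, beta, sigma2_t, sigma2_d, sigma2_w, include_effect=True
) -> float:
    """Marginal Gaussian log-likelihood at fixed parameter values.

    Used for cross-checks against a directly assembled dense covariance
    V = sigma_T^2 Z_T Z_T' + sigma_D^2 Z_D Z_D' + sigma_W^2 I.
    """
    data = _LMMData(y, np.asarray(t), np.asarray(therapist), np.asarray(doctor), include_effect)
    log_phi = np.log(
        np.array([max(sigma2_t, 1e-300) / sigma2_w, max(sigma2_d, 1e-300) / sigma2_w])
    )
    phi_t, phi_d = np.exp(log_phi)
    k, jj, n = data.k, data.j, data.n
    s = np.concatenate([np.full(k, np.sqrt(phi_t)), np.full(jj, np.sqrt(phi_d))])
    M = np.eye(k + jj) + s[:, None] * data.ZtZ * s[None, :]
    cf = linalg.cho_factor(M, lower=True)
    logdetW = 2.0 * np.sum(np.log(np.diag(cf[0])))
    resid_t = data.y - data.X @ np.asarray(beta, dtype=float)
    Ztr = s * ((data.Zty) - (data.ZtX @ np.asarray(beta, dtype=float)))
    rWr = float(resid_t @ resid_t - Ztr @ linalg.cho_solve(cf, Ztr))
    return float(
        -0.5 * n * np.log(2.0 * np.pi * sigma2_w)
        - 0.5 * logdetW
        - 0.5 * rWr / sigma2_w
    )


_LOG_PHI_BOUNDS = (-12.0, 4.0)
_STARTS = (np.array([-2.0, -2.0]), np.array([0.0, 0.0]), np.array([-6.0, -6.0]))


def fit_lmm_ml(y, t, therapist, doctor, include_effect=True) -> dict:
    """ML fit of the univariate working model by profile likelihood.

    Variance ratios are optimised on the log scale from several starts;
    fixed effects and sigma_W^2 come from GLS at the optimum.  Returns a
    dict with loglik, beta, sigma2_t/d/w and a convergence flag.
    """
    data = _LMMData(
        np.asarray(y, dtype=float),
        np.asarray(t, dtype=int),
        np.asarray(therapist, dtype=int),
        np.asarray(doctor, dtype=int),
        include_effect,
    )
    best = None
    bounds = [_LOG_PHI_BOUNDS, _LOG_PHI_BOUNDS]
    for x0 in _STARTS:
        try:
            res = optimize.minimize(
                data.profile_nll_grad,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
            )
        except (linalg.LinAlgError, ValueError):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        logger.warning("mixed-model fit failed to converge from all starts")
        return {"converged": False, "loglik": np.nan, "beta": None}
    nll, beta, sigma_w2 = data.profile_nll(best.x)
    phi_t, phi_d = np.exp(best.x)
    return {
        "converged": True,
        "loglik": -float(nll),
        "beta": beta,
        "beta1": float(beta[1]) if include_effect else 0.0,
        "sigma2_t": float(phi_t * sigma_w2),
        "sigma2_d": float(phi_d * sigma_w2),
        "sigma2_w": float(sigma_w2),
    }


def lmm_fit_and_lrt(dataset: pd.DataFrame, endpoint: str, nominal_alpha: float):
    """One-sided likelihood ratio test of the treatment effect on one endpoint.

    Fits the working model with and without the treatment term (the random
    structure unchanged), forms the signed root of the LRT statistic
    z = sign(beta1_hat) sqrt(2 (l1 - l0)) and the one-sided p-value
    1 - Phi(z).  A replicate whose fit fails is recorded as a
    non-rejection (conservative) with a logged flag.
    """
    col = f"y_{endpoint}"
    if col not in dataset.columns:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    y = dataset[col].to_numpy()
    t = dataset["arm"].to_numpy()
    therapist = dataset["therapist"].to_numpy()
    doctor = dataset["doctor"].to_numpy()
    fit1 = fit_lmm_ml(y, t, therapist, doctor, include_effect=True)
    fit0 = fit_lmm_ml(y, t, therapist, doctor, include_effect=False)
    if not (fit1["converged"] and fit0["converged"]):
        logger.warning("LRT recorded as non-rejection after fit failure")
        return 1.0, 0
    lam = max(2.0 * (fit1["loglik"] - fit0["loglik"]), 0.0)
    z = np.sign(fit1["beta1"]) * np.sqrt(lam)
    p_one = float(1.0 - norm.cdf(z))
    return p_one, int(p_one <= nominal_alpha)


def multilevel_reject_once(
    design: MultilevelDesign,
    params: MultilevelTrialParams,
    hypothesis: str,
    rng: np.random.Generator,
    decision_rule: str = "either",
) -> int:
    """One replicate: simulate, test both endpoints, combine.

    Under 'either' (the default decision rule) the trial is positive if at
    least one endpoint rejects at the nominal level; 'both' requires both.
    """
    data = multilevel_simulate_dataset(design, params, hypothesis, rng)
    _, rej_f = lmm_fit_and_lrt(data, "F", design.a)
    _, rej_d = lmm_fit_and_lrt(data, "D", design.a)
    if decision_rule == "either":
        return int(rej_f or rej_d)
    if decision_rule == "both":
        return int(rej_f and rej_d)
    raise ValueError(f"unknown decision rule {decision_rule!r}")


class MultilevelTrialSimulator:
    """Reject-indicator simulator for the two-endpoint multilevel trial."""

    hypotheses = frozenset({"null", "alternative"})

    def __init__(
        self,
        params: MultilevelTrialParams = MultilevelTrialParams(),
        decision_rule: str = "either",
    ):
        self.params = params
        self.decision_rule = decision_rule

    def simulate_once(self, x, hypothesis: str, rng: np.random.Generator) -> int:
        design = MultilevelDesign.from_array(x)
        return multilevel_reject_once(
            design, self.params, hypothesis, rng, self.decision_rule
        )


def default_multilevel_space() -> SolutionSpace:
    return SolutionSpace(
        names=("n1", "k", "r", "j", "a"),
        lower=np.array([50.0, 2.0, 0.5, 3.0, 0.05]),
        upper=np.array([100.0, 10.0, 1.5, 20.0, 0.2]),
        integer=np.array([True, True, False, True, False]),
    )


def _total_participants(x) -> float:
    n1 = round(x[0])
    return float(n1 + np.floor(x[2] * n1 + 0.5))


def make_pace_problem(
    params: MultilevelTrialParams = MultilevelTrialParams(),
    type2_threshold: float = 0.1,
    type1_threshold: float = 0.2,
    decision_rule: str = "either",
    space: SolutionSpace | None = None,
):
    """The multilevel pilot-trial problem as a (ProblemSpec, simulator) pair.

    Three objectives (total participants, therapists, doctors); two
    simulation-estimated constraints (type II error under H1 at
    ``type2_threshold``; familywise type I error under the global null at
    ``type1_threshold``).
    """
    from ..ego import Constraint, ProblemSpec

    space = space or default_multilevel_space()
    problem = ProblemSpec(
        space=space,
        objectives=[
            _total_participants,
            lambda x: float(round(x[1])),
            lambda x: float(round(x[3])),
        ],
        objective_names=("total_participants", "therapists", "doctors"),
        constraints=[
            Constraint(
                name="type2_error",
                hypothesis="alternative",
                threshold=type2_threshold,
                complement=True,
            ),
            Constraint(
                name="type1_error",
                hypothesis="null",
                threshold=type1_threshold,
                complement=False,
            ),
        ],
    )
    return problem, MultilevelTrialSimulator(params, decision_rule)
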