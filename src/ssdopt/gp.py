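"""Gaussian-process regression with fixed heteroscedastic Monte-Carlo noise.

The surrogate for each simulation-estimated operating characteristic is a
zero-mean GP (after centering) with a squared-exponential kernel

    k(x, x') = sigma * exp(-sum_j (x_j - x'_j)^2 / lambda_j^2)

over inputs affinely mapped to the unit box.  Observation noise is the
known binomial MC variance omega^2 of each estimate, entering as a fixed
diagonal Delta: it is an input of the model, not an estimated nugget.
Hyperparameters (sigma, lambda_1..lambda_D) are chosen by maximising the
log marginal likelihood over a bounded log-scale box from multiple starts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GPHyperparams",
    "PredictiveDistribution",
    "se_kernel",
    "se_kernel_matrix",
    "log_marginal_likelihood",
    "GaussianProcess",
    "fit_gp",
]

logger = logging.getLogger(__name__)

_JITTER_START = 1e-8
_JITTER_MAX = 1e-4


@dataclass(frozen=True)
class GPHyperparams:
    """Kernel hyperparameters: signal variance and per-dimension length-scales."""

    signal_variance: float
    length_scales: np.ndarray

    def __post_init__(self) -> None:
        ls = np.atleast_1d(np.asarray(self.length_scales, dtype=float))
        if not (np.isfinite(self.signal_variance) and self.signal_variance > 0):
            raise ValueError("signal_variance must be positive and finite")
        if not np.all(np.isfinite(ls) & (ls > 0)):
            raise ValueError("length_scales must be positive and finite")
        object.__setattr__(self, "length_scales", ls)


@dataclass(frozen=True)
class PredictiveDistribution:
    """Normal predictive distribution (m, s^2) at a single point."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "variance", max(float(self.variance), 0.0))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def se_kernel(x, x2, hp: GPHyperparams) -> float:
    """Squared-exponential covariance between two (scaled) points."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    if x.shape != x2.shape or x.shape != hp.length_scales.shape:
        raise ValueError("dimension mismatch between points and hyperparameters")
    d2 = np.sum(((x - x2) / hp.length_scales) ** 2)
    return float(hp.signal_variance * np.exp(-d2))


def se_kernel_matrix(X1: np.ndarray, X2: np.ndarray, hp: GPHyperparams) -> np.ndarray:
    X1 = np.atleast_2d(X1) / hp.length_scales
    X2 = np.atleast_2d(X2) / hp.length_scales
    d2 = (
        np.sum(X1**2, axis=1)[:, None]
        + np.sum(X2**2, axis=1)[None, :]
        - 2.0 * X1 @ X2.T
    )
    return hp.signal_variance * np.exp(-np.maximum(d2, 0.0))


def _chol_with_jitter(A: np.ndarray, context: str = ""):
    jitter = 0.0
    while True:
        try:
            return linalg.cho_factor(
                A + jitter * np.eye(A.shape[0]), lower=True
            ), jitter
        except linalg.LinAlgError:
            jitter = _JITTER_START if jitter == 0.0 else jitter * 10.0
            if jitter > _JITTER_MAX:
                raise linalg.LinAlgError(
                    f"covariance not positive definite after maximal jitter {context}"
                )


def log_marginal_likelihood(
    X: np.ndarray, y_centered: np.ndarray, noise_var: np.ndarray, hp: GPHyperparams
) -> float:
    """Log marginal likelihood of centered targets under the GP.

    -1/2 y'(K+Delta)^-1 y - 1/2 log|K+Delta| - (n/2) log 2pi, with Delta the
    fixed diagonal of MC noise variances.
    """
    X = np.atleast_2d(X)
    y = np.asarray(y_centered, dtype=float)
    n = y.shape[0]
    K = se_kernel_matrix(X, X, hp) + np.diag(np.asarray(noise_var, dtype=float))
    try:
        cf, _ = _chol_with_jitter(K, context=f"at hyperparameters {hp}")
    except linalg.LinAlgError:
        raise
    alpha = linalg.cho_solve(cf, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi))


class GaussianProcess(RegressorMixin, BaseEstimator):
    """GP regressor with known per-point noise variances.

    Parameters
    ----------
    bounds : (lower, upper) arrays or None
        Box used to map raw inputs onto the unit square before kernel
        evaluation.  When None, the bounds are inferred from the training
        inputs (with a guard for zero-width dimensions).
    n_restarts : int
        Number of multi-start local maximisations of the log marginal
        likelihood (quasi-random starts in the log-hyperparameter box).
    log_lambda_bounds, log_sigma_bounds : tuple of float
        Search bounds for log length-scales (unit-box scale) and log signal
        variance.
    random_state : int
        Seed for the start-point design.

    Attributes (after :meth:`fit`)
    ------------------------------
    hyperparams_ : GPHyperparams
    X_train_ : scaled training inputs
    y_offset_ : centering offset (empirical target mean)
    log_marginal_likelihood_value_ : achieved LML
    """

    def __init__(
        self,
        bounds=None,
        n_restarts: int = 10,
        log_lambda_bounds=(np.log(0.01), np.log(10.0)),
        log_sigma_bounds=(np.log(1e-6), np.log(1.0)),
        random_state: int = 0,
    ):
        self.bounds = bounds
        self.n_restarts = n_restarts
        self.log_lambda_bounds = log_lambda_bounds
        self.log_sigma_bounds = log_sigma_bounds
        self.random_state = random_state

    # -- internal ---------------------------------------------------------
    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_lower_) / self.scale_width_

    def _resolve_scaling(self, X: np.ndarray) -> None:
        if self.bounds is not None:
            lower = np.asarray(self.bounds[0], dtype=float)
            upper = np.asarray(self.bounds[1], dtype=float)
        else:
            lower = X.min(axis=0)
            upper = X.max(axis=0)
        width = upper - lower
        width[width <= 0] = 1.0
        self.scale_lower_ = lower
        self.scale_width_ = width

    def _theta_to_hp(self, theta: np.ndarray, d: int) -> GPHyperparams:
        return GPHyperparams(float(np.exp(theta[0])), np.exp(theta[1 : 1 + d]))

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y, noise_var=None):
        """Fit hyperparameters by multi-start maximum marginal likelihood.

        ``noise_var`` holds the fixed MC noise variance omega^2 per target
        (zeros allowed: jitter protects the factorisation).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0] or X.shape[0] < 2:
            raise ValueError("need >=2 training points with matching targets")
        if not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")
        noise_var = (
            np.zeros(y.shape[0])
            if noise_var is None
            else np.asarray(noise_var, dtype=float)
        )
        self._resolve_scaling(X)
        Xs = self._scale(X)
        self.y_offset_ = float(np.mean(y))
        yc = y - self.y_offset_
        d = X.shape[1]

        lo = np.array([self.log_sigma_bounds[0]] + [self.log_lambda_bounds[0]] * d)
        hi = np.array([self.log_sigma_bounds[1]] + [self.log_lambda_bounds[1]] * d)

        def nll(theta):
            try:
                return -log_marginal_likelihood(
                    Xs, yc, noise_var, self._theta_to_hp(theta, d)
                )
            except linalg.LinAlgError:
                return 1e12

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sampler = qmc.Sobol(d + 1, scramble=True, seed=self.random_state)
            starts = lo + sampler.random(max(self.n_restarts, 1)) * (hi - lo)
        # Seed one start from data: empirical target variance and median scale.
        heur = np.concatenate(
            [[np.log(max(np.var(yc), 1e-6))], np.full(d, np.log(0.5))]
        )
        starts = np.vstack([np.clip(heur, lo, hi), starts])

        best_theta, best_val = None, np.inf
        for theta0 in starts:
            try:
                res = optimize.minimize(
                    nll, theta0, method="L-BFGS-B", bounds=list(zip(lo, hi))
                )
                cand_val = min(res.fun, nll(theta0))
                cand = res.x if res.fun <= nll(theta0) else theta0
            except Exception:  # pragma: no cover - defensive
                continue
            if cand_val < best_val:
                best_val, best_theta = cand_val, cand
        if best_theta is None or not np.isfinite(best_val):
            logger.warning("all LML starts failed; falling back to median heuristic")
            best_theta = np.clip(heur, lo, hi)
            best_val = nll(best_theta)

        self.hyperparams_ = self._theta_to_hp(best_theta, d)
        self.log_marginal_likelihood_value_ = -float(best_val)
        self.X_train_ = Xs
        self.y_train_ = y
        self.noise_var_ = noise_var
        K = se_kernel_matrix(Xs, Xs, self.hyperparams_) + np.diag(noise_var)
        self._chol_, self._jitter_ = _chol_with_jitter(K, context="at fitted hyperparameters")
        self._alpha_ = linalg.cho_solve(self._chol_, yc)
        return self

    def predict(self, X, return_std: bool = False):
        """Predictive mean (and sd) at raw-coordinate query points.

        mean = k*'(K+Delta)^-1 y_c + offset;
        var  = k(x*,x*) - k*'(K+Delta)^-1 k*, clipped at zero.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = self._scale(X)
        Kstar = se_kernel_matrix(Xs, self.X_train_, self.hyperparams_)
        mean = Kstar @ self._alpha_ + self.y_offset_
        if not return_std:
            return mean
        v = linalg.cho_solve(self._chol_, Kstar.T)
        var = self.hyperparams_.signal_variance - np.einsum("ij,ji->i", Kstar, v)
        return mean, np.sqrt(np.clip(var, 0.0, None))

    def predict_dist(self, x) -> PredictiveDistribution:
        m, s = self.predict(np.atleast_2d(x), return_std=True)
        return PredictiveDistribution(float(m[0]), float(s[0] ** 2))

    # -- checkpointing ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "signal_variance": self.hyperparams_.signal_variance,
            "length_scales": self.hyperparams_.length_scales.tolist(),
            "scale_lower": self.scale_lower_.tolist(),
            "scale_width": self.scale_width_.tolist(),
            "X_train_scaled": self.X_train_.tolist(),
            "y_train": self.y_train_.tolist(),
            "noise_var": self.noise_var_.tolist(),
            "y_offset": self.y_offset_,
            "log_marginal_likelihood": self.log_marginal_likelihood_value_,
            "params": {
                "n_restarts": self.n_restarts,
                "random_state": self.random_state,
            },
        }

    @classmethod
    def from_dict(cls, state: dict) -> "GaussianProcess":
        gp = cls(
            n_restarts=state["params"]["n_restarts"],
            random_state=state["params"]["random_state"],
        )
        gp.hyperparams_ = GPHyperparams(
            state["signal_variance"], np.asarray(state["length_scales"])
        )
        gp.scale_lower_ = np.asarray(state["scale_lower"])
        gp.scale_width_ = np.asarray(state["scale_width"])
        gp.X_train_ = np.asarray(state["X_train_scaled"])
        gp.y_train_ = np.asarray(state["y_train"])
        gp.noise_var_ = np.asarray(state["noise_var"])
        gp.y_offset_ = state["y_offset"]
        gp.log_marginal_likelihood_value_ = state["log_marginal_likelihood"]
        K = se_kernel_matrix(gp.X_train_, gp.X_train_, gp.hyperparams_) + np.diag(
            gp.noise_var_
        )
        gp._chol_, gp._jitter_ = _chol_with_jitter(K)
        gp._alpha_ = linalg.cho_solve(gp._chol_, gp.y_train_ - gp.y_offset_)
        return gp


def fit_gp(
    train_inputs, train_targets, noise_diag, bounds=None, n_restarts=10, random_state=0
) -> GaussianProcess:
    """Functional wrapper over :class:`GaussianProcess`."""
    return GaussianProcess(
        bounds=bounds, n_restarts=n_restarts, random_state=random_state
    ).fit(train_inputs, train_targets, noise_var=noise_diag)
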