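"""Constrained expected hypervolume improvement for MC-noisy constraints.

A design is *deemed feasible* when the upper 100p% quantile of the GP
predictive distribution of every constraint, q(x) = m + Phi^-1(p) s, is
at or below zero.  Before an evaluation with planned MC error omega, the
post-evaluation quantile q+ is itself normal with

    m+ = m + Phi^-1(p) sqrt(omega^2 s^2 / (omega^2 + s^2))
    s+^2 = s^4 / (omega^2 + s^2)

(the noisy-Kriging one-step update; omega -> 0 gives (m, s), omega -> inf
gives (q, 0)).  The acquisition value of a candidate is its hypervolume
gain over the current approximation set multiplied by the probability
Phi(-m+/s+) of being deemed feasible for every constraint; it is
maximised globally by particle swarm over the continuous design box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .pareto import hvi_batch_2d, hypervolume_improvement

__all__ = [
    "FeasibilityRule",
    "QuantileUpdatePrediction",
    "feasibility_quantile",
    "predict_updated_quantile",
    "prob_deemed_feasible",
    "expected_improvement",
    "maximize_ei",
    "PSOSettings",
]

logger = logging.getLogger(__name__)

_MEAN_CLIP = (0.001, 0.999)  # planned-evaluation MC error uses a clipped OC mean


@dataclass(frozen=True)
class FeasibilityRule:
    """Quantile level p of the 'deemed feasible' rule (fixed for a run)."""

    quantile_level: float = 0.9

    def __post_init__(self) -> None:
        # p = 0.5 (q collapses to the predictive mean) is allowed as the
        # non-conservative edge case; p >= 1 would make q infinite.
        if not 0.5 <= self.quantile_level < 1.0:
            raise ValueError("quantile_level must lie in [0.5, 1)")

    @property
    def z(self) -> float:
        return float(norm.ppf(self.quantile_level))


@dataclass(frozen=True)
class QuantileUpdatePrediction:
    """Normal predictive distribution of the post-evaluation quantile."""

    mean_plus: float
    sd_plus: float


def feasibility_quantile(mean, sd, rule: FeasibilityRule):
    """q = m + Phi^-1(p) s; the design is deemed feasible iff q <= 0."""
    return np.asarray(mean, dtype=float) + rule.z * np.asarray(sd, dtype=float)


def predict_updated_quantile(
    mean, sd, planned_omega, rule: FeasibilityRule
) -> QuantileUpdatePrediction:
    """Distribution N(m+, s+^2) of the feasibility quantile after evaluation."""
    m = float(mean)
    s2 = float(sd) ** 2
    if np.isinf(planned_omega):
        # an uninformative evaluation leaves the quantile where it stands
        return QuantileUpdatePrediction(m + rule.z * float(sd), 0.0)
    w2 = float(planned_omega) ** 2
    if s2 == 0.0 and w2 == 0.0:
        return QuantileUpdatePrediction(m, 0.0)
    denom = w2 + s2
    m_plus = m + rule.z * np.sqrt(w2 * s2 / denom)
    s_plus = np.sqrt(s2 * s2 / denom)
    return QuantileUpdatePrediction(float(m_plus), float(s_plus))


def prob_deemed_feasible(qup: QuantileUpdatePrediction) -> float:
    """Phi(-m+ / s+); a degenerate s+ = 0 collapses to the indicator m+ <= 0."""
    if qup.sd_plus == 0.0:
        return 1.0 if qup.mean_plus <= 0.0 else 0.0
    return float(norm.cdf(-qup.mean_plus / qup.sd_plus))


def _feasibility_products(
    X: np.ndarray, constraint_models, thresholds, rule: FeasibilityRule, planned_n: int
) -> np.ndarray:
    """Vectorised product over constraints of Phi(-m+/s+) at each row of X."""
    prod = np.ones(X.shape[0])
    for model, thr in zip(constraint_models, thresholds):
        m_oc, s = model.predict(X, return_std=True)
        m = m_oc - thr
        m_clip = np.clip(m_oc, *_MEAN_CLIP)
        w2 = m_clip * (1.0 - m_clip) / planned_n
        s2 = s**2
        denom = w2 + s2
        with np.errstate(divide="ignore", invalid="ignore"):
            m_plus = m + rule.z * np.sqrt(np.where(denom > 0, w2 * s2 / denom, 0.0))
            s_plus = np.sqrt(np.where(denom > 0, s2 * s2 / denom, 0.0))
            z = np.where(s_plus > 0, -m_plus / np.where(s_plus > 0, s_plus, 1.0), np.nan)
        p = np.where(s_plus > 0, norm.cdf(z), (m_plus <= 0).astype(float))
        prod *= p
    return prod


def expected_improvement(
    x_star,
    objectives,
    constraint_models,
    thresholds,
    current_set,
    ref,
    rule: FeasibilityRule,
    planned_n: int,
) -> float:
    """EI(x) = [H(A u {f(x)}) - H(A)] * prod_j Phi(-m_{j,+}/s_{j,+}).

    ``objectives`` maps a design point to its (cheap, deterministic)
    objective vector; each constraint GP models the operating
    characteristic itself, with its nominal threshold subtracted at
    quantile time.  The planned MC error of each constraint uses the GP
    predictive mean clipped to [0.001, 0.999].
    """
    x = np.atleast_1d(np.asarray(x_star, dtype=float))
    y = np.asarray(objectives(x), dtype=float)
    hvi = hypervolume_improvement(current_set, y, ref)
    if hvi == 0.0:
        return 0.0
    prod = _feasibility_products(x[None, :], constraint_models, thresholds, rule, planned_n)
    return float(hvi * prod[0])


@dataclass(frozen=True)
class PSOSettings:
    """Particle-swarm settings for the inner acquisition maximisation."""

    swarm_size: int = 40
    iterations: int = 200
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618


def maximize_ei(
    constraint_models,
    thresholds,
    current_set,
    ref,
    rule: FeasibilityRule,
    space,
    objectives,
    planned_n: int,
    rng: np.random.Generator,
    settings: PSOSettings = PSOSettings(),
    return_details: bool = False,
):
    """Globally maximise EI over the continuous box by particle swarm.

    Bounds are handled by clamping with velocity reflection.  If every EI
    value encountered is zero (nothing can improve the front), the point
    with the highest product of feasibility probabilities is returned as
    an exploration fallback (logged).
    """
    lo, hi = space.lower, space.upper
    d = space.dim
    n = settings.swarm_size
    pos = lo + rng.random((n, d)) * (hi - lo)
    vel = (rng.random((n, d)) - 0.5) * (hi - lo) * 0.2

    front = current_set.objective_array if hasattr(current_set, "objective_array") else np.asarray(current_set, dtype=float)
    two_d = front.shape[1] == 2 if front.size else len(np.atleast_1d(ref)) == 2

    def batch_ei(P: np.ndarray):
        feas = _feasibility_products(P, constraint_models, thresholds, rule, planned_n)
        Y = np.array([np.asarray(objectives(p), dtype=float) for p in P])
        if two_d:
            hvi = hvi_batch_2d(front, Y, ref)
        else:
            hvi = np.array(
                [hypervolume_improvement(front, y, ref) for y in Y]
            )
        return hvi * feas, feas

    ei, feas = batch_ei(pos)
    pbest, pbest_val = pos.copy(), ei.copy()
    gbest_i = int(np.argmax(ei))
    gbest, gbest_val = pos[gbest_i].copy(), ei[gbest_i]
    fallback, fallback_val = pos[int(np.argmax(feas))].copy(), feas.max()

    for _ in range(settings.iterations):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        vel = (
            settings.inertia * vel
            + settings.cognitive * r1 * (pbest - pos)
            + settings.social * r2 * (gbest - pos)
        )
        pos = pos + vel
        below, above = pos < lo, pos > hi
        pos = np.clip(pos, lo, hi)
        vel[below | above] *= -1.0
        ei, feas = batch_ei(pos)
        improved = ei > pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = ei[improved]
        i = int(np.argmax(pbest_val))
        if pbest_val[i] > gbest_val:
            gbest, gbest_val = pbest[i].copy(), pbest_val[i]
        j = int(np.argmax(feas))
        if feas[j] > fallback_val:
            fallback, fallback_val = pos[j].copy(), feas[j]

    if gbest_val <= 0.0:
        logger.info(
            "EI is zero everywhere searched; exploration fallback to the most "
            "plausibly feasible point (feasibility product %.3g)",
            fallback_val,
        )
        chosen, value = fallback, 0.0
    else:
        chosen, value = gbest, float(gbest_val)
    if not return_details:
        return chosen
    per_constraint = [
        float(
            _feasibility_products(
                chosen[None, :], [model], [thr], rule, planned_n
            )[0]
        )
        for model, thr in zip(constraint_models, thresholds)
    ]
    return chosen, value, per_constraint
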