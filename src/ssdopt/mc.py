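"""Monte Carlo estimation of trial operating characteristics.

A trial simulator maps (design, hypothesis) to a binary reject indicator
per replicate.  Averaging N independent indicators gives an unbiased
estimate of the operating characteristic (power, type I error rate, ...)
with binomial standard error omega = sqrt(p(1-p)/N); for large N the
estimate behaves as the truth plus N(0, omega^2) noise, which is the
error model the Gaussian-process surrogate consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

__all__ = [
    "TrialSimulator",
    "MCEstimate",
    "estimate_oc",
    "mc_standard_error",
    "pool_estimates",
    "spawn_rng",
]


@runtime_checkable
class TrialSimulator(Protocol):
    """Contract for user-supplied trial simulators.

    ``simulate_once`` must return exactly 0 or 1 (reject indicator for one
    simulated trial) and be reproducible given the same generator state.
    A simulator may additionally expose ``simulate_batch(x, hypothesis,
    n, rng) -> array`` returning ``n`` indicators; when present it is used
    for speed and must be distributionally identical to ``simulate_once``.
    """

    hypotheses: frozenset[str]

    def simulate_once(
        self, x: np.ndarray, hypothesis: str, rng: np.random.Generator
    ) -> int: ...


@dataclass(frozen=True)
class MCEstimate:
    """A Monte Carlo estimate of a probability with its binomial error."""

    estimate: float
    n_samples: int
    successes: int
    std_error: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.successes <= self.n_samples:
            raise ValueError("successes must lie in [0, n_samples]")

    @property
    def complement(self) -> "MCEstimate":
        """The estimate of the complementary event (e.g. power -> type II)."""
        return MCEstimate(
            estimate=1.0 - self.estimate,
            n_samples=self.n_samples,
            successes=self.n_samples - self.successes,
            std_error=self.std_error,
        )


def mc_standard_error(p_hat: float, n_samples: int) -> float:
    """Binomial standard error sqrt(p(1-p)/N) of an MC probability estimate.

    ``p_hat`` is clipped to [0.5/N, 1 - 0.5/N] first, so the returned value
    is strictly positive even for degenerate estimates of 0 or 1: a zero
    error would be an artefact of finite N, not certainty, and would put a
    zero on the GP noise diagonal.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    half = 0.5 / n_samples
    p = min(max(p_hat, half), 1.0 - half)
    return float(np.sqrt(p * (1.0 - p) / n_samples))


def _validate_binary(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    bad = ~((arr == 0) | (arr == 1))
    if np.any(bad):
        idx = int(np.nonzero(bad.ravel())[0][0])
        raise ValueError(
            f"simulator returned non-binary value {arr.ravel()[idx]!r} at "
            f"replicate {idx} for design {np.asarray(x).tolist()}"
        )
    return arr.astype(np.int64)


def estimate_oc(
    sim: TrialSimulator,
    x: np.ndarray,
    hypothesis: str,
    n_samples: int,
    rng: np.random.Generator,
) -> MCEstimate:
    """Estimate one operating characteristic by Monte Carlo.

    Runs ``n_samples`` replicates of ``sim`` at design ``x`` under the named
    hypothesis and averages the binary reject indicators.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if hypothesis not in sim.hypotheses:
        raise ValueError(
            f"unknown hypothesis {hypothesis!r}; simulator offers {sorted(sim.hypotheses)}"
        )
    batch = getattr(sim, "simulate_batch", None)
    if batch is not None:
        indicators = _validate_binary(batch(x, hypothesis, n_samples, rng), x)
        if indicators.shape != (n_samples,):
            raise ValueError("simulate_batch must return n_samples indicators")
    else:
        indicators = np.empty(n_samples, dtype=np.int64)
        for i in range(n_samples):
            val = sim.simulate_once(x, hypothesis, rng)
            arr = np.asarray(val)
            if arr.shape != () or not (arr == 0 or arr == 1):
                raise ValueError(
                    f"simulator returned non-binary value {val!r} at replicate "
                    f"{i} for design {np.asarray(x).tolist()}"
                )
            indicators[i] = int(arr)
    successes = int(indicators.sum())
    p_hat = successes / n_samples
    return MCEstimate(
        estimate=p_hat,
        n_samples=n_samples,
        successes=successes,
        std_error=mc_standard_error(p_hat, n_samples),
    )


def pool_estimates(estimates: Iterable[MCEstimate]) -> MCEstimate:
    """Pool independent MC estimates of the same probability.

    Successes and replicate counts add; the standard error is recomputed at
    the pooled sample size (it shrinks, tightening the GP noise entry for a
    re-proposed design).
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("nothing to pool")
    n = sum(e.n_samples for e in ests)
    s = sum(e.successes for e in ests)
    p = s / n
    return MCEstimate(p, n, s, mc_standard_error(p, n))


def spawn_rng(root_seed: int, *path: int) -> np.random.Generator:
    """An independent, reproducible substream of a single root seed.

    Streams are keyed by an integer path (e.g. evaluation index, constraint
    index), so a resumed run regenerates exactly the substreams it has not
    yet consumed.
    """
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(p) for p in path))
    return np.random.Generator(np.random.PCG64(ss))
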