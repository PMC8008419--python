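"""Bounded design-parameter spaces.

A candidate trial design is a point ``x`` in a box with per-dimension
integrality flags: sample sizes and cluster counts are integers, while
allocation ratios or nominal test levels are continuous.  Surrogate models
and the acquisition search operate on the continuous box; integer
dimensions are rounded (half-up) only when a design is actually evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SolutionSpace"]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class SolutionSpace:
    """A bounded box of design parameters with integrality flags.

    Parameters
    ----------
    names : tuple of str
        One name per design dimension (e.g. ``("k", "n")``).
    lower, upper : array-like
        Inclusive box bounds, one entry per dimension.
    integer : array-like of bool, optional
        True for dimensions that must take integer values at evaluation
        time.  Defaults to all-continuous.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    integer: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        integer = (
            np.zeros(lower.shape, dtype=bool)
            if self.integer is None
            else np.asarray(self.integer, dtype=bool)
        )
        if not (lower.shape == upper.shape == integer.shape == (len(self.names),)):
            raise ValueError("names, lower, upper and integer must have equal length")
        if np.any(upper <= lower):
            bad = [self.names[i] for i in np.nonzero(upper <= lower)[0]]
            raise ValueError(f"zero- or negative-width dimension(s): {bad}")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "integer", integer)

    @property
    def dim(self) -> int:
        return len(self.names)

    def scale(self, x: np.ndarray) -> np.ndarray:
        """Affinely map raw design values onto the unit box."""
        x = np.asarray(x, dtype=float)
        return (x - self.lower) / (self.upper - self.lower)

    def unscale(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        return self.lower + u * (self.upper - self.lower)

    def round_point(self, x: np.ndarray) -> np.ndarray:
        """Round integer dimensions half-up; clip everything to the box."""
        x = np.clip(np.asarray(x, dtype=float), self.lower, self.upper)
        out = x.copy()
        out[..., self.integer] = _round_half_up(x[..., self.integer])
        return np.clip(out, self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )

    def key(self, x: np.ndarray) -> tuple:
        """Hashable identity of an evaluated design (post-rounding)."""
        x = self.round_point(x)
        return tuple(
            int(v) if flag else float(v)
            for v, flag in zip(np.atleast_1d(x), self.integer)
        )
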