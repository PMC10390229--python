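"""Deterministic mathematics of the adjacent-category rating-scale model.

The model places plots, rating events, and category boundaries on a common
latent logit scale.  For a plot with perceived quality ``theta`` rated in an
event with severity ``beta``, the log-odds between two adjacent rating
categories ``s`` and ``s - 1`` is

    ln( p[s] / p[s-1] ) = theta - beta - tau[s]

where ``tau[s]`` is the threshold at which the two categories are equally
probable.  Normalising these adjacent log-odds over the ``M + 1`` categories
(ratings are re-indexed from the 1-9 field scale to 0..M) gives the standard
adjacent-category (Rasch rating-scale) probabilities

    p[s] = exp(s*c - T[s]) / sum_r exp(r*c - T[r]),   c = theta - beta,

with ``T[s] = tau[1] + ... + tau[s]`` and ``T[0] = 0``.  Everything in this
module is pure computation; the inference, simulation, and diagnostics
modules build on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "CategoryThresholds",
    "LatentState",
    "CategoryProbabilities",
    "reindex_ratings",
    "complete_sum_to_zero",
    "category_probabilities",
    "category_probability_matrix",
    "adjacent_logit",
    "expected_category",
]

#: Maximum number of thresholds supported by the 1-9 field scale.
MAX_THRESHOLDS = 8

_SUM_TOL = 1e-8


class ValidationError(ValueError):
    """Raised when input data violate a documented precondition."""


@dataclass(frozen=True)
class CategoryThresholds:
    """Threshold vector ``tau`` on the latent logit scale.

    ``tau`` has length ``M`` (one threshold per adjacent-category boundary)
    and sums to zero: the last element is the negative sum of the others,
    anchoring the zero of the latent scale.  No ordering is imposed —
    disordered thresholds are a diagnosable data condition, not an error.
    """

    tau: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 1 or not (1 <= tau.size <= MAX_THRESHOLDS):
            raise ValidationError(
                f"tau must be a 1-d vector of length 1..{MAX_THRESHOLDS}, "
                f"got shape {tau.shape}"
            )
        if not np.all(np.isfinite(tau)):
            raise ValidationError("tau contains non-finite values")
        if abs(tau.sum()) > _SUM_TOL * max(1.0, np.abs(tau).max()):
            raise ValidationError(
                f"tau must sum to zero (got sum {tau.sum():.3e}); "
                "construct via CategoryThresholds.from_free"
            )
        object.__setattr__(self, "tau", tau)

    @property
    def M(self) -> int:
        """Number of thresholds == maximum re-indexed rating."""
        return self.tau.size

    @classmethod
    def from_free(cls, free: np.ndarray) -> "CategoryThresholds":
        """Build a sum-to-zero threshold vector from its M-1 free components."""
        return cls(complete_sum_to_zero(free))

    @classmethod
    def evenly_spaced(cls, lo: float, hi: float, M: int) -> "CategoryThresholds":
        """M thresholds evenly spaced on [lo, hi]; must already sum to zero."""
        return cls(np.linspace(lo, hi, M))

    @property
    def is_ordered(self) -> bool:
        return bool(np.all(np.diff(self.tau) > 0)) if self.M > 1 else True

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative sums ``T[s] = tau[1] + .. + tau[s]`` with ``T[0] = 0``."""
        return np.concatenate([[0.0], np.cumsum(self.tau)])


@dataclass(frozen=True)
class LatentState:
    """Latent position of one plot x rating-event cell.

    ``theta`` is the plot's perceived quality and ``beta`` the event's rating
    severity, both in logit units; probabilities depend on them only through
    the difference ``theta - beta``.
    """

    theta: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and np.isfinite(self.beta)):
            raise ValidationError("theta and beta must be finite")


@dataclass(frozen=True)
class CategoryProbabilities:
    """Probabilities of the M+1 rating categories 0..M for one cell."""

    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValidationError("p must be a 1-d vector of >= 2 probabilities")
        # strictly interior in exact arithmetic; zeros only via underflow at
        # extreme latent positions, which must not raise
        if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
            raise ValidationError("category probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(f"probabilities must sum to 1 (got {p.sum()!r})")
        object.__setattr__(self, "p", p)

    @property
    def M(self) -> int:
        return self.p.size - 1


def reindex_ratings(raw_ratings) -> np.ndarray:
    """Map field-scale ratings 1..9 to the model's 0..8 categories.

    Raises :class:`ValidationError` naming the first offending row if a value
    is non-integer or outside [1, 9].
    """
    raw = np.asarray(raw_ratings)
    if raw.size == 0:
        return np.asarray([], dtype=int)
    as_float = raw.astype(float)
    rounded = np.round(as_float)
    bad = ~np.isfinite(as_float) | (as_float != rounded) | (rounded < 1) | (rounded > 9)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValidationError(
            f"rating {raw.ravel()[idx]!r} at row {idx} is not an integer in [1, 9]"
        )
    return rounded.astype(int) - 1


def complete_sum_to_zero(free_params) -> np.ndarray:
    """Append the negative sum so the completed vector sums to zero."""
    free = np.asarray(free_params, dtype=float)
    if free.ndim != 1 or free.size == 0:
        raise ValidationError("free_params must be a non-empty 1-d vector")
    return np.concatenate([free, [-free.sum()]])


def _log_unnormalized(c: float | np.ndarray, cum_tau: np.ndarray) -> np.ndarray:
    """Log unnormalised category weights s*c - T[s] for s = 0..M."""
    s = np.arange(cum_tau.size)
    return np.multiply.outer(np.asarray(c, dtype=float), s) - cum_tau


def category_probabilities(
    state: LatentState, thresholds: CategoryThresholds
) -> CategoryProbabilities:
    """Category probabilities for one plot x event cell.

    Overflow-safe: the maximum log-weight is subtracted before
    exponentiating, so extreme latent positions cannot overflow.
    """
    c = state.theta - state.beta
    logw = _log_unnormalized(c, thresholds.cumulative).ravel()
    logw -= logw.max()
    w = np.exp(logw)
    p = w / w.sum()
    if not np.all(np.isfinite(p)):
        raise ValidationError(
            f"non-finite probabilities for theta-beta={c!r}, tau={thresholds.tau!r}"
        )
    return CategoryProbabilities(p)


def category_probability_matrix(c: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Vectorised category probabilities.

    Parameters
    ----------
    c
        Array of latent differences ``theta - beta``, any shape.
    tau
        Threshold vector of length M (must sum to zero is *not* required
        here; callers inside the sampler pass structurally completed
        vectors).

    Returns
    -------
    Array of shape ``c.shape + (M + 1,)`` of probabilities.
    """
    cum = np.concatenate([[0.0], np.cumsum(np.asarray(tau, dtype=float))])
    logw = _log_unnormalized(np.asarray(c, dtype=float), cum)
    logw -= logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=-1, keepdims=True)


def adjacent_logit(p: CategoryProbabilities, s: int) -> float:
    """Log-odds ``ln(p[s]/p[s-1])`` between adjacent categories.

    Round-trips with :func:`category_probabilities`: the result equals
    ``theta - beta - tau[s]`` for the constructing parameters.
    """
    if not (1 <= s <= p.M):
        raise IndexError(f"s must be in 1..{p.M}, got {s}")
    return float(np.log(p.p[s]) - np.log(p.p[s - 1]))


def expected_category(p: CategoryProbabilities | np.ndarray) -> float | np.ndarray:
    """Expected rating E[Y] under the category distribution(s)."""
    arr = p.p if isinstance(p, CategoryProbabilities) else np.asarray(p)
    s = np.arange(arr.shape[-1])
    return arr @ s
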