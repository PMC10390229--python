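"""Trial geometry and the Gaussian-process covariance for plot-location effects.

Within-field heterogeneity (soil texture, drainage, edge effects, ...) makes
neighbouring plots look more alike than distant ones.  The plot-location
effect LOC is modelled as a zero-mean Gaussian process over plot centres with
an exponentiated-quadratic covariance plus an independent per-plot nugget:

    K[i, j] = alpha^2 * exp(-d_ij^2 / (2 rho^2)) + delta_ij * sigma_e^2

where ``d_ij`` is the Euclidean distance between plot centres, ``alpha`` the
marginal spatial scale (logit units), ``rho`` the correlation length in
plot-length units, and ``sigma_e`` the nugget scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import ValidationError

__all__ = [
    "TrialLayout",
    "GpHyperparams",
    "pairwise_distances",
    "exp_quad_covariance",
    "draw_gp_field",
]

_JITTER = 1e-9


@dataclass(frozen=True)
class GpHyperparams:
    """Hyperparameters of the spatial covariance; all strictly positive."""

    alpha: float
    rho: float
    sigma_e: float

    def __post_init__(self) -> None:
        for name in ("alpha", "rho", "sigma_e"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class TrialLayout:
    """Plot grid of a trial: ids, row/column indices, and centre coordinates.

    When only row/column indices are known, plot centres default to
    ``(x, y) = (col, row)`` in unit plot-lengths.
    """

    plot_ids: np.ndarray
    row: np.ndarray
    col: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.plot_ids)
        row = np.asarray(self.row, dtype=int)
        col = np.asarray(self.col, dtype=int)
        n = ids.size
        if not (row.size == col.size == n) or n == 0:
            raise ValidationError("plot_ids, row, col must be equal-length, non-empty")
        if np.any(row < 1) or np.any(col < 1):
            raise ValidationError("row and col indices are 1-based (>= 1)")
        if len({(r, c) for r, c in zip(row, col)}) != n:
            raise ValidationError("(row, col) pairs must be unique across plots")
        if len(set(ids.tolist())) != n:
            raise ValidationError("plot_ids must be unique")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValidationError("plot coordinates must be finite")
        for name, v in (("plot_ids", ids), ("row", row), ("col", col), ("x", x), ("y", y)):
            object.__setattr__(self, name, v)

    @property
    def n_plots(self) -> int:
        return self.plot_ids.size

    @classmethod
    def from_grid(
        cls, rows: int, cols: int, plot_ids: Sequence | None = None
    ) -> "TrialLayout":
        """Full rows x cols grid with unit spacing; ids default to P001.."""
        rr, cc = np.meshgrid(np.arange(1, rows + 1), np.arange(1, cols + 1), indexing="ij")
        rr, cc = rr.ravel(), cc.ravel()
        if plot_ids is None:
            plot_ids = np.array([f"P{i + 1:03d}" for i in range(rr.size)])
        return cls(np.asarray(plot_ids), rr, cc, cc.astype(float), rr.astype(float))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialLayout":
        """Build from a table with columns plot_id, row, col and optional x, y."""
        required = {"plot_id", "row", "col"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"layout table missing columns: {sorted(missing)}")
        x = df["x"].to_numpy(float) if "x" in df else df["col"].to_numpy(float)
        y = df["y"].to_numpy(float) if "y" in df else df["row"].to_numpy(float)
        return cls(df["plot_id"].to_numpy(), df["row"].to_numpy(int),
                   df["col"].to_numpy(int), x, y)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"plot_id": self.plot_ids, "row": self.row, "col": self.col,
             "x": self.x, "y": self.y}
        )

    def index_of(self, plot_ids) -> np.ndarray:
        """Positions of the given plot ids within this layout."""
        lookup = {pid: i for i, pid in enumerate(self.plot_ids.tolist())}
        try:
            return np.array([lookup[p] for p in np.asarray(plot_ids).tolist()], dtype=int)
        except KeyError as err:
            raise ValidationError(f"unknown plot id {err.args[0]!r}") from None


def pairwise_distances(layout: TrialLayout) -> np.ndarray:
    """Symmetric matrix of Euclidean distances between plot centres."""
    pts = np.column_stack([layout.x, layout.y])
    if layout.n_plots == 1:
        return np.zeros((1, 1))
    d = squareform(pdist(pts))
    off = d[np.triu_indices_from(d, k=1)]
    if off.size and np.any(off == 0.0):
        warnings.warn(
            "duplicate plot coordinates: distinct plots at zero distance "
            "(the nugget keeps the covariance positive definite)",
            stacklevel=2,
        )
    return d


def exp_quad_covariance(d: np.ndarray, hp: GpHyperparams) -> np.ndarray:
    """Exponentiated-quadratic covariance with nugget on the diagonal."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    nugget = hp.sigma_e**2
    if nugget < _JITTER:
        warnings.warn(
            f"sigma_e^2 below {_JITTER}: adding jitter {_JITTER} for stability",
            stacklevel=2,
        )
        nugget = nugget + _JITTER
    K = hp.alpha**2 * np.exp(-(d**2) / (2.0 * hp.rho**2))
    K[np.diag_indices_from(K)] += nugget
    return K


def draw_gp_field(
    layout: TrialLayout,
    hp: GpHyperparams,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One zero-mean multivariate-normal draw of the plot-location effects.

    Reproducible: the same seed yields the same field.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = exp_quad_covariance(pairwise_distances(layout), hp)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as err:  # unreachable with nugget > 0
        raise ValidationError(f"covariance factorization failed: {err}") from err
    return L @ rng.standard_normal(layout.n_plots)
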