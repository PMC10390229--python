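"""Applied diagnostics: rating histograms, threshold geometry, severity
trends, spatial maps, cross-location alignment, and variance partitioning.

Every output is a plain table (DataFrame or array); figure rendering is left
to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import CategoryThresholds, ValidationError
from .inference import PosteriorSamples
from .model import ObservationData
from .spatial import TrialLayout

__all__ = [
    "monthly_histograms",
    "category_widths",
    "severity_trend",
    "spatial_map",
    "cross_location_table",
    "variance_partition",
    "VariancePartition",
]

MIN_RATINGS_FOR_TREND = 3  # raters with more than 3 ratings get a trend line


def monthly_histograms(data: pd.DataFrame, rating_column: str = "rating") -> pd.DataFrame:
    """Per-calendar-month counts of each 1-9 category, with range and median.

    Expects ratings on the 1-9 interchange scale and a ``month`` column;
    rows with a missing month are excluded with a warning.  Returns one row
    per observed month with columns ``count_1 .. count_9``, ``lo``, ``hi``,
    ``median``.
    """
    for col in ("month", rating_column):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    df = data[["month", rating_column]].copy()
    missing = df["month"].isna()
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} rows with missing month",
                      stacklevel=2)
        df = df[~missing]
    out = []
    for month, grp in df.groupby("month"):
        r = grp[rating_column].to_numpy()
        counts = {f"count_{s}": int(np.sum(r == s)) for s in range(1, 10)}
        out.append({"month": int(month), **counts,
                    "lo": int(r.min()), "hi": int(r.max()),
                    "median": float(np.median(r))})
    return pd.DataFrame(out).sort_values("month").reset_index(drop=True)


def category_widths(tau: CategoryThresholds) -> tuple[np.ndarray, bool]:
    """Widths of the non-terminal categories and an ordering flag.

    Category ``s`` (between thresholds ``s`` and ``s+1``) has width
    ``tau[s+1] - tau[s]``; all widths positive <=> ordered thresholds.  A
    negative width is a diagnosable condition (the scale is misused), not an
    error.  Widths telescope: their sum is ``tau[M] - tau[1]`` exactly.
    """
    if tau.M < 2:
        raise ValidationError("need M >= 2 thresholds for category widths")
    widths = np.diff(tau.tau)
    return widths, bool(np.all(widths > 0))


def severity_trend(
    severities: pd.DataFrame,
    smoothing_fraction: float = 0.6,
) -> dict:
    """LOWESS trend of rating severity against month-of-year, per rater.

    ``severities`` needs columns ``rater``, ``month``, ``beta`` (posterior
    means of the event severities).  Raters with more than
    ``MIN_RATINGS_FOR_TREND`` events get a smoothed curve; the rest are
    listed under ``excluded``.  Returns ``{"trends": DataFrame(rater, month,
    beta, smoothed), "severity_sd": DataFrame(rater, sd, n_events),
    "excluded": [rater, ...]}``.
    """
    for col in ("rater", "month", "beta"):
        if col not in severities.columns:
            raise ValidationError(f"missing column {col!r}")
    trends, sds, excluded = [], [], []
    for rater, grp in severities.groupby("rater"):
        n = grp.shape[0]
        sds.append({"rater": rater, "sd": float(grp["beta"].std(ddof=1)) if n > 1 else 0.0,
                    "n_events": int(n)})
        if n <= MIN_RATINGS_FOR_TREND:
            excluded.append(rater)
            continue
        grp = grp.sort_values("month")
        smoothed = lowess(grp["beta"].to_numpy(), grp["month"].to_numpy(float),
                          frac=smoothing_fraction, return_sorted=False)
        t = grp[["rater", "month", "beta"]].copy()
        t["smoothed"] = smoothed
        trends.append(t)
    trends_df = (pd.concat(trends, ignore_index=True) if trends
                 else pd.DataFrame(columns=["rater", "month", "beta", "smoothed"]))
    return {"trends": trends_df, "severity_sd": pd.DataFrame(sds), "excluded": excluded}


def spatial_map(loc_means: np.ndarray, layout: TrialLayout) -> np.ndarray:
    """Matrix of plot-location effects keyed by (row, col); NaN = no plot."""
    loc_means = np.asarray(loc_means, dtype=float)
    if loc_means.size != layout.n_plots:
        raise ValidationError("loc vector length does not match layout")
    grid = np.full((layout.row.max(), layout.col.max()), np.nan)
    for v, r, c in zip(loc_means, layout.row, layout.col):
        if not np.isnan(grid[r - 1, c - 1]):
            raise ValidationError(f"duplicate grid cell (row={r}, col={c})")
        grid[r - 1, c - 1] = v
    return grid


def cross_location_table(per_location_eta: dict) -> pd.DataFrame:
    """Align cultivar means across locations on their zero-centred scales.

    ``per_location_eta`` maps location name -> {cultivar: posterior mean}.
    Returns one row per cultivar and one column per location; a cultivar
    absent from a location is NaN (explicitly missing, never zero).  Values
    stay on each location's own latent logit scale — the alignment
    assumption is only that zero marks the average level everywhere, so
    within-location differences are directly comparable by subtraction.
    """
    if not per_location_eta:
        raise ValidationError("need at least one location")
    table = pd.DataFrame(per_location_eta)
    table.index.name = "cultivar"
    return table.sort_index()


@dataclass(frozen=True)
class VariancePartition:
    """Posterior-mean percentages of linear-predictor variance by component."""

    pct_cultivar: float
    pct_severity: float
    pct_spatial: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.degenerate:
            return
        total = self.pct_cultivar + self.pct_severity + self.pct_spatial
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(f"percentages must sum to 100, got {total}")


def variance_partition(samples: PosteriorSamples, data: ObservationData) -> VariancePartition:
    """Share of linear-predictor variance from cultivar, severity, spatial terms.

    For each posterior draw, the across-observation variances of the three
    components of the linear predictor — ``eta[cultivar(n)]``, ``beta_i``,
    ``LOC_n`` — are expressed as percentages of their sum; reported values
    are posterior means of those percentages.  If all three components are
    constant in every draw the partition is undefined (``degenerate``).
    """
    if data.n_obs == 0:
        raise ValidationError("empty observation table")
    eta = samples.extract("eta")[:, :, data.cultivar_of_plot[data.plot_idx]]
    loc = samples.extract("loc")[:, :, data.plot_idx]
    beta = samples.extract("beta")[:, :, data.event_idx]
    v = np.stack([comp.var(axis=2) for comp in (eta, beta, loc)])  # (3, chains, per)
    total = v.sum(axis=0)
    if np.all(total == 0.0):
        return VariancePartition(np.nan, np.nan, np.nan, degenerate=True)
    pct = 100.0 * v / total
    pc, ps, pl = pct.mean(axis=(1, 2))
    return VariancePartition(float(pc), float(ps), float(pl))
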