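"""Linear-mixed-model baseline that treats ratings as continuous.

The comparator model is ``Y = eta + u + eps``: a fixed cultivar effect, a
random rating-event intercept, and residual noise, fit by REML on the raw
1-9 scale.  Because it ignores the ordinal nature of the data, it assigns
every cultivar the same standard error under a balanced design — one of the
shortcomings the latent-scale model addresses.  Agreement between the two
models' cultivar means is summarised by Pearson and Spearman correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .core import ValidationError

__all__ = ["LmmFit", "fit_lmm", "compare_cultivar_means"]


@dataclass(frozen=True)
class LmmFit:
    """REML fit of rating ~ cultivar (fixed) + event (random intercept)."""

    cultivar_names: np.ndarray
    cultivar_means: np.ndarray     # cell-means coding, raw rating scale
    cultivar_sds: np.ndarray       # standard errors of the means
    event_variance: float
    residual_variance: float
    singular: bool = False

    @property
    def uniform_sds(self) -> bool:
        """The diagnosable property: identical SDs for every cultivar."""
        return bool(np.ptp(self.cultivar_sds) <= 1e-8 * max(1.0, self.cultivar_sds.max()))


def fit_lmm(data: pd.DataFrame, rating_column: str = "rating") -> LmmFit:
    """Fit the baseline mixed model to a rating table.

    Requires columns ``cultivar``, ``event_id`` and the rating column (any
    numeric scale; correlations with latent-scale means are location/scale
    invariant).  Singular fits (a variance component on the boundary) are
    reported through ``singular`` with a warning, not an exception.
    """
    for col in ("cultivar", "event_id", rating_column):
        if col not in data.columns:
            raise ValidationError(f"LMM data missing column {col!r}")
    if data["cultivar"].nunique() < 2 or data["event_id"].nunique() < 2:
        raise ValidationError("LMM needs >= 2 cultivars and >= 2 rating events")

    df = data[["cultivar", "event_id", rating_column]].copy()
    df[rating_column] = df[rating_column].astype(float)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM.from_formula(
            f"{rating_column} ~ 0 + C(cultivar)", groups="event_id", data=df
        )
        result = model.fit(reml=True)
    singular = (
        any(issubclass(w.category, ConvergenceWarning) for w in caught)
        or result.cov_re.iloc[0, 0] <= 1e-10
    )
    if singular:
        warnings.warn("singular or boundary LMM fit: event variance ~ 0",
                      stacklevel=2)

    names = np.array(sorted(df["cultivar"].unique()))
    means = result.fe_params.to_numpy()
    sds = result.bse_fe.to_numpy()
    return LmmFit(
        cultivar_names=names,
        cultivar_means=means,
        cultivar_sds=sds,
        event_variance=float(result.cov_re.iloc[0, 0]),
        residual_variance=float(result.scale),
        singular=singular,
    )


def compare_cultivar_means(rsm_means, lmm_means) -> dict:
    """Pearson and Spearman correlations between matched cultivar means.

    A zero-variance vector has no defined correlation; NaN is returned for
    the affected coefficient(s) rather than raising.
    """
    a = np.asarray(rsm_means, dtype=float)
    b = np.asarray(lmm_means, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("mean vectors must be 1-d and matched by cultivar")
    if a.size < 3:
        raise ValidationError("need >= 3 cultivars for a meaningful correlation")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return {"pearson": float("nan"), "spearman": float("nan")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pearson = float(stats.pearsonr(a, b).statistic)
        spearman = float(stats.spearmanr(a, b).statistic)
    return {"pearson": pearson, "spearman": spearman}
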