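"""Delimited-text readers and writers for ratings, layouts, truth, and draws.

Interchange convention: rating files carry the human-facing 1-9 field scale;
in memory everything is re-indexed to 0..M.  The re-indexing boundary is
read/write, nowhere else.  All tables are UTF-8 CSV with a header row; the
truth and run-metadata files are YAML key-value documents.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CategoryThresholds, ValidationError, reindex_ratings
from .model import RsmParameters
from .spatial import GpHyperparams, TrialLayout

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_layout",
    "write_layout",
    "read_truth",
    "write_truth",
    "write_posterior",
    "read_posterior",
]

_RATING_COLUMNS = ["plot_id", "cultivar", "rater", "event_id", "month", "rating"]


def read_ratings(path, layout: TrialLayout | None = None) -> pd.DataFrame:
    """Load and validate a rating table; ratings come back re-indexed 0..8.

    Requires header columns plot_id, cultivar, rater, event_id, month,
    rating (1-9 scale); an optional year column is preserved.  When a layout
    is given, every plot_id must exist in it.
    """
    df = pd.read_csv(path)
    missing = set(_RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["rating"] = reindex_ratings(df["rating"].to_numpy())
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None
    month = df["month"].to_numpy()
    if not np.all((month >= 1) & (month <= 12)):
        bad = np.nonzero((month < 1) | (month > 12))[0]
        raise ValidationError(f"{path}: month out of 1..12 at rows {bad.tolist()[:10]}")
    dup = df.duplicated(subset=["plot_id", "event_id"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (plot_id, event_id) at rows {np.nonzero(dup.to_numpy())[0].tolist()[:10]}"
        )
    if layout is not None:
        layout.index_of(df["plot_id"])  # raises on unknown plots
    return df


def write_ratings(observations: pd.DataFrame, path) -> None:
    """Write a 0..M-indexed observation table on the 1-9 interchange scale."""
    out = observations.copy()
    out["rating"] = out["rating"].to_numpy() + 1
    out.to_csv(path, index=False)


def read_layout(path) -> TrialLayout:
    return TrialLayout.from_dataframe(pd.read_csv(path))


def write_layout(layout: TrialLayout, path) -> None:
    layout.to_dataframe().to_csv(path, index=False)


def write_truth(truth: RsmParameters, path, extra: dict | None = None) -> None:
    """Serialize one parameter realization as a YAML key-value document."""
    doc = {
        "eta": truth.eta.tolist(),
        "loc": truth.loc.tolist(),
        "beta": truth.beta.tolist(),
        "tau": truth.tau.tau.tolist(),
        "sigma": float(truth.sigma),
        "alpha": float(truth.gp.alpha),
        "rho": float(truth.gp.rho),
        "sigma_e": float(truth.gp.sigma_e),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truth(path) -> RsmParameters:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return RsmParameters(
            eta=np.asarray(doc["eta"], dtype=float),
            loc=np.asarray(doc["loc"], dtype=float),
            beta=np.asarray(doc["beta"], dtype=float),
            tau=CategoryThresholds(np.asarray(doc["tau"], dtype=float)),
            sigma=float(doc["sigma"]),
            gp=GpHyperparams(float(doc["alpha"]), float(doc["rho"]), float(doc["sigma_e"])),
        )
    except KeyError as err:
        raise ValidationError(f"{path}: truth file missing key {err.args[0]!r}") from None


def write_posterior(samples, directory, stem: str = "posterior") -> tuple[Path, Path]:
    """Write draws as a flat CSV (one row per retained draw) plus metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    draws_path = directory / f"{stem}_draws.csv"
    meta_path = directory / f"{stem}_meta.yaml"
    samples.to_dataframe().to_csv(draws_path, index=False)
    Path(meta_path).write_text(yaml.safe_dump(samples.meta, sort_keys=False))
    return draws_path, meta_path


def read_posterior(draws_path, meta_path=None):
    """Load a posterior draws table (and metadata) written by write_posterior."""
    from .inference import PosteriorSamples  # local import to avoid a cycle

    df = pd.read_csv(draws_path)
    meta = yaml.safe_load(Path(meta_path).read_text()) if meta_path else {}
    return PosteriorSamples.from_dataframe(df, meta)
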