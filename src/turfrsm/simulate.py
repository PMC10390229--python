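"""Synthetic rating trials with known ground truth.

Emulates the full generative structure of a replicated turfgrass trial rated
on the 1-9 scale: normally distributed cultivar effects, a Gaussian-process
spatial field over a randomized-complete-block plot grid, per-rater severity
shifts attached to rating events, fixed sum-to-zero category thresholds, and
adjacent-category sampling of the ordinal ratings.

The default configuration (:func:`recovery_study_config`) is the parameter
recovery study design: 3 replications of 10 cultivars rated monthly for 5
years by 5 raters, cultivar effects with sd 0.7, GP hyperparameters
(alpha, rho, sigma_e) = (0.15, 2.5, 0.2), rater severities evenly spaced on
[-0.8, 0.8], and 8 thresholds evenly spaced on [-2, 2].

Random number usage order is fixed and documented so seeds are portable:
(1) cultivar effects, (2) plot-assignment permutations, (3) the spatial
field, (4) ratings event by event.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import CategoryThresholds, ValidationError, category_probability_matrix
from .model import RsmParameters
from .spatial import GpHyperparams, TrialLayout, draw_gp_field

__all__ = ["SimulationConfig", "SyntheticTrial", "recovery_study_config", "simulate_trial"]


@dataclass(frozen=True)
class SimulationConfig:
    """Design and generative parameters of a synthetic trial.

    ``n_months`` counts rating events per calendar (one rater per event,
    raters cycling month by month); set ``all_raters_each_month=True`` for
    the variant where every rater rates every month.
    """

    n_cultivars: int
    n_reps: int
    n_months: int
    n_raters: int
    sigma: float
    gp: GpHyperparams
    severity_range: tuple[float, float]
    threshold_range: tuple[float, float]
    M: int = 8
    seed: int = 0
    all_raters_each_month: bool = False

    def __post_init__(self) -> None:
        for name in ("n_cultivars", "n_reps", "n_months", "n_raters"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0")
        for name in ("severity_range", "threshold_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must satisfy lo < hi")
        if not 1 <= self.M <= 8:
            raise ValidationError("M must be in 1..8")

    @property
    def severities(self) -> np.ndarray:
        return np.linspace(*self.severity_range, self.n_raters)

    @property
    def thresholds(self) -> np.ndarray:
        return np.linspace(*self.threshold_range, self.M)

    @property
    def n_events(self) -> int:
        return self.n_months * (self.n_raters if self.all_raters_each_month else 1)


@dataclass(frozen=True)
class SyntheticTrial:
    """Observations, layout, and the generating truth of one simulated trial."""

    observations: pd.DataFrame   # plot_id, cultivar, rater, event_id, month, year, rating 0..M
    layout: TrialLayout
    truth: RsmParameters
    config: SimulationConfig

    @property
    def cultivar_names(self) -> np.ndarray:
        return np.array([_cultivar_name(k) for k in range(self.config.n_cultivars)])

    @property
    def event_ids(self) -> np.ndarray:
        return np.array([_event_id(e) for e in range(self.config.n_events)])


def _cultivar_name(k: int) -> str:
    return f"CV{k + 1:03d}"


def _event_id(e: int) -> str:
    return f"E{e + 1:03d}"


def recovery_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The parameter-recovery study design (see module docstring)."""
    cfg = SimulationConfig(
        n_cultivars=10,
        n_reps=3,
        n_months=60,
        n_raters=5,
        sigma=0.7,
        gp=GpHyperparams(alpha=0.15, rho=2.5, sigma_e=0.2),
        severity_range=(-0.8, 0.8),
        threshold_range=(-2.0, 2.0),
        M=8,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def simulate_trial(config: SimulationConfig) -> SyntheticTrial:
    """Draw one complete synthetic trial; fully reproducible under the seed.

    Plots form an ``n_reps x n_cultivars`` grid with unit spacing; each row
    is one replication block holding a random permutation of all cultivars
    (randomized complete block layout).  Each rating event covers every plot
    exactly once; the event's true severity is its rater's fixed severity.
    """
    rng = np.random.default_rng(config.seed)

    # (1) cultivar effects
    eta = rng.normal(0.0, config.sigma, size=config.n_cultivars)

    # (2) RCBD plot assignment: one replicate of every cultivar per grid row
    layout = TrialLayout.from_grid(config.n_reps, config.n_cultivars)
    cultivar_of_plot = np.concatenate(
        [rng.permutation(config.n_cultivars) for _ in range(config.n_reps)]
    )

    # (3) spatial field over the grid
    loc = draw_gp_field(layout, config.gp, rng)

    # event calendar: month-of-year cycles, raters cycle deterministically
    severities = config.severities
    thresholds = config.thresholds
    if abs(thresholds.sum()) > 1e-9:
        raise ValidationError(
            "threshold_range must be symmetric so the true thresholds sum to zero"
        )
    events = []
    for m in range(config.n_months):
        month, year = m % 12 + 1, m // 12 + 1
        if config.all_raters_each_month:
            events.extend((month, year, r) for r in range(config.n_raters))
        else:
            events.append((month, year, m % config.n_raters))
    beta = np.array([severities[r] for _, _, r in events])
    if abs(beta.sum()) > 1e-9:
        raise ValidationError(
            "per-event severities do not sum to zero under this design; "
            "adjust n_months to a multiple of n_raters or the severity range"
        )

    truth = RsmParameters(
        eta=eta,
        loc=loc,
        beta=beta,
        tau=CategoryThresholds(thresholds),
        sigma=config.sigma,
        gp=config.gp,
    )
    theta = truth.theta(cultivar_of_plot)

    # (4) ratings, event by event, inverse-CDF sampling per plot
    n_plots = layout.n_plots
    rows = []
    for e, (month, year, r) in enumerate(events):
        probs = category_probability_matrix(theta - beta[e], thresholds)
        u = rng.random(n_plots)
        ratings = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "plot_id": layout.plot_ids,
                    "cultivar": [_cultivar_name(k) for k in cultivar_of_plot],
                    "rater": f"R{r + 1}",
                    "event_id": _event_id(e),
                    "month": month,
                    "year": year,
                    "rating": ratings.astype(int),
                }
            )
        )
    observations = pd.concat(rows, ignore_index=True)
    return SyntheticTrial(observations=observations, layout=layout, truth=truth,
                          config=config)


def write_trial(trial: SyntheticTrial, directory, overwrite: bool = False) -> dict:
    """Write observations, layout, and truth files; round-trippable via io.

    Refuses to clobber an existing trial unless ``overwrite=True``.
    """
    from pathlib import Path

    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": directory / "observations.csv",
        "layout": directory / "layout.csv",
        "truth": directory / "truth.yaml",
    }
    existing = [str(p) for p in paths.values() if p.exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"trial files already present ({existing[0]}, ...); pass overwrite=True"
        )
    _io.write_ratings(trial.observations, paths["observations"])
    _io.write_layout(trial.layout, paths["layout"])
    cfg = trial.config
    _io.write_truth(
        trial.truth,
        paths["truth"],
        extra={
            "config": {
                "n_cultivars": cfg.n_cultivars,
                "n_reps": cfg.n_reps,
                "n_months": cfg.n_months,
                "n_raters": cfg.n_raters,
                "M": cfg.M,
                "seed": cfg.seed,
                "all_raters_each_month": cfg.all_raters_each_month,
                "severity_range": list(cfg.severity_range),
                "threshold_range": list(cfg.threshold_range),
            }
        },
    )
    return {k: str(v) for k, v in paths.items()}
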