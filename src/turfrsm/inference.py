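"""Posterior estimation for the latent rating-scale model.

``fit_rsm`` samples the posterior defined in :mod:`turfrsm.model` with the
package's no-U-turn sampler: by default four chains of 1,000 iterations each,
the first 500 discarded as warmup and the rest thinned by taking every other
draw (250 retained per chain).  Sum-to-zero constraints on the event
severities and thresholds are enforced structurally — the sampler works on
the free components and the last element is completed as their negative sum —
so every retained draw satisfies them exactly.

Convergence is summarised by split R-hat and bulk effective sample size for
every scalar parameter and the log posterior; parameter recovery against a
known simulation truth is summarised by posterior quantiles of
``draw - truth`` per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .core import CategoryThresholds, ValidationError
from .model import ObservationData, PriorConfig, RsmModel, RsmParameters
from .sampler import NutsConfig, nuts_sample
from .spatial import GpHyperparams, TrialLayout

__all__ = [
    "PosteriorSamples",
    "ConvergenceReport",
    "RecoveryReport",
    "fit_rsm",
    "convergence_diagnostics",
    "recovery_report",
]

_SCALAR_NAMES = ["sigma", "alpha", "rho", "sigma_e"]


@dataclass
class PosteriorSamples:
    """Retained posterior draws on the natural scale, with provenance.

    ``draws`` has shape (chains, draws_per_chain, n_params); columns follow
    ``param_names`` (eta[...], loc[...], beta[...], tau[...], sigma, alpha,
    rho, sigma_e).  ``lp`` is the per-draw log density of the sampled
    parameterization.
    """

    draws: np.ndarray = field(repr=False)
    param_names: list
    lp: np.ndarray = field(repr=False)
    meta: dict
    coords: dict

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        """Total retained draws across chains."""
        return self.draws.shape[0] * self.draws.shape[1]

    def param_index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def extract(self, prefix: str) -> np.ndarray:
        """All columns named ``prefix`` or ``prefix[...]`` -> (chains, draws, k)."""
        idx = [i for i, n in enumerate(self.param_names)
               if n == prefix or n.startswith(prefix + "[")]
        if not idx:
            raise KeyError(f"no parameters matching {prefix!r}")
        return self.draws[:, :, idx]

    def posterior_mean(self, prefix: str) -> np.ndarray:
        return self.extract(prefix).mean(axis=(0, 1)).squeeze()

    def flat(self) -> np.ndarray:
        """(total draws, n_params) with chains stacked."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def draw_parameters(self, chain: int, i: int) -> RsmParameters:
        """Rebuild one retained draw as an RsmParameters realization."""
        row = dict(zip(self.param_names, self.draws[chain, i]))
        pick = lambda p: np.array(
            [v for n, v in row.items() if n.startswith(p + "[")]
        )
        return RsmParameters(
            eta=pick("eta"), loc=pick("loc"), beta=pick("beta"),
            tau=CategoryThresholds(pick("tau")),
            sigma=row["sigma"],
            gp=GpHyperparams(row["alpha"], row["rho"], row["sigma_e"]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        chains, per, P = self.draws.shape
        df = pd.DataFrame(self.flat(), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(chains), per))
        df.insert(1, "iteration", np.tile(np.arange(per), chains))
        df["lp"] = self.lp.reshape(-1)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: dict | None = None):
        meta = meta or {}
        chains = int(df["chain"].max()) + 1
        per = int(df["iteration"].max()) + 1
        names = [c for c in df.columns if c not in ("chain", "iteration", "lp")]
        draws = df[names].to_numpy().reshape(chains, per, len(names))
        lp = df["lp"].to_numpy().reshape(chains, per)
        return cls(draws=draws, param_names=names, lp=lp, meta=meta,
                   coords=meta.get("coords", {}))


@dataclass
class ConvergenceReport:
    """Split R-hat and bulk ESS per scalar parameter and the log posterior."""

    table: pd.DataFrame
    max_rhat: float

    @property
    def converged(self) -> bool:
        """True when the maximum split R-hat rounds to 1.0 at one decimal."""
        return bool(np.isfinite(self.max_rhat) and round(self.max_rhat, 1) <= 1.0)


@dataclass
class RecoveryReport:
    """Posterior quantiles of (draw - truth) for every scalar parameter."""

    table: pd.DataFrame  # parameter, truth, q2.5, q50, q97.5, excludes_zero

    @property
    def n_excluding_zero(self) -> int:
        return int(self.table["excludes_zero"].sum())

    @property
    def n_parameters(self) -> int:
        return int(self.table.shape[0])


def _param_names(data: ObservationData) -> list:
    names = [f"eta[{c}]" for c in data.cultivar_names]
    names += [f"loc[{p}]" for p in data.layout.plot_ids]
    names += [f"beta[{e}]" for e in data.event_ids]
    names += [f"tau[{s}]" for s in range(1, data.M + 1)]
    names += _SCALAR_NAMES
    return names


def _constrain_draws(model: RsmModel, z_draws: np.ndarray) -> np.ndarray:
    out = np.empty((z_draws.shape[0], model.n_c + model.n_p + model.n_e + model.M + 4))
    for i, z in enumerate(z_draws):
        p = model.constrain(z)
        out[i] = np.concatenate(
            [p.eta, p.loc, p.beta, p.tau.tau,
             [p.sigma, p.gp.alpha, p.gp.rho, p.gp.sigma_e]]
        )
    return out


def fit_rsm(
    observations: pd.DataFrame,
    layout: TrialLayout,
    chains: int = 4,
    iterations: int = 1000,
    warmup: int = 500,
    thin: int = 2,
    seed: int = 0,
    M: int = 8,
    priors: PriorConfig = PriorConfig(),
    target_accept: float = 0.8,
) -> PosteriorSamples:
    """Sample the posterior for one trial location.

    ``iterations`` counts total iterations per chain including warmup;
    retained draws per chain are ``(iterations - warmup) / thin``.
    Divergences and poor mixing are reported through the metadata and
    :func:`convergence_diagnostics`, never raised.
    """
    if observations.shape[0] == 0:
        raise ValidationError("cannot fit on an empty observation table")
    if warmup >= iterations:
        raise ValidationError("warmup must be smaller than iterations")
    data = ObservationData(observations, layout, M=M)
    model = RsmModel(data, priors)
    cfg = NutsConfig(iterations=iterations, warmup=warmup, thin=thin,
                     target_accept=target_accept)

    seeds = np.random.SeedSequence(seed).spawn(chains)
    z_chains, lp_chains, meta_chains = [], [], []
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        z0 = rng.uniform(-0.5, 0.5, size=model.dim)
        # start scale parameters below 1 on the natural scale
        for idx in (model.i_sigma, model.i_alpha, model.i_rho, model.i_sige):
            z0[idx] -= 1.0
        res = nuts_sample(model.logp_grad, z0, rng, cfg)
        z_chains.append(res.draws)
        lp_chains.append(res.logp)
        meta_chains.append(
            {"step_size": float(res.step_size),
             "divergences": int(res.divergences),
             "mean_accept": float(res.accept_stat[warmup:].mean()),
             "mean_tree_depth": float(res.tree_depths[warmup:].mean())}
        )

    draws = np.stack([_constrain_draws(model, zc) for zc in z_chains])
    lp = np.stack(lp_chains)
    coords = {
        "cultivars": data.cultivar_names.tolist(),
        "plots": data.layout.plot_ids.tolist(),
        "events": data.event_ids.tolist(),
    }
    meta = {
        "chains": chains, "iterations": iterations, "warmup": warmup,
        "thin": thin, "seed": int(seed), "M": int(M),
        "backend": "turfrsm-nuts",
        "per_chain": meta_chains, "coords": coords,
    }
    return PosteriorSamples(draws=draws, param_names=_param_names(data),
                            lp=lp, meta=meta, coords=coords)


def convergence_diagnostics(samples: PosteriorSamples) -> ConvergenceReport:
    """Split R-hat and bulk ESS for every parameter and the log posterior.

    Parameters whose draws are constant across all chains (zero variance)
    are flagged with NaN rather than reported as converged.
    """
    if samples.n_chains < 2:
        raise ValidationError("split R-hat requires at least 2 chains")
    arr = samples.draws  # (chains, per, P)
    ds = az.convert_to_dataset({"p": arr})
    rhat = az.rhat(ds, method="split")["p"].values
    ess = az.ess(ds, method="bulk")["p"].values
    variances = arr.reshape(-1, arr.shape[-1]).var(axis=0)
    rhat = np.where(variances == 0.0, np.nan, rhat)

    lp = samples.lp[:, :, None]
    lp_rhat = float(az.rhat(az.convert_to_dataset({"p": lp}), method="split")["p"].values[0])
    lp_ess = float(az.ess(az.convert_to_dataset({"p": lp}), method="bulk")["p"].values[0])
    if samples.lp.var() == 0.0:
        lp_rhat, lp_ess = np.nan, np.nan

    table = pd.DataFrame(
        {"parameter": samples.param_names + ["lp"],
         "rhat": np.append(rhat, lp_rhat),
         "ess_bulk": np.append(ess, lp_ess)}
    )
    finite = table["rhat"].to_numpy()
    max_rhat = float(np.nanmax(finite)) if np.any(np.isfinite(finite)) else float("nan")
    return ConvergenceReport(table=table, max_rhat=max_rhat)


def _truth_vector(samples: PosteriorSamples, truth: RsmParameters) -> np.ndarray:
    parts = [truth.eta, truth.loc, truth.beta, truth.tau.tau,
             [truth.sigma, truth.gp.alpha, truth.gp.rho, truth.gp.sigma_e]]
    vec = np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])
    if vec.size != len(samples.param_names):
        raise ValidationError(
            f"truth has {vec.size} scalars but posterior monitors "
            f"{len(samples.param_names)} parameters"
        )
    return vec


def recovery_report(samples: PosteriorSamples, truth: RsmParameters) -> RecoveryReport:
    """95% credible intervals of (draw - truth) and how many exclude zero.

    Truth arrays must follow the same cultivar/plot/event orderings as the
    posterior (the synthetic-trial generator and ``fit_rsm`` share them).
    """
    tv = _truth_vector(samples, truth)
    diff = samples.flat() - tv
    lo, med, hi = np.percentile(diff, [2.5, 50.0, 97.5], axis=0)
    table = pd.DataFrame(
        {"parameter": samples.param_names, "truth": tv,
         "q2.5": lo, "q50": med, "q97.5": hi,
         "excludes_zero": (lo > 0) | (hi < 0)}
    )
    return RecoveryReport(table=table)
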