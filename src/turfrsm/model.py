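"""Log posterior of the latent rating-scale model, with analytic gradients.

Model
-----
For plot ``n`` rated in event ``i`` the adjacent-category log-odds are
``theta_n - beta_i - tau_s`` (see :mod:`turfrsm.core`).  The latent quality is
partitioned as ``theta = eta[cultivar(n)] + LOC_n`` where

* ``eta_k | sigma  ~ Normal(0, sigma^2)``          (cultivar effects)
* ``LOC | alpha, rho, sigma_e ~ MVN(0, K)``        (spatial GP, nugget)
* ``beta`` and ``tau`` carry sum-to-zero constraints: the last element is
  structurally the negative sum of the free components.

Priors: half-Student-t(3, 0, 1) on ``sigma``, ``alpha`` and ``sigma_e``;
Inverse-Gamma(5, 5) on ``rho``; weakly informative normals on the free
components of ``beta`` (sd 1) and ``tau`` (sd 2).

Sampling parameterization
-------------------------
:class:`RsmModel` works on an unconstrained vector
``z = [eta_raw, z_loc, beta_free, tau_free, log sigma, log alpha, log rho,
log sigma_e]`` with ``eta = sigma * eta_raw`` and ``LOC = L(alpha, rho,
sigma_e) @ z_loc`` (non-centred, Cholesky-factor form), which removes the
scale/latent funnels that hurt mixing.  ``logp_grad`` returns the log density
of this parameterization (Jacobian terms included) together with its exact
gradient; hyperparameter gradients propagate through the Cholesky factor via
the standard forward-mode differentiation ``dL = L * Phi(L^-1 dK L^-T)``.

:func:`log_posterior` is the reference density on the natural (constrained)
scale, fully normalized; it is the contract the sampler is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .core import (
    CategoryThresholds,
    ValidationError,
    complete_sum_to_zero,
)
from .spatial import GpHyperparams, TrialLayout, exp_quad_covariance, pairwise_distances

__all__ = ["PriorConfig", "RsmParameters", "ObservationData", "RsmModel", "log_posterior"]


def _complete(free: np.ndarray) -> np.ndarray:
    """Sum-to-zero completion that tolerates an empty free vector (-> [0])."""
    return np.zeros(1) if free.size == 0 else complete_sum_to_zero(free)


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative prior settings (logit-scale units)."""

    beta_sd: float = 1.0       # free event-severity components
    tau_sd: float = 2.0        # free threshold components (thresholds span more)
    scale_df: float = 3.0      # half-Student-t df for sigma, alpha, sigma_e
    scale_scale: float = 1.0   # half-Student-t scale
    rho_shape: float = 5.0     # Inverse-Gamma shape for rho
    rho_rate: float = 5.0      # Inverse-Gamma rate (scipy's `scale`) for rho


@dataclass(frozen=True)
class RsmParameters:
    """One full parameter realization: simulation truth or a posterior draw."""

    eta: np.ndarray
    loc: np.ndarray
    beta: np.ndarray
    tau: CategoryThresholds
    sigma: float
    gp: GpHyperparams

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=float)
        loc = np.asarray(self.loc, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        for name, v in (("eta", eta), ("loc", loc), ("beta", beta)):
            if v.ndim != 1 or not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} must be a finite 1-d vector")
        if abs(beta.sum()) > 1e-8 * max(1.0, np.abs(beta).max() * beta.size):
            raise ValidationError(f"beta must sum to zero, got {beta.sum():.3e}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValidationError("sigma must be strictly positive")
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "loc", loc)
        object.__setattr__(self, "beta", beta)

    def theta(self, cultivar_of_plot: np.ndarray) -> np.ndarray:
        """Per-plot latent quality eta[cultivar(plot)] + LOC."""
        return self.eta[np.asarray(cultivar_of_plot, dtype=int)] + self.loc


class ObservationData:
    """Index-encoded observation table bound to a trial layout.

    Validates referential integrity once so the likelihood can run on plain
    integer arrays.  Cultivar, plot, and event orderings are sorted and
    recorded in ``cultivar_names`` / ``plot_ids`` / ``event_ids``; parameter
    vectors follow these orders everywhere downstream.
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        layout: TrialLayout,
        M: int = 8,
        event_ids: np.ndarray | None = None,
        cultivar_names: np.ndarray | None = None,
    ) -> None:
        required = {"plot_id", "cultivar", "event_id", "rating"}
        missing = required - set(observations.columns)
        if missing:
            raise ValidationError(f"observations missing columns: {sorted(missing)}")
        if not (1 <= M <= 8):
            raise ValidationError(f"M must be in 1..8, got {M}")
        self.M = int(M)
        self.layout = layout
        obs = observations.reset_index(drop=True)

        self.plot_idx = layout.index_of(obs["plot_id"])
        if event_ids is None:
            event_ids = np.unique(obs["event_id"].to_numpy())
        self.event_ids = np.asarray(event_ids)
        ev_lookup = {e: i for i, e in enumerate(self.event_ids.tolist())}
        try:
            self.event_idx = np.array(
                [ev_lookup[e] for e in obs["event_id"].tolist()], dtype=int
            )
        except KeyError as err:
            raise ValidationError(f"unknown event id {err.args[0]!r}") from None

        y = obs["rating"].to_numpy()
        if y.size and (not np.issubdtype(y.dtype, np.integer) or y.min() < 0 or y.max() > M):
            raise ValidationError(f"re-indexed ratings must be integers in 0..{M}")
        self.y = y.astype(int)

        dup = pd.MultiIndex.from_arrays([self.plot_idx, self.event_idx]).duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate (plot, event) observations at rows {np.nonzero(dup)[0].tolist()[:10]}"
            )

        # per-plot cultivar assignment, required to be consistent across events
        if cultivar_names is None:
            cultivar_names = np.unique(obs["cultivar"].to_numpy())
        self.cultivar_names = np.asarray(cultivar_names)
        cv_lookup = {c: i for i, c in enumerate(self.cultivar_names.tolist())}
        try:
            obs_cv = np.array([cv_lookup[c] for c in obs["cultivar"].tolist()], dtype=int)
        except KeyError as err:
            raise ValidationError(f"unknown cultivar {err.args[0]!r}") from None
        cv_of_plot = np.full(layout.n_plots, -1, dtype=int)
        for p, c in zip(self.plot_idx, obs_cv):
            if cv_of_plot[p] == -1:
                cv_of_plot[p] = c
            elif cv_of_plot[p] != c:
                raise ValidationError(
                    f"plot {layout.plot_ids[p]!r} assigned to multiple cultivars"
                )
        # plots never rated keep their spatial effect but contribute no
        # likelihood; park them on cultivar 0 so indexing stays valid
        self.rated_plot_mask = cv_of_plot >= 0
        self.cultivar_of_plot = np.where(cv_of_plot < 0, 0, cv_of_plot)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_plots(self) -> int:
        return self.layout.n_plots

    @property
    def n_events(self) -> int:
        return self.event_ids.size

    @property
    def n_cultivars(self) -> int:
        return self.cultivar_names.size


def _adjacent_category_loglik(
    theta: np.ndarray, beta: np.ndarray, tau: np.ndarray, data: ObservationData
) -> float:
    if data.n_obs == 0:
        return 0.0
    c = theta[data.plot_idx] - beta[data.event_idx]
    cum = np.concatenate([[0.0], np.cumsum(tau)])
    logw = c[:, None] * np.arange(data.M + 1) - cum
    return float(np.sum(data.y * c - cum[data.y] - logsumexp(logw, axis=1)))


def log_posterior(
    params: RsmParameters, data: ObservationData, priors: PriorConfig = PriorConfig()
) -> float:
    """Normalized log posterior density on the natural (constrained) scale.

    Likelihood: adjacent-category probabilities of every observed rating.
    Latent densities: ``eta | sigma`` iid normal, ``LOC`` multivariate normal
    with the exponentiated-quadratic-plus-nugget covariance over the layout.
    Priors: normals on the free components of ``beta`` and ``tau``;
    half-Student-t on the scale parameters; Inverse-Gamma on ``rho``.
    """
    if params.eta.size != data.n_cultivars and data.n_cultivars > 0:
        raise ValidationError("eta length does not match number of cultivars")
    if params.loc.size != data.n_plots:
        raise ValidationError("loc length does not match number of plots")
    if data.n_events and params.beta.size != data.n_events:
        raise ValidationError("beta length does not match number of events")
    if params.tau.M != data.M:
        raise ValidationError("tau length does not match data M")

    theta = params.theta(data.cultivar_of_plot) if data.n_obs else params.loc
    lp = _adjacent_category_loglik(theta, params.beta, params.tau.tau, data)

    lp += float(np.sum(stats.norm.logpdf(params.eta, scale=params.sigma)))
    K = exp_quad_covariance(pairwise_distances(data.layout), params.gp)
    lp += float(stats.multivariate_normal.logpdf(params.loc, cov=K))
    lp += float(np.sum(stats.norm.logpdf(params.beta[:-1], scale=priors.beta_sd)))
    lp += float(np.sum(stats.norm.logpdf(params.tau.tau[:-1], scale=priors.tau_sd)))
    for scale in (params.sigma, params.gp.alpha, params.gp.sigma_e):
        lp += float(
            np.log(2.0)
            + stats.t.logpdf(scale, df=priors.scale_df, scale=priors.scale_scale)
        )
    lp += float(stats.invgamma.logpdf(params.gp.rho, priors.rho_shape, scale=priors.rho_rate))
    if not np.isfinite(lp):
        raise ValidationError("non-finite log posterior for valid-looking inputs")
    return lp


class RsmModel:
    """Unconstrained-parameter density and gradient used by the sampler."""

    def __init__(self, data: ObservationData, priors: PriorConfig = PriorConfig()):
        if data.n_obs == 0:
            raise ValidationError("cannot build a sampling model from empty data")
        self.data = data
        self.priors = priors
        self.d2 = pairwise_distances(data.layout) ** 2
        self.n_c = data.n_cultivars
        self.n_p = data.n_plots
        self.n_e = data.n_events
        self.M = data.M
        self._s = np.arange(self.M + 1)
        # unconstrained slices
        i = 0
        self.sl_eta = slice(i, i + self.n_c); i += self.n_c
        self.sl_loc = slice(i, i + self.n_p); i += self.n_p
        self.sl_beta = slice(i, i + self.n_e - 1); i += self.n_e - 1
        self.sl_tau = slice(i, i + self.M - 1); i += self.M - 1
        self.i_sigma, self.i_alpha, self.i_rho, self.i_sige = i, i + 1, i + 2, i + 3
        self.dim = i + 4

    # -- parameter transforms ------------------------------------------------
    def _gp_chol(self, alpha: float, rho: float, sigma_e: float):
        Kx = alpha**2 * np.exp(-self.d2 / (2.0 * rho**2))  # spatial part, no nugget
        K = Kx + sigma_e**2 * np.eye(self.n_p)
        return Kx, np.linalg.cholesky(K)

    def constrain(self, z: np.ndarray) -> RsmParameters:
        """Map an unconstrained vector to natural-scale parameters."""
        sigma, alpha, rho, sigma_e = np.exp(
            [z[self.i_sigma], z[self.i_alpha], z[self.i_rho], z[self.i_sige]]
        )
        _, L = self._gp_chol(alpha, rho, sigma_e)
        return RsmParameters(
            eta=sigma * z[self.sl_eta],
            loc=L @ z[self.sl_loc],
            beta=_complete(z[self.sl_beta]),
            tau=CategoryThresholds(_complete(z[self.sl_tau])),
            sigma=float(sigma),
            gp=GpHyperparams(float(alpha), float(rho), float(sigma_e)),
        )

    # -- density and gradient ------------------------------------------------
    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        d, pr = self.data, self.priors
        eta_raw = z[self.sl_eta]
        z_loc = z[self.sl_loc]
        beta_free = z[self.sl_beta]
        tau_free = z[self.sl_tau]
        ls, la, lr, le = z[self.i_sigma], z[self.i_alpha], z[self.i_rho], z[self.i_sige]
        with np.errstate(over="ignore"):
            sigma, alpha, rho, sigma_e = np.exp([ls, la, lr, le])
        if not np.all(np.isfinite([sigma, alpha, rho, sigma_e])):
            return -np.inf, np.zeros(self.dim)
        try:
            # extreme trajectories can make K numerically singular; the
            # sampler treats such points as divergent, not fatal
            Kx, L = self._gp_chol(alpha, rho, sigma_e)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(self.dim)
        loc = L @ z_loc
        eta = sigma * eta_raw
        beta = _complete(beta_free)
        tau = _complete(tau_free)
        theta = eta[d.cultivar_of_plot] + loc

        # likelihood: sum_n [ y*c - T[y] - logsumexp_s (s*c - T[s]) ]
        c = theta[d.plot_idx] - beta[d.event_idx]
        cum = np.concatenate([[0.0], np.cumsum(tau)])
        logw = c[:, None] * self._s - cum
        rowmax = logw.max(axis=1)
        w = np.exp(logw - rowmax[:, None])
        Z = w.sum(axis=1)
        P = w / Z[:, None]
        lp = float(np.sum(d.y * c - cum[d.y] - (np.log(Z) + rowmax)))

        # d loglik / dc per observation: y - E[s]
        dc = d.y - P @ self._s
        g_theta = np.bincount(d.plot_idx, weights=dc, minlength=self.n_p)
        g_eta = np.bincount(d.cultivar_of_plot, weights=g_theta, minlength=self.n_c)
        g_loc = g_theta.copy()
        g_beta = -np.bincount(d.event_idx, weights=dc, minlength=self.n_e)
        # d loglik / d tau_k = sum_n [ P(s >= k) - 1{y >= k} ],  k = 1..M
        tail = 1.0 - np.cumsum(P, axis=1)[:, : self.M]
        ind = d.y[:, None] >= np.arange(1, self.M + 1)
        g_tau = np.sum(tail - ind, axis=0)

        grad = np.zeros(self.dim)

        # non-centred latent priors: eta_raw, z_loc ~ N(0, 1)
        lp += -0.5 * float(eta_raw @ eta_raw) - 0.5 * float(z_loc @ z_loc)
        grad[self.sl_eta] = sigma * g_eta - eta_raw
        grad[self.sl_loc] = L.T @ g_loc - z_loc

        # sum-to-zero completion: last element is minus the sum of the free ones
        g_bf = g_beta[:-1] - g_beta[-1]
        g_tf = g_tau[:-1] - g_tau[-1]
        lp += -0.5 * float(beta_free @ beta_free) / pr.beta_sd**2
        lp += -0.5 * float(tau_free @ tau_free) / pr.tau_sd**2
        grad[self.sl_beta] = g_bf - beta_free / pr.beta_sd**2
        grad[self.sl_tau] = g_tf - tau_free / pr.tau_sd**2

        # scale parameters: half-t(df, 0, s) density + log-Jacobian of exp
        nu, s2 = pr.scale_df, pr.scale_scale**2
        for idx, val, lik_grad in (
            (self.i_sigma, sigma, float(g_eta @ eta) ),
            (self.i_alpha, alpha, None),
            (self.i_sige, sigma_e, None),
        ):
            q = val**2 / (nu * s2)
            lp += -0.5 * (nu + 1.0) * np.log1p(q) + np.log(val)
            grad[idx] += -(nu + 1.0) * q / (1.0 + q) + 1.0
            if lik_grad is not None:
                grad[idx] += lik_grad
        # rho ~ Inverse-Gamma(shape a, rate b), plus log-Jacobian
        a, b = pr.rho_shape, pr.rho_rate
        lp += -(a + 1.0) * lr - b / rho + lr
        grad[self.i_rho] += -a + b / rho

        # GP hyperparameter gradients through the Cholesky factor:
        # dL = L * Phi(L^-1 dK L^-T), Phi = lower triangle with halved diagonal
        dK_la = 2.0 * Kx                                   # d K / d log(alpha)
        dK_lr = Kx * (self.d2 / rho**2)                    # d K / d log(rho)
        dK_le = 2.0 * sigma_e**2 * np.eye(self.n_p)        # d K / d log(sigma_e)
        for idx, dK in ((self.i_alpha, dK_la), (self.i_rho, dK_lr), (self.i_sige, dK_le)):
            X = solve_triangular(L, dK, lower=True)
            A = solve_triangular(L, X.T, lower=True).T     # L^-1 dK L^-T
            Phi = np.tril(A)
            Phi[np.diag_indices_from(Phi)] *= 0.5
            dloc = L @ (Phi @ z_loc)
            grad[idx] += float(g_loc @ dloc)

        if not (np.isfinite(lp) and np.all(np.isfinite(grad))):
            return -np.inf, np.zeros(self.dim)
        return lp, grad
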