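"""Sampler plumbing, convergence diagnostics, and recovery reporting."""

import numpy as np
import pandas as pd
import pytest

import turfrsm
from turfrsm.core import CategoryThresholds, ValidationError
from turfrsm.inference import (
    PosteriorSamples,
    convergence_diagnostics,
    fit_rsm,
    recovery_report,
)
from turfrsm.model import RsmParameters
from turfrsm.sampler import NutsConfig, nuts_sample
from turfrsm.spatial import GpHyperparams, TrialLayout


def split_rhat_oracle(chains: np.ndarray) -> float:
    """Closed-form split R-hat: between/within variance ratio on half-chains."""
    m, n = chains.shape
    half = n // 2
    splits = np.vstack([chains[:, :half], chains[:, half: 2 * half]])
    w = splits.var(axis=1, ddof=1).mean()
    b = half * splits.mean(axis=1).var(ddof=1)
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))


def synthetic_samples(draws, lp=None, names=None):
    chains, per, P = draws.shape
    names = names or [f"p{i}" for i in range(P)]
    lp = lp if lp is not None else np.zeros((chains, per))
    return PosteriorSamples(draws=draws, param_names=list(names), lp=lp,
                            meta={}, coords={})


class TestNutsOnKnownDensity:
    def test_recovers_gaussian_moments(self):
        # correlated 4-d Gaussian: sample mean/cov must approach the truth
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        cov = A @ A.T + 4 * np.eye(4)
        mu = np.array([1.0, -2.0, 0.5, 3.0])
        prec = np.linalg.inv(cov)

        def logp_grad(z):
            d = z - mu
            return -0.5 * d @ prec @ d, -prec @ d

        res = nuts_sample(logp_grad, np.zeros(4), np.random.default_rng(1),
                          NutsConfig(iterations=3000, warmup=1000, thin=1))
        assert res.draws.shape[0] == 2000
        err = np.abs(res.draws.mean(axis=0) - mu)
        mcse = np.sqrt(np.diag(cov) / 200)  # conservative ESS guess
        assert np.all(err < 4 * mcse)
        np.testing.assert_allclose(np.cov(res.draws.T), cov, rtol=0.35, atol=0.5)


class TestFitRsm:
    def test_retained_draw_count_follows_protocol(self, recovery_fit):
        s = recovery_fit
        assert s.n_chains == 4
        assert s.draws.shape[1] == (1000 - 500) // 2
        assert s.n_draws == 1000

    def test_every_draw_satisfies_sum_to_zero_constraints(self, recovery_fit):
        beta = recovery_fit.extract("beta")
        tau = recovery_fit.extract("tau")
        assert np.abs(beta.sum(axis=2)).max() < 1e-8
        assert np.abs(tau.sum(axis=2)).max() < 1e-8

    def test_scale_parameters_positive_in_every_draw(self, recovery_fit):
        for name in ("sigma", "alpha", "rho", "sigma_e"):
            assert recovery_fit.extract(name).min() > 0

    def test_posterior_ordering_matches_mean_ratings_on_tiny_data(self):
        # sanity oracle: balanced data + symmetric priors => posterior
        # cultivar ordering agrees with empirical mean-rating ordering
        cfg = turfrsm.recovery_study_config(
            seed=17, n_cultivars=2, n_reps=2, n_months=2, n_raters=2,
            sigma=1.4, M=2, threshold_range=(-1.0, 1.0),
        )
        trial = turfrsm.simulate_trial(cfg)
        emp = trial.observations.groupby("cultivar")["rating"].mean()
        s = fit_rsm(trial.observations, trial.layout, chains=2, iterations=400,
                    warmup=200, thin=2, seed=3, M=2)
        eta = s.posterior_mean("eta")
        assert (np.argsort(eta) == np.argsort(emp.to_numpy())).all()

    def test_empty_data_rejected(self):
        layout = TrialLayout.from_grid(2, 2)
        with pytest.raises(ValidationError):
            fit_rsm(pd.DataFrame(columns=["plot_id", "cultivar", "event_id",
                                          "month", "rating"]), layout)


class TestConvergenceDiagnostics:
    def test_matches_closed_form_split_rhat(self):
        rng = np.random.default_rng(5)
        chains = rng.normal(size=(4, 250))
        s = synthetic_samples(chains[:, :, None], lp=rng.normal(size=(4, 250)))
        report = convergence_diagnostics(s)
        ours = report.table.loc[report.table.parameter == "p0", "rhat"].item()
        assert ours == pytest.approx(split_rhat_oracle(chains), rel=1e-6)

    def test_offset_chains_flagged_far_above_threshold(self):
        rng = np.random.default_rng(6)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        s = synthetic_samples(chains[:, :, None], lp=rng.normal(size=(2, 500)))
        report = convergence_diagnostics(s)
        assert report.max_rhat > 1.1
        assert report.max_rhat == pytest.approx(split_rhat_oracle(chains), rel=1e-6)
        assert not report.converged

    def test_constant_chains_reported_as_degenerate_not_converged(self):
        draws = np.ones((4, 100, 2))
        draws[:, :, 1] = np.random.default_rng(0).normal(size=(4, 100))
        s = synthetic_samples(draws, lp=np.ones((4, 100)))
        report = convergence_diagnostics(s)
        assert np.isnan(report.table.loc[report.table.parameter == "p0", "rhat"]).all()
        assert np.isnan(report.table.loc[report.table.parameter == "lp", "rhat"]).all()

    def test_single_chain_rejected(self):
        s = synthetic_samples(np.random.default_rng(0).normal(size=(1, 100, 2)))
        with pytest.raises(ValidationError, match="2 chains"):
            convergence_diagnostics(s)


def _tiny_truth():
    return RsmParameters(
        eta=np.array([0.2, -0.2]), loc=np.array([0.0, 0.1]),
        beta=np.array([0.1, -0.1]), tau=CategoryThresholds(np.array([-0.5, 0.5])),
        sigma=0.7, gp=GpHyperparams(0.15, 2.5, 0.2),
    )


def _names_for_tiny():
    return (["eta[A]", "eta[B]", "loc[P1]", "loc[P2]", "beta[E1]", "beta[E2]",
             "tau[1]", "tau[2]", "sigma", "alpha", "rho", "sigma_e"])


class TestRecoveryReport:
    def test_symmetric_spread_around_truth_includes_zero_everywhere(self, rng):
        truth = _tiny_truth()
        tv = np.concatenate([truth.eta, truth.loc, truth.beta, truth.tau.tau,
                             [truth.sigma, truth.gp.alpha, truth.gp.rho,
                              truth.gp.sigma_e]])
        draws = tv + rng.normal(0, 0.3, size=(2, 400, tv.size))
        s = synthetic_samples(draws, names=_names_for_tiny())
        report = recovery_report(s, truth)
        assert report.n_excluding_zero == 0
        assert report.n_parameters == tv.size

    def test_point_mass_off_truth_excludes_zero_everywhere(self):
        truth = _tiny_truth()
        tv = np.concatenate([truth.eta, truth.loc, truth.beta, truth.tau.tau,
                             [truth.sigma, truth.gp.alpha, truth.gp.rho,
                              truth.gp.sigma_e]])
        draws = np.tile(tv + 1.0, (2, 50, 1))
        s = synthetic_samples(draws, names=_names_for_tiny())
        report = recovery_report(s, truth)
        assert report.n_excluding_zero == report.n_parameters
        widths = report.table["q97.5"] - report.table["q2.5"]
        assert np.allclose(widths, 0.0)

    def test_dimension_mismatch_rejected(self):
        truth = _tiny_truth()
        s = synthetic_samples(np.zeros((2, 10, 3)))
        with pytest.raises(ValidationError, match="monitors"):
            recovery_report(s, truth)


class TestPosteriorRoundTrip:
    def test_dataframe_round_trip_preserves_draws(self, rng):
        draws = rng.normal(size=(3, 20, 4))
        s = synthetic_samples(draws, lp=rng.normal(size=(3, 20)),
                              names=["a", "b", "c", "d"])
        df = s.to_dataframe()
        s2 = PosteriorSamples.from_dataframe(df)
        np.testing.assert_allclose(s2.draws, s.draws)
        np.testing.assert_allclose(s2.lp, s.lp)
        assert s2.param_names == s.param_names
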