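"""Applied diagnostics: histograms, widths, trends, maps, variance shares."""

import numpy as np
import pandas as pd
import pytest

from turfrsm.core import CategoryThresholds, ValidationError
from turfrsm.diagnostics import (
    VariancePartition,
    category_widths,
    cross_location_table,
    monthly_histograms,
    severity_trend,
    spatial_map,
    variance_partition,
)
from turfrsm.inference import PosteriorSamples
from turfrsm.model import ObservationData
from turfrsm.spatial import TrialLayout


class TestMonthlyHistograms:
    def test_singleton_rating_lands_in_its_month(self):
        df = pd.DataFrame({"month": [5], "rating": [5]})
        out = monthly_histograms(df)
        assert out.shape[0] == 1
        assert out.loc[0, "count_5"] == 1
        assert out.loc[0, "month"] == 5

    def test_summary_reports_range_and_median(self):
        # winter-dormancy pattern: ratings squeezed into [3, 6], median 4
        df = pd.DataFrame({"month": 2, "rating": [3, 4, 4, 5, 6, 4, 3]})
        out = monthly_histograms(df)
        assert (out.loc[0, "lo"], out.loc[0, "hi"]) == (3, 6)
        assert out.loc[0, "median"] == 4

    def test_uniform_ratings_give_flat_histogram(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"month": 6, "rating": rng.integers(1, 10, 9000)})
        out = monthly_histograms(df)
        counts = out.filter(like="count_").to_numpy().ravel()
        assert counts.min() > 0.8 * counts.max()

    def test_missing_month_rows_excluded_with_warning(self):
        df = pd.DataFrame({"month": [5, None], "rating": [5, 6]})
        with pytest.warns(UserWarning, match="missing month"):
            out = monthly_histograms(df)
        assert out["count_6"].sum() == 0


class TestCategoryWidths:
    def test_even_spacing_gives_constant_widths(self):
        tau = CategoryThresholds(np.linspace(-2, 2, 8))
        widths, ordered = category_widths(tau)
        np.testing.assert_allclose(widths, 4 / 7)
        assert ordered and widths.size == 7

    def test_reports_narrow_category_width(self):
        # a narrow second category of 0.59 logits, as seen in practice
        free = np.array([-1.0, -0.41, 0.1, 0.5, 0.9, 1.4, 1.8])
        tau = CategoryThresholds.from_free(free)
        widths, ordered = category_widths(tau)
        assert widths[0] == pytest.approx(0.59)

    def test_disorder_yields_negative_width_and_flag(self):
        tau = CategoryThresholds(np.array([0.5, 1.0, 0.2, -1.7]))
        widths, ordered = category_widths(tau)
        assert (widths < 0).any() and not ordered

    def test_widths_telescope_to_threshold_range(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tau = CategoryThresholds.from_free(rng.normal(0, 2, 7))
            widths, _ = category_widths(tau)
            assert widths.sum() == pytest.approx(tau.tau[-1] - tau.tau[0], abs=1e-12)


class TestSeverityTrend:
    def test_constant_severity_gives_flat_curve(self):
        df = pd.DataFrame({"rater": "R1", "month": np.arange(1, 13),
                           "beta": 0.4})
        out = severity_trend(df)
        np.testing.assert_allclose(out["trends"]["smoothed"], 0.4, atol=1e-12)

    def test_linear_severity_stays_monotone(self):
        df = pd.DataFrame({"rater": "R1", "month": np.arange(1, 13),
                           "beta": np.linspace(-1, 1, 12)})
        out = severity_trend(df)
        assert np.all(np.diff(out["trends"]["smoothed"]) > 0)

    def test_smoother_tracks_sinusoid_within_noise(self):
        rng = np.random.default_rng(9)
        months = np.tile(np.arange(1, 13), 6)
        signal = 0.8 * np.sin(2 * np.pi * months / 12)
        noise_sd = 0.25
        df = pd.DataFrame({"rater": "R1", "month": months,
                           "beta": signal + rng.normal(0, noise_sd, months.size)})
        out = severity_trend(df, smoothing_fraction=0.35)
        merged = out["trends"]
        truth = 0.8 * np.sin(2 * np.pi * merged["month"] / 12)
        rmse = np.sqrt(np.mean((merged["smoothed"] - truth) ** 2))
        assert rmse < noise_sd

    def test_raters_below_event_threshold_excluded(self):
        df = pd.DataFrame({"rater": ["R1"] * 3 + ["R2"] * 8,
                           "month": list(range(1, 4)) + list(range(1, 9)),
                           "beta": 0.1})
        out = severity_trend(df)
        assert out["excluded"] == ["R1"]
        assert set(out["trends"]["rater"]) == {"R2"}
        assert set(out["severity_sd"]["rater"]) == {"R1", "R2"}


class TestSpatialMap:
    def test_zero_field_maps_to_zero_matrix(self):
        layout = TrialLayout.from_grid(3, 4)
        grid = spatial_map(np.zeros(12), layout)
        np.testing.assert_array_equal(grid, 0.0)

    def test_single_hot_plot_localised(self):
        layout = TrialLayout.from_grid(3, 4)
        loc = np.zeros(12)
        loc[5] = 2.5
        grid = spatial_map(loc, layout)
        r, c = layout.row[5] - 1, layout.col[5] - 1
        assert grid[r, c] == 2.5
        assert np.count_nonzero(grid) == 1

    def test_bijection_between_plots_and_cells(self):
        layout = TrialLayout.from_grid(3, 10)
        grid = spatial_map(np.arange(30, dtype=float), layout)
        assert np.isfinite(grid).sum() == 30
        assert set(grid.ravel()) == set(np.arange(30.0))

    def test_missing_cells_marked(self):
        layout = TrialLayout(plot_ids=np.array(["a", "b"]),
                             row=np.array([1, 2]), col=np.array([1, 2]),
                             x=np.array([1.0, 2.0]), y=np.array([1.0, 2.0]))
        grid = spatial_map(np.array([1.0, 2.0]), layout)
        assert np.isnan(grid[0, 1]) and np.isnan(grid[1, 0])


class TestCrossLocationTable:
    def test_single_location_identity(self):
        table = cross_location_table({"MN": {"A": 0.5, "B": -0.5}})
        np.testing.assert_allclose(table["MN"].to_numpy(), [0.5, -0.5])

    def test_below_average_everywhere_flagged_by_sign(self):
        table = cross_location_table(
            {"MN": {"A": 0.5, "K": -0.3}, "OK": {"A": -0.1, "K": -0.6}}
        )
        assert (table.loc["K"] < 0).all()

    def test_pairwise_differences_by_subtraction(self):
        table = cross_location_table(
            {"MN": {"A": 0.5, "B": 0.1}, "OK": {"A": 0.4, "B": -0.2}}
        )
        diff = table.loc["A"] - table.loc["B"]
        np.testing.assert_allclose(diff.to_numpy(), [0.4, 0.6])

    def test_absent_cultivar_is_missing_not_zero(self):
        table = cross_location_table({"MN": {"A": 0.5}, "OK": {"A": 0.4, "B": 0.2}})
        assert np.isnan(table.loc["B", "MN"])


def _samples_with_components(eta_by_plot, beta, loc, data):
    """Build a synthetic posterior with identical draws from given fields."""
    n_c, n_p, n_e = (data.n_cultivars, data.n_plots, data.n_events)
    names = ([f"eta[{c}]" for c in data.cultivar_names]
             + [f"loc[{p}]" for p in data.layout.plot_ids]
             + [f"beta[{e}]" for e in data.event_ids]
             + [f"tau[{s}]" for s in range(1, data.M + 1)]
             + ["sigma", "alpha", "rho", "sigma_e"])
    vec = np.concatenate([eta_by_plot, loc, beta, np.zeros(data.M),
                          [0.7, 0.15, 2.5, 0.2]])
    draws = np.tile(vec, (2, 10, 1))
    return PosteriorSamples(draws=draws, param_names=names,
                            lp=np.zeros((2, 10)), meta={}, coords={})


@pytest.fixture()
def grid_data():
    layout = TrialLayout.from_grid(2, 3)
    rows = []
    for e in ("E1", "E2"):
        for i, pid in enumerate(layout.plot_ids):
            rows.append({"plot_id": pid, "cultivar": f"C{i % 3}", "rater": "R1",
                         "event_id": e, "month": 1, "rating": 4})
    return ObservationData(pd.DataFrame(rows), layout, M=8)


class TestVariancePartition:
    def test_single_active_component_takes_all_variance(self, grid_data):
        d = grid_data
        eta = np.array([-0.5, 0.0, 0.5])
        s = _samples_with_components(eta, np.zeros(d.n_events), np.zeros(d.n_plots), d)
        vp = variance_partition(s, d)
        assert vp.pct_cultivar == pytest.approx(100.0)
        assert vp.pct_severity == pytest.approx(0.0)
        assert vp.pct_spatial == pytest.approx(0.0)

    def test_all_zero_components_degenerate(self, grid_data):
        d = grid_data
        s = _samples_with_components(np.zeros(3), np.zeros(d.n_events),
                                     np.zeros(d.n_plots), d)
        vp = variance_partition(s, d)
        assert vp.degenerate

    def test_dominant_severity_spread_outweighs_cultivar(self, grid_data):
        d = grid_data
        eta = np.array([-0.1, 0.0, 0.1])
        beta = np.array([-2.0, 2.0])
        s = _samples_with_components(eta, beta, np.zeros(d.n_plots), d)
        vp = variance_partition(s, d)
        assert vp.pct_severity > vp.pct_cultivar

    def test_percentages_always_sum_to_hundred(self, grid_data):
        d = grid_data
        rng = np.random.default_rng(2)
        s = _samples_with_components(rng.normal(0, 1, 3), rng.normal(0, 1, 2),
                                     rng.normal(0, 0.3, d.n_plots), d)
        vp = variance_partition(s, d)
        assert vp.pct_cultivar + vp.pct_severity + vp.pct_spatial == pytest.approx(100.0, abs=1e-9)

    def test_partition_validation(self):
        with pytest.raises(ValidationError):
            VariancePartition(50.0, 10.0, 10.0)


class TestSpatialRecovery:
    def test_estimated_field_correlates_with_generating_field(
        self, recovery_trial, recovery_fit
    ):
        # posterior-mean spatial effects must track the simulated field
        from scipy import stats as sps

        loc_hat = recovery_fit.posterior_mean("loc")
        r = sps.pearsonr(loc_hat, recovery_trial.truth.loc).statistic
        assert r > 0.5
        grid = spatial_map(loc_hat, recovery_trial.layout)
        assert np.isfinite(grid).sum() == recovery_trial.layout.n_plots
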