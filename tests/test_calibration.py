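import numpy as np
import pandas as pd
import pytest

from exposim.calibration import (
    DistanceDecayFit,
    SitePairSeries,
    estimate_instrument_error,
    fit_distance_decay,
    generate_site_fixtures,
    pairwise_standardized_correlations,
    read_sites_csv,
    summarize_sites,
    write_sites_csv,
)
from exposim.errors import CtmSpec
from exposim.geometry import URBAN_OZONE_CORRELATION, CorrelationModel, DistanceModel

URBAN_FIXTURE_PARAMS = dict(
    correlation=URBAN_OZONE_CORRELATION,
    site_mean=61.73,
    site_mean_sd=7.38,
    within_site_sd=25.28,
    sigma_err=6.77,
    ctm=CtmSpec(
        cov_xz=455.78, var_z=23.41**2, var_xstar=25.28**2 - 6.77**2, bias_c=10.25
    ),
)


def make_site(site_id="A", site_type="urban", e=0.0, n=0.0, monitor=None, ctm=None,
              n_days=400):
    if monitor is None:
        monitor = np.random.default_rng(0).normal(60, 20, n_days)
    if ctm is None:
        ctm = monitor
    return SitePairSeries(
        site_id=site_id, site_type=site_type, easting_km=e, northing_km=n,
        records=pd.DataFrame(
            {
                "date": pd.date_range("2003-01-01", periods=len(monitor)),
                "monitor_value": monitor,
                "ctm_value": ctm,
            }
        ),
    )


@pytest.fixture(scope="module")
def urban_fixtures():
    return generate_site_fixtures(
        n_urban=35, n_rural=0, area_km=600.0, n_days=1095, seed=42,
        **URBAN_FIXTURE_PARAMS,
    )


class TestSummarizeSites:
    def test_identical_channels(self):
        summary = summarize_sites([make_site()], min_days=364)
        s = summary.by_type["urban"]
        assert s.mean_correlation == pytest.approx(1.0)
        assert s.mean_of_mean_diff == 0.0
        # zero-variance differences: correlation with differences is missing
        assert np.isnan(s.mean_corr_monitor_with_diff)

    def test_short_site_excluded(self):
        short = make_site(site_id="B", n_days=100)
        with pytest.warns(UserWarning, match="excluded"):
            summary = summarize_sites([make_site(), short], min_days=364)
        assert summary.n_sites_excluded == 1
        assert summary.by_type["urban"].n_sites == 1

    def test_fixture_recovery_of_generating_parameters(self, urban_fixtures):
        summary = summarize_sites(urban_fixtures, min_days=364)
        s = summary.by_type["urban"]
        assert s.n_sites == 35
        # 3-sigma-style tolerances for 35 sites x 1095 days
        assert s.mean_of_site_means_monitor == pytest.approx(61.73, abs=4.0)
        assert s.sd_of_site_means_monitor == pytest.approx(7.38, abs=2.7)
        assert s.mean_within_sd_monitor == pytest.approx(25.28, abs=0.8)
        assert s.mean_within_sd_ctm == pytest.approx(23.41, abs=0.8)
        assert s.mean_covariance == pytest.approx(455.78, rel=0.08)
        assert s.mean_of_mean_diff == pytest.approx(10.25, abs=0.35)

    def test_missingness_drops_sites_below_threshold(self):
        # 40% missing per channel: paired days ~ Bin(500, 0.36), far below 364
        sites = generate_site_fixtures(
            n_urban=5, n_rural=0, area_km=300.0, n_days=500, missing_rate=0.4,
            seed=7, **URBAN_FIXTURE_PARAMS,
        )
        assert all(s.n_paired_days < 364 for s in sites)
        with pytest.warns(UserWarning):
            summary = summarize_sites(sites, min_days=364)
        assert summary.n_sites_excluded == 5
        assert "urban" not in summary.by_type


class TestPairwiseCorrelations:
    def test_identical_series_correlate_perfectly(self):
        mon = np.random.default_rng(1).normal(60, 20, 400)
        a = make_site("A", e=0.0, monitor=mon)
        b = make_site("B", e=30.0, monitor=mon)
        pairs = pairwise_standardized_correlations([a, b], min_paired=364)
        assert len(pairs) == 1
        assert pairs["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert pairs["distance_km"].iloc[0] == 30.0

    def test_short_overlap_omitted(self):
        a = make_site("A", n_days=400)
        b = make_site("B", e=10.0, n_days=200,
                      monitor=np.random.default_rng(2).normal(60, 20, 200))
        pairs = pairwise_standardized_correlations([a, b], min_paired=364)
        assert len(pairs) == 0

    def test_cross_type_pairs_excluded(self):
        a = make_site("A")
        b = make_site("B", site_type="rural", e=10.0,
                      monitor=np.random.default_rng(3).normal(60, 20, 400))
        assert len(pairwise_standardized_correlations([a, b], min_paired=364)) == 0

    def test_standardization_is_mean_zero_unit_sd(self, urban_fixtures):
        s = urban_fixtures[0]
        p = s.paired
        std = (p["monitor_value"] - p["monitor_value"].mean()) / p["monitor_value"].std(ddof=1)
        assert std.mean() == pytest.approx(0.0, abs=1e-12)
        assert std.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestFitDistanceDecay:
    def test_exact_linear_relationship(self):
        d = np.array([10.0, 50.0, 120.0, 300.0])
        fit = fit_distance_decay(list(zip(d, 0.9 - 0.001 * d)))
        assert fit.intercept == pytest.approx(0.9, abs=1e-12)
        assert fit.slope_per_km == pytest.approx(-0.001, abs=1e-14)
        assert fit.r_squared == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_distance_decay([(5.0, 0.9), (5.0, 0.8)])

    def test_quadratic_gain_negligible_on_linear_truth(self, urban_fixtures):
        pairs = pairwise_standardized_correlations(urban_fixtures, min_paired=364)
        fit = fit_distance_decay(pairs, include_quadratic=True)
        assert fit.r_squared_gain < 0.01

    def test_recovers_generating_decay_model(self, urban_fixtures):
        pairs = pairwise_standardized_correlations(urban_fixtures, min_paired=364)
        assert len(pairs) == 35 * 34 // 2
        fit = fit_distance_decay(pairs)
        assert fit.intercept == pytest.approx(0.93031, abs=0.02)
        assert fit.slope_per_km == pytest.approx(-0.00080, abs=0.0002)


class TestEstimateInstrumentError:
    def test_hand_arithmetic_case(self):
        fit = DistanceDecayFit(intercept=0.75, slope_per_km=0.0, r_squared=1.0, n_pairs=10)
        assert estimate_instrument_error(fit, DistanceModel(), 100.0) == pytest.approx(5.0)

    def test_published_urban_ozone_inputs(self):
        # (1 - 0.92823) * 25.28^2 => sigma_err ~= 6.79, near the published 6.77
        sd = estimate_instrument_error(
            URBAN_OZONE_CORRELATION, DistanceModel(), 25.28**2
        )
        assert sd == pytest.approx(6.77, abs=0.05)

    def test_perfect_reliability_gives_zero(self):
        fit = DistanceDecayFit(intercept=1.0, slope_per_km=0.0, r_squared=1.0, n_pairs=5)
        assert estimate_instrument_error(fit, DistanceModel(), 100.0) == 0.0

    def test_monotone_decreasing_in_within_square_correlation(self):
        sds = [
            estimate_instrument_error(
                DistanceDecayFit(intercept=r, slope_per_km=0.0, r_squared=1.0, n_pairs=5),
                DistanceModel(),
                100.0,
            )
            for r in np.linspace(0.5, 1.0, 11)
        ]
        assert np.all(np.diff(sds) < 0)

    def test_out_of_range_correlation_rejected(self):
        fit = DistanceDecayFit(intercept=0.2, slope_per_km=-0.01, r_squared=1.0, n_pairs=5)
        with pytest.raises(ValueError):
            estimate_instrument_error(fit, DistanceModel(within_square_D_km=30.0), 100.0)


class TestFixturesAndIO:
    def test_no_error_limit_channels_identical(self):
        sites = generate_site_fixtures(
            n_urban=3, n_rural=0, area_km=100.0,
            correlation=CorrelationModel(intercept=0.9, slope_per_km=-0.0005),
            site_mean=50.0, site_mean_sd=5.0, within_site_sd=20.0, sigma_err=0.0,
            ctm=None, n_days=400, seed=5,
        )
        for s in sites:
            assert np.array_equal(
                s.records["monitor_value"].to_numpy(), s.records["ctm_value"].to_numpy()
            )

    def test_full_recovery_loop(self, urban_fixtures):
        """Headline chain: fixtures -> decay fit -> implied instrument error."""
        pairs = pairwise_standardized_correlations(urban_fixtures, min_paired=364)
        fit = fit_distance_decay(pairs)
        summary = summarize_sites(urban_fixtures, min_days=364)
        mwv = summary.by_type["urban"].mean_within_sd_monitor ** 2
        sigma_err = estimate_instrument_error(fit, DistanceModel(), mwv)
        assert sigma_err == pytest.approx(6.77, abs=1.0)

    def test_csv_round_trip(self, tmp_path, urban_fixtures):
        path = tmp_path / "sites.csv"
        write_sites_csv(urban_fixtures[:3], path)
        back = read_sites_csv(path)
        assert [s.site_id for s in back] == [s.site_id for s in urban_fixtures[:3]]
        for a, b in zip(urban_fixtures[:3], back):
            assert np.allclose(
                a.records["monitor_value"], b.records["monitor_value"], equal_nan=True
            )

    def test_deterministic_given_seed(self):
        kw = dict(n_urban=2, n_rural=1, area_km=100.0, n_days=30, seed=9,
                  **URBAN_FIXTURE_PARAMS)
        a = generate_site_fixtures(**kw)
        b = generate_site_fixtures(**kw)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.records, y.records)

    def test_duplicate_dates_rejected(self):
        records = pd.DataFrame(
            {
                "date": ["2003-01-01", "2003-01-01"],
                "monitor_value": [1.0, 2.0],
                "ctm_value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            SitePairSeries("A", "urban", 0.0, 0.0, records)
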