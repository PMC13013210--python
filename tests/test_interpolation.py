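"""Drift fitting, variogram estimation, and ordinary kriging of residuals."""

import numpy as np
import pytest

from simmermap.grid import Grid
from simmermap.interpolation import (
    DegenerateDesignError,
    InterpolationConfig,
    StationRecord,
    VariogramEstimate,
    VariogramKind,
    VariogramModel,
    dedupe_stations,
    empirical_variogram,
    fit_drift,
    fit_variogram,
    interpolate_surface,
    krige_point,
)
from simmermap.synthetic import ScenarioConfig, make_scenario


def stations_on_line(n, lapse=-0.0065, base=30.0, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 10_000, (n, 2))
    elev = rng.uniform(0, 1500, n)
    vals = base + lapse * elev
    if noise:
        vals = vals + rng.normal(0, noise, n)
    return [StationRecord(x, y, e, v) for (x, y), e, v in zip(xy, elev, vals)]


class TestDrift:
    def test_noiseless_recovery_is_exact(self):
        model, resid = fit_drift(stations_on_line(20))
        assert model.elevation_coef == pytest.approx(-0.0065, abs=1e-12)
        assert model.intercept == pytest.approx(30.0, abs=1e-9)
        assert np.allclose(resid, 0.0)

    def test_two_stations_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_drift(stations_on_line(2))

    def test_constant_elevation_degenerate(self):
        sts = [StationRecord(i * 100.0, 0.0, 500.0, 25.0) for i in range(5)]
        with pytest.raises(DegenerateDesignError):
            fit_drift(sts)

    def test_noisy_recovery_within_ten_percent(self):
        model, _ = fit_drift(stations_on_line(60, noise=0.5, seed=1))
        assert abs(model.elevation_coef - (-0.0065)) / 0.0065 < 0.1


class TestEmpiricalVariogram:
    def test_constant_residuals_give_zero_semivariance(self):
        sts = stations_on_line(15)
        est = empirical_variogram(sts, np.zeros(15), n_lags=6, max_dist=20_000)
        ok = est.pair_counts > 0
        assert np.allclose(est.semivariances[ok], 0.0)

    def test_two_points_closed_form(self):
        sts = [StationRecord(0, 0, 0, 0), StationRecord(100, 0, 0, 0)]
        est = empirical_variogram(sts, np.array([1.0, 4.0]), n_lags=1, max_dist=200)
        # gamma = (z1 - z2)^2 / 2 = 4.5
        assert est.semivariances[0] == pytest.approx(4.5)
        assert est.pair_counts[0] == 1

    def test_empty_bins_flagged_not_dropped(self):
        sts = [StationRecord(0, 0, 0, 0), StationRecord(10, 0, 0, 0)]
        est = empirical_variogram(sts, np.array([0.0, 1.0]), n_lags=4, max_dist=100)
        assert len(est.pair_counts) == 4
        assert np.isnan(est.semivariances[est.pair_counts == 0]).all()

    def test_tracks_known_model_on_simulated_field(self):
        # dense sample of a spectral field with exponential correlogram:
        # the binned estimator must rise with distance toward the sill
        bundle = make_scenario(ScenarioConfig(seed=5, n_stations=200))
        _, resid = fit_drift(bundle.temp_stations)
        est = empirical_variogram(bundle.temp_stations, resid, n_lags=10)
        ok = est.pair_counts > 0
        g = est.semivariances[ok]
        assert g[0] < g[3:].mean()  # short lags below the sill plateau


class TestFitVariogram:
    @pytest.mark.parametrize("kind", list(VariogramKind))
    def test_self_consistent_recovery(self, kind):
        true = VariogramModel(kind, 0.2, 1.5, 900.0)
        h = np.linspace(60, 2500, 18)
        est = VariogramEstimate(h, true(h), np.full(18, 50))
        fit = fit_variogram(est, kind)
        assert fit.nugget == pytest.approx(true.nugget, abs=1e-3)
        assert fit.partial_sill == pytest.approx(true.partial_sill, rel=1e-3)
        assert fit.range_param == pytest.approx(true.range_param, rel=1e-3)

    def test_all_zero_semivariances_mean_pure_drift(self):
        est = VariogramEstimate(np.array([1.0, 2, 3, 4]), np.zeros(4), np.full(4, 5))
        fit = fit_variogram(est)
        assert fit.nugget == 0.0 and fit.partial_sill == 0.0

    def test_too_few_bins_error(self):
        est = VariogramEstimate(np.array([1.0, 2.0]), np.array([0.5, 0.6]), np.array([3, 3]))
        with pytest.raises(ValueError, match="3 non-empty"):
            fit_variogram(est)


class TestKrigePoint:
    MODEL = VariogramModel(VariogramKind.EXPONENTIAL, 0.0, 1.0, 500.0)

    def test_exact_at_station_with_zero_nugget(self):
        sts = stations_on_line(8, seed=2)
        resid = np.random.default_rng(2).normal(0, 1, 8)
        r = krige_point((sts[3].x, sts[3].y), sts, resid, self.MODEL)
        assert r.prediction == pytest.approx(resid[3], abs=1e-9)
        assert r.variance == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_pair_gets_equal_weights(self):
        sts = [StationRecord(-100, 0, 0, 1.0), StationRecord(100, 0, 0, 3.0)]
        r = krige_point((0, 0), sts, np.array([1.0, 3.0]), self.MODEL)
        assert r.weights == pytest.approx([0.5, 0.5], abs=1e-12)
        assert r.prediction == pytest.approx(2.0)

    def test_weights_sum_to_one_on_random_configurations(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(3, 30)
            sts = [StationRecord(x, y, 0, v) for x, y, v in rng.uniform(0, 1000, (n, 3))]
            target = tuple(rng.uniform(0, 1000, 2))
            r = krige_point(target, sts, np.array([s.value for s in sts]), self.MODEL,
                            neighborhood=12)
            assert abs(r.weights.sum() - 1.0) < 1e-9

    def test_three_point_system_matches_dense_solve(self):
        sts = [StationRecord(0, 0, 0, 1.0), StationRecord(800, 0, 0, -0.5),
               StationRecord(300, 600, 0, 0.25)]
        z = np.array([s.value for s in sts])
        target = (250.0, 200.0)
        r = krige_point(target, sts, z, self.MODEL)
        # independent dense assembly and solve of the same OK system
        xy = np.array([(s.x, s.y) for s in sts])
        a = np.zeros((4, 4))
        for i in range(3):
            for j in range(3):
                a[i, j] = self.MODEL(np.hypot(*(xy[i] - xy[j])))
        a[3, :3] = a[:3, 3] = 1.0
        b = np.append([self.MODEL(np.hypot(*(xy[i] - target))) for i in range(3)], 1.0)
        lam = np.linalg.solve(a, b)
        assert r.weights == pytest.approx(lam[:3], abs=1e-10)
        assert r.prediction == pytest.approx(lam[:3] @ z, abs=1e-10)

    def test_duplicate_coordinates_rejected(self):
        sts = [StationRecord(0, 0, 0, 1.0), StationRecord(0, 0, 0, 2.0),
               StationRecord(5, 5, 0, 3.0)]
        with pytest.raises(ValueError, match="duplicate"):
            krige_point((1, 1), sts, np.array([1.0, 2.0, 3.0]), self.MODEL)

    def test_dedupe_averages_with_warning(self):
        sts = [StationRecord(0, 0, 100, 1.0), StationRecord(0, 0, 200, 3.0),
               StationRecord(5, 5, 0, 3.0)]
        with pytest.warns(UserWarning, match="duplicate"):
            out = dedupe_stations(sts)
        assert len(out) == 2
        merged = next(s for s in out if s.x == 0)
        assert merged.value == 2.0 and merged.elevation == 150.0


class TestInterpolateSurface:
    def test_zero_noise_equals_drift_of_dem(self, small_bundle):
        cfg = ScenarioConfig(shape=(30, 30), residual_sd=0.0, rh_residual_sd=0.0,
                             n_stations=20, n_zones=4)
        bundle = make_scenario(cfg)
        surface = interpolate_surface(bundle.temp_stations, bundle.dem)
        truth = cfg.base_temp + cfg.lapse_rate * bundle.dem.values.astype(float)
        err = np.abs(surface.values.astype(float) - truth)
        assert err.max() < 1e-4  # float32 storage bounds the residual error

    def test_exact_at_station_pixels(self, small_bundle):
        surface = interpolate_surface(small_bundle.temp_stations, small_bundle.dem)
        x0, px, _, y0, _, py = small_bundle.dem.transform
        for s in small_bundle.temp_stations[:10]:
            col = int((s.x - x0) / px)
            row = int((s.y - y0) / py)
            assert surface.values[row, col] == pytest.approx(s.value, abs=5e-3)

    def test_nodata_where_dem_nodata(self, small_bundle):
        dem = small_bundle.dem
        vals = dem.values.copy()
        vals[:5, :5] = dem.nodata
        holey = Grid(vals, dem.transform, dem.crs, nodata=dem.nodata)
        surface = interpolate_surface(small_bundle.temp_stations, holey)
        assert (surface.values[:5, :5] == surface.nodata).all()

    def test_all_stations_outside_dem_error(self, small_bundle):
        far = [StationRecord(0.0, 0.0, 100.0, 20.0),
               StationRecord(10.0, 0.0, 120.0, 21.0),
               StationRecord(0.0, 10.0, 140.0, 22.0)]
        with pytest.raises(ValueError, match="outside"):
            interpolate_surface(far, small_bundle.dem)

    def test_geographic_dem_rejected(self):
        dem = Grid(np.zeros((4, 4)) + 10, (35.0, 0.01, 0, 37.0, 0, -0.01), "EPSG:4326")
        with pytest.raises(ValueError, match="geographic"):
            interpolate_surface(stations_on_line(5), dem)

    def test_covariate_reduces_rmse(self, default_bundle):
        bundle = default_bundle
        truth = bundle.temp_truth.values.astype(float)
        with_drift = interpolate_surface(bundle.temp_stations, bundle.dem)
        without = interpolate_surface(bundle.temp_stations, bundle.dem,
                                      InterpolationConfig(use_elevation_drift=False))

        def rmse(surface):
            return np.sqrt(np.mean((surface.values.astype(float) - truth) ** 2))

        assert rmse(with_drift) <= rmse(without)
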