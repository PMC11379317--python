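"""Variograms, ordinary kriging, totals, Moran's I."""

import numpy as np
import pandas as pd
import pytest

from zoosonde.geostats import (
    KrigedField,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    great_circle_km,
    krige_at,
    morans_i,
    ordinary_krige,
    total_biomass,
)


def scatter_points(n=30, seed=0, value_fn=None):
    rng = np.random.default_rng(seed)
    lon = -17.6 + rng.uniform(0, 0.5, n)
    lat = 14.3 + rng.uniform(0, 0.5, n)
    if value_fn is None:
        vals = rng.uniform(0, 1, n)
    else:
        vals = value_fn(lon, lat, rng)
    return pd.DataFrame({"lon": lon, "lat": lat, "value": vals})


class TestEmpiricalVariogram:
    def test_constant_field_has_zero_semivariance(self):
        pts = scatter_points(12)
        pts["value"] = 3.0
        emp = empirical_variogram(pts, n_bins=5)
        assert (emp["semivariance"] == 0).all()

    def test_matches_brute_force(self):
        pts = scatter_points(12, seed=1)
        emp = empirical_variogram(pts, n_bins=1, max_dist_km=1e4)
        lon, lat, z = pts["lon"].to_numpy(), pts["lat"].to_numpy(), pts["value"].to_numpy()
        acc, cnt = 0.0, 0
        for i in range(12):
            for j in range(i + 1, 12):
                acc += 0.5 * (z[i] - z[j]) ** 2
                cnt += 1
        assert emp["semivariance"].iloc[0] == pytest.approx(acc / cnt)
        assert emp["n_pairs"].iloc[0] == cnt

    def test_white_noise_is_flat_at_variance(self):
        rng = np.random.default_rng(5)
        pts = scatter_points(300, seed=5, value_fn=lambda lon, lat, r: r.normal(0, 1, 300))
        emp = empirical_variogram(pts, n_bins=6)
        # every bin close to the process variance (1); sill estimate unbiased
        np.testing.assert_allclose(emp["semivariance"], 1.0, atol=0.25)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            empirical_variogram(scatter_points(5))

    def test_coincident_points_rejected(self):
        pts = scatter_points(12)
        pts["lon"] = -17.6
        pts["lat"] = 14.3
        with pytest.raises(ValueError):
            empirical_variogram(pts)


class TestFitVariogram:
    def _simulate_spherical(self, n=200, seed=11, nugget=0.1, psill=1.0, range_km=55.0):
        rng = np.random.default_rng(seed)
        lon = -17.6 + rng.uniform(0, 1.0, n)
        lat = 14.0 + rng.uniform(0, 1.0, n)
        vgm = VariogramModel("spherical", nugget, psill, range_km)
        d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        cov = (nugget + psill) - vgm(d)
        cov[np.diag_indices(n)] = nugget + psill
        chol = np.linalg.cholesky(cov + 1e-9 * np.eye(n))
        z = chol @ rng.standard_normal(n)
        return pd.DataFrame({"lon": lon, "lat": lat, "value": z}), vgm

    def test_recovers_known_model(self):
        pts, truth = self._simulate_spherical()
        emp = empirical_variogram(pts, n_bins=14, max_dist_km=110.0)
        fit = fit_variogram(emp, "spherical")
        assert fit.psill + fit.nugget == pytest.approx(truth.psill + truth.nugget, rel=0.25)
        assert fit.range_km == pytest.approx(truth.range_km, rel=0.25)

    def test_flat_variogram_flagged(self):
        emp = pd.DataFrame(
            {"dist_km": [1.0, 2, 3, 4, 5], "semivariance": [1.0] * 5, "n_pairs": [50] * 5}
        )
        fit = fit_variogram(emp)
        assert fit.flagged_flat or fit.range_km < 1.0

    def test_negative_semivariance_rejected(self):
        emp = pd.DataFrame(
            {"dist_km": [1.0, 2, 3, 4], "semivariance": [0.1, -0.2, 0.3, 0.4], "n_pairs": [5] * 4}
        )
        with pytest.raises(ValueError):
            fit_variogram(emp)

    def test_too_few_bins_rejected(self):
        emp = pd.DataFrame({"dist_km": [1.0, 2, 3], "semivariance": [1.0] * 3, "n_pairs": [5] * 3})
        with pytest.raises(ValueError):
            fit_variogram(emp)


class TestOrdinaryKriging:
    VGM = VariogramModel("spherical", 0.0, 1.0, 30.0)

    def test_single_point_constant_surface(self):
        pts = pd.DataFrame({"lon": [-17.5], "lat": [14.5], "value": [42.0]})
        field = ordinary_krige(pts, self.VGM, grid_step_deg=0.05, clip_to_hull=False)
        np.testing.assert_allclose(field.prediction, 42.0)

    def test_exact_at_data_with_zero_nugget(self):
        pts = scatter_points(20, seed=3)
        pred, _ = krige_at(pts, self.VGM, pts["lon"].to_numpy(), pts["lat"].to_numpy())
        np.testing.assert_allclose(pred, pts["value"].to_numpy(), atol=1e-6)

    def test_equal_values_give_constant_surface(self):
        pts = scatter_points(8, seed=4)
        pts["value"] = 7.5
        field = ordinary_krige(pts, self.VGM)
        np.testing.assert_allclose(field.prediction, 7.5, atol=1e-9)
        np.testing.assert_allclose(field.variance >= 0, True)

    def test_weights_sum_to_one_everywhere(self):
        pts = scatter_points(25, seed=6)
        field = ordinary_krige(pts, self.VGM, grid_step_deg=0.1)
        np.testing.assert_allclose(field.weight_sums, 1.0, atol=1e-9)

    def test_predictions_within_data_range_zero_nugget(self):
        pts = scatter_points(25, seed=7)
        field = ordinary_krige(pts, self.VGM, grid_step_deg=0.1)
        if field.negative_weight_nodes == 0:
            assert field.prediction.min() >= pts["value"].min() - 1e-9
            assert field.prediction.max() <= pts["value"].max() + 1e-9

    def test_cell_area_shrinks_with_latitude(self):
        pts = scatter_points(25, seed=8)
        field = ordinary_krige(pts, self.VGM, grid_step_deg=0.1, clip_to_hull=False)
        order = np.argsort(field.lat)
        areas = field.area_m2[order]
        assert areas[-1] < areas[0]  # higher latitude, smaller cell


class TestTotalBiomass:
    def _uniform_field(self, b, var, n=10, area=1e8):
        return KrigedField(
            lon=np.zeros(n),
            lat=np.zeros(n),
            prediction=np.full(n, float(b)),
            variance=np.full(n, float(var)),
            area_m2=np.full(n, area),
            weight_sums=np.ones(n),
            negative_weight_nodes=0,
        )

    def test_unit_conversion(self):
        # 100 mg m^-2 over 1e9 m^2 -> 1e11 mg = 100 t
        out = total_biomass(self._uniform_field(100.0, 0.0, n=10, area=1e8))
        assert out["B_t_tons"] == pytest.approx(100.0)

    def test_zero_field(self):
        assert total_biomass(self._uniform_field(0.0, 0.0))["B_t_tons"] == 0.0

    def test_linear_in_area(self):
        f1 = self._uniform_field(50.0, 0.0, area=1e8)
        f2 = self._uniform_field(50.0, 0.0, area=2e8)
        assert total_biomass(f2)["B_t_tons"] == pytest.approx(
            2 * total_biomass(f1)["B_t_tons"]
        )

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        f = self._uniform_field(0.0, 0.0, n=20)
        f.prediction = rng.uniform(0, 200, 20)
        f.variance = rng.uniform(0, 50, 20)
        perm = rng.permutation(20)
        g = KrigedField(
            f.lon[perm], f.lat[perm], f.prediction[perm], f.variance[perm],
            f.area_m2[perm], f.weight_sums[perm], 0,
        )
        a, b = total_biomass(f), total_biomass(g)
        assert a["B_t_tons"] == pytest.approx(b["B_t_tons"])
        assert a["cv_percent"] == pytest.approx(b["cv_percent"])

    def test_negative_predictions_clipped_and_counted(self):
        f = self._uniform_field(10.0, 0.0, n=4)
        f.prediction[0] = -5.0
        out = total_biomass(f)
        assert out["n_clipped"] == 1
        assert out["B_t_tons"] == pytest.approx(3 * 10.0 * 1e8 * 1e-9)


class TestMoransI:
    def test_checkerboard_rook_is_minus_one(self):
        # brute-force oracle over the 4 sites gives exactly -1
        values = [1.0, 0.0, 0.0, 1.0]  # 2x2 grid, row-major
        rook = np.array(
            [
                [0, 1, 1, 0],
                [1, 0, 0, 1],
                [1, 0, 0, 1],
                [0, 1, 1, 0],
            ],
            dtype=float,
        )
        assert morans_i(values, weights=rook) == pytest.approx(-1.0)

    def test_gradient_field_positive(self):
        lon = np.linspace(-18, -17, 20)
        lat = np.full(20, 14.5)
        values = np.linspace(0, 10, 20)
        coords = np.column_stack([lon, lat])
        assert morans_i(values, coords) > 0

    def test_permutation_null_expectation(self):
        rng = np.random.default_rng(12)
        n = 16
        coords = np.column_stack([rng.uniform(-18, -17, n), rng.uniform(14, 15, n)])
        values = rng.uniform(0, 1, n)
        sims = [morans_i(rng.permutation(values), coords) for _ in range(300)]
        assert np.mean(sims) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            morans_i([1.0] * 6, np.zeros((6, 2)))
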