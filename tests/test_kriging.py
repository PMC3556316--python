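"""Residuals, coregionalization fitting and the cokriging solver."""

import numpy as np
import pytest

from gamcokrige.kriging import (
    CoregionalizationModel,
    ResidualSet,
    Structure,
    cokrige,
    compute_residuals,
    fit_lmc,
    ordinary_kriging,
)
from gamcokrige.variograms import VariogramModel, simulate_correlated_pair, simulate_gaussian_field


class TestResiduals:
    def test_arithmetic(self):
        res = compute_residuals([0, 1, 2], [0.5, 1.0, 1.5])
        assert res.spatial.tolist() == [-0.5, 0.0, 0.5]
        assert res.regional.tolist() == [-1.0, 0.0, 1.0]

    def test_perfect_fit_zero_spatial(self):
        res = compute_residuals([3, 1, 4], [3.0, 1.0, 4.0])
        assert np.all(res.spatial == 0.0)

    def test_equal_counts_zero_regional(self):
        res = compute_residuals([2, 2, 2], [1.0, 2.0, 3.0])
        assert np.all(res.regional == 0.0)

    def test_regional_mean_zero_exactly(self, rng):
        counts = rng.poisson(1.0, 50)
        res = compute_residuals(counts, rng.uniform(0, 2, 50))
        assert res.regional.mean() == pytest.approx(0.0, abs=1e-12)


def _lmc(b_nugget, b_struct, range_m=3000.0):
    structures = [Structure("nugget"), Structure("spherical", range_m)]
    dl = VariogramModel("spherical", b_nugget[0][0], b_struct[0][0], range_m)
    dr = VariogramModel("spherical", b_nugget[1][1], b_struct[1][1], range_m)
    return CoregionalizationModel(
        structures, [np.array(b_nugget, float), np.array(b_struct, float)], dl, dr
    )


@pytest.fixture()
def residual_cloud(rng):
    coords = rng.uniform(0, 10_000, (60, 2))
    eps_s = rng.normal(size=60)
    eps_r = rng.normal(size=60)
    return coords, ResidualSet(eps_s, eps_r - eps_r.mean())


class TestCokrige:
    def test_zero_cross_matches_single_variable_oracle(self, residual_cloud):
        """With no cross-structure the solution collapses to simple kriging of
        eps_s alone; checked against a dense solver written here."""
        coords, res = residual_cloud
        m = _lmc([[0.3, 0.0], [0.0, 0.2]], [[0.7, 0.0], [0.0, 0.5]])
        tgt = np.array([[4200.0, 5100.0]])
        out = cokrige(tgt, res, coords, m, n_neighbors=16, mode="simple")
        nb = out.neighborhoods[0]
        pc = coords[nb]

        def cov(h):
            u = np.minimum(h / 3000.0, 1.0)
            return 0.7 * (1 - 1.5 * u + 0.5 * u**3) + np.where(h > 0, 0.0, 0.3)

        dd = np.hypot(pc[:, 0, None] - pc[None, :, 0], pc[:, 1, None] - pc[None, :, 1])
        d0 = np.hypot(pc[:, 0] - tgt[0, 0], pc[:, 1] - tgt[0, 1])
        w = np.linalg.solve(cov(dd), cov(d0))
        assert out.estimate[0] == pytest.approx(w @ res.spatial[nb], abs=1e-8)

    def test_exact_at_data_sites_without_nugget(self, residual_cloud):
        coords, res = residual_cloud
        m = _lmc([[0.0, 0.0], [0.0, 0.0]], [[0.7, 0.3], [0.3, 0.5]])
        out = cokrige(coords[:5], res, coords, m, mode="simple")
        assert np.allclose(out.estimate, res.spatial[:5], atol=1e-8)
        out_o = cokrige(coords[:5], res, coords, m, mode="ordinary")
        assert np.allclose(out_o.estimate, res.spatial[:5], atol=1e-6)

    def test_zero_residuals_zero_estimate(self, residual_cloud):
        coords, _ = residual_cloud
        res0 = ResidualSet(np.zeros(60), np.zeros(60))
        m = _lmc([[0.1, 0.0], [0.0, 0.1]], [[0.5, 0.2], [0.2, 0.4]])
        out = cokrige(np.array([[1000.0, 1000.0]]), res0, coords, m)
        assert out.estimate[0] == 0.0
        assert out.variance[0] >= 0.0

    def test_ordinary_weight_constraints(self, residual_cloud):
        coords, res = residual_cloud
        m = _lmc([[0.2, 0.0], [0.0, 0.2]], [[0.6, 0.25], [0.25, 0.5]])
        out = cokrige(np.array([[3000.0, 7000.0]]), res, coords, m, mode="ordinary")
        ws, wr = out.weights[0]
        assert ws.sum() == pytest.approx(1.0, abs=1e-8)
        assert wr.sum() == pytest.approx(0.0, abs=1e-8)

    def test_weights_depend_on_geometry_not_values(self, residual_cloud, rng):
        coords, res = residual_cloud
        m = _lmc([[0.2, 0.0], [0.0, 0.2]], [[0.6, 0.25], [0.25, 0.5]])
        tgt = np.array([[3000.0, 7000.0]])
        w1 = cokrige(tgt, res, coords, m).weights[0]
        res2 = ResidualSet(rng.normal(size=60), rng.normal(size=60))
        w2 = cokrige(tgt, res2, coords, m).weights[0]
        assert np.allclose(w1[0], w2[0]) and np.allclose(w1[1], w2[1])

    def test_translation_invariance(self, residual_cloud):
        coords, res = residual_cloud
        m = _lmc([[0.2, 0.0], [0.0, 0.2]], [[0.6, 0.25], [0.25, 0.5]])
        tgt = np.array([[3000.0, 7000.0]])
        a = cokrige(tgt, res, coords, m).estimate
        b = cokrige(tgt + 123_456.0, res, coords + 123_456.0, m).estimate
        assert np.allclose(a, b)

    def test_secondary_variable_reduces_variance(self, residual_cloud):
        """When the primary carries a nugget the secondary's shared structure
        lowers the cokriging variance below primary-only kriging."""
        coords, res = residual_cloud
        m = _lmc([[0.5, 0.0], [0.0, 0.0]], [[0.5, 0.45], [0.45, 0.5]])
        tgt = np.array([[4200.0, 5100.0]])
        with_sec = cokrige(tgt, res, coords, m, mode="simple").variance[0]
        m_nosec = _lmc([[0.5, 0.0], [0.0, 0.0]], [[0.5, 0.0], [0.0, 0.5]])
        without = cokrige(tgt, res, coords, m_nosec, mode="simple").variance[0]
        assert with_sec < without

    def test_invalid_mode_raises(self, residual_cloud):
        coords, res = residual_cloud
        m = _lmc([[0.1, 0.0], [0.0, 0.1]], [[0.5, 0.0], [0.0, 0.5]])
        with pytest.raises(ValueError):
            cokrige(coords[:1], res, coords, m, mode="universal")


class TestLmcFit:
    def test_identical_series_give_unit_cross_ratio(self, scattered_coords):
        field = simulate_gaussian_field(
            scattered_coords, VariogramModel("spherical", 0.1, 0.6, 5000.0), 21
        )
        res = ResidualSet(field, field)
        lmc = fit_lmc(res, scattered_coords)
        assert lmc.cross_correlation == pytest.approx(1.0, abs=0.02)

    def test_independent_series_give_small_cross_ratio(self, scattered_coords):
        m = VariogramModel("spherical", 0.0, 0.6, 5000.0)
        ratios = []
        for rep in range(50):
            a, b = simulate_correlated_pair(scattered_coords, m, m, 0.0, 300 + rep)
            lmc = fit_lmc(ResidualSet(a, b), scattered_coords)
            ratios.append(abs(lmc.cross_correlation))
        assert np.median(ratios) < 0.2

    def test_psd_projection_engaged_on_violation(self, scattered_coords):
        base = simulate_gaussian_field(
            scattered_coords, VariogramModel("spherical", 0.0, 0.5, 4000.0), 9
        )
        res = ResidualSet(base, 2.0 * base)  # cross sill == bound; noise tips it over
        lmc = fit_lmc(res, scattered_coords)
        assert lmc.psd_flag
        for bm in lmc.b_matrices:
            assert bm[0, 1] ** 2 <= bm[0, 0] * bm[1, 1] + 1e-10

    def test_coefficient_matrices_validated(self):
        with pytest.raises(ValueError):
            CoregionalizationModel(
                [Structure("nugget")],
                [np.array([[1.0, 0.5], [0.4, 1.0]])],  # asymmetric
                VariogramModel("spherical", 0, 1, 1000.0),
                VariogramModel("spherical", 0, 1, 1000.0),
            )


def test_ordinary_kriging_exactness_and_constant_field(rng):
    coords = rng.uniform(0, 5000, (40, 2))
    vals = rng.normal(size=40)
    m = VariogramModel("exponential", 0.0, 1.0, 2000.0)
    est, var = ordinary_kriging(coords[:3], vals, coords, m)
    assert np.allclose(est, vals[:3], atol=1e-8)
    est_c, _ = ordinary_kriging(np.array([[2500.0, 2500.0]]), np.full(40, 7.0), coords, m)
    assert est_c[0] == pytest.approx(7.0)  # unit-sum weights reproduce a constant
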