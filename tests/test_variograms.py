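"""Variogram models, empirical estimation, WLS fitting and field simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gamcokrige.variograms import (
    FAMILIES,
    VariogramModel,
    covariance_matrix,
    empirical_variogram,
    fit_variogram,
    mean_nn_distance,
    simulate_correlated_pair,
    simulate_gaussian_field,
)


@pytest.mark.parametrize("family", FAMILIES)
def test_model_shape_properties(family):
    """gamma(0)=0, nondecreasing toward the sill, covariance complements it."""
    m = VariogramModel(family, nugget=0.1, partial_sill=0.9, range_m=2000.0)
    h = np.linspace(0, 10_000, 400)
    g = m.semivariance(h)
    assert g[0] == 0.0
    assert np.all(np.diff(g) >= -1e-12)
    assert np.isclose(g[-1], m.sill, atol=1e-3)
    # C(h) = sill - gamma(h) away from the origin; C(0) = sill
    assert np.allclose(m.covariance(h[1:]), m.sill - g[1:], atol=1e-12)
    assert m.covariance(0.0) == pytest.approx(m.sill)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(family="spherical", nugget=-0.1, partial_sill=1.0, range_m=1.0),
        dict(family="spherical", nugget=0.0, partial_sill=-1.0, range_m=1.0),
        dict(family="spherical", nugget=0.0, partial_sill=1.0, range_m=0.0),
        dict(family="stable", nugget=0.0, partial_sill=1.0, range_m=1.0, stable_exponent=2.5),
        dict(family="nope", nugget=0.0, partial_sill=1.0, range_m=1.0),
    ],
)
def test_invalid_model_parameters_raise(kwargs):
    with pytest.raises(ValueError):
        VariogramModel(**kwargs)


def test_gaussian_equals_stable_with_exponent_two():
    h = np.linspace(1, 8000, 50)
    g = VariogramModel("gaussian", 0.0, 1.0, 3000.0).semivariance(h)
    s = VariogramModel("stable", 0.0, 1.0, 3000.0, stable_exponent=2.0).semivariance(h)
    assert np.allclose(g, s)


class TestEmpiricalVariogram:
    def test_two_site_half_squared_difference(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        emp = empirical_variogram([0.0, 2.0], coords, lag_size=150.0, n_lags=2)
        assert emp.gamma.tolist() == [2.0]  # (1/2) * (2)^2
        assert emp.counts.tolist() == [1]

    def test_constant_field_is_zero(self, scattered_coords):
        emp = empirical_variogram(np.full(326, 3.3), scattered_coords)
        assert np.allclose(emp.gamma, 0.0)

    def test_coincident_sites_raise(self):
        coords = np.zeros((5, 2))
        with pytest.raises(ValueError, match="coincident"):
            empirical_variogram(np.arange(5.0), coords)

    def test_bins_with_no_pairs_are_omitted(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [5000.0, 0.0]])
        emp = empirical_variogram([0.0, 1.0, 2.0], coords, lag_size=200.0, n_lags=30)
        # pairs at 100, 4900 and 5000 m: three occupied bins, 27 omitted
        assert len(emp.bin_centers) == 3
        assert emp.counts.sum() == 3


class TestFitVariogram:
    @pytest.mark.parametrize("family", ["spherical", "exponential", "gaussian"])
    def test_noise_free_inversion(self, family):
        """Exact model semivariances at bin centers are recovered within 1%."""
        truth = VariogramModel(family, nugget=0.2, partial_sill=0.8, range_m=2500.0)
        h = np.arange(250.0, 9000.0, 500.0)
        from gamcokrige.variograms import EmpiricalVariogram

        emp = EmpiricalVariogram(
            bin_centers=h, gamma=truth.semivariance(h), counts=np.full(len(h), 200), lag_size=500.0
        )
        fit = fit_variogram(emp, family)
        assert fit.nugget == pytest.approx(truth.nugget, rel=0.01, abs=0.01)
        assert fit.sill == pytest.approx(truth.sill, rel=0.01)
        assert fit.range_m == pytest.approx(truth.range_m, rel=0.01)

    def test_flat_plateau_flagged(self):
        from gamcokrige.variograms import EmpiricalVariogram

        h = np.arange(250.0, 5000.0, 500.0)
        emp = EmpiricalVariogram(
            bin_centers=h, gamma=np.full(len(h), 0.7), counts=np.full(len(h), 50), lag_size=500.0
        )
        model, info = fit_variogram(emp, "spherical", full_output=True)
        assert info["flat"]
        assert model.partial_sill == pytest.approx(0.7)
        assert model.range_m == pytest.approx(h.max())

    def test_too_few_bins_raise(self):
        from gamcokrige.variograms import EmpiricalVariogram

        emp = EmpiricalVariogram(
            bin_centers=np.array([100.0, 300.0]),
            gamma=np.array([0.1, 0.2]),
            counts=np.array([5, 5]),
            lag_size=200.0,
        )
        with pytest.raises(ValueError):
            fit_variogram(emp, "spherical")


class TestSimulation:
    def test_zero_sill_gives_zero_field(self, scattered_coords):
        m = VariogramModel("spherical", 0.0, 0.0, 1000.0)
        assert np.all(simulate_gaussian_field(scattered_coords, m, 3) == 0.0)

    def test_seed_reproducibility(self, scattered_coords):
        m = VariogramModel("exponential", 0.1, 0.9, 4000.0)
        a = simulate_gaussian_field(scattered_coords, m, 11)
        b = simulate_gaussian_field(scattered_coords, m, 11)
        assert np.array_equal(a, b)

    def test_pure_nugget_decorrelates_neighbors(self, scattered_coords):
        """Nearest-neighbour pairs of a pure-nugget field are uncorrelated."""
        from scipy.spatial import cKDTree

        m = VariogramModel("spherical", 1.0, 0.0, 1000.0)
        _, idx = cKDTree(scattered_coords).query(scattered_coords, k=2)
        rs = []
        draws = simulate_gaussian_field(scattered_coords, m, 5, n_draws=100)
        for z in draws:
            rs.append(np.corrcoef(z, z[idx[:, 1]])[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_empirical_variogram_converges_to_model(self, scattered_coords):
        """Mean binned semivariance over 200 draws matches the generating model.

        The expectation is checked against an independently computed oracle:
        the model's own gamma evaluated through the covariance matrix used
        nowhere in the estimator (E[gamma_hat(h)] = sill - C(h)).
        """
        truth = VariogramModel("spherical", 0.0, 0.65, 2425.41)
        draws = simulate_gaussian_field(scattered_coords, truth, 99, n_draws=200)
        gams = []
        for z in draws:
            emp = empirical_variogram(z, scattered_coords, lag_size=800.0, n_lags=3)
            gams.append(emp.gamma)
        mean_gamma = np.mean(gams, axis=0)
        # oracle: expected semivariance from the covariance matrix route
        c = covariance_matrix(scattered_coords, truth)
        d = np.hypot(
            scattered_coords[:, None, 0] - scattered_coords[None, :, 0],
            scattered_coords[:, None, 1] - scattered_coords[None, :, 1],
        )
        iu = np.triu_indices(len(scattered_coords), 1)
        expected = []
        for k in range(3):
            sel = (d[iu] >= k * 800.0) & (d[iu] < (k + 1) * 800.0)
            expected.append(np.mean(truth.sill - c[iu][sel]))
        assert np.allclose(mean_gamma, expected, rtol=0.15)

    def test_correlated_pair_limits(self, scattered_coords):
        m = VariogramModel("spherical", 0.0, 0.5, 3000.0)
        a, b = simulate_correlated_pair(scattered_coords, m, m, 1.0, 77)
        assert np.allclose(a, b)
        a0, b0 = simulate_correlated_pair(scattered_coords, m, m, 0.0, 77)
        assert abs(np.corrcoef(a0, b0)[0, 1]) < 0.35  # independent white inputs

    def test_invalid_cross_corr_raises(self, scattered_coords):
        m = VariogramModel("spherical", 0.0, 0.5, 3000.0)
        with pytest.raises(ValueError):
            simulate_correlated_pair(scattered_coords, m, m, 1.5, 1)


@settings(max_examples=30, deadline=None)
@given(
    nugget=st.floats(0.0, 1.0),
    psill=st.floats(0.0, 2.0),
    rng_m=st.floats(100.0, 20_000.0),
    family=st.sampled_from(list(FAMILIES)),
)
def test_semivariance_bounded_by_sill(nugget, psill, rng_m, family):
    """0 <= gamma(h) <= sill for every admissible parameter combination."""
    m = VariogramModel(family, nugget, psill, rng_m)
    h = np.linspace(0.0, 5 * rng_m, 200)
    g = m.semivariance(h)
    assert np.all(g >= 0.0) and np.all(g <= m.sill + 1e-9)


def test_mean_nn_distance_simple_grid():
    coords = np.array([[0, 0], [0, 10], [0, 25]], dtype=float)
    assert mean_nn_distance(coords) == pytest.approx((10 + 10 + 15) / 3)
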