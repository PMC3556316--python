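"""Geographic covariates: buffer proportions, distances, screening."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

from gamcokrige.geo import (
    BufferScreenResult,
    GeoLayer,
    area_proportion,
    buffer_screen,
    default_radius_grid,
    screen_filter,
    shortest_distance,
)


@pytest.fixture()
def halfplane_layer():
    """Category A fills x < 0, category B fills x >= 0, inside a 20 km square."""
    return GeoLayer(
        kind="polygon-categorical",
        name="soil",
        polygons=[
            (box(-10_000, -10_000, 0, 10_000), "A"),
            (box(0, -10_000, 10_000, 10_000), "B"),
        ],
    )


class TestAreaProportion:
    def test_fully_inside_category(self, halfplane_layer):
        assert area_proportion((-5_000, 0), halfplane_layer, "A", 1_000) == pytest.approx(1.0)

    def test_fully_outside_category(self, halfplane_layer):
        assert area_proportion((9_000, 0), halfplane_layer, "A", 1_000) == pytest.approx(0.0)

    def test_straight_boundary_through_site_gives_half(self, halfplane_layer):
        assert area_proportion((0, 0), halfplane_layer, "A", 1_000) == pytest.approx(0.5, abs=1e-6)

    def test_errors(self, halfplane_layer):
        with pytest.raises(KeyError):
            area_proportion((0, 0), halfplane_layer, "Z", 1_000)
        with pytest.raises(ValueError):
            area_proportion((0, 0), halfplane_layer, "A", -5)
        lines = GeoLayer(kind="polyline", name="river", lines=[LineString([(0, 0), (1, 1)])])
        with pytest.raises(ValueError):
            area_proportion((0, 0), lines, "A", 100)


class TestShortestDistance:
    def test_perpendicular_foot(self):
        layer = GeoLayer(kind="polyline", name="river", lines=[LineString([(0, 3), (4, 3)])])
        assert shortest_distance((0, 0), layer) == pytest.approx(3.0)

    def test_beyond_endpoint(self):
        layer = GeoLayer(kind="polyline", name="fault", lines=[LineString([(0, 0), (3, 0)])])
        assert shortest_distance((5, 0), layer) == pytest.approx(2.0)

    def test_empty_layer_raises(self):
        with pytest.raises(ValueError):
            shortest_distance((0, 0), GeoLayer(kind="polyline", name="road", lines=[]))

    def test_matches_dense_sampling_oracle(self, rng):
        """Distance equals a brute-force minimum over densely sampled points."""
        pts = rng.uniform(0, 10_000, (51, 2))
        line = LineString(pts)
        layer = GeoLayer(kind="polyline", name="river", lines=[line])
        # oracle: 1e5 points placed uniformly along the polyline by arc length
        ts = np.linspace(0, line.length, 100_000)
        dense = np.array([line.interpolate(t).coords[0] for t in ts])
        for _ in range(5):
            site = rng.uniform(-2_000, 12_000, 2)
            d = shortest_distance(site, layer)
            d_oracle = np.min(np.hypot(dense[:, 0] - site[0], dense[:, 1] - site[1]))
            assert d == pytest.approx(d_oracle, rel=1e-3)

    def test_site_shift_is_lipschitz(self, rng):
        """Moving the site by delta changes the distance by at most delta."""
        layer = GeoLayer(
            kind="polyline", name="road", lines=[LineString(rng.uniform(0, 1000, (10, 2)))]
        )
        site = np.array([500.0, 500.0])
        base = shortest_distance(site, layer)
        for _ in range(20):
            delta = rng.uniform(-50, 50, 2)
            moved = shortest_distance(site + delta, layer)
            assert abs(moved - base) <= np.hypot(*delta) + 1e-9


class TestBufferScreen:
    def _sites(self, rng, n=60):
        return pd.DataFrame(
            {"x": rng.uniform(-9_000, 9_000, n), "y": rng.uniform(-9_000, 9_000, n)}
        )

    def test_self_consistent_target_finds_planted_radius(self, rng, halfplane_layer):
        sites = self._sites(rng)
        radii = [500.0, 1_000.0, 1_500.0, 2_000.0]
        planted = np.array(
            [area_proportion((x, y), halfplane_layer, "A", 1_500.0) for x, y in sites[["x", "y"]].to_numpy()]
        )
        res = buffer_screen(sites, halfplane_layer, "A", radii=radii, target=planted)
        assert res.optimal_radius == 1_500.0
        assert res.optimal_r == pytest.approx(1.0)
        assert res.kept

    def test_null_target_rarely_kept(self, rng, halfplane_layer):
        """A target independent of the layer passes the |r|>=0.2, p<=0.1 screen rarely."""
        sites = self._sites(rng, n=326)
        radii = [500.0, 1_000.0, 2_000.0, 3_000.0]
        null_rng = np.random.default_rng(5150)
        kept = 0
        for _ in range(15):
            target = null_rng.normal(size=len(sites))
            res = buffer_screen(sites, halfplane_layer, "A", radii=radii, target=target)
            kept += res.kept
        assert kept <= 1  # at n=326 an |r|>=0.2 fluke is very rare

    def test_constant_target_all_missing(self, rng, halfplane_layer):
        sites = self._sites(rng)
        res = buffer_screen(
            sites, halfplane_layer, "A", radii=[500.0, 1_000.0, 1_500.0],
            target=np.full(len(sites), 2.0),
        )
        assert np.all(np.isnan(res.correlations))
        assert not res.kept

    def test_affine_target_rescaling_keeps_r(self, rng, halfplane_layer):
        sites = self._sites(rng)
        target = rng.normal(size=len(sites))
        radii = [500.0, 1_500.0]
        r1 = buffer_screen(sites, halfplane_layer, "A", radii=radii, target=target)
        r2 = buffer_screen(sites, halfplane_layer, "A", radii=radii, target=3.0 * target + 7.0)
        assert np.allclose(r1.correlations, r2.correlations)

    def test_radius_bounds_enforced(self, rng, halfplane_layer):
        with pytest.raises(ValueError):
            buffer_screen(self._sites(rng), halfplane_layer, "A", radii=[10.0, 500.0],
                          target=np.zeros(60))


def test_default_radius_grid_span():
    grid = default_radius_grid()
    assert grid[0] == 20.0 and grid[-1] == 3000.0
    assert np.all(np.diff(grid) > 0)


def test_screen_filter_thresholds():
    """Sign-agnostic keep rule: |r| >= 0.2 and p <= 0.1 at the optimal radius."""
    def res(r, p):
        return BufferScreenResult(
            layer="soil", category="A", radii=np.array([100.0]),
            correlations=np.array([r]), p_values=np.array([p]),
            optimal_radius=100.0, optimal_r=r, optimal_p=p,
            kept=abs(r) >= 0.2 and p <= 0.1,
        )

    kept = screen_filter([res(0.30, 0.001), res(0.19, 0.01), res(-0.23, 0.02)])
    assert [k.optimal_r for k in kept] == [0.30, -0.23]
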