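"""Rossmo surface construction, origin estimation and hit scores.

The vectorized surface is checked cell-by-cell against a deliberately
naive double-loop implementation of the same scoring rule, which serves as
the independent oracle throughout.
"""

import numpy as np
import pytest

from invasiontrace.distances import haversine_km
from invasiontrace.geoprofile import (
    Geoprofile,
    GeoprofileParams,
    cluster_geoprofiles,
    estimate_origin,
    hit_score,
    origin_in_top_region,
    rossmo_surface,
)
from invasiontrace.synthetic import default_three_origin_scenario, simulate_invasion


def naive_rossmo(points, gp: Geoprofile) -> np.ndarray:
    """Straightforward double-loop evaluation of the scoring rule, using the
    buffer/epsilon values the surface actually used (pre-normalisation)."""
    params = gp.params
    b, eps = gp.buffer_used, gp.epsilon_used
    f, g = params.exponent_f, params.exponent_g
    lons, lats = gp.lons, gp.lats
    out = np.zeros((params.grid_ny, params.grid_nx))
    for iy in range(params.grid_ny):
        for ix in range(params.grid_nx):
            cell = (lons[ix], lats[iy])
            total = 0.0
            for p in points:
                if params.distance_metric == "haversine_km":
                    d = float(haversine_km(np.asarray(p, float), np.asarray(cell, float)))
                else:
                    d = float(np.hypot(p[0] - cell[0], p[1] - cell[1]))
                d = max(d, eps)
                if d > b:
                    total += d ** (-f)
                else:
                    total += (b ** (g - f)) * max(2.0 * b - d, eps) ** (-g)
            out[iy, ix] = total
    return out


class TestRossmoSurface:
    @pytest.mark.parametrize("metric", ["euclidean_degrees", "haversine_km"])
    def test_matches_naive_double_loop(self, metric):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = rng.integers(1, 31)
            pts = np.column_stack([rng.uniform(0, 10, n), rng.uniform(40, 45, n)])
            params = GeoprofileParams(grid_nx=10, grid_ny=10, distance_metric=metric)
            gp = rossmo_surface(pts, params)
            expected = naive_rossmo(pts, gp)
            assert np.allclose(gp.raw_scores, expected, rtol=1e-12, atol=0.0)

    def test_normalised_to_unit_mass(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5, (12, 2)) + [5, 40]
        gp = rossmo_surface(pts, GeoprofileParams(grid_nx=40, grid_ny=30))
        assert gp.scores.sum() == pytest.approx(1.0, abs=1e-9)
        assert (gp.scores >= 0).all()

    def test_single_observation_ring_maximum(self):
        # max on the ring d = B, strictly decreasing beyond it, radially symmetric
        params = GeoprofileParams(
            buffer_b=2.0,
            grid_nx=81,
            grid_ny=81,
            distance_metric="euclidean_degrees",
            epsilon_d=0.05,
        )
        gp = rossmo_surface([[0.0, 0.0]], params, extent=(-8, 8, -8, 8))
        d = np.hypot(*np.meshgrid(gp.lons, gp.lats))
        peak_d = d.ravel()[np.argmax(gp.scores)]
        assert abs(peak_d - 2.0) < 0.25  # within ~one cell of the buffer ring
        # monotone decay outside the buffer, checked along the +x axis
        row = gp.scores[40, :]
        xs = gp.lons
        outside = xs > 2.2
        assert np.all(np.diff(row[outside]) < 0)
        # mirror symmetry about the observation
        assert np.allclose(gp.scores, gp.scores[:, ::-1], rtol=1e-10)
        assert np.allclose(gp.scores, gp.scores[::-1, :], rtol=1e-10)

    def test_mirror_symmetry_two_observations(self):
        params = GeoprofileParams(
            buffer_b=1.0, grid_nx=20, grid_ny=15, distance_metric="euclidean_degrees", epsilon_d=0.1
        )
        gp = rossmo_surface([[-3.0, 0.0], [3.0, 0.0]], params, extent=(-6, 6, -4, 4))
        assert np.allclose(gp.scores, gp.scores[:, ::-1], rtol=1e-10)

    def test_additive_in_observations(self):
        # the raw surface is a sum over observations: adding a point adds its
        # one-point surface (same extent and fixed B/epsilon throughout)
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 4, (6, 2))
        extra = np.array([[1.5, 2.5]])
        extent = (-1, 5, -1, 5)
        params = GeoprofileParams(
            buffer_b=0.8, grid_nx=15, grid_ny=15, distance_metric="euclidean_degrees", epsilon_d=0.1
        )
        a = rossmo_surface(pts, params, extent=extent).raw_scores
        b = rossmo_surface(extra, params, extent=extent).raw_scores
        both = rossmo_surface(np.vstack([pts, extra]), params, extent=extent).raw_scores
        assert np.allclose(both, a + b, rtol=1e-12)

    def test_translation_equivariance_euclidean(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 3, (10, 2))
        shift = np.array([2.5, -1.5])
        params = GeoprofileParams(
            buffer_b=0.5, grid_nx=25, grid_ny=25, distance_metric="euclidean_degrees", epsilon_d=0.05
        )
        extent = (-2.0, 5.0, -2.0, 5.0)
        shifted_extent = tuple(np.array(extent) + [shift[0], shift[0], shift[1], shift[1]])
        gp1 = rossmo_surface(pts, params, extent=extent)
        gp2 = rossmo_surface(pts + shift, params, extent=shifted_extent)
        assert np.allclose(gp1.scores, gp2.scores, rtol=1e-10)
        p1, p2 = np.array(gp1.peak_lonlat), np.array(gp2.peak_lonlat)
        assert np.allclose(p2 - p1, shift, atol=1e-9)

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            rossmo_surface(np.empty((0, 2)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GeoprofileParams(buffer_b=-1.0)
        with pytest.raises(ValueError):
            GeoprofileParams(exponent_f=0.0)


class TestOriginEstimate:
    def test_q_one_covers_the_whole_grid(self):
        gp = rossmo_surface([[0.0, 40.0]], GeoprofileParams(grid_nx=10, grid_ny=10))
        est = estimate_origin(gp, q=1.0)
        assert est.top_region.all()

    def test_small_q_region_is_annulus_around_single_observation(self):
        params = GeoprofileParams(
            buffer_b=2.0, grid_nx=61, grid_ny=61, distance_metric="euclidean_degrees", epsilon_d=0.05
        )
        gp = rossmo_surface([[0.0, 0.0]], params, extent=(-6, 6, -6, 6))
        est = estimate_origin(gp, q=0.05)
        d = np.hypot(*np.meshgrid(gp.lons, gp.lats))
        sel = d[est.top_region]
        assert sel.min() > 0.5  # hole at the centre
        assert abs(np.median(sel) - 2.0) < 0.6  # mass concentrated near the ring

    def test_peak_always_inside_top_region(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 5, (8, 2)) + [10, 40]
        gp = rossmo_surface(pts, GeoprofileParams(grid_nx=30, grid_ny=30))
        for q in (0.01, 0.1, 0.5):
            est = estimate_origin(gp, q=q)
            iy, ix = gp.cell_index(*est.peak_lonlat)
            assert est.top_region[iy, ix]
            assert est.mass >= q

    def test_region_is_smallest_top_set(self):
        gp = rossmo_surface([[3.0, 41.0]], GeoprofileParams(grid_nx=12, grid_ny=12))
        est = estimate_origin(gp, q=0.3)
        flat = np.sort(gp.scores.ravel())[::-1]
        assert flat[: est.n_cells].sum() >= 0.3
        assert flat[: est.n_cells - 1].sum() < 0.3

    def test_invalid_q_rejected(self):
        gp = rossmo_surface([[0.0, 40.0]], GeoprofileParams(grid_nx=5, grid_ny=5))
        for q in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                estimate_origin(gp, q=q)


class TestHitScore:
    def test_uniform_surface_scores_one(self):
        gp = rossmo_surface([[0.0, 40.0]], GeoprofileParams(grid_nx=8, grid_ny=8))
        gp.scores = np.full_like(gp.scores, 1.0 / gp.scores.size)
        assert hit_score(gp, (0.0, 40.0)) == 1.0

    def test_origin_at_peak_attains_minimum(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 4, (10, 2)) + [8, 38]
        gp = rossmo_surface(pts, GeoprofileParams(grid_nx=25, grid_ny=25))
        hs = hit_score(gp, gp.peak_lonlat)
        ties = np.count_nonzero(gp.scores >= gp.scores.max())
        assert hs == pytest.approx(ties / gp.scores.size)
        assert hs <= 1.0 / gp.scores.size * ties + 1e-12

    def test_origin_outside_extent_rejected(self):
        gp = rossmo_surface([[0.0, 40.0]], GeoprofileParams(grid_nx=5, grid_ny=5))
        with pytest.raises(ValueError):
            hit_score(gp, (50.0, 40.0))

    def test_stable_under_grid_refinement(self):
        sc = default_three_origin_scenario(seed=4, n_points=30)
        rs, _ = simulate_invasion(sc)
        pts = rs.coordinates()[:30]
        origin = sc.true_origins()[0]
        coarse = rossmo_surface(pts, GeoprofileParams(grid_nx=100, grid_ny=100))
        fine = rossmo_surface(
            pts, GeoprofileParams(grid_nx=200, grid_ny=200), extent=coarse.extent
        )
        # smooth surface: doubling the grid moves the hit score only slightly
        assert abs(hit_score(coarse, origin) - hit_score(fine, origin)) < 0.02


class TestClusterGeoprofiles:
    def test_two_origin_cutoff_excludes_late_wave(self):
        sc = default_three_origin_scenario(seed=0)
        rs, _ = simulate_invasion(sc)
        # the third origin starts in 1845: a 1840 cutoff leaves two waves
        part, profile, clusters = cluster_geoprofiles(
            rs, cutoff=1840, seed=0, q=0.1,
            gp_params=GeoprofileParams(grid_nx=60, grid_ny=60),
        )
        assert part.k == 2
        assert len(clusters) == 2

    def test_three_origin_recovery_single_seed(self):
        sc = default_three_origin_scenario(seed=7)
        rs, _ = simulate_invasion(sc)
        part, profile, clusters = cluster_geoprofiles(
            rs, seed=7, q=0.10, gp_params=GeoprofileParams(grid_nx=120, grid_ny=120)
        )
        assert part.k == 3
        for o in sc.true_origins():
            d = [float(haversine_km(o, cg.points.mean(axis=0))) for cg in clusters]
            cg = clusters[int(np.argmin(d))]
            assert origin_in_top_region(cg.origin, cg.geoprofile, o)
            assert hit_score(cg.geoprofile, o) <= 0.10

    def test_empty_after_filter_rejected(self):
        sc = default_three_origin_scenario(seed=0)
        rs, _ = simulate_invasion(sc)
        with pytest.raises(ValueError):
            cluster_geoprofiles(rs, cutoff=1500)


def test_asc_export_round_trips_grid(tmp_path):
    gp = rossmo_surface([[5.0, 40.0]], GeoprofileParams(grid_nx=6, grid_ny=4))
    path = tmp_path / "surface.asc"
    gp.write_asc(path)
    lines = path.read_text().splitlines()
    assert lines[0].split() == ["ncols", "6"]
    assert lines[1].split() == ["nrows", "4"]
    body = np.loadtxt(lines[6:])
    assert np.allclose(body[::-1], gp.scores, rtol=1e-6)
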