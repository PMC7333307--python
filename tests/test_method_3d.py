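import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vinecanopy import SiteConfig, SyntheticSiteSpec, build_grid, generate_site, render_cloud
from vinecanopy.gridding import GridCell
from vinecanopy.io_formats import PointCloud3D
from vinecanopy.method_3d import (
    PlaneModel,
    alphashape_volume,
    average_vine_volume,
    clip_cell,
    fit_ground_plane,
    missing_plants_3d,
    row_volume_map,
    run_3d,
    split_ground_canopy,
    _bucket_points,
)
from vinecanopy.synthetic import site_rows

from _oracles import alphashape_volume_bruteforce


def _ground_and_slab(rng, n_ground=2000, n_canopy=800, tilt=0.0, noise=0.0):
    gxy = rng.random((n_ground, 2)) * 10.0
    gz = gxy[:, 0] * math.tan(math.radians(tilt)) + rng.normal(0, noise, n_ground)
    ground = np.column_stack([gxy, gz])
    cxy = rng.random((n_canopy, 2)) * [10.0, 0.4] + [0.0, 4.8]
    cz = (
        cxy[:, 0] * math.tan(math.radians(tilt))
        + 0.8 + rng.random(n_canopy) * 1.2
        + rng.normal(0, noise, n_canopy)
    )
    return np.vstack([ground, np.column_stack([cxy, cz])]), n_ground


class TestFitGroundPlane:
    def test_noise_free_flat_ground_recovered_exactly(self, rng):
        pts, n_ground = _ground_and_slab(rng)
        plane, inliers = fit_ground_plane(PointCloud3D(pts), seed=1)
        assert abs(plane.offset) < 1e-6
        assert plane.angle_to_vertical() < 1e-4
        assert np.array_equal(np.sort(inliers), np.arange(n_ground))

    def test_tilted_noisy_ground_within_tolerance(self, rng):
        pts, _ = _ground_and_slab(rng, tilt=3.0, noise=0.01)
        plane, _ = fit_ground_plane(PointCloud3D(pts), seed=2)
        assert abs(plane.angle_to_vertical() - 3.0) < 0.3

    def test_steep_ground_rejected(self, rng):
        pts, _ = _ground_and_slab(rng, tilt=10.0)
        with pytest.raises(ValueError, match="admissible|constraint"):
            fit_ground_plane(PointCloud3D(pts), seed=3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ground_plane(PointCloud3D(np.zeros((2, 3))), seed=0)

    def test_deterministic_given_seed(self, rng):
        pts, _ = _ground_and_slab(rng, tilt=2.0, noise=0.01)
        p1, i1 = fit_ground_plane(PointCloud3D(pts), seed=9)
        p2, i2 = fit_ground_plane(PointCloud3D(pts), seed=9)
        assert np.array_equal(p1.normal, p2.normal) and p1.offset == p2.offset
        assert np.array_equal(i1, i2)


class TestSplitGroundCanopy:
    def test_labels_match_construction(self, rng):
        pts, n_ground = _ground_and_slab(rng)
        cloud = PointCloud3D(pts)
        plane, inliers = fit_ground_plane(cloud, seed=1)
        ground, canopy = split_ground_canopy(cloud, plane, inliers)
        assert len(ground) == n_ground
        assert len(canopy) == len(pts) - n_ground

    def test_all_points_on_plane_leave_empty_canopy(self, rng):
        xy = rng.random((500, 2)) * 5
        cloud = PointCloud3D(np.column_stack([xy, np.zeros(500)]))
        plane = PlaneModel(normal=[0, 0, 1.0], offset=0.0)
        with pytest.warns(UserWarning, match="empty"):
            ground, canopy = split_ground_canopy(cloud, plane, np.arange(500))
        assert len(ground) == 500 and len(canopy) == 0

    def test_below_ground_outliers_discarded(self, rng):
        import warnings as _warnings

        xy = rng.random((100, 2))
        pts = np.column_stack([xy, np.zeros(100)])
        pts = np.vstack([pts, [[0.5, 0.5, -2.0]]])
        plane = PlaneModel(normal=[0, 0, 1.0], offset=0.0)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            _, canopy = split_ground_canopy(PointCloud3D(pts), plane, np.arange(100))
        messages = [str(w.message) for w in caught]
        assert any("discarded 1" in m for m in messages)
        assert any("empty" in m for m in messages)  # no canopy left either
        assert len(canopy) == 0


class TestClipCell:
    def _cell(self, cell_id=0, origin=(0.0, 0.0)):
        return GridCell(cell_id, 0, np.asarray(origin), np.array([1.0, 0.0]), 2.7, 2.5)

    def test_half_open_edge_assigns_point_once(self):
        c0 = self._cell(0, (0.0, 0.0))
        c1 = self._cell(1, (2.7, 0.0))
        pt = PointCloud3D(np.array([[2.7, 1.0, 0.5]]))
        assert len(clip_cell(pt, c0)) == 0
        assert len(clip_cell(pt, c1)) == 1

    def test_cell_outside_cloud_is_empty(self, rng):
        cloud = PointCloud3D(np.column_stack([rng.random((50, 2)), np.zeros(50)]))
        assert len(clip_cell(cloud, self._cell(0, (100.0, 100.0)))) == 0

    def test_clipped_counts_conserved(self, rng):
        cloud = PointCloud3D(
            np.column_stack([rng.random((400, 2)) * [8.1, 2.5], rng.random(400)])
        )
        cells = [self._cell(i, (2.7 * i, 0.0)) for i in range(3)]
        total = sum(len(clip_cell(cloud, c)) for c in cells)
        assert total == 400  # the three cells tile the cloud extent exactly

    def test_bucketed_assignment_matches_clip_cell(self, rng):
        cloud = PointCloud3D(
            np.column_stack([rng.random((500, 2)) * [9.0, 3.0], rng.random(500)])
        )
        cells = [self._cell(i, (2.7 * i, 0.2)) for i in range(3)]
        buckets = _bucket_points(cloud.points, cells)
        for c in cells:
            direct = clip_cell(cloud, c).points
            assert np.array_equal(
                direct[np.lexsort(direct.T)], buckets[c.cell_id][np.lexsort(buckets[c.cell_id].T)]
            )


class TestAlphashapeVolume:
    def test_matches_bruteforce_oracle_on_random_sets(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 26))
            pts = rng.random((n, 3))
            alpha = float(rng.uniform(0.2, 0.8))
            ours = alphashape_volume(pts, alpha)
            oracle = alphashape_volume_bruteforce(pts, alpha)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_regular_tetrahedron_closed_form(self):
        e = 0.2
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) * e / (2 * math.sqrt(2))
        circumradius = e * math.sqrt(3.0 / 8.0)
        vol = alphashape_volume(pts, circumradius + 1e-9)
        assert vol == pytest.approx(e**3 / (6 * math.sqrt(2)), rel=1e-12)

    def test_alpha_below_circumradius_drops_tetrahedron(self):
        e = 0.2
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) * e / (2 * math.sqrt(2))
        assert alphashape_volume(pts, 0.5 * e * math.sqrt(3.0 / 8.0)) == 0.0

    def test_vanishing_alpha_gives_zero(self, rng):
        assert alphashape_volume(rng.random((50, 3)), 1e-9) == 0.0

    def test_fewer_than_four_points_give_zero(self, rng):
        assert alphashape_volume(rng.random((3, 3)), 1.0) == 0.0

    def test_coplanar_points_warn_and_give_zero(self, rng):
        xy = rng.random((30, 2))
        pts = np.column_stack([xy, np.zeros(30)])
        with pytest.warns(UserWarning, match="degenerate"):
            assert alphashape_volume(pts, 1.0) == 0.0

    def test_large_alpha_equals_convex_hull(self, rng):
        trimesh = pytest.importorskip("trimesh")
        pts = rng.random((120, 3))
        hull_volume = trimesh.PointCloud(pts).convex_hull.volume
        assert alphashape_volume(pts, np.inf) == pytest.approx(hull_volume, rel=1e-9)

    @given(seed=st.integers(0, 2**16), n=st.integers(10, 60))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_volume_monotone_in_alpha(self, seed, n):
        pts = np.random.default_rng(seed).random((n, 3))
        alphas = [0.1, 0.3, 0.6, np.inf]
        vols = [alphashape_volume(pts, a) for a in alphas]
        assert all(v1 <= v2 + 1e-12 for v1, v2 in zip(vols, vols[1:]))


class TestMissingPlantArithmetic:
    def test_average_vine_volume_from_reference_cells(self):
        cells = [
            _metrics(0, 1.2), _metrics(1, 0.9), _metrics(2, 1.5), _metrics(3, 0.2)
        ]
        avg = average_vine_volume(cells, [0, 1, 2])
        assert avg.v_bar == pytest.approx(0.4)
        assert avg.n_reference_cells == 3

    def test_single_reference_cell_fontone_value(self):
        avg = average_vine_volume([_metrics(0, 0.93)], [0])
        assert avg.v_bar == pytest.approx(0.31)

    def test_uniform_reference_volume(self):
        cells = [_metrics(i, 0.6) for i in range(4)]
        assert average_vine_volume(cells, [0, 1, 2, 3]).v_bar == pytest.approx(0.2)

    def test_no_reference_cells_instructs_manual_vbar(self):
        with pytest.raises(ValueError, match="v_bar"):
            average_vine_volume([_metrics(0, 1.0)], [])

    @pytest.mark.parametrize("rounding", ["nearest", "ceil"])
    def test_volume_below_two_average_plants_flags_missing(self, rounding):
        assert missing_plants_3d(1.8 * 0.4, 0.4, rounding=rounding) >= 1

    def test_empty_cell_counts_all_plants(self):
        assert missing_plants_3d(0.0, 0.4) == 3

    def test_full_cell_counts_none(self):
        assert missing_plants_3d(3 * 0.4, 0.4) == 0
        assert missing_plants_3d(10 * 0.4, 0.4) == 0  # clamped

    def test_rounding_conventions_differ_at_boundary(self):
        assert missing_plants_3d(2.2 * 0.4, 0.4, rounding="nearest") == 1
        assert missing_plants_3d(2.2 * 0.4, 0.4, rounding="ceil") == 0


def _metrics(cell_id, volume, row_id=0):
    from vinecanopy.method_3d import CanopyMetrics3D

    return CanopyMetrics3D(
        cell_id=cell_id, row_id=row_id, canopy_points=100, alpha_volume=volume
    )


class TestRowVolumeMap:
    def _grid(self, n, row_id=0, y=0.0):
        return [
            GridCell(i, row_id, np.array([2.7 * i, y]), np.array([1.0, 0.0]), 2.7, 2.5)
            for i in range(n)
        ]

    def test_uniform_cells_give_flat_profile(self):
        grid = self._grid(10)
        cells = [_metrics(i, 0.7) for i in range(10)]
        profile = row_volume_map(cells, grid)[0]
        assert [v for _, v in profile] == [0.7] * 10
        assert [s for s, _ in profile] == pytest.approx(
            [2.7 * i + 1.35 for i in range(10)]
        )

    def test_profile_conserves_total_volume(self, rng):
        grid = self._grid(6)
        vols = rng.random(6)
        cells = [_metrics(i, v) for i, v in enumerate(vols)]
        profile = row_volume_map(cells, grid)[0]
        assert sum(v for _, v in profile) == pytest.approx(vols.sum())

    def test_empty_row_absent_from_map(self):
        grid = self._grid(2)
        cells = [_metrics(0, 0.5), _metrics(1, 0.6)]
        assert 1 not in row_volume_map(cells, grid)


class TestRun3D:
    def test_missing_cell_detected_on_tiny_site(self):
        spec = SyntheticSiteSpec(
            n_rows=2, row_length=8.1, row_azimuth=90.0, terrain_slope=0.0,
            terrain_noise_sd=0.005, missing_fraction=0.25, per_vine_size_cv=0.05,
            point_density=150.0, seed=17,
        )
        truth = generate_site(spec)
        cloud = render_cloud(truth, spec)
        cfg = SiteConfig(inter_row=2.5, intra_row=0.9)
        cells = build_grid(site_rows(spec), cfg)
        # reference cells: those whose slots are all occupied in the truth
        complete = [
            c.cell_id
            for c in cells
            if not c.contains(truth.missing_plant_points).any()
        ]
        metrics = run_3d(cloud, cells, cfg, seed=5, complete_cell_ids=complete)
        assert sum(m.n_missing for m in metrics) == truth.n_missing

    def test_hidden_gap_under_neighbor_overhang_still_detected(self):
        spec = SyntheticSiteSpec(
            n_rows=1, row_length=8.1, row_azimuth=90.0, terrain_slope=0.0,
            terrain_noise_sd=0.005, missing_fraction=0.0, per_vine_size_cv=0.0,
            point_density=150.0, seed=19, overhang_frac=0.3,
        )
        truth = generate_site(spec)
        # carve one missing slot by hand in the middle of the row
        recs = truth.vine_records
        victim = 4
        recs.loc[victim, "present"] = False
        truth.missing_plant_points = recs.loc[[victim], ["x", "y"]].to_numpy()
        cloud = render_cloud(truth, spec)
        cfg = SiteConfig(inter_row=2.5, intra_row=0.9)
        cells = build_grid(site_rows(spec), cfg)
        v_bar = float(recs.loc[0, "true_volume"])
        metrics = run_3d(cloud, cells, cfg, seed=5, v_bar=v_bar)
        assert sum(m.n_missing for m in metrics) == 1
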