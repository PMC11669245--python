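"""Shape-metric correctness against closed forms and brute-force hulls."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from microglia3d.core import MicrogliaROI
from microglia3d.morphometry import (
    convex_hull_2d,
    count_density,
    measure_roi,
    metrics_2d,
    metrics_3d,
    project_z,
)
from microglia3d.core import AcquisitionGeometry, LabelVolume

from conftest import digitized_ball, digitized_disk
from oracles import hull_2d_brute, hull_3d_brute


def roi_from_mask(mask, spacing=(1.0, 1.0, 1.0), label=1):
    return MicrogliaROI(label_id=label, coords=np.argwhere(mask), spacing=spacing)


class TestMetrics3D:
    def test_cube_is_its_own_hull(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        v, hv, sol = metrics_3d(roi_from_mask(mask))
        assert v == pytest.approx(1000.0)
        assert hv == pytest.approx(1000.0, rel=1e-12)
        assert sol == pytest.approx(1.0, abs=1e-12)

    def test_digitized_sphere_high_solidity(self):
        """Ball solidity under the corner-hull convention approaches 1 as
        (r/(r+half voxel))^3; it exceeds 0.95 once the radius spans ~40 voxels
        and improves monotonically with resolution."""
        # r = 8 um at 0.2 um isotropic spacing -> 40-voxel radius
        mask = digitized_ball(40.0)
        v, hv, sol = metrics_3d(roi_from_mask(mask, spacing=(0.2, 0.2, 0.2)))
        assert sol >= 0.95
        assert v == pytest.approx(4 / 3 * np.pi * 8**3, rel=0.05)
        # coarser digitization (16-voxel radius) is strictly less solid
        coarse = digitized_ball(16.0)
        _, _, sol_coarse = metrics_3d(roi_from_mask(coarse, spacing=(0.5, 0.5, 0.5)))
        assert sol_coarse < sol
        assert sol_coarse == pytest.approx((16 / 16.5) ** 3, abs=0.02)

    def test_plus_sign_solidity_matches_brute_force_hull(self):
        # two orthogonal 3x3x11 bars through a common centre
        mask = np.zeros((13, 13, 13), bool)
        mask[1:12, 5:8, 5:8] = True
        mask[5:8, 1:12, 5:8] = True
        roi = roi_from_mask(mask)
        v, hv, sol = metrics_3d(roi)
        # the hull of the union equals the hull of the two bars' outer corners
        corners = []
        for (z0, z1, y0, y1, x0, x1) in [(1, 12, 5, 8, 5, 8), (5, 8, 1, 12, 5, 8)]:
            for z in (z0, z1):
                for y in (y0, y1):
                    for x in (x0, x1):
                        corners.append((z, y, x))
        bv, _ = hull_3d_brute(np.array(sorted(set(corners)), float))
        assert hv == pytest.approx(bv, rel=1e-9)
        assert sol == pytest.approx(v / bv, rel=1e-9)

    def test_single_voxel_degenerates_to_unit_cube(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        v, hv, sol = metrics_3d(roi_from_mask(mask))
        assert v == pytest.approx(1.0)
        assert hv == pytest.approx(1.0)
        assert sol == pytest.approx(1.0)


class TestHullOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_3d_hull_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(60, 3))
        hull = ConvexHull(pts)
        bv, ba = hull_3d_brute(pts)
        assert hull.volume == pytest.approx(bv, rel=1e-9)
        assert hull.area == pytest.approx(ba, rel=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_2d_hull_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(300, 2))
        hull = ConvexHull(pts)
        ba, bp = hull_2d_brute(pts)
        assert hull.volume == pytest.approx(ba, rel=1e-9)  # 2D: volume == area
        assert hull.area == pytest.approx(bp, rel=1e-9)  # 2D: area == perimeter

    def test_corner_cloud_hull_of_blob_matches_brute_force(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((9, 9), bool)
        mask[tuple(rng.integers(0, 9, size=(2, 25)))] = True
        area, perim = convex_hull_2d(mask, (1.0, 1.0))
        idx = np.argwhere(mask)
        corners = np.unique(
            (idx[:, None, :] + np.array([[0, 0], [0, 1], [1, 0], [1, 1]])[None]).reshape(-1, 2),
            axis=0,
        ).astype(float)
        ba, bp = hull_2d_brute(corners)
        assert area == pytest.approx(ba, rel=1e-9)
        assert perim == pytest.approx(bp, rel=1e-9)


class TestMetrics2D:
    def test_square_closed_form(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        m, flags = metrics_2d(mask, pixel_size=1.0)
        assert m["area_um2"] == pytest.approx(100.0)
        assert m["perimeter_um"] == pytest.approx(40.0, abs=1e-9)
        assert m["convex_hull_area_um2"] == pytest.approx(100.0)
        assert m["convex_hull_perimeter_um"] == pytest.approx(40.0)
        assert m["solidity_2d"] == pytest.approx(1.0)
        assert m["convexity"] == pytest.approx(1.0)
        assert m["circularity"] == pytest.approx(np.pi / 4, abs=1e-12)
        assert m["axis_ratio"] == pytest.approx(1.0, abs=1e-12)
        assert flags == ""

    def test_large_disk_near_unit_circularity(self):
        mask = digitized_disk(50.0, shape=(120, 120))
        m, _ = metrics_2d(mask, pixel_size=1.0)
        assert m["circularity"] == pytest.approx(1.0, rel=0.08)
        assert m["axis_ratio"] == pytest.approx(1.0, rel=0.02)
        assert m["solidity_2d"] > 0.98

    def test_elongated_ellipse_axis_ratio(self):
        yy, xx = np.ogrid[:60, :220]
        mask = ((yy - 30) / 25.0) ** 2 + ((xx - 110) / 100.0) ** 2 <= 1.0
        m, _ = metrics_2d(mask, pixel_size=1.0)
        assert m["axis_ratio"] == pytest.approx(0.25, rel=0.05)
        assert m["major_axis_um"] == pytest.approx(200.0, rel=0.05)

    def test_single_pixel_is_flagged_unit_square(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        m, flags = metrics_2d(mask, pixel_size=1.0)
        assert "single_pixel" in flags
        assert m["circularity"] == pytest.approx(np.pi / 4)
        assert m["axis_ratio"] == pytest.approx(1.0)
        assert m["solidity_2d"] == pytest.approx(1.0)

    def test_multi_component_mask_is_flagged(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        _, flags = metrics_2d(mask, pixel_size=1.0)
        assert "multi_component_projection" in flags

    @pytest.mark.parametrize("seed", range(4))
    def test_ratio_invariants_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((40, 40), bool)
        # random connected blob: union of random walks
        pos = np.array([20, 20])
        for _ in range(250):
            mask[pos[0], pos[1]] = True
            pos = np.clip(pos + rng.integers(-1, 2, 2), 1, 38)
        m, _ = metrics_2d(mask, pixel_size=1.0)
        for key in ("solidity_2d", "convexity", "circularity", "axis_ratio"):
            assert 0.0 < m[key] <= 1.0, key
        assert m["area_um2"] <= m["convex_hull_area_um2"]
        assert m["perimeter_um"] >= m["convex_hull_perimeter_um"]
        assert m["minor_axis_um"] <= m["major_axis_um"]

    def test_scale_equivariance(self):
        mask = digitized_disk(9.0) | np.eye(23, dtype=bool)
        m1, _ = metrics_2d(mask, pixel_size=1.0)
        m2, _ = metrics_2d(mask, pixel_size=2.5)
        assert m2["area_um2"] == pytest.approx(m1["area_um2"] * 2.5**2, rel=1e-9)
        assert m2["perimeter_um"] == pytest.approx(m1["perimeter_um"] * 2.5, rel=1e-9)
        for key in ("solidity_2d", "convexity", "circularity", "axis_ratio"):
            assert m2[key] == pytest.approx(m1[key], rel=1e-9)


class TestProjection:
    def test_single_slice_projects_to_itself(self):
        mask = np.zeros((1, 8, 8), bool)
        mask[0, 2:6, 3:7] = True
        roi = roi_from_mask(mask)
        assert np.array_equal(project_z(roi), mask[0, 2:6, 3:7])

    def test_stacked_slices_idempotent(self):
        sl = np.zeros((8, 8), bool)
        sl[2:6, 3:7] = True
        mask = np.stack([sl, sl, sl])
        roi = roi_from_mask(mask)
        assert project_z(roi).sum() == sl.sum()

    def test_cylinder_projects_to_disk(self):
        disk = digitized_disk(10.0, shape=(25, 25))
        mask = np.broadcast_to(disk, (6, 25, 25)).copy()
        roi = roi_from_mask(mask)
        proj = project_z(roi)
        lo = np.argwhere(disk).min(axis=0)
        hi = np.argwhere(disk).max(axis=0) + 1
        assert np.array_equal(proj, disk[lo[0]:hi[0], lo[1]:hi[1]])


class TestCountDensity:
    def test_acquisition_field_arithmetic(self):
        geom = AcquisitionGeometry(nx=2048, ny=2048, nz=40, dx=319.45 / 2048,
                                   dy=319.45 / 2048, dz=1.0)
        labels = np.zeros((4, 8, 8), np.int32)
        lv = LabelVolume(labels=labels, spacing=geom.spacing)
        # place 50 fake labels by id only: count_density uses max id
        lv.labels[0, 0, :8] = np.arange(1, 9)
        lv.labels[1, 0, :8] = np.arange(9, 17)
        lv.labels[2, 0, :8] = np.arange(17, 25)
        lv.labels[3, 0, :8] = np.arange(25, 33)
        lv.labels[0, 1, :8] = np.arange(33, 41)
        lv.labels[1, 1, :8] = np.arange(41, 49)
        lv.labels[2, 1, :2] = np.arange(49, 51)
        d = count_density(lv, geom)
        assert d.n_cells == 50
        field_mm2 = (319.45e-3) ** 2
        assert d.density_2d == pytest.approx(50 / field_mm2, rel=1e-12)
        assert d.density_3d == pytest.approx(50 / (field_mm2 * 0.040), rel=1e-12)
        assert d.density_3d == pytest.approx(12249, rel=2e-3)

    def test_zero_cells(self):
        geom = AcquisitionGeometry(nx=8, ny=8, nz=4, dx=1, dy=1, dz=1)
        d = count_density(LabelVolume(np.zeros((4, 8, 8), np.int32), geom.spacing), geom)
        assert d.density_2d == 0 and d.density_3d == 0

    def test_doubling_depth_halves_3d_density_only(self):
        g1 = AcquisitionGeometry(nx=64, ny=64, nz=10, dx=0.5, dy=0.5, dz=1.0)
        g2 = AcquisitionGeometry(nx=64, ny=64, nz=20, dx=0.5, dy=0.5, dz=1.0)
        lab = np.zeros((10, 64, 64), np.int32)
        lab[0, 0, :5] = np.arange(1, 6)
        d1 = count_density(LabelVolume(lab, g1.spacing), g1)
        lab2 = np.zeros((20, 64, 64), np.int32)
        lab2[0, 0, :5] = np.arange(1, 6)
        d2 = count_density(LabelVolume(lab2, g2.spacing), g2)
        assert d2.density_3d == pytest.approx(d1.density_3d / 2)
        assert d2.density_2d == pytest.approx(d1.density_2d)


def test_amoeboid_cells_score_higher_solidity_than_ramified(small_geometry):
    """The metric suite discriminates the morphology spectrum it targets."""
    from microglia3d.synthetic import control_params, generate_scene, render_stack
    from microglia3d.core import rois_from_labels

    def mean_metrics(amoeboid_range, seed):
        # volume chosen so even a fully amoeboid cell fits inside the soma
        # radius bound and the soma/process trade-off is unconstrained
        params = control_params(
            geometry=small_geometry, n_cells=5, n_vessels=0,
            amoeboid_range=amoeboid_range, mean_volume_um3=600.0, volume_cv=0.2,
        )
        _, truth = render_stack(generate_scene(params, seed))
        sols, circs = [], []
        for roi in rois_from_labels(truth.labels):
            if roi.label_id > truth.n_cells:
                continue
            rec = measure_roi(roi)
            sols.append(rec.solidity_3d)
            circs.append(rec.circularity)
        return np.mean(sols), np.mean(circs)

    sol_am, circ_am = mean_metrics((0.9, 0.98), seed=21)
    sol_ra, circ_ra = mean_metrics((0.02, 0.1), seed=21)
    assert sol_am > sol_ra
    assert circ_am > circ_ra
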