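"""Vessel quantification: skeleton + radii, Poiseuille flow, power law,
FWHM resolution, and region statistics."""

import numpy as np
import pytest

from ulm3d.core import VoxelGrid
from ulm3d.maps import VolumetricMap, accumulate_density
from ulm3d.quantify import (
    CenterlinePoint,
    RegionLabels,
    centerline_velocity,
    fit_power_law,
    flow_rate,
    fwhm_of_profile,
    fwhm_resolution,
    layer_velocity_comparison,
    region_stats,
    skeletonize_with_radius,
    smooth_binarize,
)
from ulm3d.tracking import Track


def _iso_grid(n=60, pitch=0.02):
    return VoxelGrid((0, 0, 0), (pitch,) * 3, (n, n, n))


def _density_map(values, grid):
    v = np.asarray(values)
    return VolumetricMap(grid, "density", v, v.astype(np.int64))


def _cylinder_mask(grid, radius_mm, axis=0):
    centers = [
        grid.origin[a] + (np.arange(grid.shape[a]) + 0.5) * grid.pitch[a] for a in range(3)
    ]
    x, y, z = np.meshgrid(*centers, indexing="ij")
    cy = centers[1][grid.shape[1] // 2]
    cz = centers[2][grid.shape[2] // 2]
    return ((y - cy) ** 2 + (z - cz) ** 2) <= radius_mm**2


class TestSmoothBinarize:
    def test_zero_map_empty_mask(self):
        g = _iso_grid(20)
        assert not smooth_binarize(_density_map(np.zeros(g.shape), g)).any()

    def test_uniform_map_full_interior(self):
        g = _iso_grid(20)
        mask = smooth_binarize(_density_map(np.full(g.shape, 10.0), g))
        assert mask[2:-2, 2:-2, 2:-2].all()

    def test_cylinder_diameter_within_one_voxel(self):
        # counts ~2 per voxel: the sparse-map regime the threshold-of-1
        # binarization is designed for (much larger counts dilate the
        # mask because even heavily attenuated smoothing tails clear 1)
        g = _iso_grid(40)
        cyl = _cylinder_mask(g, 0.1)  # radius 5 voxels
        mask = smooth_binarize(_density_map(cyl * 2.0, g))
        mid = mask[20, :, 20]
        got_diam = mid.sum() * g.pitch_mm[1]
        assert abs(got_diam - 0.2) <= g.pitch_mm[1] + 1e-9

    def test_anisotropic_grid_rejected(self):
        g = VoxelGrid((0, 0, 0), (0.02, 0.02, 0.04), (10, 10, 10))
        with pytest.raises(ValueError):
            smooth_binarize(_density_map(np.ones(g.shape), g))


class TestSkeletonizeWithRadius:
    def test_cylinder_centerline_and_radius(self):
        g = _iso_grid(50)
        mask = _cylinder_mask(g, 0.1)
        graph = skeletonize_with_radius(mask, g)
        assert len(graph.points) > 10
        pts = np.array([p.position_mm for p in graph.points])
        center_y = g.origin[1] + (25 + 0.5) * g.pitch[1]
        interior = (pts[:, 0] > 0.2) & (pts[:, 0] < 0.8)
        assert np.all(np.abs(pts[interior, 1] - center_y) <= g.pitch_mm[1] + 1e-9)
        radii = np.array([p.radius_mm for p in graph.points])[interior]
        assert abs(np.mean(radii) - 0.1) <= 1.5 * g.pitch_mm[0]

    def test_sphere_collapses_to_point_cluster(self):
        g = _iso_grid(30)
        centers = [g.origin[a] + (np.arange(30) + 0.5) * g.pitch[a] for a in range(3)]
        x, y, z = np.meshgrid(*centers, indexing="ij")
        c = centers[0][15]
        mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 0.15**2
        graph = skeletonize_with_radius(mask, g)
        pts = np.array([p.position_mm for p in graph.points])
        assert len(pts) <= 10
        assert np.ptp(pts, axis=0).max() <= 0.1

    def test_y_junction_three_segments(self):
        g = _iso_grid(40)
        mask = np.zeros(g.shape, dtype=bool)
        mask[5:20, 18:23, 18:23] = True  # stem
        mask[20:35, 10:15, 18:23] = True
        mask[20:35, 26:31, 18:23] = True
        # connect branches to stem
        mask[18:22, 10:23, 18:23] = True
        mask[18:22, 18:31, 18:23] = True
        graph = skeletonize_with_radius(mask, g)
        assert len(graph.segments) >= 3
        assert any(graph.graph.degree(n) > 2 for n in graph.graph.nodes)

    def test_empty_mask_empty_graph(self):
        g = _iso_grid(10)
        graph = skeletonize_with_radius(np.zeros(g.shape, bool), g)
        assert graph.points == [] and graph.segments == []

    def test_skeleton_subset_of_mask(self):
        g = _iso_grid(40)
        mask = _cylinder_mask(g, 0.08)
        graph = skeletonize_with_radius(mask, g)
        for p in graph.points:
            assert mask[p.voxel]


class TestFlowRate:
    def test_poiseuille_formula(self):
        p = CenterlinePoint(np.zeros(3), radius_mm=0.1, voxel=(0, 0, 0), v_max_mm_s=50.0)
        q_mm3, q_ul_min = flow_rate(p)
        assert q_mm3 == pytest.approx(0.7853981633974483, rel=1e-12)
        assert q_ul_min == pytest.approx(47.12, abs=0.01)

    def test_zero_velocity_zero_flow(self):
        p = CenterlinePoint(np.zeros(3), 0.1, (0, 0, 0), v_max_mm_s=0.0)
        assert flow_rate(p)[0] == 0.0

    def test_radius_squared_scaling(self):
        p1 = CenterlinePoint(np.zeros(3), 0.1, (0, 0, 0), v_max_mm_s=10.0)
        p2 = CenterlinePoint(np.zeros(3), 0.2, (0, 0, 0), v_max_mm_s=10.0)
        assert flow_rate(p2)[0] == pytest.approx(4 * flow_rate(p1)[0], rel=1e-12)

    def test_poiseuille_identity_roundtrip(self):
        p = CenterlinePoint(np.zeros(3), 0.07, (0, 0, 0), v_max_mm_s=23.0)
        q, _ = flow_rate(p)
        assert q * 2 / (np.pi * p.radius_mm**2) == pytest.approx(23.0, rel=1e-12)

    def test_missing_fields_rejected(self):
        p = CenterlinePoint(np.zeros(3), 0.1, (0, 0, 0))
        with pytest.raises(ValueError):
            flow_rate(p)


class TestFitPowerLaw:
    @pytest.mark.parametrize("gamma", [2.0, 2.62, 3.0])
    def test_noiseless_recovery_exact(self, gamma):
        radii = np.linspace(0.02, 0.2, 12)
        flows = 2.0 * radii**gamma
        fit = fit_power_law(list(zip(radii, flows)))
        assert fit.exponent == pytest.approx(gamma, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.prefactor == pytest.approx(2.0, rel=1e-9)

    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(0.1, 1.0), (0.1, 2.0), (0.1, 3.0)])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(0.1, 1.0), (0.2, 2.0)])


class TestFWHM:
    def test_gaussian_profile_closed_form(self):
        sigma = 0.02
        xs = np.arange(0, 0.2, 0.01)
        profile = np.exp(-0.5 * ((xs - 0.1) / sigma) ** 2)
        fwhm = fwhm_of_profile(profile, step_mm=0.01)
        assert fwhm == pytest.approx(2.3548 * sigma, abs=0.01)

    def test_tophat_width(self):
        profile = np.zeros(21)
        profile[8:13] = 1.0  # 5 samples x 10 um
        fwhm = fwhm_of_profile(profile, step_mm=0.01)
        assert fwhm == pytest.approx(0.05, abs=0.011)

    def test_flat_profile_flagged(self):
        with pytest.raises(ValueError):
            fwhm_of_profile(np.ones(10), 0.01)

    def test_vessel_cross_section_on_map(self):
        g = VoxelGrid((0, 0, 0), (0.01,) * 3, (60, 60, 60))
        tracks = []
        rng = np.random.default_rng(0)
        for i in range(100):
            y = 0.3 + rng.uniform(-0.01, 0.01)
            z = 0.3 + rng.uniform(-0.01, 0.01)
            tr = Track(i, np.arange(2), np.array([[0.05, y, z], [0.55, y, z]]))
            tr.velocities_mm_s = np.zeros((2, 3))
            tracks.append(tr)
        density = accumulate_density(tracks, g, step_mm=0.01)
        fwhm = fwhm_resolution(density, (0.3, 0.1, 0.3), (0.3, 0.5, 0.3))
        assert 0.01 <= fwhm <= 0.04  # ~20 um vessel


class TestRegionStats:
    def _labels(self, grid):
        lab = np.zeros(grid.shape, dtype=np.int32)
        lab[:, :, :10] = 1  # region 1
        lab[:, :, 10:] = 2
        return RegionLabels(lab, grid, {1: "upper", 2: "lower"})

    def test_hand_computed_density(self):
        g = VoxelGrid((0, 0, 0), (0.1,) * 3, (20, 20, 20))
        labels = self._labels(g)
        # region 1 volume = 20*20*10 voxels * 0.001 mm^3 = 4 mm^3... use 2 mm^3 region
        lab = np.zeros(g.shape, np.int32)
        lab[:10, :10, :20] = 1  # 2000 voxels x 1e-3 mm3 = 2 mm^3
        labels = RegionLabels(lab, g, {1: "r"})
        rng = np.random.default_rng(1)
        pts = rng.random((500, 3)) * [1.0, 1.0, 2.0]  # inside region 1
        tr = Track(0, np.arange(500), pts)
        tr.velocities_mm_s = np.zeros((500, 3))
        out = region_stats([tr], labels, [1])
        assert out[1]["mb_count"] == 500
        assert out[1]["volume_mm3"] == pytest.approx(2.0, rel=1e-12)
        assert out[1]["mb_density_per_mm3"] == pytest.approx(250.0, rel=1e-12)

    def test_empty_region(self):
        g = VoxelGrid((0, 0, 0), (0.1,) * 3, (20, 20, 20))
        labels = self._labels(g)
        tr = Track(0, np.arange(4), np.full((4, 3), 0.05))  # all in region 1
        tr.velocities_mm_s = np.zeros((4, 3))
        out = region_stats([tr], labels, [2])
        assert out[2]["mb_count"] == 0
        assert len(out[2]["velocity_mm_s"]) == 0

    def test_unknown_region_rejected(self):
        g = VoxelGrid((0, 0, 0), (0.1,) * 3, (10, 10, 10))
        labels = self._labels(g)
        with pytest.raises(ValueError):
            region_stats([], labels, [99])

    def test_density_invariant_under_shared_rigid_shift(self):
        g = VoxelGrid((0, 0, 0), (0.1,) * 3, (20, 20, 20))
        lab = np.zeros(g.shape, np.int32)
        lab[5:15, 5:15, 5:15] = 1
        rng = np.random.default_rng(2)
        pts = 0.6 + rng.random((200, 3)) * 0.8
        tr = Track(0, np.arange(200), pts)
        tr.velocities_mm_s = np.zeros((200, 3))
        base = region_stats([tr], RegionLabels(lab, g, {1: "r"}), [1])
        # shift tracks by t and compose the affine to undo it
        shift = np.array([0.25, -0.15, 0.3])
        tr2 = Track(0, np.arange(200), pts + shift)
        tr2.velocities_mm_s = np.zeros((200, 3))
        aff = np.hstack([np.eye(3), -shift[:, None]])
        moved = region_stats([tr2], RegionLabels(lab, g, {1: "r"}, affine=aff), [1])
        assert moved[1]["mb_count"] == base[1]["mb_count"]
        assert moved[1]["mb_density_per_mm3"] == pytest.approx(
            base[1]["mb_density_per_mm3"]
        )


class TestLayerVelocityComparison:
    def _setup(self, rng, mean_a=8.8, mean_b=7.8, n=400):
        g = VoxelGrid((0, 0, 0), (0.1,) * 3, (20, 20, 10))
        lab = np.zeros(g.shape, np.int32)
        lab[:, :, :5] = 1
        lab[:, :, 5:] = 2
        labels = RegionLabels(lab, g, {1: "L1", 2: "L2"})
        tracks = []
        tid = 0
        for lid, mean in ((1, mean_a), (2, mean_b)):
            zlo = 0.0 if lid == 1 else 0.5
            for i in range(n // 4):
                pts = np.column_stack(
                    [rng.random(4) * 2, rng.random(4) * 2, zlo + rng.random(4) * 0.5]
                )
                speeds = np.abs(rng.normal(mean, 1.0, 4))
                v = np.zeros((4, 3))
                v[:, 2] = speeds  # downward: arteriole
                tr = Track(tid, np.arange(4), pts)
                tr.velocities_mm_s = v
                tracks.append(tr)
                tid += 1
        return tracks, labels

    def test_distinct_means_highly_significant(self, rng):
        tracks, labels = self._setup(rng)
        out = layer_velocity_comparison(tracks, labels, [1, 2])
        comp = [c for c in out["comparisons"] if c["class"] == "arteriole"]
        assert len(comp) == 1
        assert comp[0]["p"] < 0.001
        assert comp[0]["significance"] == "***"

    def test_all_downward_flow_no_venules(self, rng):
        tracks, labels = self._setup(rng)
        out = layer_velocity_comparison(tracks, labels, [1, 2])
        assert all(cls != "venule" for (_, cls) in out["distributions"])
        assert (1, "venule") in out["excluded"]

    def test_normality_reported(self, rng):
        tracks, labels = self._setup(rng)
        out = layer_velocity_comparison(tracks, labels, [1, 2])
        for key, rep in out["normality"].items():
            assert "statistic" in rep and "normal_at_5pct" in rep


class TestCenterlineVelocity:
    def test_uniform_velocity_map(self):
        g = _iso_grid(40)
        mask = _cylinder_mask(g, 0.08)
        graph = skeletonize_with_radius(mask, g)
        vmap = VolumetricMap(g, "velocity_amplitude", np.full(g.shape, 10.0), np.ones(g.shape, np.int64))
        centerline_velocity(graph, vmap)
        assert all(p.v_max_mm_s == pytest.approx(10.0) for p in graph.points)
        # Poiseuille identity at every point
        for p in graph.points:
            assert p.flow_mm3_s * 2 / (np.pi * p.radius_mm**2) == pytest.approx(
                p.v_max_mm_s, rel=1e-12
            )

    def test_empty_velocity_map_flags_points(self):
        g = _iso_grid(30)
        mask = _cylinder_mask(g, 0.08)
        graph = skeletonize_with_radius(mask, g)
        vmap = VolumetricMap(g, "velocity_amplitude", np.full(g.shape, np.nan), np.zeros(g.shape, np.int64))
        centerline_velocity(graph, vmap)
        assert all(p.flagged for p in graph.points)
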