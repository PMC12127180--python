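import numpy as np
import pytest

from otokin import canal_morphometry as cm
from otokin.io_formats import CanalVolume
from otokin.synthetic_data import CanalPhantomConfig, simulate_canal


def _ellipse_points(a, b, n=100, noise=0.0, seed=0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([a * np.cos(th), b * np.sin(th)], axis=1)
    if noise:
        rng = np.random.default_rng(seed)
        pts *= 1.0 + noise * rng.normal(size=(n, 1))
    return pts


class TestCircuitRadius:
    def test_circle_case(self):
        assert cm.circuit_radius(600.0, 600.0) == pytest.approx(600.0)

    def test_closed_form(self):
        assert cm.circuit_radius(3.0, 4.0) == pytest.approx(np.sqrt(12.5))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cm.circuit_radius(0.0, 5.0)


class TestEllipseFit:
    def test_exact_samples_recovered(self):
        fit = cm.fit_ellipse_2d(_ellipse_points(600.0, 500.0))
        assert fit.semi_major == pytest.approx(600.0, rel=1e-3)
        assert fit.semi_minor == pytest.approx(500.0, rel=1e-3)

    def test_circle_gives_equal_axes(self):
        fit = cm.fit_ellipse_2d(_ellipse_points(400.0, 400.0))
        assert fit.semi_major == pytest.approx(fit.semi_minor, rel=1e-6)

    def test_one_percent_radial_noise_within_two_percent(self):
        fit = cm.fit_ellipse_2d(_ellipse_points(620.0, 543.5, noise=0.01, seed=1))
        assert fit.semi_major == pytest.approx(620.0, rel=0.02)
        assert fit.semi_minor == pytest.approx(543.5, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(cm.FitError):
            cm.fit_ellipse_2d(_ellipse_points(600.0, 500.0, n=5))

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(10.0), np.arange(10.0) * 2.0], axis=1)
        with pytest.raises(cm.FitError):
            cm.fit_ellipse_2d(pts)


class TestAmpullaShape:
    def test_circle_ratio_one(self):
        _, _, ratio = cm.ampulla_shape(_ellipse_points(50.0, 50.0))
        assert ratio == pytest.approx(1.0, rel=1e-6)

    def test_two_to_one_ellipse(self):
        _, _, ratio = cm.ampulla_shape(_ellipse_points(80.0, 40.0))
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_elongated_exceeds_round(self):
        _, _, round_r = cm.ampulla_shape(_ellipse_points(50.0, 45.0))
        _, _, elong_r = cm.ampulla_shape(_ellipse_points(70.0, 40.0))
        assert elong_r > round_r


class TestSegmentVolume:
    @pytest.fixture(scope="class")
    def fat_tube(self):
        cfg = CanalPhantomConfig(
            semi_axes=(600.0, 600.0), tube_radius=100.0, arc_span=180.0, voxel_size=4.0
        )
        return simulate_canal(cfg).volume

    def test_noiseless_phantom_dice(self, fat_tube):
        gray = CanalVolume(
            np.asarray(fat_tube.voxels, float), fat_tube.voxel_size, is_binary=False
        )
        seg = cm.segment_volume(gray, blur_sigma=4.0)
        gt = fat_tube.voxels > 0
        m = seg.voxels > 0
        dice = 2 * (m & gt).sum() / (m.sum() + gt.sum())
        assert dice > 0.98

    def test_noisy_phantom_dice(self, fat_tube):
        rng = np.random.default_rng(2)
        noisy = np.asarray(fat_tube.voxels, float) + rng.normal(
            0.0, 0.10, fat_tube.voxels.shape
        )
        seg = cm.segment_volume(CanalVolume(noisy, fat_tube.voxel_size), blur_sigma=4.0)
        gt = fat_tube.voxels > 0
        m = seg.voxels > 0
        dice = 2 * (m & gt).sum() / (m.sum() + gt.sum())
        assert dice > 0.95

    def test_background_only_rejected(self):
        vol = CanalVolume(np.zeros((20, 20, 20)), (1, 1, 1))
        with pytest.raises(cm.SegmentationError):
            cm.segment_volume(vol)


class TestEllipsoid:
    @staticmethod
    def _solid_ellipsoid(a_vox, b_vox, c_vox, voxel=5.0):
        zz, yy, xx = np.mgrid[: 2 * c_vox + 8, : 2 * b_vox + 8, : 2 * a_vox + 8]
        mask = (
            ((xx - a_vox - 4) / a_vox) ** 2
            + ((yy - b_vox - 4) / b_vox) ** 2
            + ((zz - c_vox - 4) / c_vox) ** 2
        ) <= 1
        return CanalVolume(mask.astype(np.uint8), (voxel,) * 3, is_binary=True)

    def test_solid_ellipsoid_axes_and_ratios(self):
        # semi-axes 600/500/100 um at 5 um voxels
        vol = self._solid_ellipsoid(120, 100, 20)
        a, b, c, elong, flat, _ = cm.fit_ellipsoid_3d(vol)
        assert a == pytest.approx(600.0, rel=0.03)
        assert b == pytest.approx(500.0, rel=0.03)
        assert c == pytest.approx(100.0, rel=0.03)
        assert elong == pytest.approx(1.2, rel=0.03)
        assert flat == pytest.approx(5.0, rel=0.03)

    def test_sphere_ratios_unity(self):
        vol = self._solid_ellipsoid(30, 30, 30)
        *_, elong, flat, _ = cm.fit_ellipsoid_3d(vol)
        assert elong == pytest.approx(1.0, abs=0.02)
        assert flat == pytest.approx(1.0, abs=0.02)

    def test_volume_is_voxel_count_times_voxel_volume(self):
        vol = self._solid_ellipsoid(10, 10, 10, voxel=2.0)
        *_, measured = cm.fit_ellipsoid_3d(vol)
        assert measured == pytest.approx((vol.voxels > 0).sum() * 8.0)

    def test_tilt_reduces_zext_flatness_only(self):
        # a rigid tilt cannot change the moment eigenvalues, but it raises
        # the anatomical z-extent, so the depth-axis reading drops sharply
        results = {}
        for tilt in (0.0, 30.0):
            cfg = CanalPhantomConfig(
                semi_axes=(600.0, 500.0),
                tube_radius=66.0,
                arc_span=360.0,
                voxel_size=5.0,
                out_of_plane_tilt=tilt,
            )
            vol = simulate_canal(cfg).volume
            flat_m = cm.fit_ellipsoid_3d(vol, c_mode="moment")[4]
            flat_z = cm.fit_ellipsoid_3d(vol, c_mode="zext")[4]
            results[tilt] = (flat_m, flat_z)
        assert results[0.0][1] > 2.0 * results[30.0][1]
        assert results[0.0][0] == pytest.approx(results[30.0][0], rel=0.05)

    def test_tiny_foreground_rejected(self):
        vol = CanalVolume(np.zeros((10, 10, 10), np.uint8), (1, 1, 1))
        vol.voxels[5, 5, 5] = 1
        with pytest.raises(cm.ResolutionError):
            cm.fit_ellipsoid_3d(vol)


class TestCenterline:
    def test_straight_tube_length(self):
        # 1000 um tube of radius 40 um at 5 um voxels
        zz, yy, xx = np.mgrid[0:24, 0:24, 0:220]
        mask = ((yy - 12) ** 2 + (zz - 12) ** 2) * 25 <= 40**2
        mask &= (xx >= 5) & (xx < 205)
        vol = CanalVolume(mask.astype(np.uint8), (5.0, 5.0, 5.0), is_binary=True)
        _, length = cm.extract_centerline(vol)
        assert length == pytest.approx(1000.0, rel=0.05)

    def test_half_torus_length(self, half_torus):
        # analytic arc length pi * 600 um
        _, length = cm.extract_centerline(half_torus.volume)
        assert length == pytest.approx(np.pi * 600.0, rel=0.03)

    def test_closed_loop_rejected(self):
        cfg = CanalPhantomConfig(
            semi_axes=(300.0, 300.0), tube_radius=40.0, arc_span=360.0, voxel_size=5.0
        )
        vol = simulate_canal(cfg).volume
        with pytest.raises(cm.TopologyError):
            cm.extract_centerline(vol)


class TestCrossSectionProfile:
    def test_constant_tube_area(self, half_torus):
        cl, _ = cm.extract_centerline(half_torus.volume)
        prof = cm.cross_section_profile(half_torus.volume, cl)
        analytic = np.pi * 66.0**2
        assert prof.cs_mean == pytest.approx(analytic, rel=0.05)
        mid = prof.area[20:-20]
        assert np.abs(mid - analytic).max() / analytic < 0.08
        assert not prof.has_stenosis

    def test_stenosis_area_scales_with_factor_squared(self, stenosis_torus):
        cl, _ = cm.extract_centerline(stenosis_torus.volume)
        prof = cm.cross_section_profile(stenosis_torus.volume, cl)
        # radial factor 0.5 -> area factor 0.25 of the unconstricted lumen,
        # at the programmed arclength (ampulla orients the profile)
        assert prof.cs_min / (np.pi * 66.0**2) == pytest.approx(0.25, abs=0.04)
        assert prof.stenosis_position == pytest.approx(0.75, abs=0.03)
        assert prof.stenosis_ratio == pytest.approx(
            stenosis_torus.truth.stenosis_ratio, rel=0.10
        )
        assert prof.has_stenosis

    def test_ratio_bounded_by_one(self, half_torus):
        cl, _ = cm.extract_centerline(half_torus.volume)
        prof = cm.cross_section_profile(half_torus.volume, cl)
        assert 0.0 < prof.stenosis_ratio <= 1.0


class TestXmax:
    def test_unit_case(self):
        assert cm.xmax(1.0, 1.0) == 1.0

    def test_functional_form(self):
        base = cm.xmax(500.0, 60.0)
        assert cm.xmax(500.0, 120.0) == pytest.approx(4 * base)
        assert cm.xmax(1000.0, 60.0) == pytest.approx(2 * base)

    def test_published_radii_rank_species(self):
        # axolotl canal (R 582.91, r 66.32) less sensitive than Xenopus
        # (R 634.09, r 77.11)
        ratio = cm.xmax(582.91, 66.32) / cm.xmax(634.09, 77.11)
        assert ratio < 1.0

    def test_grid_shapes(self):
        r, R, X = cm.xmax_grid(n=50)
        assert X.shape == (50, 50)
        assert X[0, 0] == pytest.approx(R[0] * r[0] ** 2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cm.xmax(-1.0, 2.0)


class TestScalingInvariance:
    def test_isotropic_voxel_rescale(self, half_torus):
        """Lengths scale linearly, volumes cubically, ratios not at all."""
        vol1 = half_torus.volume
        vol2 = CanalVolume(vol1.voxels, tuple(2 * v for v in vol1.voxel_size), True)
        _, L1 = cm.extract_centerline(vol1)
        _, L2 = cm.extract_centerline(vol2)
        assert L2 == pytest.approx(2 * L1, rel=1e-6)
        a1 = cm.fit_ellipsoid_3d(vol1)
        a2 = cm.fit_ellipsoid_3d(vol2)
        assert a2[0] == pytest.approx(2 * a1[0], rel=1e-9)  # length axis
        assert a2[5] == pytest.approx(8 * a1[5], rel=1e-9)  # volume
        assert a2[3] == pytest.approx(a1[3], rel=1e-9)  # elongation
        assert a2[4] == pytest.approx(a1[4], rel=1e-9)  # flatness


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_phantoms_match_generator_truth(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(450, 650)
        b = a * rng.uniform(0.85, 1.0)
        cfg = CanalPhantomConfig(
            semi_axes=(a, b),
            tube_radius=rng.uniform(55, 80),
            arc_span=rng.uniform(150, 260),
            voxel_size=5.0,
            out_of_plane_tilt=rng.uniform(0, 15),
            seed=seed,
        )
        res = simulate_canal(cfg)
        cl, length = cm.extract_centerline(res.volume)
        assert length == pytest.approx(res.truth.arc_length, rel=0.05)
        prof = cm.cross_section_profile(res.volume, cl)
        assert prof.cs_mean == pytest.approx(res.truth.cs_mean, rel=0.05)
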