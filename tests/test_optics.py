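"""Camera geometry, demosaicking, stereo and fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stressphen import optics
from stressphen.optics import (CameraIntrinsics, HSImage, demosaic_snapshot,
                               distort_normalized, fuse_spectral_cloud,
                               project_points, read_ply, remosaic, stereo_match,
                               triangulate, undistort_normalized, write_ply,
                               default_band_wavelengths)
from stressphen import synthscene as ss
from conftest import random_cloud


# ---------------------------------------------------------------------------
# demosaicking
# ---------------------------------------------------------------------------


class TestDemosaic:
    def test_band_offsets_are_pure_subsampling(self):
        raw = np.arange(100).reshape(10, 10).astype(float)  # raw[r, c] = 10r + c
        hs = demosaic_snapshot(raw)
        np.testing.assert_array_equal(hs.data[0], [[0, 5], [50, 55]])
        # band b at offset (rb, cb): pixel (i, j) == raw[5i+rb, 5j+cb]
        for b, (rb, cb) in [(7, (1, 2)), (24, (4, 4))]:
            np.testing.assert_array_equal(
                hs.data[b], raw[rb::5, cb::5])

    def test_constant_raw_gives_constant_bands(self):
        hs = demosaic_snapshot(np.full((15, 20), 0.37))
        assert np.all(hs.data == 0.37)

    def test_sensor_native_dimensions(self):
        raw = np.zeros((1085, 2045))
        hs = demosaic_snapshot(raw)
        assert hs.data.shape == (25, 217, 409)
        # tile-aligned portion: 2045 = 409*5; 1085 = 217*5
        assert hs.shape == (217, 409)

    def test_non_multiple_dimensions_are_cropped(self):
        hs = demosaic_snapshot(np.zeros((13, 17)))
        assert hs.shape == (2, 3)

    def test_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            demosaic_snapshot(np.zeros((4, 9)))

    def test_remosaic_inverts_on_tile_aligned_input(self, rng):
        raw = rng.random((25, 35))
        mosaic = rng.permutation(25).reshape(5, 5)
        hs = demosaic_snapshot(raw, mosaic)
        np.testing.assert_array_equal(remosaic(hs, mosaic), raw)


# ---------------------------------------------------------------------------
# stereo
# ---------------------------------------------------------------------------


class TestStereo:
    def _textured(self, rng, shape=(60, 90)):
        from scipy import ndimage
        img = ndimage.gaussian_filter(rng.random(shape), 1.0)
        return img

    def test_constructed_shift_recovered(self, rng):
        left = self._textured(rng)
        right = np.roll(left, -7, axis=1)  # right = left shifted by 7 px
        disp = stereo_match(left, right, block_size=5, max_disparity=15)
        core = disp[10:-10, 15:-15]
        ok = np.isfinite(core)
        assert ok.mean() > 0.9
        assert np.nanmedian(np.abs(core - 7)) < 0.5

    def test_identical_images_give_zero_disparity(self, rng):
        left = self._textured(rng)
        disp = stereo_match(left, left, block_size=5, max_disparity=10)
        assert np.nanmax(np.abs(disp)) < 0.5

    def test_textureless_images_all_invalid(self):
        flat = np.full((40, 60), 0.5)
        disp = stereo_match(flat, flat, block_size=5, max_disparity=10)
        assert np.all(np.isnan(disp))

    @pytest.mark.parametrize("block", [2, 1, 4])
    def test_bad_block_size_raises(self, block):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError):
            stereo_match(img, img, block_size=block)

    def test_synthetic_pair_matches_true_disparity(self, plan, rig, effects, config):
        """>= 90% of textured pixels within 1 px of the rendered truth.

        A mid-growth canopy: at full closure the steep silhouette bands
        violate the fronto-parallel window assumption (a documented
        limitation of local block matching).
        """
        scene = ss.grow_canopy(plan[7], 23, effects, seed=1)
        frames, truth = ss.render_frameset(scene, rig, effects, seed=1)
        disp = stereo_match(frames.ir_left, frames.ir_right,
                            block_size=config.stereo_block_size,
                            max_disparity=config.max_disparity(rig))
        mat = truth.material["ir_left"]
        textured = (mat != ss.MAT_BACKGROUND) & (mat != ss.MAT_PANEL)
        ok = np.isfinite(disp) & textured
        err = np.abs(disp - truth.disparity)[ok]
        assert (err < 1.0).mean() >= 0.90


# ---------------------------------------------------------------------------
# triangulation / projection
# ---------------------------------------------------------------------------


class TestTriangulate:
    def test_closed_form_depth(self, rig_full):
        # f = 600 px, b = 0.07 m, d = 42 px  ->  z = 1.0 m
        disp = np.full(rig_full.cameras["ir_left"].shape, np.nan)
        disp[120, 160] = 42.0
        pts, pix = triangulate(disp, rig_full)
        assert pts.shape == (1, 3)
        assert pts[0, 2] == pytest.approx(600 * 0.07 / 42, abs=1e-12)

    def test_doubling_disparity_halves_depth(self, rig_full):
        disp = np.full(rig_full.cameras["ir_left"].shape, np.nan)
        disp[10, 10], disp[20, 20] = 13.0, 26.0
        pts, _ = triangulate(disp, rig_full)
        assert pts[0, 2] == pytest.approx(2 * pts[1, 2])

    def test_principal_point_on_optical_axis(self, rig_full):
        import copy
        rig = copy.deepcopy(rig_full)
        rig.cameras["ir_left"] = CameraIntrinsics(fx=600, fy=600, cx=160, cy=120,
                                                  width=320, height=240)
        disp = np.full((240, 320), np.nan)
        disp[120, 160] = 30.0
        pts, _ = triangulate(disp, rig)
        assert abs(pts[0, 0]) < 1e-12 and abs(pts[0, 1]) < 1e-12

    def test_invalid_pixels_emit_no_points(self, rig_full):
        disp = np.full((5, 5), np.nan)
        disp[0, 0] = 0.0    # non-positive disparity: skipped
        pts, pix = triangulate(disp, rig_full)
        assert len(pts) == 0


class TestProjection:
    def test_optical_axis_maps_to_principal_point(self):
        cam = CameraIntrinsics(fx=500, fy=500, cx=64, cy=48, width=128, height=96)
        pix, valid = project_points([[0, 0, 2.0]], cam)
        assert valid[0]
        np.testing.assert_allclose(pix[0], [48, 64], atol=1e-12)

    def test_point_behind_camera_invalid(self):
        cam = CameraIntrinsics(fx=500, fy=500, cx=64, cy=48, width=128, height=96)
        _, valid = project_points([[0.1, 0.1, -1.0]], cam)
        assert not valid[0]

    def test_triangulate_project_round_trip(self, rig_full, rng):
        """project o triangulate is the identity on valid pixels (zero dist)."""
        cam = rig_full.cameras["ir_left"]
        disp = np.full(cam.shape, np.nan)
        rows = rng.integers(5, cam.height - 5, 200)
        cols = rng.integers(5, cam.width - 5, 200)
        disp[rows, cols] = rng.uniform(20, 60, 200)
        pts, pix = triangulate(disp, rig_full)
        repix, valid = project_points(pts, cam)
        assert valid.all()
        assert np.max(np.abs(repix - pix)) < 1e-6

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.tuples(*[st.floats(-0.1, 0.1) for _ in range(2)]),
           st.tuples(*[st.floats(-0.01, 0.01) for _ in range(2)]),
           st.floats(-0.4, 0.4), st.floats(-0.3, 0.3))
    def test_distortion_round_trip(self, ks, ps, xn, yn):
        dist = (*ks, *ps)
        xd, yd = distort_normalized(np.array([xn]), np.array([yn]), dist)
        xu, yu = undistort_normalized(xd, yd, dist)
        assert abs(xu[0] - xn) < 1e-8 and abs(yu[0] - yn) < 1e-8


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


class TestFusion:
    def test_single_point_carries_exact_pixel_values(self, rig):
        rgb = np.full((*rig.cameras["rgb"].shape, 3), [0.1, 0.6, 0.2])
        hs = HSImage(np.full((25, *rig.cameras["hs"].shape), 0.33),
                     rig.wavelengths)
        cloud = fuse_spectral_cloud([[0, 0, 1.0]], rgb, hs, rig)
        assert len(cloud) == 1
        np.testing.assert_allclose(cloud.rgb[0], [0.1, 0.6, 0.2])
        np.testing.assert_allclose(cloud.bands[0], 0.33)

    def test_point_outside_hs_fov_dropped(self, rig):
        rgb = np.zeros((*rig.cameras["rgb"].shape, 3))
        hs = HSImage(np.zeros((25, *rig.cameras["hs"].shape)), rig.wavelengths)
        # extreme lateral point: projects outside every camera
        cloud = fuse_spectral_cloud([[5.0, 0, 1.0]], rgb, hs, rig)
        assert len(cloud) == 0

    def test_output_is_subset_of_input(self, rig, rng):
        pts = np.column_stack([rng.uniform(-1, 1, 300), rng.uniform(-1, 1, 300),
                               rng.uniform(0.5, 1.5, 300)])
        rgb = rng.random((*rig.cameras["rgb"].shape, 3))
        hs = HSImage(rng.random((25, *rig.cameras["hs"].shape)), rig.wavelengths)
        cloud = fuse_spectral_cloud(pts, rgb, hs, rig)
        assert len(cloud) <= len(pts)
        # every output coordinate appears in the input set
        as_set = {tuple(p) for p in np.round(pts, 12)}
        assert all(tuple(p) in as_set for p in np.round(cloud.xyz, 12))

    def test_missing_wavelengths_raise(self, rig):
        rgb = np.zeros((*rig.cameras["rgb"].shape, 3))
        bad = HSImage(np.zeros((25, 4, 4)), default_band_wavelengths())
        bad.wavelengths = None
        with pytest.raises(ValueError, match="calibration"):
            fuse_spectral_cloud([[0, 0, 1.0]], rgb, bad, rig)

    def test_fused_colors_match_material_map(self, frameset, rig, config):
        """Renderer ground truth: fused colors agree with the material map."""
        from stressphen import io_cli
        frames, truth = frameset
        panel = ss.default_panel_spec(rig)
        factors = io_cli.measure_factors(frames, rig, panel)
        _, cloud, _ = io_cli.process_frameset(frames, rig, config, factors,
                                              return_cloud=True)
        veg_true = ss.point_truth_vegetation(cloud, truth, rig)
        # vegetation is green (G dominant); everything else is not
        greenish = cloud.rgb[:, 1] > 1.15 * np.maximum(cloud.rgb[:, 0], cloud.rgb[:, 2])
        assert (greenish == veg_true).mean() >= 0.99


# ---------------------------------------------------------------------------
# PLY serialization
# ---------------------------------------------------------------------------


def test_ply_round_trip(tmp_path, rng):
    cloud = random_cloud(rng, n=50)
    cloud.vegetation = rng.random(50) < 0.5
    path = tmp_path / "cloud.ply"
    write_ply(cloud, path)
    back = read_ply(path)
    assert len(back) == 50
    np.testing.assert_allclose(back.xyz, cloud.xyz, atol=1e-6)
    np.testing.assert_allclose(back.bands, cloud.bands, atol=1e-6)
    np.testing.assert_allclose(back.rgb, np.clip(cloud.rgb, 0, 1), atol=1 / 255)
    np.testing.assert_array_equal(back.vegetation, cloud.vegetation)
    np.testing.assert_allclose(back.wavelengths, cloud.wavelengths, atol=0.5)


def test_rig_yaml_round_trip(tmp_path, rig):
    path = tmp_path / "rig.yaml"
    rig.to_yaml(path)
    back = optics.CameraRig.from_yaml(path)
    assert back.cameras["rgb"].fx == pytest.approx(rig.cameras["rgb"].fx)
    np.testing.assert_allclose(back.extrinsics["ir_right"], rig.extrinsics["ir_right"])
    np.testing.assert_allclose(back.wavelengths, rig.wavelengths)
    np.testing.assert_array_equal(back.mosaic, rig.mosaic)
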