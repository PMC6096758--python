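"""DRR rendering, moving-image generation, ROI extraction, resampling."""

from dataclasses import replace

import numpy as np
import pytest

from lvreg import (
    CArmGeometry,
    CaptureRangeError,
    InPlaneTransform,
    ProjectionImage,
    extract_roi,
    render_drr,
    render_model_projection,
    resample_to_input,
)
from lvreg.phantom import AnatomyModel, AttenuationVolume
from lvreg.projection import projected_center_mm
from lvreg.validation import drr_oracle


def _random_volume(rng, n, spacing):
    vox = rng.random((n, n, n)).astype(np.float32) * 0.05
    origin = -np.full(3, (n - 1) * spacing / 2)
    return AttenuationVolume(vox, np.full(3, spacing), origin)


class TestRenderDRR:
    def test_zero_volume_gives_zero_image(self):
        vol = AttenuationVolume(np.zeros((8, 8, 8), np.float32), [2, 2, 2], [-7, -7, -7])
        img = render_drr(vol, CArmGeometry(), fov_mm=100, size=32)
        assert np.all(img.pixels == 0)

    def test_single_voxel_chord_length(self):
        """Central pixel integrates mu times the exact chord (2 mm here)."""
        vox = np.zeros((1, 1, 1), np.float32)
        vox[0, 0, 0] = 0.5
        vol = AttenuationVolume(vox, [2, 2, 2], [0, 0, 0])
        img = render_drr(vol, CArmGeometry(), fov_mm=8, size=9)
        assert img.pixels[4, 4] == pytest.approx(1.0, rel=0.02)

    def test_matches_ray_box_oracle(self):
        """Exact per-voxel chord oracle, random geometries, tiny volumes."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(2, 9))
            sp = float(rng.uniform(1, 3))
            vol = _random_volume(rng, n, sp)
            geo = CArmGeometry(
                primary_angle_deg=rng.uniform(-30, 30),
                secondary_angle_deg=rng.uniform(-10, 10),
                source_to_isocenter_mm=rng.uniform(400, 900),
                center_of_projection=rng.uniform(-5, 5, 3),
            )
            fov = n * sp * 2.5
            drr = render_drr(vol, geo, fov_mm=fov, size=12).pixels
            orc = drr_oracle(vol, geo, fov, 12)
            hit = orc > 0
            assert np.all(np.abs(drr - orc)[hit] <= 0.02 * orc[hit])

    def test_linearity_of_line_integral(self):
        rng = np.random.default_rng(9)
        v1 = _random_volume(rng, 6, 2.0)
        v2 = AttenuationVolume(
            rng.random((6, 6, 6)).astype(np.float32) * 0.05, v1.spacing, v1.origin
        )
        geo = CArmGeometry(primary_angle_deg=17)
        combo = AttenuationVolume(
            2.0 * v1.voxels + 0.5 * v2.voxels, v1.spacing, v1.origin
        )
        d1 = render_drr(v1, geo, fov_mm=40, size=16).pixels
        d2 = render_drr(v2, geo, fov_mm=40, size=16).pixels
        dc = render_drr(combo, geo, fov_mm=40, size=16).pixels
        assert np.allclose(dc, 2.0 * d1 + 0.5 * d2, rtol=1e-5, atol=1e-7)

    def test_parallel_projection_limit(self, small_phantom):
        """Very distant source converges to the orthographic axis sum."""
        vol, _ = small_phantom
        geo = CArmGeometry(source_to_isocenter_mm=1e6)
        n = vol.voxels.shape[0]
        fov = n * vol.spacing[0]  # pixel centres land on voxel centres
        drr = render_drr(vol, geo, fov_mm=fov, size=n).pixels
        ortho = vol.voxels.astype(float).sum(axis=1) * vol.spacing[1]
        # image row r is world z = ((n-1)/2 - r) * sp, col c is world x
        expected = ortho[:, ::-1].T
        assert np.allclose(drr, expected, rtol=0.01, atol=0.01 * ortho.max())

    def test_source_inside_volume_rejected(self):
        vol = AttenuationVolume(
            np.ones((9, 9, 9), np.float32), [50, 50, 50], [-200, -200, -200]
        )
        with pytest.raises(ValueError, match="degenerate"):
            render_drr(vol, CArmGeometry(source_to_isocenter_mm=100), fov_mm=50, size=8)


class TestMovingImage:
    def test_pure_translations_identical(self, small_phantom, geometry):
        vol, model = small_phantom
        geo = geometry.with_center(model.center)
        a = render_model_projection(model, InPlaneTransform(0, 0, 5), geo, size=48)
        b = render_model_projection(model, InPlaneTransform(25, -30, 5), geo, size=48)
        assert np.array_equal(a.pixels, b.pixels)

    def test_central_symmetry_under_180_rotation(self, geometry):
        """An ellipsoid is centrally symmetric: rz=180 equals rz=0."""
        g = np.mgrid[-15:16, -15:16, -15:16].astype(float)
        mask = ((g[0] / 10) ** 2 + (g[1] / 12) ** 2 + (g[2] / 14) ** 2) <= 1.0
        model = AnatomyModel(mask=mask, spacing=[2, 2, 2], origin=[-30, -30, -30])
        geo = geometry.with_center(model.center)
        a = render_model_projection(model, InPlaneTransform(), geo, size=48)
        b = render_model_projection(model, InPlaneTransform(0, 0, 180), geo, size=48)
        assert np.abs(a.pixels - b.pixels).max() < 1e-3

    def test_sphere_max_thickness_is_diameter(self):
        g = np.mgrid[-15:16, -15:16, -15:16].astype(float)
        r_mm = 20.0
        mask = (g**2).sum(axis=0) * 4.0 <= r_mm**2  # spacing 2 mm
        model = AnatomyModel(mask=mask, spacing=[2, 2, 2], origin=[-30, -30, -30])
        img = render_model_projection(
            model, InPlaneTransform(), CArmGeometry(), size=64, normalize=False
        )
        assert img.pixels.max() == pytest.approx(2 * r_mm, rel=0.06)

    def test_normalized_to_unit_maximum(self, small_phantom, geometry):
        vol, model = small_phantom
        img = render_model_projection(
            model, InPlaneTransform(), geometry.with_center(model.center), size=48
        )
        assert img.pixels.max() == pytest.approx(1.0)
        assert img.pixels.min() >= 0.0


class TestExtractROI:
    def test_roi_at_ground_truth_overlaps_moving_support(self, lv_only_phantom):
        """Same geometry renders both images: supports must coincide."""
        vol, model = lv_only_phantom
        geo = CArmGeometry().with_center(model.center)
        fixed = render_drr(vol, geo, size=192)
        roi = extract_roi(
            fixed, InPlaneTransform(), geo, model_center=model.center, size=64
        )
        moving = render_model_projection(model, InPlaneTransform(), geo, size=64)
        a = roi.pixels > 0.05 * roi.pixels.max()
        b = moving.pixels > 0.05
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.95

    def test_translation_moves_roi_center_exactly(self, small_fixed):
        """ROI centre tracks the projected translation (cop at LV centre)."""
        fixed, geo, model = small_fixed
        for t in [InPlaneTransform(10, -20, 0), InPlaneTransform(-35, 5, 9)]:
            c = projected_center_mm(t, model.center, geo)
            assert np.allclose(c, [t.tx_mm, t.ty_mm], atol=1e-9)
            roi = extract_roi(fixed, t, geo, model_center=model.center, size=32)
            assert np.allclose(roi.meta["center_mm"], [t.tx_mm, t.ty_mm], atol=1e-9)

    def test_window_leaving_fov_raises_capture_range(self, small_fixed):
        fixed, geo, model = small_fixed
        with pytest.raises(CaptureRangeError):
            extract_roi(
                fixed, InPlaneTransform(120, 0, 0), geo, model_center=model.center
            )

    def test_zero_fixed_gives_zero_roi(self, geometry):
        fixed = ProjectionImage(np.zeros((64, 64)), 300.0, "fixed", geometry)
        roi = extract_roi(fixed, InPlaneTransform(5, 5, 0), geometry, np.zeros(3))
        assert np.all(roi.pixels == 0)


class TestResampleToInput:
    def test_standardized_image_unchanged(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(32, 32))
        img = (img - img.mean()) / img.std()
        out = resample_to_input(img, 32)
        assert np.allclose(out, img, atol=1e-6)

    def test_constant_image_maps_to_zeros(self):
        assert np.all(resample_to_input(np.full((20, 20), 7.0), 16) == 0)

    def test_downsampled_ramp_keeps_slope(self):
        """2x reduction of a linear ramp stays a ramp of the same slope,
        matching a brute-force 2x2 block average in the interior."""
        x = np.arange(64, dtype=float)
        img = np.tile(x, (64, 1))
        out = resample_to_input(img, 32)
        block = img.reshape(32, 2, 32, 2).mean(axis=(1, 3))
        expected = (block - block.mean()) / block.std()
        interior = np.s_[4:-4, 4:-4]
        assert np.allclose(out[interior], expected[interior], atol=0.02)

    def test_rejects_tiny_sides(self):
        with pytest.raises(ValueError):
            resample_to_input(np.zeros((16, 16)), 4)

    def test_output_is_standardized(self):
        rng = np.random.default_rng(3)
        out = resample_to_input(rng.random((50, 50)), 24)
        assert out.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.std() == pytest.approx(1.0, abs=1e-5)


def test_projection_png_json_roundtrip(tmp_path, small_fixed):
    fixed, geo, model = small_fixed
    p = tmp_path / "fixed.png"
    fixed.save(p)
    back = ProjectionImage.load(p)
    assert back.role == "fixed"
    assert back.fov_mm == fixed.fov_mm
    assert back.pixel_spacing_mm == pytest.approx(fixed.pixel_spacing_mm)
    assert np.allclose(back.pixels, fixed.pixels, atol=fixed.pixels.max() / 60000)
    assert np.allclose(
        back.geometry.center_of_projection, geo.center_of_projection
    )
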