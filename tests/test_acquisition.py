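"""Body detection, focus scoring, compositing and field-of-view cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from xenoscreen import (
    AcquisitionParams,
    ZStack,
    best_focus_composite,
    body_centroid,
    crop_fov,
    focus_score,
    generate_scene,
    render_zstack,
)


def _brute_force_tenengrad(image):
    """Independent oracle: central finite differences, same spacing as np.gradient."""
    image = np.asarray(image, float)
    gx = np.empty_like(image)
    gx[:, 1:-1] = (image[:, 2:] - image[:, :-2]) / 2
    gx[:, 0] = image[:, 1] - image[:, 0]
    gx[:, -1] = image[:, -1] - image[:, -2]
    gy = np.empty_like(image)
    gy[1:-1] = (image[2:] - image[:-2]) / 2
    gy[0] = image[1] - image[0]
    gy[-1] = image[-1] - image[-2]
    return np.mean(gx**2 + gy**2)


class TestBodyCentroid:
    def test_uniform_square_centroid_at_geometric_center(self):
        img = np.zeros((50, 50))
        img[10:21, 20:31] = 100.0
        det = body_centroid(img, threshold_mode="k_sigma", k=1.0)
        assert det.ok
        assert det.centroid_um == pytest.approx((25.0, 15.0))

    def test_two_equal_pixels_centroid_at_midpoint(self):
        img = np.zeros((20, 20))
        img[0, 0] = img[0, 10] = 50.0
        det = body_centroid(img, threshold_mode="k_sigma", k=1.0, min_area_px=2)
        assert det.centroid_um == pytest.approx((5.0, 0.0))

    def test_constant_image_flags_failure_without_raising(self):
        det = body_centroid(np.full((30, 30), 7.0))
        assert not det.ok
        assert det.centroid_um is None

    def test_tiny_mask_flags_failure(self):
        img = np.zeros((30, 30))
        img[5, 5] = 100.0
        det = body_centroid(img, threshold_mode="k_sigma", k=1.0, min_area_px=10)
        assert not det.ok and det.reason == "mask_below_min_area"

    def test_intensity_scaling_leaves_centroid_unchanged(self, scene, noise_free_params):
        stack = render_zstack(scene, noise_free_params, "body", 1)
        img = stack.slices[noise_free_params.focus_index]
        a = body_centroid(img, threshold_mode="k_sigma", pixel_size_um=3.25)
        b = body_centroid(img * 7.5, threshold_mode="k_sigma", pixel_size_um=3.25)
        assert a.centroid_um == pytest.approx(b.centroid_um, abs=1e-9)

    def test_synthetic_larva_centroid_near_truth(self, scene, noise_free_params):
        stack = render_zstack(scene, noise_free_params, "body", 1)
        det = body_centroid(
            stack.slices[noise_free_params.focus_index],
            pixel_size_um=noise_free_params.pixel_size_um,
        )
        assert det.ok
        err = np.hypot(
            det.centroid_um[0] - scene.body_center_um[0],
            det.centroid_um[1] - scene.body_center_um[1],
        )
        assert err < 5.0  # um


class TestFocusScore:
    def test_constant_image_scores_zero(self):
        assert focus_score(np.full((10, 10), 42.0)) == 0.0

    def test_offset_invariance(self, tumor_composite):
        assert focus_score(tumor_composite) == pytest.approx(
            focus_score(tumor_composite + 100.0)
        )

    @given(c=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (16, 16))
        assert focus_score(c * img) == pytest.approx(c**2 * focus_score(img), rel=1e-9)

    def test_blur_strictly_reduces_score(self, tumor_composite):
        sharp = focus_score(tumor_composite)
        blurred = focus_score(gaussian_filter(tumor_composite, 2.0))
        assert _brute_force_tenengrad(tumor_composite) == pytest.approx(sharp, rel=1e-9)
        assert blurred < sharp

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            focus_score(np.ones((2, 5)))


class TestBestFocusComposite:
    def test_selects_true_focal_slice(self, scene, noise_free_params):
        stack = render_zstack(scene, noise_free_params, "tumor", 1)
        # oracle: score every slice independently
        expected = int(np.argmax([_brute_force_tenengrad(s) for s in stack.slices]))
        comp = best_focus_composite(stack)
        assert comp.source_index == expected == noise_free_params.focus_index
        assert np.array_equal(comp.image, stack.slices[expected])

    def test_tie_breaks_to_lowest_index(self):
        stack = ZStack(np.tile(np.arange(36.0).reshape(6, 6), (4, 1, 1)), 40.0, 3.25)
        assert best_focus_composite(stack).source_index == 0

    def test_single_slice_identity(self):
        img = np.arange(64.0).reshape(8, 8)
        stack = ZStack(img[None], 40.0, 3.25)
        comp = best_focus_composite(stack)
        assert comp.source_index == 0
        assert np.array_equal(comp.image, img)

    def test_tile_mode_picks_locally_sharpest(self):
        # slice 0 sharp on the left half, slice 1 sharp on the right
        rng = np.random.default_rng(1)
        texture = rng.uniform(0, 100, (32, 32))
        s0 = texture.copy()
        s0[:, 16:] = gaussian_filter(texture[:, 16:], 3)
        s1 = texture.copy()
        s1[:, :16] = gaussian_filter(texture[:, :16], 3)
        comp = best_focus_composite(ZStack(np.stack([s0, s1]), 40.0, 3.25), mode="tile", tile_px=16)
        assert comp.source_index.tolist() == [[0, 1], [0, 1]]
        assert np.array_equal(comp.image[:, :16], texture[:, :16])
        assert np.array_equal(comp.image[:, 16:], texture[:, 16:])

    def test_focal_slice_selected_under_read_noise(self):
        # compositing is driven by the body (FITC) channel, whose sharp
        # edges keep selection reliable at read noise of 2% of its peak
        params = AcquisitionParams(shot_noise=False, read_noise_sd=20.0)
        hits = 0
        for trial in range(200):
            sc = generate_scene(params, 1, [150.0], 1.0, seed=trial)
            stack = render_zstack(sc, params, "body", 1)
            hits += best_focus_composite(stack).source_index == params.focus_index
        assert hits >= 198  # >= 99% of 200 seeded trials

    def test_tumor_intensity_insensitive_to_noisy_slice_choice(self):
        # smooth low-texture tumor foci blur so little per z-step that read
        # noise can shift the winning slice; blur conserves total intensity,
        # so the integrated readout barely moves even then
        params = AcquisitionParams(shot_noise=False, read_noise_sd=60.0)
        for trial in range(20):
            sc = generate_scene(params, 1, [150.0], 1.0, seed=trial)
            stack = render_zstack(sc, params, "tumor", 1)
            comp = best_focus_composite(stack)
            bg = params.background_level
            selected = (comp.image - bg).sum()
            focal = (stack.slices[params.focus_index] - bg).sum()
            assert selected == pytest.approx(focal, rel=0.05)


class TestCropFov:
    def test_full_size_center_crop_is_identity(self):
        img = np.arange(121.0).reshape(11, 11)
        out = crop_fov(img, (5.0, 5.0), (11, 11))
        assert np.array_equal(out, img)

    def test_corner_crop_zero_padded(self):
        img = np.ones((20, 20))
        out = crop_fov(img, (0.0, 0.0), (11, 11))
        assert out[:5].sum() == 0 and out[:, :5].sum() == 0
        assert np.all(out[5:, 5:] == 1)

    def test_recrop_is_idempotent(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(30, 30))
        once = crop_fov(img, (15.0, 15.0), (21, 21))
        twice = crop_fov(once, (10.0, 10.0), (21, 21))
        assert np.array_equal(once, twice)

    def test_micron_center_rounds_to_nearest_pixel(self):
        img = np.arange(100.0).reshape(10, 10)
        out = crop_fov(img, (2.6 * 2.0, 2.6 * 2.0), (3, 3), pixel_size_um=2.6)
        assert out[1, 1] == img[2, 2]
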