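import dataclasses

import numpy as np
import pytest

from perspire.imaging import (
    FrameStack,
    SegmentationParams,
    apply_overrides,
    midgrey_threshold,
    normalize_stack,
    phansalkar_threshold,
    refine_mask,
    stabilize_stack,
    wet_area_series,
)
from ._oracles import brute_midgrey, brute_phansalkar


def _disk_image(size=64, center=(32, 32), radius=7.5, contrast=0.1, bg=0.35,
                noise=0.0, rng=None):
    """Uniform background with one dark disk; optionally noisy.

    The default background level is dark-ish: Phansalkar's exponential
    term makes its threshold track close to the local mean only at low
    gray levels, which is where a 10%-of-range feature is detectable
    (the normalization convention puts sweat near the bottom of the
    range).
    """
    img = np.full((size, size), bg)
    yy, xx = np.ogrid[:size, :size]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img[disk] -= contrast
    if noise and rng is not None:
        img = np.clip(img + rng.normal(0, noise, img.shape), 0, 1)
    return img, disk


class TestThresholdOracles:
    @pytest.mark.parametrize("size,radius", [(32, 3), (32, 5), (64, 10)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_phansalkar_matches_brute_force(self, size, radius, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (size, size))
        assert np.array_equal(
            phansalkar_threshold(img, radius), brute_phansalkar(img, radius)
        )

    @pytest.mark.parametrize("size,radius", [(32, 3), (32, 5), (64, 10)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_midgrey_matches_brute_force(self, size, radius, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (size, size))
        assert np.array_equal(
            midgrey_threshold(img, radius), brute_midgrey(img, radius)
        )

    def test_midgrey_step_image_matches_oracle(self):
        img = np.full((40, 40), 0.9)
        img[:, 20:] = 0.3
        assert np.array_equal(midgrey_threshold(img, 8), brute_midgrey(img, 8))


class TestPhansalkar:
    def test_uniform_image_single_class(self):
        mask = phansalkar_threshold(np.full((30, 30), 0.6), 5)
        assert mask.all() or (~mask).all()

    def test_requires_normalized_input(self):
        with pytest.raises(ValueError, match="normalized"):
            phansalkar_threshold(np.full((10, 10), 200.0), 5)

    def test_dark_disk_detected_within_ten_percent(self):
        img, disk = _disk_image(radius=7.5, contrast=0.1)
        mask = phansalkar_threshold(img, 20)
        assert mask.sum() == pytest.approx(disk.sum(), rel=0.10)
        assert (mask & disk).sum() > 0.9 * disk.sum()

    def test_polarity_dark_detected_bright_not(self):
        img, disk = _disk_image()
        dark_hits = phansalkar_threshold(img, 20)[disk].mean()
        bright_hits = phansalkar_threshold(1.0 - img, 20)[disk].mean()
        assert dark_hits > 0.9
        assert bright_hits < 0.1


class TestMidgrey:
    def test_uniform_image_empty(self):
        assert not midgrey_threshold(np.full((30, 30), 0.5), 5).any()

    def test_polarity_inversion_complements_detection(self):
        # t_inv = 1 − t, so wet pixels of the inverted image are exactly
        # the above-threshold pixels of the original
        rng = np.random.default_rng(7)
        img = rng.uniform(0.1, 0.9, (30, 30))
        size = 2 * 4 + 1
        from scipy import ndimage

        t = (
            ndimage.maximum_filter(img, size=size, mode="mirror")
            + ndimage.minimum_filter(img, size=size, mode="mirror")
        ) / 2.0
        inverted_wet = midgrey_threshold(1.0 - img, 4)
        assert np.array_equal(inverted_wet, img > t)

    def test_wide_shallow_puddle_needs_large_radius(self):
        from scipy import ndimage

        img, disk = _disk_image(
            size=128, center=(64, 64), radius=20, contrast=0.02, bg=0.8
        )
        interior = ndimage.binary_erosion(disk, iterations=7)
        detected_large = midgrey_threshold(img, 35)
        detected_small = midgrey_threshold(img, 5)
        # the small window sees zero local contrast inside the puddle
        assert detected_large[interior].mean() > 0.9
        assert detected_small[interior].mean() < 0.1

    def test_opening_suppresses_bright_lines(self):
        img = np.full((60, 60), 0.5)
        img[30, 5:55] = 1.0  # warm crevice line
        plain = midgrey_threshold(img, 10)
        robust = midgrey_threshold(img, 10, open_px=2)
        assert plain.any()  # the line inflates the midrange
        assert not robust.any()


class TestRefineMask:
    def test_single_pixel_hole_closed(self):
        mask = np.zeros((30, 30), dtype=bool)
        yy, xx = np.ogrid[:30, :30]
        mask[(yy - 15) ** 2 + (xx - 15) ** 2 <= 49] = True
        mask[15, 15] = False
        params = SegmentationParams(morphology=("close",), blur_radius=0)
        assert refine_mask(mask, params)[15, 15]

    def test_isolated_pixel_removed_by_blur(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10, 10] = True
        params = SegmentationParams(morphology=(), blur_radius=2.0)
        assert not refine_mask(mask, params).any()

    def test_near_idempotent_on_disk_masks(self):
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.ogrid[:64, :64]
        for cy, cx, r in [(20, 20, 8), (45, 40, 6), (30, 52, 5)]:
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        params = SegmentationParams.dropwise()
        once = refine_mask(mask, params)
        twice = refine_mask(once, params)
        assert (once ^ twice).mean() < 0.01

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError):
            refine_mask(np.zeros((5, 5), bool), SegmentationParams(morphology=("sharpen",)))


class TestStabilization:
    def test_static_stack_identity(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 1, (64, 64))
        stack = FrameStack(np.stack([frame] * 5), 10.0, 26.7)
        _, offsets = stabilize_stack(stack, reference=0)
        assert np.allclose(offsets, 0.0, atol=0.051)

    def test_integer_shift_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 1, (64, 64))
        shifted = np.roll(np.roll(base, 5, axis=0), -2, axis=1)
        stack = FrameStack(np.stack([base, shifted]), 10.0, 26.7)
        _, offsets = stabilize_stack(stack, reference=0, exclude_wet_px=0)
        assert offsets[1] == pytest.approx([5.0, -2.0], abs=0.1)

    def test_constant_frames_warn_and_return_zero(self):
        stack = FrameStack(np.zeros((3, 16, 16)), 10.0, 26.7)
        with pytest.warns(UserWarning):
            _, offsets = stabilize_stack(stack, reference=0)
        assert np.all(offsets == 0)

    def test_synthetic_shake_recovered(self, dropwise_recovery):
        assert dropwise_recovery["stabilization_rms_px"] < 0.5


class TestWetAreaSeries:
    def test_all_wet_frame(self):
        series = wet_area_series(np.ones((1, 10, 10), bool), 26.7, 10 * 10 * (26.7e-4) ** 2)
        assert series.omega[0] == pytest.approx(1.0)

    def test_printed_wet_fraction(self):
        # 0.1 cm² of 1.93 cm² exposed skin is the 5% wet fraction
        pitch = 26.7
        pixel_area = (pitch * 1e-4) ** 2
        n_wet = int(round(0.1 / pixel_area))
        mask = np.zeros((1, 400, 400), dtype=bool)
        mask.ravel()[:n_wet] = True
        series = wet_area_series(mask, pitch, total_area_cm2=1.93)
        assert series.omega[0] == pytest.approx(0.0518, abs=2e-4)

    def test_omega_bounded(self, dropwise_recovery):
        omega = dropwise_recovery["wet_series"].omega
        assert np.all(omega >= 0) and np.all(omega <= 1)

    def test_pipeline_recovers_truth_within_five_percent(self, dropwise_recovery):
        assert dropwise_recovery["omega_mae_rel"] <= 0.05

    def test_invalid_total_area(self):
        with pytest.raises(ValueError):
            wet_area_series(np.ones((1, 4, 4), bool), 26.7, total_area_cm2=0.0)


class TestOverrides:
    def test_add_and_remove_rect(self):
        masks = np.zeros((4, 10, 10), dtype=bool)
        overrides = [
            {"frames": (0, 1), "rect": (2, 5, 2, 5), "action": "add"},
            {"frames": (1, 1), "rect": (2, 4, 2, 4), "action": "remove"},
        ]
        with pytest.warns(UserWarning):
            out = apply_overrides(masks, overrides)
        assert out[0, 3, 3] and not out[2, 3, 3]
        assert not out[1, 3, 3] and out[1, 4, 4]
        assert not masks.any()  # input untouched


def test_normalize_stack_range():
    rng = np.random.default_rng(3)
    frames = rng.uniform(100, 900, (3, 16, 16))
    out = normalize_stack(frames)
    assert out.min() == 0.0 and out.max() == 1.0
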