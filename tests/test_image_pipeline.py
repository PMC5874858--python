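"""Dark subtraction, filtering, flat-field, ROI accumulation, extraction."""

import numpy as np
import pytest

from scintqa.image_pipeline import (ROI, ImageStack, accumulate_roi,
                                    extract_axis_profile, flat_field,
                                    median_filter, run_pipeline, subtract_dark)
from scintqa.qa import closed_loop


def stack_of(arr, n=1, **kw):
    return ImageStack(np.broadcast_to(np.asarray(arr, float),
                                      (n,) + np.shape(arr)).copy(), **kw)


class TestSubtractDark:
    def test_identical_stacks_give_zero(self):
        s = stack_of(np.full((8, 8), 7.0), n=3)
        out = subtract_dark(s, s)
        assert np.all(out.frames == 0)

    def test_zero_dark_is_identity(self):
        rng = np.random.default_rng(0)
        s = ImageStack(rng.integers(0, 1000, (2, 8, 8)).astype(float))
        out = subtract_dark(s, stack_of(np.zeros((8, 8))))
        np.testing.assert_array_equal(out.frames, s.frames)

    def test_known_dark_level_removed(self):
        # in signal-carrying regions (where zero-clipping never binds) the
        # dark bias after subtraction is below 1 count over 10^6 px
        rng = np.random.default_rng(1)
        dark_true, signal = 100.0, 1000.0
        beam = ImageStack(
            rng.poisson(dark_true + signal, (3, 600, 600)).astype(float),
            bit_depth=16)
        dark = ImageStack(rng.poisson(dark_true, (3, 600, 600)).astype(float))
        out = subtract_dark(beam, dark)
        assert abs(out.frames.mean() - signal) < 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_dark(stack_of(np.ones((4, 4))), stack_of(np.ones((5, 5))))


class TestFlatField:
    def test_unit_gain_identity(self):
        s = stack_of(np.full((4, 4), 9.0))
        out = flat_field(s, np.ones((4, 4)))
        np.testing.assert_array_equal(out.frames, s.frames)

    def test_half_gain_doubles(self):
        s = stack_of(np.full((4, 4), 9.0))
        out = flat_field(s, np.full((4, 4), 0.5))
        np.testing.assert_array_equal(out.frames, 2 * s.frames)

    def test_synthetic_vignetting_flattened(self):
        from scintqa.synthetic_data import make_vignetting

        gain = make_vignetting((64, 64), 0.3)
        s = stack_of(1000.0 * gain)
        out = flat_field(s, gain)
        cv = out.frames.std() / out.frames.mean()
        assert cv < 0.005

    def test_invalid_gain_rejected(self):
        s = stack_of(np.ones((4, 4)))
        with pytest.raises(ValueError):
            flat_field(s, np.zeros((4, 4)))


class TestMedianFilter:
    def test_kernel_one_identity(self):
        rng = np.random.default_rng(2)
        s = ImageStack(rng.random((2, 8, 8)) * 100)
        np.testing.assert_array_equal(median_filter(s, 1).frames, s.frames)

    def test_hot_pixel_removed(self):
        img = np.full((9, 9), 10.0)
        img[4, 4] = 5000.0
        out = median_filter(stack_of(img), 3)
        assert out.frames.max() == 10.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.random((16, 16)) * 100
        out = median_filter(stack_of(img), 3).frames[0]
        padded = np.pad(img, 1, mode="symmetric")   # ndimage's 'reflect'
        brute = np.empty_like(img)
        for i in range(16):
            for j in range(16):
                brute[i, j] = np.median(padded[i:i + 3, j:j + 3])
        np.testing.assert_array_equal(out, brute)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_filter(stack_of(np.ones((4, 4))), 2)


class TestAccumulateRoi:
    def test_single_frame_of_ones(self):
        _, mean, sd = accumulate_roi(stack_of(np.ones((12, 12))),
                                     ROI(1, 11, 1, 11))
        assert mean == 1.0 and sd == 0.0

    def test_three_identical_frames_triple(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        summed, _, _ = accumulate_roi(stack_of(img, n=3), ROI(0, 8, 0, 8))
        np.testing.assert_array_equal(summed, 3 * img)

    def test_against_direct_recomputation(self):
        rng = np.random.default_rng(4)
        frames = rng.random((3, 10, 14)) * 50
        roi = ROI(2, 9, 3, 12)
        summed, mean, sd = accumulate_roi(ImageStack(frames), roi)
        direct = frames[:, 2:9, 3:12].sum(axis=0)
        np.testing.assert_allclose(summed, direct)
        assert mean == pytest.approx(direct.mean())
        assert sd == pytest.approx(direct.std())

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            accumulate_roi(stack_of(np.ones((4, 4))), ROI(0, 8, 0, 8))


class TestExtractAxisProfile:
    def test_centroid_of_symmetric_beam(self):
        img = np.zeros((21, 30))
        img[8:13, :] = 5.0
        prof = extract_axis_profile(img, ROI(0, 21, 0, 30), 2, "cols")
        np.testing.assert_allclose(prof, 5.0)

    def test_uniform_image_gives_flat_profile(self):
        img = np.full((11, 20), 3.0)
        prof = extract_axis_profile(img, ROI(0, 11, 0, 20), 3, "cols")
        np.testing.assert_allclose(prof, 3.0)

    def test_rows_axis_transposes(self):
        rng = np.random.default_rng(5)
        img = rng.random((15, 20))
        a = extract_axis_profile(img, ROI(0, 15, 0, 20), 4, "cols")
        b = extract_axis_profile(img.T, ROI(0, 20, 0, 15), 4, "rows")
        np.testing.assert_allclose(a, b)

    def test_band_exceeding_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_axis_profile(np.ones((5, 5)), ROI(0, 5, 0, 5), 3, "cols")


class TestFullPipeline:
    def test_deterministic_given_fixed_inputs(self, scene60):
        a = run_pipeline(scene60.pipeline_config, beam_stack=scene60.beam_on,
                         dark_stack=scene60.dark, flat_stack=scene60.flat)
        b = run_pipeline(scene60.pipeline_config, beam_stack=scene60.beam_on,
                         dark_stack=scene60.dark, flat_stack=scene60.flat)
        np.testing.assert_array_equal(a.values, b.values)

    def test_all_dark_input_gives_near_zero_profile(self, scene60):
        out = run_pipeline(scene60.pipeline_config, beam_stack=scene60.dark,
                           dark_stack=scene60.dark, flat_stack=scene60.flat)
        beam = run_pipeline(scene60.pipeline_config, beam_stack=scene60.beam_on,
                            dark_stack=scene60.dark, flat_stack=scene60.flat)
        assert out.values.max() < 0.01 * beam.values.max()

    def test_chain_is_linear_in_exposure(self, scene60_clean):
        cfg = scene60_clean.pipeline_config
        base = run_pipeline(cfg, beam_stack=scene60_clean.beam_on,
                            dark_stack=scene60_clean.dark)
        frames = scene60_clean.beam_on.frames.copy()
        dark = scene60_clean.dark.frames
        scaled = ImageStack(np.clip(dark + 0.5 * (frames - dark), 0, None),
                            bit_depth=16)
        half = run_pipeline(cfg, beam_stack=scaled,
                            dark_stack=scene60_clean.dark)
        sel = base.values > 0.05 * base.values.max()
        np.testing.assert_allclose(half.values[sel], 0.5 * base.values[sel],
                                   rtol=0.02)

    def test_background_below_one_percent_of_signal(self, scene60):
        """After dark subtraction the residual background in the signal-free
        region stays below 1% of the beam signal."""
        out = run_pipeline(scene60.pipeline_config, beam_stack=scene60.beam_on,
                           dark_stack=scene60.dark, flat_stack=scene60.flat)
        z = out.depths
        background = out.values[z > 40.0].mean()
        assert background < 0.01 * out.values.max()

    def test_stage_error_names_the_stage(self, scene60):
        from dataclasses import replace

        bad = replace(scene60.pipeline_config, median_kernel=2)
        with pytest.raises(RuntimeError, match="median"):
            run_pipeline(bad, beam_stack=scene60.beam_on,
                         dark_stack=scene60.dark, flat_stack=scene60.flat)
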