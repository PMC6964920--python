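import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burstkit as bk
from burstkit.imaging_roi import RhythmMap, forward_moving_average


def stack_from(frames, fps=32.0, pitch=bk.DEFAULT_PIXEL_PITCH_UM):
    return bk.ImagingStack(np.asarray(frames, dtype=float), frame_rate=fps,
                           pixel_pitch=pitch)


class TestMeanFrameTrace:
    def test_constant_stack(self):
        tr = bk.mean_frame_trace(stack_from(np.full((5, 4, 4), 3.5)))
        np.testing.assert_allclose(tr.samples, 3.5)
        assert tr.rate == 32.0

    def test_two_frame_means(self):
        frames = np.stack([np.full((4, 4), 1.0), np.full((4, 4), 3.0)])
        tr = bk.mean_frame_trace(stack_from(frames))
        np.testing.assert_allclose(tr.samples, [1.0, 3.0])

    def test_global_modulation_dominates_spectrum(self):
        T, f0, fps = 512, 2.0, 32.0
        t = np.arange(T) / fps
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * f0 * t)
        frames = np.ones((T, 4, 4)) * mod[:, None, None]
        tr = bk.mean_frame_trace(stack_from(frames))
        spec = np.abs(np.fft.rfft(tr.samples - tr.samples.mean()))
        freqs = np.fft.rfftfreq(T, 1 / fps)
        assert freqs[np.argmax(spec)] == pytest.approx(f0)


class TestCyclePeriodModel:
    def test_arithmetic_of_ci_and_band(self):
        # periods {3.5, 4.0, 4.5} s -> mean 4.0, sample SD 0.5
        m = bk.CyclePeriodModel(4.0, 0.5, 3)
        assert m.ci == (3.0, 5.0)
        lo, hi = m.band_hz
        assert lo == pytest.approx(0.2)
        assert hi == pytest.approx(1 / 3.0)

    def test_negative_ci_low_rejected(self):
        with pytest.raises(ValueError):
            bk.CyclePeriodModel(4.0, 3.0, 5).band_hz

    def test_estimated_from_periodic_stack(self, small_imaging):
        _, stack, truth = small_imaging
        model = bk.collective_cycle_model(bk.mean_frame_trace(stack))
        assert model.mean_period_s == pytest.approx(4.0, abs=0.3)
        assert model.n_cycles >= 5

    def test_too_few_peaks_rejected(self):
        tr = bk.Trace(np.zeros(320), rate=32.0)
        model = bk.NoiseModel(centers=[5.0], mu=[0.0], sigma=[0.01], k=2.0)
        with pytest.raises(ValueError):
            bk.collective_cycle_model(tr, model)


class TestDownsample:
    def test_block_mean_2x2(self):
        frames = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        frames = np.repeat(frames, 2, axis=0)
        out = bk.downsample_stack(stack_from(frames), 1)
        np.testing.assert_allclose(out.frames, 4.0)
        assert out.pixel_pitch == pytest.approx(2 * bk.DEFAULT_PIXEL_PITCH_UM)

    def test_constant_stack_stays_constant(self):
        out = bk.downsample_stack(stack_from(np.full((3, 16, 16), 2.0)), 2)
        np.testing.assert_allclose(out.frames, 2.0)
        assert out.frames.shape == (3, 4, 4)

    def test_grand_mean_preserved_for_divisible_shapes(self):
        rng = np.random.default_rng(0)
        frames = rng.random((4, 32, 32))
        out = bk.downsample_stack(stack_from(frames), 1)
        # stacks are stored float32, so the identity holds to that precision
        np.testing.assert_allclose(
            out.frames.mean(axis=(1, 2)), frames.mean(axis=(1, 2)), rtol=1e-6
        )

    def test_edge_blocks_average_available_pixels(self):
        frames = np.arange(2 * 3 * 3, dtype=float).reshape(2, 3, 3)
        out = bk.downsample_stack(stack_from(frames), 1)
        assert out.frames.shape == (2, 2, 2)
        np.testing.assert_allclose(
            out.frames[0], [[(0 + 1 + 3 + 4) / 4, (2 + 5) / 2], [(6 + 7) / 2, 8.0]]
        )

    def test_factor_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            bk.downsample_stack(stack_from(np.zeros((2, 4, 4))), 3)


class TestFFTMap:
    def test_constant_stack_maps_to_zero(self):
        rmap = bk.fft_rhythm_map(stack_from(np.full((64, 4, 4), 5.0)), (0.1, 0.5))
        np.testing.assert_allclose(rmap.values, 0.0, atol=1e-9)

    def test_on_bin_cosine_closed_form(self):
        # cos(2 pi f0 t) of amplitude a on an exact bin -> magnitude a*T/2
        T, fps, a = 256, 32.0, 0.7
        f0 = 8 * fps / T  # exactly bin 8 = 1.0 Hz
        t = np.arange(T) / fps
        frames = np.zeros((T, 2, 2))
        frames[:, 0, 0] = 10.0 + a * np.cos(2 * np.pi * f0 * t)
        rmap = bk.fft_rhythm_map(stack_from(frames), (0.8, 1.2))
        assert rmap.values[0, 0] == pytest.approx(a * T / 2, rel=1e-6)
        assert rmap.values[1, 1] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_band_widens_to_neighboring_bins(self):
        T, fps = 256, 32.0
        frames = np.random.default_rng(0).random((T, 4, 4))
        rmap = bk.fft_rhythm_map(stack_from(frames), (0.25, 0.25))
        lo, hi = rmap.bin_hz
        assert lo < 0.25 < hi or lo <= 0.25 <= hi

    def test_out_of_band_oscillation_suppressed(self):
        T, fps = 512, 32.0
        t = np.arange(T) / fps
        frames = np.zeros((T, 8, 8))
        in_band = np.sin(2 * np.pi * 0.25 * t)
        out_band = np.sin(2 * np.pi * 0.75 * t)
        frames[:, :4, :] = in_band[:, None, None]
        frames[:, 4:, :] = out_band[:, None, None]
        rmap = bk.fft_rhythm_map(stack_from(frames), (0.2, 0.3))
        assert rmap.values[:4].min() > 10 * rmap.values[4:].max()


class TestSegmentation:
    def _map(self, values, pitch=2 * bk.DEFAULT_PIXEL_PITCH_UM):
        return RhythmMap(values=np.asarray(values, dtype=float), downsample_n=1,
                         pixel_pitch_um=pitch, band_hz=(0.1, 0.3),
                         bin_hz=(0.1, 0.3))

    def test_uniform_map_has_no_rois(self):
        assert bk.segment_rois(self._map(np.ones((16, 16)))) == []

    def test_disk_above_six_micron_kept(self):
        values = np.zeros((32, 32))
        rr, cc = np.ogrid[:32, :32]
        disk = (rr - 16) ** 2 + (cc - 16) ** 2 <= 25  # radius 5 px
        values[disk] = 10.0
        rois = bk.segment_rois(self._map(values))
        assert len(rois) == 1
        # equivalent diameter ~ 2*sqrt(81/pi)*0.906 ~ 9.2 um
        assert rois[0].equivalent_diameter_um > 6.0
        assert rois[0].mask.sum() == disk.sum()

    def test_single_pixel_discarded(self):
        values = np.zeros((16, 16))
        values[8, 8] = 10.0
        assert bk.segment_rois(self._map(values)) == []

    def test_fullres_backprojection_shape(self):
        # 6x6 composite block at the corner of a 31x31 (odd) full frame:
        # back-projection doubles it to 12x12 and crops the last row/col
        values = np.zeros((16, 16))
        values[10:16, 10:16] = 10.0
        [roi] = bk.segment_rois(self._map(values), full_shape=(31, 31))
        assert roi.mask_fullres.shape == (31, 31)
        assert roi.mask_fullres.sum() == 12 * 12 - 12 - 12 + 1

    def test_scaling_stack_leaves_segmentation_unchanged(self, small_imaging):
        _, stack, truth = small_imaging
        cyc = bk.collective_cycle_model(bk.mean_frame_trace(stack))
        ds = bk.downsample_stack(stack, 1)
        rmap1 = bk.fft_rhythm_map(ds, cyc.band_hz)
        scaled = bk.ImagingStack(ds.frames * 3.0, frame_rate=ds.frame_rate,
                                 pixel_pitch=ds.pixel_pitch)
        rmap2 = bk.fft_rhythm_map(scaled, cyc.band_hz)
        np.testing.assert_allclose(rmap2.values, 3.0 * rmap1.values, rtol=1e-5)
        m1 = [r.mask for r in bk.segment_rois(rmap1)]
        m2 = [r.mask for r in bk.segment_rois(rmap2)]
        assert len(m1) == len(m2)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a, b)


class TestDFF:
    def test_constant_roi_gives_zero(self, small_imaging):
        _, stack, truth = small_imaging
        frames = np.full_like(stack.frames, 7.0)
        const = bk.ImagingStack(frames, frame_rate=32.0)
        roi = _truth_roi(truth, 0)
        dff = bk.compute_dff(const, roi)
        np.testing.assert_allclose(dff.values, 0.0)

    def test_unsmoothed_series_has_zero_mean(self, small_imaging):
        _, stack, truth = small_imaging
        for k in range(truth.roi_masks.shape[0]):
            dff = bk.compute_dff(stack, _truth_roi(truth, k))
            assert abs(dff.values.mean()) < 1e-10

    def test_default_smoothing_window_is_four_frames(self, small_imaging):
        _, stack, truth = small_imaging
        dff = bk.compute_dff(stack, _truth_roi(truth, 0))
        assert dff.smooth_window == 4
        np.testing.assert_allclose(
            dff.smoothed, forward_moving_average(dff.values, 4)
        )

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_forward_moving_average_trailing_edge(self, seed):
        x = np.random.default_rng(seed).normal(size=9)
        y = forward_moving_average(x, 4)
        assert y[0] == pytest.approx(x[:4].mean())
        assert y[-1] == pytest.approx(x[-1])
        assert y[-2] == pytest.approx(x[-2:].mean())


def _truth_roi(truth, k):
    from burstkit.imaging_roi import ROI

    mask = truth.roi_masks[k]
    return ROI(roi_id=k, mask=mask, mask_fullres=mask,
               equivalent_diameter_um=10.0, centroid=(0.0, 0.0))


class TestEndToEndRecovery:
    def test_planted_cells_recovered(self, small_imaging):
        cfg, stack, truth = small_imaging
        cyc = bk.collective_cycle_model(bk.mean_frame_trace(stack))
        rmap = bk.fft_rhythm_map(bk.downsample_stack(stack, 1), cyc.band_hz,
                                 downsample_n=1)
        rois = bk.segment_rois(rmap, full_shape=stack.frames.shape[1:])
        assert len(rois) == cfg.n_cells
        for k in range(cfg.n_cells):
            t = truth.roi_masks[k]
            jac = max(
                (r.mask_fullres & t).sum() / (r.mask_fullres | t).sum()
                for r in rois
            )
            assert jac >= 0.6
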