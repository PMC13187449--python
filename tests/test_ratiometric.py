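import numpy as np
import pytest

from btk.errors import InputError, ModelError, SegmentationError
from btk.io_core import ImageStack
from btk.ratiometric import (
    DualChannelTrace,
    Kymograph,
    StimulusProtocol,
    align_and_test,
    bleaching_summary,
    detect_pump_events,
    extract_traces,
    mixed_effect_test,
    motion_correct_kymograph,
    ratiometric_signal,
    segment_neuron,
    split_by_reversal,
    subtract_background,
)

from oracles import grid_minimize_alpha


class TestBackground:
    def test_constant_stack_becomes_zero(self):
        stack = ImageStack(np.full((5, 8, 8), 10.0))
        out = subtract_background(stack)
        assert out.frames.max() == 0.0

    def test_half_dark_half_bright_median(self):
        frames = np.zeros((1, 10, 10))
        frames[0, :, 5:] = 100.0
        out = subtract_background(ImageStack(frames), sample_stride=1)
        # background = 50th percentile = 50; bright pixels become 50, dark clip to 0
        assert out.frames.max() == 50.0 and out.frames.min() == 0.0

    def test_stride_beyond_length_uses_first_frame(self):
        frames = np.stack([np.full((4, 4), 3.0), np.full((4, 4), 99.0)])
        out = subtract_background(ImageStack(frames), sample_stride=100)
        assert out.frames[1].max() == 96.0  # background 3 from frame 0 only

    def test_empty_stack_rejected(self):
        with pytest.raises(InputError):
            subtract_background(ImageStack(np.zeros((0, 4, 4))))


class TestSegmentation:
    @staticmethod
    def blob(cy, cx, amp, sigma, shape=(40, 40)):
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        return amp * np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2) / (2 * sigma**2))

    def test_mask_covers_half_max_region(self):
        frame = self.blob(20, 20, 100.0, 4.0)
        mask = segment_neuron(frame)
        half_max = frame >= 50.0
        assert (mask & half_max).sum() / half_max.sum() >= 0.9

    def test_blank_frame_raises(self):
        with pytest.raises(SegmentationError):
            segment_neuron(np.zeros((20, 20)))

    def test_largest_blob_retained(self):
        frame = self.blob(10, 10, 100.0, 5.0) + self.blob(30, 32, 100.0, 1.5)
        mask = segment_neuron(frame)
        ys, xs = np.nonzero(mask)
        assert ys.mean() < 20 and xs.mean() < 20


class TestExtraction:
    def test_uniform_frames_give_constant_trace(self):
        sig = ImageStack(np.full((4, 6, 6), 7.0))
        ref = ImageStack(np.full((4, 6, 6), 3.0))
        mask = np.ones((6, 6), dtype=bool)
        tr = extract_traces((sig, ref), mask)
        np.testing.assert_allclose(tr.F_sig, 7.0)
        np.testing.assert_allclose(tr.F_ref, 3.0)

    def test_green_doubling_leaves_reference_unchanged(self):
        base = np.random.default_rng(0).uniform(1, 2, (3, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        tr1 = extract_traces((ImageStack(base), ImageStack(base)), mask)
        tr2 = extract_traces((ImageStack(2 * base), ImageStack(base)), mask)
        np.testing.assert_allclose(tr2.F_sig, 2 * tr1.F_sig)
        np.testing.assert_allclose(tr2.F_ref, tr1.F_ref)

    def test_mask_shape_mismatch_rejected(self):
        sig = ImageStack(np.ones((2, 4, 4)))
        with pytest.raises(InputError):
            extract_traces((sig, sig), np.ones((5, 5), dtype=bool))

    def test_empty_mask_gives_nan_frame(self):
        sig = ImageStack(np.ones((2, 4, 4)))
        masks = np.stack([np.ones((4, 4), bool), np.zeros((4, 4), bool)])
        tr = extract_traces((sig, sig), masks)
        assert np.isfinite(tr.F_sig[0]) and np.isnan(tr.F_sig[1])


class TestRatio:
    def test_identical_channels_give_unit_ratio(self):
        tr = DualChannelTrace(time=np.arange(5.0), F_sig=[1, 2, 3, 2, 1], F_ref=[1, 2, 3, 2, 1])
        out = ratiometric_signal(tr)
        np.testing.assert_allclose(out.R, 1.0)
        np.testing.assert_allclose(out.dRR0, 0.0, atol=1e-15)

    def test_printed_worked_example(self):
        # F_sig=[2,4], F_ref=[1,1]: means 3 and 1, so R=[(2/4)/(1/2),(4/4)/(1/2)]
        tr = DualChannelTrace(time=[0.0, 1.0], F_sig=[2.0, 4.0], F_ref=[1.0, 1.0])
        out = ratiometric_signal(tr, pedestal="on")
        np.testing.assert_allclose(out.R, [1.0, 2.0])
        np.testing.assert_allclose(out.dRR0, [-1 / 3, 1 / 3])

    def test_zero_reference_is_an_error(self):
        tr = DualChannelTrace(time=[0.0, 1.0], F_sig=[1.0, 1.0], F_ref=[0.0, 0.0])
        with pytest.raises(InputError):
            ratiometric_signal(tr)

    def test_pedestal_off_cancels_shared_artifact_exactly(self, rng):
        n = 50
        f_sig = rng.uniform(50, 100, n)
        f_ref = rng.uniform(100, 200, n)
        artifact = rng.uniform(0.5, 1.5, n)
        clean = ratiometric_signal(
            DualChannelTrace(np.arange(n, dtype=float), f_sig, f_ref), pedestal="off"
        )
        dirty = ratiometric_signal(
            DualChannelTrace(np.arange(n, dtype=float), f_sig * artifact, f_ref * artifact),
            pedestal="off",
        )
        # per-frame artifact cancels in the instantaneous ratio; the window
        # means contribute only a constant factor, which dRR0 removes exactly
        ratio = dirty.R / clean.R
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)
        np.testing.assert_allclose(dirty.dRR0, clean.dRR0, atol=1e-12)

    def test_drr0_zero_mean_over_window(self, rng):
        tr = DualChannelTrace(
            np.arange(100, dtype=float), rng.uniform(10, 20, 100), rng.uniform(5, 10, 100)
        )
        for pedestal in ("on", "off"):
            out = ratiometric_signal(tr, pedestal=pedestal)
            assert abs(np.mean(out.dRR0)) < 1e-10


class TestKymographCorrection:
    def test_exact_multiple_fully_cancelled(self):
        kymo = Kymograph(G=3.0 * np.ones((2, 10)), R=np.ones((2, 10)))
        out = motion_correct_kymograph(kymo)
        np.testing.assert_allclose(out.alpha, 3.0)
        np.testing.assert_allclose(out.F_corr, 0.0, atol=1e-12)

    def test_hand_least_squares_example(self):
        out = motion_correct_kymograph(Kymograph(G=[[1, 2, 3]], R=[[1, 1, 1]]))
        np.testing.assert_allclose(out.alpha, [2.0])
        np.testing.assert_allclose(out.F_corr, [[-1.0, 0.0, 1.0]])

    def test_matches_grid_search_oracle(self, rng):
        g = rng.normal(0, 2, (6, 40))
        r = rng.normal(1, 0.5, (6, 40))
        out = motion_correct_kymograph(Kymograph(G=g, R=r))
        for loc in range(6):
            assert abs(out.alpha[loc] - grid_minimize_alpha(g[loc], r[loc])) < 1e-6

    def test_zero_reference_location_named(self):
        with pytest.raises(InputError, match="1"):
            motion_correct_kymograph(Kymograph(G=np.ones((2, 5)), R=[[1] * 5, [0] * 5]))


class TestStimulusStats:
    def make_traces(self, rng, n_traces=4, response=0.0, fs=20.0, dur=200.0):
        onsets = 30.0 + 31.0 * np.arange(5)
        t = np.arange(int(dur * fs)) / fs
        traces = []
        for _ in range(n_traces):
            y = rng.normal(0, 0.05, len(t))
            for o in onsets:
                y[(t >= o) & (t < o + 1.0)] += response
            traces.append(y)
        return traces, t, StimulusProtocol(onsets=onsets)

    def test_step_response_detected(self, rng):
        traces, t, proto = self.make_traces(rng, response=0.5)
        aligned, pre, post, t_stat, p = align_and_test(traces, proto, time=t)
        assert p < 0.01 and t_stat > 0
        assert aligned["matrix"].shape[0] == 20  # 4 traces x 5 repeats

    def test_zero_variance_returns_p_one(self):
        t = np.arange(0, 100, 0.05)
        y = np.zeros_like(t)
        proto = StimulusProtocol(onsets=[30.0, 61.0])
        with pytest.warns(UserWarning):
            _, _, _, t_stat, p = align_and_test([y, y], proto, time=t)
        assert t_stat == 0.0 and p == 1.0

    def test_window_outside_trace_excluded_with_warning(self, rng):
        t = np.arange(0, 40, 0.05)
        y = rng.normal(0, 1, len(t))
        proto = StimulusProtocol(onsets=[12.0, 35.0, 39.0])  # last two lack full windows
        with pytest.warns(UserWarning, match="excluded"):
            align_and_test([y, y], proto, time=t)


class TestReversalSplit:
    def test_no_reversals_all_forward(self):
        rev, fwd = split_by_reversal([10.0, 50.0, 90.0], [])
        assert len(rev) == 0 and list(fwd) == [0, 1, 2]

    def test_reversal_within_window_goes_to_reversal_group(self):
        rev, fwd = split_by_reversal([10.0], [(11.0, 11.5)], window=2.0)
        assert list(rev) == [0]

    def test_reversal_outside_window_stays_forward(self):
        rev, fwd = split_by_reversal([10.0], [(13.5, 14.0)], window=2.0)
        assert list(fwd) == [0]


class TestMixedModel:
    def test_parameter_recovery_within_two_se(self, rng):
        n_animals, n_obs, effect = 12, 8, 0.8
        ids = np.repeat(np.arange(n_animals), n_obs)
        intercepts = rng.normal(0, 0.5, n_animals)
        flag = rng.integers(0, 2, n_animals * n_obs)
        y = intercepts[ids] + effect * flag + rng.normal(0, 0.3, len(ids))
        coef, z, p = mixed_effect_test(y, flag, ids)
        se = effect / z * coef / effect  # |coef/z| = SE
        assert abs(coef - effect) < 2 * abs(coef / z)

    def test_single_animal_rejected(self):
        with pytest.raises(ModelError):
            mixed_effect_test(np.ones(10), np.arange(10) % 2, np.zeros(10))

    def test_single_flag_level_rejected(self):
        with pytest.raises(ModelError):
            mixed_effect_test(np.ones(10), np.zeros(10), np.arange(10) % 2)


class TestPumpEvents:
    def test_flat_trace_no_events(self):
        times, rate = detect_pump_events(np.zeros(300), 30.0, min_prominence=0.1)
        assert len(times) == 0 and rate == 0.0

    def test_four_hertz_train_recovered(self):
        fs, dur = 30.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        y = np.zeros_like(t)
        for pk in np.arange(0.5, dur, 0.25):
            y += np.exp(-((t - pk) ** 2) / (2 * 0.03**2))
        _, rate = detect_pump_events(y, fs, min_prominence=0.3)
        assert abs(rate - 4.0) < 0.1

    def test_close_peaks_merge_to_larger(self):
        t = np.arange(300) / 30.0
        y = np.exp(-((t - 5.0) ** 2) / (2 * 0.05**2)) + 0.6 * np.exp(
            -((t - 5.15) ** 2) / (2 * 0.05**2)
        )
        times, _ = detect_pump_events(y, 30.0, min_prominence=0.1, min_separation=0.5)
        assert len(times) == 1 and abs(times[0] - 5.0) < 0.1


class TestBleaching:
    def test_constant_trace(self):
        red, tau = bleaching_summary(np.full(200, 5.0))
        assert red == 0.0 and np.isinf(tau)

    def test_exponential_recovery_within_two_percent(self):
        t = np.arange(3600.0)
        tau0 = 7200.0
        red, tau = bleaching_summary(100 * np.exp(-t / tau0), t)
        assert abs(tau - tau0) / tau0 < 0.02
        # reduction per its own 5%-window definition: window centers 90 s / 3510 s
        expected = 1.0 - np.exp(-3420.0 / tau0)
        assert abs(red - expected) < 1e-6

    def test_nonpositive_start_rejected(self):
        with pytest.raises(InputError):
            bleaching_summary(np.zeros(100))
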