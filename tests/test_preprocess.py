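import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sp_signal

from emgsynergy.errors import (
    DegenerateChannelError,
    DegenerateSegmentError,
    SamplingRateError,
)
from emgsynergy.preprocess import (
    attach_envelopes,
    filter_and_rectify,
    moving_rms,
    normalize_and_envelope,
    resample_segment,
    segment_motion,
)
from emgsynergy.synthetic_data import GAIT_CYCLE_S, SynthSpec, generate_recording


class TestFilterAndRectify:
    def test_zero_input_gives_zero_output(self):
        out = filter_and_rectify(np.zeros(2000), 1000.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_output_nonnegative_and_length_preserved(self, rng):
        x = rng.standard_normal(5000)
        out = filter_and_rectify(x, 1000.0)
        assert out.shape == x.shape
        assert np.all(out >= 0)

    def test_low_frequency_attenuated(self):
        """A 5 Hz sinusoid sits far below the 20 Hz corner; its output RMS
        must not exceed the attenuation the filter's own frequency response
        predicts (squared: the filter runs forward and backward)."""
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 5 * t)
        out = filter_and_rectify(x, fs)
        sos = sp_signal.butter(4, [20, 450], btype="bandpass", fs=fs, output="sos")
        _, resp = sp_signal.sosfreqz(sos, worN=[5.0], fs=fs)
        gain = np.abs(resp[0]) ** 2  # zero-phase = twice through the filter
        assert gain < 0.001  # the response itself predicts heavy attenuation
        rms_in = np.sqrt(np.mean(x**2))
        rms_out = np.sqrt(np.mean(out**2))
        assert rms_out < 0.05 * rms_in

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(SamplingRateError):
            filter_and_rectify(np.zeros(100), 900.0)


class TestEnvelope:
    def test_constant_channel_normalizes_to_one(self):
        rect = np.full((1, 500), 3.7)
        env = normalize_and_envelope(rect, 1000.0, session_max=np.array([3.7]))
        np.testing.assert_allclose(env.values, 1.0, atol=1e-9)

    def test_window_spans_100_samples_at_1khz(self):
        """A unit impulse smoothed by the 100 ms RMS window leaves the
        closed-form value sqrt(1/L) wherever the full window covers it."""
        rect = np.zeros((1, 401))
        rect[0, 200] = 1.0
        env = normalize_and_envelope(rect, 1000.0, session_max=np.array([1.0]))
        covered = env.values[0] > 0
        assert covered.sum() == 100
        np.testing.assert_allclose(
            env.values[0, covered], np.sqrt(1 / 100), atol=1e-12
        )

    def test_zero_session_max_names_channel(self):
        with pytest.raises(DegenerateChannelError, match="1"):
            normalize_and_envelope(
                np.ones((2, 100)), 1000.0, session_max=np.array([1.0, 0.0])
            )

    @given(st.integers(min_value=1, max_value=30))
    @settings(max_examples=20, deadline=None)
    def test_moving_rms_of_constant_is_constant(self, window):
        x = np.full(50, 2.5)
        np.testing.assert_allclose(moving_rms(x, window), 2.5, atol=1e-12)

    def test_envelope_range_is_unit_interval(self, rng):
        rect = np.abs(rng.standard_normal((4, 2000)))
        env = normalize_and_envelope(rect, 1000.0)
        assert np.all(env.values >= 0)
        assert np.all(env.values <= 1 + 1e-12)


class TestResampleSegment:
    def test_same_length_is_identity(self, rng):
        x = rng.random((4, 100))
        np.testing.assert_allclose(resample_segment(x, 100), x, atol=1e-12)

    def test_constant_matrix_unchanged(self):
        x = np.full((3, 57), 0.4)
        np.testing.assert_allclose(resample_segment(x, 100), 0.4, atol=1e-12)

    def test_linear_ramp_stays_linear(self):
        ramp = np.linspace(0, 1, 50)[None, :]
        out = resample_segment(ramp, 100)
        np.testing.assert_allclose(out[0], np.linspace(0, 1, 100), atol=1e-9)

    def test_too_short_segment_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            resample_segment(np.ones((4, 1)), 100)


def _speed_scan_oracle(angle, fs, frac=0.10):
    """Brute-force single-bell boundary scan: smooth, differentiate, then
    walk the speed trace sample by sample."""
    window = 100
    csum = np.concatenate([[0.0], np.cumsum(angle)])
    n = angle.size
    idx = np.arange(n)
    lo = np.maximum(idx - (window - 1) // 2, 0)
    hi = np.minimum(idx + window // 2 + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    speed = np.abs(np.gradient(smoothed) * fs)
    peak = int(np.argmax(smoothed))
    thr_init = frac * speed[:peak].max()
    start = next(i for i in range(peak) if speed[i] >= thr_init)
    term_peak = peak + int(np.argmax(speed[peak:]))
    thr_term = frac * speed[peak:].max()
    end = next(i for i in range(term_peak, n) if speed[i] < thr_term)
    return start, end


class TestSegmentMotion:
    def test_flat_trace_yields_no_segments(self):
        assert segment_motion(np.zeros(5000), 1000.0, "STD") == []

    def test_short_trace_yields_no_segments(self):
        assert segment_motion(np.ones(500), 1000.0, "STD") == []

    def test_single_bell_matches_threshold_scan_oracle(self):
        fs = 1000.0
        t = np.linspace(0, 1, int(8 * fs))
        angle = np.zeros(int(8 * fs))
        bell = 60 * 0.5 * (1 - np.cos(2 * np.pi * np.linspace(0, 1, 6000)))
        angle[1000:7000] = bell
        segs = segment_motion(angle, fs, "STD")
        assert len(segs) == 1
        start, end = _speed_scan_oracle(angle, fs)
        assert segs[0].start == start
        assert segs[0].end == end

    def test_gait_cycle_count_and_one_maximum_per_segment(self):
        fs = 1000.0
        n_cycles = 8
        # pad by a third of a cycle so all 8 boundary minima (and the
        # maxima preceding them) lie strictly inside the trace
        t = np.arange(int((n_cycles + 0.66) * GAIT_CYCLE_S * fs)) / fs
        t -= 0.33 * GAIT_CYCLE_S
        angle = 30 - 25 * np.cos(2 * np.pi * t / GAIT_CYCLE_S)
        segs = segment_motion(angle, fs, "Gait")
        assert len(segs) in (7, 8)
        from scipy.signal import find_peaks

        for seg in segs:
            chunk = angle[seg.start : seg.end]
            peaks, _ = find_peaks(chunk, prominence=10)
            assert len(peaks) == 1

    def test_planted_bells_recovered_within_tolerance(self):
        spec = SynthSpec(n_subjects=1, reps=3, seed=11)
        rec, truth = generate_recording(spec, "CG01", "CG", "ST")
        segs = segment_motion(rec.angle, rec.fs, "ST")
        assert len(segs) == len(truth["spans"])
        for seg, (s, e) in zip(segs, truth["spans"]):
            assert abs(seg.start - s) < 200  # within 2 smoothing windows
            assert abs(seg.end - e) < 200

    def test_gait_duration_reproduces_planted_cycle(self):
        """Mean detected gait-cycle duration matches the planted 1.32 s
        within one smoothing-window length (0.1 s)."""
        spec = SynthSpec(n_subjects=1, reps=2, seed=13)
        rec, _ = generate_recording(spec, "CG01", "CG", "Gait")
        segs = segment_motion(rec.angle, rec.fs, "Gait")
        assert len(segs) >= 3
        durations = [(s.end - s.start) / rec.fs for s in segs]
        assert abs(np.mean(durations) - GAIT_CYCLE_S) < 0.1


def test_attach_envelopes_resamples_every_segment(rng):
    from emgsynergy.preprocess import EnvelopeMatrix, MotionSegment

    env = EnvelopeMatrix(values=rng.random((4, 3000)), fs_effective=1000.0)
    segs = [MotionSegment(0, 1500, "STD"), MotionSegment(1500, 3000, "STD")]
    attach_envelopes(segs, env)
    for s in segs:
        assert s.envelope_resampled.shape == (4, 100)
        assert np.all(s.envelope_resampled >= 0)
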