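"""Band-pass filtering, RMS measures, recruitment curves, normalization."""

import numpy as np
import pytest

from cordmotor.emg import (
    AttemptWindow,
    EMGSession,
    RecruitmentCurve,
    attempt_delta_rms,
    bandpass_filter,
    evoked_peak_peak,
    normalize_activation,
    recruitment_curve,
    rms_amplitude,
)
from cordmotor.synthetic import EMGSpec, make_emg_session

FS = 2000.0


class TestBandpass:
    def test_dc_rejected(self):
        x = np.full(4000, 3.7)
        y = bandpass_filter(x, FS)
        trim = y[500:-500]
        assert np.max(np.abs(trim)) < 1e-3 * 3.7

    def test_passband_sine_preserved(self):
        t = np.arange(8000) / FS
        y = bandpass_filter(np.sin(2 * np.pi * 100 * t), FS)
        amp = np.max(np.abs(y[1000:-1000]))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_sine_attenuated(self):
        t = np.arange(8000) / FS
        y = bandpass_filter(np.sin(2 * np.pi * 5 * t), FS)
        assert np.max(np.abs(y[1000:-1000])) < 0.1

    def test_high_edge_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            bandpass_filter(np.random.default_rng(0).normal(size=1000), FS, high=1000.0)

    def test_nonfinite_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            bandpass_filter(x, FS)


class TestRMS:
    def test_constant(self):
        assert rms_amplitude(np.full(50, -2.0)) == pytest.approx(2.0)

    def test_hand_value(self):
        assert rms_amplitude(np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))

    def test_sine_whole_periods(self):
        t = np.arange(2000) / FS  # 1 s = 100 periods of 100 Hz
        assert rms_amplitude(0.7 * np.sin(2 * np.pi * 100 * t)) == pytest.approx(
            0.7 / np.sqrt(2), rel=1e-6
        )

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            rms_amplitude(np.ones(100), window=(0.01, 0.01), fs=FS)


def _session(signal, attempts=None, stims=None):
    return EMGSession(
        signals=signal[None, :],
        fs=FS,
        channel_names=["m"],
        stim_events=stims or [],
        attempt_windows=attempts or [],
    )


class TestDeltaRMS:
    def test_difference_of_windows(self):
        n = int(3 * FS)
        x = np.zeros(n)
        t = np.arange(n) / FS
        burst = (t >= 1.0) & (t < 2.0)
        x[burst] = 0.3 * np.sin(2 * np.pi * 100 * t[burst])
        w = AttemptWindow(1.0, 2.0, background=(0.0, 1.0))
        d = attempt_delta_rms(_session(x, [w]), "m", w, filtered=False)
        assert d == pytest.approx(0.3 / np.sqrt(2), rel=1e-6)

    def test_stationary_noise_near_zero(self, rng):
        x = rng.normal(0, 0.1, int(4 * FS))
        w = AttemptWindow(2.0, 4.0, background=(0.0, 2.0))
        d = attempt_delta_rms(_session(x, [w]), "m", w, filtered=False)
        assert abs(d) < 0.01

    def test_suppression_is_negative(self):
        """An attempt quieter than background gives a negative delta-RMS."""
        n = int(3 * FS)
        t = np.arange(n) / FS
        x = 0.2 * np.sin(2 * np.pi * 100 * t)
        x[t >= 1.0] *= 0.25
        w = AttemptWindow(1.0, 2.0, background=(0.0, 1.0))
        d = attempt_delta_rms(_session(x, [w]), "m", w, filtered=False)
        assert d == pytest.approx((0.05 - 0.2) / np.sqrt(2), rel=1e-5)

    def test_overlapping_background_rejected(self):
        with pytest.raises(ValueError):
            AttemptWindow(1.0, 2.0, background=(0.5, 1.5))


class TestEvokedP2P:
    def test_biphasic_pulse_amplitude(self):
        x = np.zeros(int(FS))
        i0 = int(0.110 * FS)
        x[i0] = 0.6
        x[i0 + 5] = -0.4
        s = _session(x, stims=[(0.1, 1.0)])
        assert evoked_peak_peak(s, "m", 0.1) == pytest.approx(1.0)

    def test_flat_signal_zero(self):
        s = _session(np.zeros(int(FS)), stims=[(0.1, 1.0)])
        assert evoked_peak_peak(s, "m", 0.1) == 0.0

    def test_sloped_baseline_brute_force(self):
        x = np.linspace(0, 1, int(FS))
        i0 = int(0.120 * FS)
        x[i0] += 0.5
        s = _session(x, stims=[(0.1, 1.0)])
        lo, hi = int(round(0.105 * FS)), int(round(0.195 * FS))
        expected = max(x[lo:hi]) - min(x[lo:hi])
        assert evoked_peak_peak(s, "m", 0.1) == pytest.approx(expected)

    def test_window_into_next_stimulus_rejected(self):
        s = _session(np.zeros(int(FS)), stims=[(0.1, 1.0), (0.2, 1.0)])
        with pytest.raises(ValueError, match="next stimulus"):
            evoked_peak_peak(s, "m", 0.1, response_window=(0.005, 0.15))


class TestRecruitmentCurve:
    def test_noiseless_sigmoid_recovered(self):
        spec = EMGSpec(background_sd=0.0, burst_amplitude=0.0, seed=0)
        session, truth = make_emg_session(spec)
        curve = recruitment_curve(session, "TA")
        for intensity, p2p in curve.points:
            assert p2p == pytest.approx(truth.evoked_p2p[intensity], rel=1e-9)
        assert curve.max_p2p == pytest.approx(truth.max_p2p, rel=1e-9)

    def test_shuffled_stimulus_order_invariant(self, rng):
        spec = EMGSpec(background_sd=0.0, burst_amplitude=0.0, seed=0)
        session, _ = make_emg_session(spec)
        base = recruitment_curve(session, "TA")
        order = rng.permutation(len(session.stim_events))
        shuffled = EMGSession(
            signals=session.signals,
            fs=session.fs,
            channel_names=session.channel_names,
            stim_events=[session.stim_events[i] for i in order],
            attempt_windows=session.attempt_windows,
        )
        assert recruitment_curve(shuffled, "TA").points == base.points

    def test_warns_on_unexpected_stimulus_count(self):
        spec = EMGSpec(background_sd=0.0, burst_amplitude=0.0, stimuli_per_intensity=3, seed=0)
        session, _ = make_emg_session(spec)
        with pytest.warns(UserWarning, match="expected 5"):
            recruitment_curve(session, "TA")

    def test_no_stimuli_errors(self):
        s = _session(np.zeros(int(FS)))
        with pytest.raises(ValueError, match="no stimulation"):
            recruitment_curve(s, "m")


class TestNormalize:
    def _curve(self, max_p2p):
        return RecruitmentCurve("m", ((1.0, max_p2p),), max_p2p)

    def test_simple_ratio(self):
        assert normalize_activation(0.2, self._curve(1.0)) == pytest.approx(0.2)
        assert normalize_activation(0.0, self._curve(1.0)) == 0.0

    def test_zero_max_p2p_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            normalize_activation(0.2, self._curve(0.0))

    def test_overlapping_stim_and_attempt_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            EMGSpec(attempt_window=(2.0, 5.0), stim_start=3.0)
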