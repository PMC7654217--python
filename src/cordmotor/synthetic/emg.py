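"""Synthetic multichannel EMG with known burst and evoked-response truth.

A session emulates the volitional-attempt recordings used with epidural
stimulation: Gaussian background activity, a rectangular-envelope
sine-carrier burst during the attempt window, and a train of biphasic
evoked potentials at 2 Hz whose peak-to-peak amplitude follows a sigmoid
recruitment curve over stimulation intensity (five stimuli per
intensity). All ground truths are closed-form functions of the spec:

* attempt-minus-background RMS per channel:
  ``sqrt(sd^2 + A^2/2) - sd`` for carrier amplitude ``A`` and background
  standard deviation ``sd`` (the burst and noise are independent);
* evoked peak-to-peak per intensity: the sigmoid value, since the
  biphasic pulse's positive and negative lobe amplitudes sum to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from cordmotor.emg import AttemptWindow, EMGSession

__all__ = ["SigmoidRecruitment", "EMGSpec", "EMGGroundTruth", "make_emg_session"]


@dataclass(frozen=True)
class SigmoidRecruitment:
    """Evoked p2p amplitude vs stimulation intensity: logistic recruitment.

    ``p2p(I) = plateau / (1 + exp(-slope * (I - threshold)))`` (mV).
    """

    threshold: float = 3.0
    slope: float = 2.0
    plateau: float = 1.0

    def __post_init__(self) -> None:
        if self.plateau < 0:
            raise ValueError("plateau must be >= 0")

    def __call__(self, intensity: float) -> float:
        return self.plateau / (1.0 + math.exp(-self.slope * (intensity - self.threshold)))


@dataclass
class EMGSpec:
    """Parameters of a synthetic EMG session (times in s, amplitudes in mV)."""

    channel_names: tuple[str, ...] = ("TA", "SOL")
    fs: float = 2000.0
    background_sd: float = 0.02
    burst_amplitude: dict[str, float] | float = 0.3
    burst_freq: float = 150.0
    attempt_window: tuple[float, float] = (2.0, 5.0)
    background_duration: float = 1.0
    task: str = "dorsiflexion"
    stim_intensities: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    stimuli_per_intensity: int = 5
    recruitment: SigmoidRecruitment = field(default_factory=SigmoidRecruitment)
    stim_rate: float = 2.0
    stim_start: float = 7.0
    pulse_pos_width: float = 0.004
    pulse_neg_width: float = 0.006
    pulse_pos_frac: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 2000.0 - 1e-9:
            raise ValueError("fs must exceed twice the 1,000 Hz band-pass edge")
        if self.stimuli_per_intensity < 1:
            raise ValueError("stimuli_per_intensity must be >= 1")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        a0, a1 = self.attempt_window
        if not (a0 < a1) or a0 - self.background_duration < 0:
            raise ValueError("attempt window invalid or background window before t=0")
        n_stim = len(self.stim_intensities) * self.stimuli_per_intensity
        stim_end = self.stim_start + (n_stim - 1) / self.stim_rate + 0.1
        if self.stim_start < a1 and stim_end > a0 - self.background_duration:
            raise ValueError(
                "stimulation train overlaps the attempt/background windows; "
                "volitional attempts and recruitment assessment are separate epochs"
            )
        self._stim_end = stim_end

    def amplitude(self, channel: str) -> float:
        if isinstance(self.burst_amplitude, dict):
            return float(self.burst_amplitude.get(channel, 0.0))
        return float(self.burst_amplitude)

    @property
    def duration(self) -> float:
        return max(self._stim_end, self.attempt_window[1]) + 0.5


@dataclass(frozen=True)
class EMGGroundTruth:
    """Closed-form targets the processing chain should recover."""

    delta_rms: dict[str, float]
    evoked_p2p: dict[float, float]
    max_p2p: float


def _biphasic_pulse(spec: EMGSpec, p2p: float, fs: float) -> np.ndarray:
    """Positive half-sine lobe then negative half-sine lobe; p2p = lobe sum."""
    # even lobe lengths put one sample exactly on each half-sine peak, so
    # the noiseless p2p equals the lobe-amplitude sum exactly
    n_pos = max(2 * int(round(spec.pulse_pos_width * fs / 2)), 2)
    n_neg = max(2 * int(round(spec.pulse_neg_width * fs / 2)), 2)
    a_pos = spec.pulse_pos_frac * p2p
    a_neg = (1.0 - spec.pulse_pos_frac) * p2p
    pos = a_pos * np.sin(np.pi * np.arange(n_pos) / n_pos)
    neg = -a_neg * np.sin(np.pi * np.arange(n_neg) / n_neg)
    return np.concatenate([pos, neg])


def make_emg_session(spec: EMGSpec) -> tuple[EMGSession, EMGGroundTruth]:
    """Generate a session and its analytic ground truth.

    Per-channel noise uses sub-streams derived deterministically from the
    spec seed and the channel index, so adding a channel never perturbs
    the others.
    """
    fs = spec.fs
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    a0, a1 = spec.attempt_window

    # stimulation events: all stimuli at one intensity, then the next
    stim_events: list[tuple[float, float]] = []
    k = 0
    for intensity in spec.stim_intensities:
        for _ in range(spec.stimuli_per_intensity):
            stim_events.append((spec.stim_start + k / spec.stim_rate, float(intensity)))
            k += 1

    signals = np.zeros((len(spec.channel_names), n))
    in_attempt = (t >= a0) & (t < a1)
    for ci, ch in enumerate(spec.channel_names):
        rng = np.random.default_rng([spec.seed, ci])
        x = rng.normal(0.0, spec.background_sd, size=n) if spec.background_sd > 0 else np.zeros(n)
        amp = spec.amplitude(ch)
        if amp != 0.0:
            x[in_attempt] += amp * np.sin(2 * np.pi * spec.burst_freq * t[in_attempt])
        for stim_time, intensity in stim_events:
            pulse = _biphasic_pulse(spec, spec.recruitment(intensity), fs)
            i0 = int(round((stim_time + 0.010) * fs))  # 10 ms response latency
            i1 = min(i0 + pulse.size, n)
            x[i0:i1] += pulse[: i1 - i0]
        signals[ci] = x

    attempt = AttemptWindow(
        start=a0,
        end=a1,
        task=spec.task,
        background=(a0 - spec.background_duration, a0),
    )
    session = EMGSession(
        signals=signals,
        fs=fs,
        channel_names=list(spec.channel_names),
        stim_events=stim_events,
        attempt_windows=[attempt],
    )

    sd = spec.background_sd
    delta_rms = {
        ch: math.sqrt(sd * sd + spec.amplitude(ch) ** 2 / 2.0) - sd
        for ch in spec.channel_names
    }
    evoked = {float(i): spec.recruitment(i) for i in spec.stim_intensities}
    truth = EMGGroundTruth(
        delta_rms=delta_rms,
        evoked_p2p=evoked,
        max_p2p=max(evoked.values()) if evoked else 0.0,
    )
    return session, truth
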