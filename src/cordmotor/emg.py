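"""EMG processing: band-pass filtering, delta-RMS, recruitment curves.

The volitional-activation measure is computed in three steps: the raw
signal is band-pass filtered (30-1,000 Hz), the resting background RMS
recorded just before each attempt is subtracted from the attempt-window
RMS (the difference may be negative: volitional suppression of a muscle
is a real outcome), and the result is normalized by the largest evoked
potential peak-to-peak amplitude seen for that muscle on its
recruitment curve (mean p2p over the stimuli delivered at each
stimulation intensity, maximum across intensities).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "AttemptWindow",
    "EMGSession",
    "RecruitmentCurve",
    "NormalizedActivation",
    "bandpass_filter",
    "rms_amplitude",
    "attempt_delta_rms",
    "evoked_peak_peak",
    "recruitment_curve",
    "normalize_activation",
    "session_activation_table",
]

logger = logging.getLogger(__name__)

#: channels whose recruitment maximum falls below this (mV) cannot be
#: normalized and are excluded (never silently zeroed)
DEFAULT_P2P_FLOOR = 1e-6


@dataclass(frozen=True)
class AttemptWindow:
    """A volitional attempt epoch with its resting background epoch (s)."""

    start: float
    end: float
    task: str = ""
    background: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("attempt window must have start < end")
        if self.background is not None:
            b0, b1 = self.background
            if not b0 < b1:
                raise ValueError("background window must have start < end")
            if b1 > self.start:
                raise ValueError("background window must precede the attempt")


@dataclass
class EMGSession:
    """Multichannel EMG with stimulation events and attempt annotations.

    signals : channels x samples, mV. stim_events : (time s, intensity)
    pairs. attempt_windows : annotated volitional attempts.
    """

    signals: np.ndarray
    fs: float
    channel_names: list[str]
    stim_events: list[tuple[float, float]] = field(default_factory=list)
    attempt_windows: list[AttemptWindow] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError("signals rows must match channel_names")
        dur = self.signals.shape[1] / self.fs
        for w in self.attempt_windows:
            lo = w.background[0] if w.background else w.start
            if lo < 0 or w.end > dur + 1e-9:
                raise ValueError(f"attempt window {w} outside the record")
        for t, intensity in self.stim_events:
            if intensity < 0:
                raise ValueError("stimulation intensities must be nonnegative")
            if not 0 <= t <= dur:
                raise ValueError(f"stimulus at {t} s outside the record")

    @property
    def duration(self) -> float:
        return self.signals.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.signals[self.channel_names.index(name)]


@dataclass(frozen=True)
class RecruitmentCurve:
    """Mean evoked p2p per stimulation intensity for one channel."""

    channel: str
    points: tuple[tuple[float, float], ...]  # (intensity, mean p2p mV)
    max_p2p: float

    def __post_init__(self) -> None:
        if any(p2p < 0 for _, p2p in self.points):
            raise ValueError("mean p2p must be >= 0")


@dataclass(frozen=True)
class NormalizedActivation:
    """Delta-RMS (mV) and its recruitment-normalized value for one attempt."""

    channel: str
    task: str
    delta_rms: float
    normalized: float


def bandpass_filter(
    x: np.ndarray, fs: float, low: float = 30.0, high: float = 1000.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 30-1,000 Hz).

    Applied forward-backward (``sosfiltfilt``), so the passband gain is
    ~1 with no phase distortion. A high edge at or above Nyquist is
    clipped just below it with a warning.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    nyq = fs / 2.0
    if high >= nyq:
        clipped = 0.99 * nyq
        warnings.warn(
            f"band-pass high edge {high} Hz >= Nyquist {nyq} Hz; clipping to {clipped:.1f} Hz",
            stacklevel=2,
        )
        high = clipped
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _window_slice(fs: float, window: tuple[float, float], n: int) -> slice:
    t0, t1 = window
    i0 = int(round(t0 * fs))
    i1 = int(round(t1 * fs))
    i0, i1 = max(i0, 0), min(i1, n)
    if i1 <= i0:
        raise ValueError(f"window {window} is empty at fs={fs}")
    return slice(i0, i1)


def rms_amplitude(x: np.ndarray, window: tuple[float, float] | None = None, fs: float | None = None) -> float:
    """Root-mean-square amplitude, optionally over a time window (s)."""
    x = np.asarray(x, dtype=float)
    if window is not None:
        if fs is None:
            raise ValueError("fs required when a time window is given")
        x = x[_window_slice(fs, window, x.size)]
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x * x)))


def attempt_delta_rms(
    session: EMGSession,
    channel: str,
    attempt: AttemptWindow,
    filtered: bool = True,
    background_duration: float = 1.0,
) -> float:
    """Attempt-window RMS minus resting background RMS (mV; may be negative).

    If the attempt carries no explicit background window, a
    ``background_duration``-second epoch immediately preceding the
    attempt is used.
    """
    bg = attempt.background or (attempt.start - background_duration, attempt.start)
    if bg[1] > attempt.start + 1e-12:
        raise ValueError("background window overlaps the attempt")
    x = session.channel(channel)
    if filtered:
        x = bandpass_filter(x, session.fs)
    rms_attempt = rms_amplitude(x, (attempt.start, attempt.end), session.fs)
    rms_bg = rms_amplitude(x, bg, session.fs)
    return rms_attempt - rms_bg


def evoked_peak_peak(
    session: EMGSession,
    channel: str,
    stim_time: float,
    response_window: tuple[float, float] = (0.005, 0.095),
    filtered: bool = False,
) -> float:
    """Max minus min of the signal in a post-stimulus response window.

    The window (s, relative to the stimulus) must close before the next
    stimulus arrives (2 Hz stimulation leaves < 500 ms).
    """
    r0, r1 = response_window
    if not 0 <= r0 < r1:
        raise ValueError("response window must satisfy 0 <= start < end")
    later = [t for t, _ in session.stim_events if t > stim_time + 1e-9]
    if later and stim_time + r1 > min(later) + 1e-9:
        raise ValueError("response window reaches into the next stimulus")
    x = session.channel(channel)
    if filtered:
        x = bandpass_filter(x, session.fs)
    seg = x[_window_slice(session.fs, (stim_time + r0, stim_time + r1), x.size)]
    return float(seg.max() - seg.min())


def recruitment_curve(
    session: EMGSession,
    channel: str,
    response_window: tuple[float, float] = (0.005, 0.095),
    expected_stimuli: int = 5,
    filtered: bool = False,
) -> RecruitmentCurve:
    """Group stimuli by intensity and average the evoked p2p per group.

    The curve's ``max_p2p`` (the largest mean p2p across intensities) is
    the normalization constant for volitional activation. Warns when a
    group does not hold the expected number of stimuli (five in the
    standard protocol).
    """
    if not session.stim_events:
        raise ValueError("session has no stimulation events")
    groups: dict[float, list[float]] = {}
    for stim_time, intensity in session.stim_events:
        groups.setdefault(float(intensity), []).append(
            evoked_peak_peak(session, channel, stim_time, response_window, filtered)
        )
    points = []
    for intensity in sorted(groups):
        vals = groups[intensity]
        if len(vals) != expected_stimuli:
            warnings.warn(
                f"intensity {intensity}: {len(vals)} stimuli (expected {expected_stimuli})",
                stacklevel=2,
            )
        points.append((intensity, float(np.mean(vals))))
    return RecruitmentCurve(
        channel=channel,
        points=tuple(points),
        max_p2p=float(max(p2p for _, p2p in points)),
    )


def normalize_activation(
    delta_rms: float, curve: RecruitmentCurve, floor: float = DEFAULT_P2P_FLOOR
) -> float:
    """Delta-RMS divided by the channel's largest mean evoked p2p.

    Channels whose recruitment maximum is at or below ``floor`` cannot be
    normalized; they raise (callers exclude and log them rather than
    reporting a silent zero).
    """
    if curve.max_p2p <= floor:
        raise ValueError(
            f"channel {curve.channel!r}: max evoked p2p {curve.max_p2p:g} mV at or "
            f"below floor {floor:g}; normalization undefined"
        )
    return delta_rms / curve.max_p2p


def session_activation_table(
    session: EMGSession,
    response_window: tuple[float, float] = (0.005, 0.095),
    floor: float = DEFAULT_P2P_FLOOR,
) -> pd.DataFrame:
    """Normalized activation per (channel, attempt); excluded channels logged.

    Columns: subject, task, channel, delta_rms, max_p2p, normalized.
    """
    rows = []
    for ch in session.channel_names:
        try:
            curve = recruitment_curve(session, ch, response_window)
        except ValueError:
            logger.warning("channel %s: no recruitment curve; excluded", ch)
            continue
        for attempt in session.attempt_windows:
            d = attempt_delta_rms(session, ch, attempt)
            try:
                norm = normalize_activation(d, curve, floor)
            except ValueError as exc:
                logger.warning("channel %s excluded: %s", ch, exc)
                continue
            rows.append(
                {
                    "subject": session.subject_id,
                    "task": attempt.task,
                    "channel": ch,
                    "delta_rms": d,
                    "max_p2p": curve.max_p2p,
                    "normalized": norm,
                }
            )
    return pd.DataFrame(rows, columns=["subject", "task", "channel", "delta_rms", "max_p2p", "normalized"])
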