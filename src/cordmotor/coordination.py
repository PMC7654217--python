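"""Joint-probability-density (JPD) co-contraction quadrant statistic.

For an agonist/antagonist muscle pair (iliopsoas vs medial hamstrings
during lower limb flexion; tibialis anterior vs soleus during ankle
dorsiflexion) each time point of the attempt contributes one point to a
2-D amplitude plot. A threshold at 10% of the largest amplitude detected
during the attempt splits the plane into four rectangular areas:
isolated activation of either muscle, co-contraction at a higher level
of activation (both above threshold), and co-contraction at a lower
level (both below). The percentage of samples falling in each area is
the coordination summary; an attempt with no detected activation in
either muscle degenerates, by convention, to 100% co-contraction at the
low level of activation.

Thresholds are per-muscle (10% of that muscle's own attempt maximum),
which yields the axis-aligned rectangular regions of the density plot; a
single joint maximum for both axes is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "EnvelopePair",
    "JPDSummary",
    "activation_envelope",
    "jpd_quadrants",
    "jpd_panel",
]

#: attempt maxima at or below this (normalized units) count as "no
#: activation detected" for the degenerate rule
DEFAULT_ACTIVITY_FLOOR = 1e-9


def activation_envelope(x: np.ndarray, fs: float, window_ms: float = 50.0) -> np.ndarray:
    """Moving-RMS amplitude envelope of a (filtered) EMG signal.

    The mean of the squared signal over a sliding window (default 50 ms)
    is square-rooted; output is nonnegative, on the input sampling grid.
    """
    x = np.asarray(x, dtype=float)
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    n = max(int(round(window_ms * fs / 1000.0)), 1)
    if n > x.size:
        raise ValueError(f"envelope window ({n} samples) longer than signal ({x.size})")
    power = ndimage.uniform_filter1d(x * x, size=n, mode="nearest")
    return np.sqrt(np.maximum(power, 0.0))


@dataclass
class EnvelopePair:
    """Time-aligned amplitude series for two muscles during one attempt."""

    a: np.ndarray
    b: np.ndarray
    muscle_a: str = "A"
    muscle_b: str = "B"
    attempt: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("envelopes must be 1-D and of equal length")
        if self.a.size == 0:
            raise ValueError("envelope pair is empty")
        if np.any(self.a < 0) or np.any(self.b < 0):
            raise ValueError("amplitude envelopes must be nonnegative")


@dataclass(frozen=True)
class JPDSummary:
    """Four quadrant percentages (sum to 100) plus the thresholds used."""

    pct_isolated_a: float
    pct_isolated_b: float
    pct_coco_high: float
    pct_coco_low: float
    threshold_a: float
    threshold_b: float

    def __post_init__(self) -> None:
        pcts = (
            self.pct_isolated_a,
            self.pct_isolated_b,
            self.pct_coco_high,
            self.pct_coco_low,
        )
        if any(not (-1e-9 <= p <= 100 + 1e-9) for p in pcts):
            raise ValueError("quadrant percentages must lie in [0, 100]")
        if abs(sum(pcts) - 100.0) > 1e-9:
            raise ValueError(f"quadrant percentages sum to {sum(pcts)}, not 100")

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_isolated_a": self.pct_isolated_a,
            "pct_isolated_b": self.pct_isolated_b,
            "pct_coco_high": self.pct_coco_high,
            "pct_coco_low": self.pct_coco_low,
        }


def jpd_quadrants(
    pair: EnvelopePair,
    threshold_frac: float = 0.10,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
    joint_threshold: bool = False,
) -> JPDSummary:
    """Classify each sample into one of the four JPD areas.

    The threshold for each muscle is ``threshold_frac`` (default 10%) of
    its largest amplitude during the attempt; a sample is "active" for a
    muscle iff its amplitude is strictly above that muscle's threshold.
    With ``joint_threshold=True`` a single threshold from the larger of
    the two maxima is used for both axes.

    Degenerate rule: when no activation is detected for either muscle
    (both attempt maxima at or below ``activity_floor``), the attempt is
    100% co-contraction at the low level of activation.
    """
    max_a = float(pair.a.max())
    max_b = float(pair.b.max())
    if max_a <= activity_floor and max_b <= activity_floor:
        return JPDSummary(0.0, 0.0, 0.0, 100.0, 0.0, 0.0)
    if joint_threshold:
        thr_a = thr_b = threshold_frac * max(max_a, max_b)
    else:
        thr_a = threshold_frac * max_a
        thr_b = threshold_frac * max_b
    active_a = pair.a > thr_a
    active_b = pair.b > thr_b
    n = pair.a.size
    pct = lambda m: 100.0 * float(np.count_nonzero(m)) / n
    iso_a = pct(active_a & ~active_b)
    iso_b = pct(active_b & ~active_a)
    high = pct(active_a & active_b)
    low = 100.0 - iso_a - iso_b - high
    return JPDSummary(iso_a, iso_b, high, low, thr_a, thr_b)


def jpd_panel(pair: EnvelopePair, summary: JPDSummary, path) -> None:
    """Density plot of the pair with threshold lines and quadrant percentages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lim_a = max(pair.a.max(), summary.threshold_a) * 1.05 or 1.0
    lim_b = max(pair.b.max(), summary.threshold_b) * 1.05 or 1.0
    ax.hist2d(pair.a, pair.b, bins=40, range=[[0, lim_a], [0, lim_b]], cmap="viridis")
    ax.axvline(summary.threshold_a, color="w", lw=0.8, ls="--")
    ax.axhline(summary.threshold_b, color="w", lw=0.8, ls="--")
    labels = {
        f"iso {pair.muscle_a}: {summary.pct_isolated_a:.1f}%": (0.97, 0.03, "right", "bottom"),
        f"iso {pair.muscle_b}: {summary.pct_isolated_b:.1f}%": (0.03, 0.97, "left", "top"),
        f"co-co high: {summary.pct_coco_high:.1f}%": (0.97, 0.97, "right", "top"),
        f"co-co low: {summary.pct_coco_low:.1f}%": (0.03, 0.03, "left", "bottom"),
    }
    for text, (x, y, ha, va) in labels.items():
        ax.text(x, y, text, transform=ax.transAxes, color="w", fontsize=8, ha=ha, va=va)
    ax.set_xlabel(f"{pair.muscle_a} amplitude (norm.)")
    ax.set_ylabel(f"{pair.muscle_b} amplitude (norm.)")
    ax.set_title(pair.attempt or "JPD")
    fig.savefig(path, dpi=100, metadata={"Software": None} if str(path).endswith(".png") else None)
    plt.close(fig)
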