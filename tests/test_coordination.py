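"""Amplitude envelopes and the JPD four-quadrant statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cordmotor.coordination import (
    EnvelopePair,
    activation_envelope,
    jpd_panel,
    jpd_quadrants,
)

FS = 2000.0


def brute_force_quadrants(a, b, frac=0.10):
    """Independent per-sample classifier (plain loops)."""
    thr_a, thr_b = frac * max(a), frac * max(b)
    counts = {"iso_a": 0, "iso_b": 0, "high": 0, "low": 0}
    for x, y in zip(a, b):
        xa, yb = x > thr_a, y > thr_b
        if xa and not yb:
            counts["iso_a"] += 1
        elif yb and not xa:
            counts["iso_b"] += 1
        elif xa and yb:
            counts["high"] += 1
        else:
            counts["low"] += 1
    n = len(a)
    return tuple(100.0 * counts[k] / n for k in ("iso_a", "iso_b", "high", "low"))


class TestEnvelope:
    def test_constant_signal(self):
        env = activation_envelope(np.full(1000, -0.4), FS)
        np.testing.assert_allclose(env, 0.4)

    def test_zero_signal(self):
        assert activation_envelope(np.zeros(500), FS).max() == 0.0

    def test_sine_whole_periods(self):
        t = np.arange(4000) / FS
        env = activation_envelope(np.sin(2 * np.pi * 100 * t), FS, window_ms=50)
        interior = env[200:-200]
        np.testing.assert_allclose(interior, 1 / np.sqrt(2), rtol=1e-3)

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(ValueError, match="longer"):
            activation_envelope(np.zeros(10), FS, window_ms=50)


class TestJPDQuadrants:
    def test_zero_envelopes_are_all_low_cocontraction(self):
        """No detected activation in either muscle -> 100% co-co low."""
        s = jpd_quadrants(EnvelopePair(np.zeros(1000), np.zeros(1000)))
        assert (s.pct_isolated_a, s.pct_isolated_b, s.pct_coco_high, s.pct_coco_low) == (
            0.0,
            0.0,
            0.0,
            100.0,
        )

    def test_hand_enumerated_five_samples(self):
        a = np.array([1.0, 0.5, 0.05, 0.5, 0.05])
        b = np.array([1.0, 0.05, 0.5, 0.5, 0.05])
        s = jpd_quadrants(EnvelopePair(a, b))
        assert s.threshold_a == pytest.approx(0.1)
        assert (s.pct_isolated_a, s.pct_isolated_b, s.pct_coco_high, s.pct_coco_low) == (
            20.0,
            20.0,
            40.0,
            20.0,
        )

    def test_pure_isolated_activation(self):
        a = np.array([1.0, 0.9, 0.8])  # always above its own threshold
        b = np.zeros(3)  # silent muscle, threshold 0, never strictly above
        s = jpd_quadrants(EnvelopePair(a, b))
        assert s.pct_isolated_a == 100.0

    def test_sample_at_threshold_counts_inactive(self):
        a = np.array([1.0, 0.1, 0.1, 0.1])  # threshold exactly 0.1
        b = np.array([1.0, 1.0, 1.0, 1.0])
        s = jpd_quadrants(EnvelopePair(a, b))
        assert s.pct_isolated_b == 75.0 and s.pct_coco_high == 25.0

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 200))
            a = rng.gamma(1.0, 0.2, n)
            b = rng.gamma(1.0, 0.2, n)
            s = jpd_quadrants(EnvelopePair(a, b))
            got = (s.pct_isolated_a, s.pct_isolated_b, s.pct_coco_high, s.pct_coco_low)
            assert got == pytest.approx(brute_force_quadrants(a, b))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.5, 2.0, 1024.0]))
    def test_sum_100_and_scale_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        a = rng.gamma(1.0, 0.2, 50)
        b = rng.gamma(1.0, 0.2, 50)
        s1 = jpd_quadrants(EnvelopePair(a, b))
        total = s1.pct_isolated_a + s1.pct_isolated_b + s1.pct_coco_high + s1.pct_coco_low
        assert total == pytest.approx(100.0, abs=1e-9)
        # power-of-two scales are lossless in binary floating point
        s2 = jpd_quadrants(EnvelopePair(k * a, k * b))
        assert s1.as_dict() == s2.as_dict()

    def test_raising_threshold_never_lowers_coco_low(self, rng):
        for _ in range(10):
            a = rng.gamma(1.0, 0.2, 100)
            b = rng.gamma(1.0, 0.2, 100)
            low = [
                jpd_quadrants(EnvelopePair(a, b), threshold_frac=f).pct_coco_low
                for f in (0.05, 0.10, 0.20, 0.40)
            ]
            assert all(x <= y + 1e-12 for x, y in zip(low, low[1:]))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            EnvelopePair(np.zeros(4), np.zeros(5))

    def test_joint_threshold_flag(self):
        a = np.array([1.0, 0.3])
        b = np.array([0.2, 0.15])
        s = jpd_quadrants(EnvelopePair(a, b), joint_threshold=True)
        assert s.threshold_a == s.threshold_b == pytest.approx(0.1)


class TestJPDPanel:
    def test_panel_written_and_annotates_percentages(self, tmp_path):
        rng = np.random.default_rng(1)
        pair = EnvelopePair(rng.gamma(1, 0.2, 400), rng.gamma(1, 0.2, 400), "IL", "MH")
        summary = jpd_quadrants(pair)
        out = tmp_path / "panel.svg"
        jpd_panel(pair, summary, out)
        text = out.read_text()
        assert f"{summary.pct_coco_low:.1f}%" in text

    def test_zero_pair_panel_annotates_degenerate_rule(self, tmp_path):
        pair = EnvelopePair(np.zeros(100), np.zeros(100))
        summary = jpd_quadrants(pair)
        out = tmp_path / "panel.svg"
        jpd_panel(pair, summary, out)
        assert "co-co low: 100.0%" in out.read_text()

    def test_render_is_reproducible(self, tmp_path):
        rng = np.random.default_rng(7)
        pair = EnvelopePair(rng.gamma(1, 0.2, 300), rng.gamma(1, 0.2, 300))
        summary = jpd_quadrants(pair)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        jpd_panel(pair, summary, p1)
        jpd_panel(pair, summary, p2)
        assert p1.read_bytes() == p2.read_bytes()
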