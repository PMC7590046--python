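"""Extrema detection, swing construction, and the retention filter cascade."""

import numpy as np
import pytest

from armswing.periodicity import analyze_windows
from armswing.pipeline import analyze_arm
from armswing.swing_detect import (
    Extremum,
    Swing,
    build_swings,
    detect_extrema,
    enforce_alternation,
    filter_swings,
)
from armswing.synthetic import SynthConfig, generate

from conftest import FS, make_angle, make_signal


def _extremum(idx, value, kind, fs=FS):
    return Extremum(idx, idx / fs, value, kind, abs(value))


class TestDetectExtrema:
    def test_sinusoid_extrema(self, time_30s):
        """Closed form: alternating +/-10 deg extrema every 0.5 s."""
        angle = make_angle(10 * np.sin(2 * np.pi * 1.0 * time_30s))
        ext = detect_extrema(angle, analyze_windows(angle))
        assert 55 <= len(ext) <= 60
        kinds = [e.kind for e in ext]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        np.testing.assert_allclose([abs(e.value) for e in ext], 10.0, rtol=1e-3)
        gaps = np.diff([e.time for e in ext])
        np.testing.assert_allclose(gaps, 0.5, atol=0.02)

    def test_below_prominence_no_extrema(self, time_30s):
        angle = make_angle(0.9 * np.sin(2 * np.pi * 1.0 * time_30s))
        # sub-degree movement: nothing passes the 2 deg prominence gate
        # (windows computed on a detectable companion so masking is not the cause)
        wins = analyze_windows(make_angle(10 * np.sin(2 * np.pi * 1.0 * time_30s)))
        assert detect_extrema(angle, wins) == []

    def test_extrema_outside_valid_windows_dropped(self, time_30s):
        x = 10 * np.sin(2 * np.pi * 1.0 * time_30s)
        rng = np.random.default_rng(5)
        x[3000:5000] = rng.normal(0, 8, 2000)  # aperiodic stretch
        angle = make_angle(x)
        wins = analyze_windows(angle)
        assert any(not w.valid for w in wins)
        from armswing.periodicity import analyzable_mask

        mask = analyzable_mask(wins, x.size)
        for e in detect_extrema(angle, wins):
            assert mask[e.sample_index]

    def test_output_always_alternates(self):
        rng = np.random.default_rng(17)
        t = np.arange(0.0, 30.0, 1.0 / FS)
        for _ in range(3):
            x = (
                10 * np.sin(2 * np.pi * 1.0 * t + rng.uniform(0, 6))
                + rng.uniform(2, 5) * np.sin(2 * np.pi * rng.uniform(0.4, 0.7) * t)
            )
            angle = make_angle(x)
            ext = detect_extrema(angle, analyze_windows(angle))
            kinds = [e.kind for e in ext]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestEnforceAlternation:
    def test_extra_maximum_discarded(self):
        """Manual trace: of two adjacent maxima the smaller one is dropped."""
        ext = [
            _extremum(100, 10.0, "max"),
            _extremum(220, 3.0, "max"),
            _extremum(300, -9.0, "min"),
        ]
        out = enforce_alternation(ext)
        assert [(e.sample_index, e.kind) for e in out] == [(100, "max"), (300, "min")]

    def test_cascading_duplicates(self):
        ext = [
            _extremum(0, -8.0, "min"),
            _extremum(100, 4.0, "max"),
            _extremum(150, 6.0, "max"),
            _extremum(200, 5.0, "max"),
            _extremum(300, -7.0, "min"),
        ]
        out = enforce_alternation(ext)
        assert [e.sample_index for e in out] == [0, 150, 300]

    def test_alternating_input_unchanged(self):
        ext = [_extremum(0, -8.0, "min"), _extremum(100, 8.0, "max")]
        assert enforce_alternation(ext) == ext


class TestBuildSwings:
    def test_amplitude_is_sum_of_magnitudes(self):
        sig = make_signal(np.zeros(500))
        swings = build_swings(
            [_extremum(100, -10.0, "min"), _extremum(200, 10.0, "max")], sig
        )
        assert swings[0].amplitude == pytest.approx(20.0)
        swings = build_swings(
            [_extremum(100, 8.0, "max"), _extremum(200, -4.0, "min")], sig
        )
        assert swings[0].amplitude == pytest.approx(12.0)

    def test_peak_velocity_from_closed_form_derivative(self, time_30s):
        """alpha = 10 sin(2 pi t): every |peak velocity| ~ 2 pi 10 ~ 62.8 deg/s."""
        x = 10 * np.sin(2 * np.pi * 1.0 * time_30s)
        omega = 2 * np.pi * 10 * np.cos(2 * np.pi * 1.0 * time_30s)
        angle = make_angle(x)
        ext = detect_extrema(angle, analyze_windows(angle))
        swings = build_swings(ext, make_signal(omega))
        peaks = np.array([s.peak_omega for s in swings])
        np.testing.assert_allclose(np.abs(peaks), 2 * np.pi * 10, rtol=0.01)
        # consecutive swings alternate direction
        signs = np.sign(peaks)
        assert np.all(signs[1:] * signs[:-1] == -1)

    def test_fewer_than_two_extrema(self):
        sig = make_signal(np.zeros(100))
        assert build_swings([], sig) == []
        assert build_swings([_extremum(10, 5.0, "max")], sig) == []


def _swing(duration=1.0, amplitude=20.0, peak=60.0, bound=10.0, t0=0.0, fs=FS):
    return Swing(
        t_start=t0,
        t_end=t0 + duration,
        duration=duration,
        amplitude=amplitude,
        peak_omega=peak,
        direction="forward" if peak >= 0 else "backward",
        start_index=int(t0 * fs),
        end_index=int((t0 + duration) * fs),
        start_value=bound,
        end_value=-bound,
    )


class TestFilterSwings:
    MAGS = np.full(20, 10.0)  # 80th percentile = 10 -> outlier cut at 30

    def test_clean_swings_retained(self):
        out = filter_swings([_swing()], 1.0, self.MAGS)
        assert out[0].retained and out[0].reject_reason == "none"

    def test_long_swing_rule(self):
        out = filter_swings([_swing(duration=2.5)], 1.0, self.MAGS)
        assert not out[0].retained and out[0].reject_reason == "too_long"

    def test_outlier_rule_hand_traced(self):
        """Bounding extremum above 3 x 80th percentile of all magnitudes."""
        mags = np.concatenate([np.full(19, 10.0), [200.0]])
        cut = 3 * np.percentile(mags, 80)
        assert 30.0 <= cut < 200.0
        swings = [_swing(bound=10.0), _swing(bound=200.0, amplitude=210.0, t0=2.0)]
        out = filter_swings(swings, 1.0, mags)
        assert out[0].retained
        assert out[1].reject_reason == "outlier"

    def test_amplitude_threshold(self):
        out = filter_swings([_swing(amplitude=4.0, bound=2.0)], 1.0, self.MAGS)
        assert out[0].reject_reason == "below_amplitude"

    def test_velocity_threshold(self):
        out = filter_swings([_swing(peak=8.0)], 1.0, self.MAGS)
        assert out[0].reject_reason == "below_velocity"

    def test_first_tripped_rule_recorded(self):
        out = filter_swings([_swing(duration=2.5, amplitude=4.0, peak=8.0)], 1.0, self.MAGS)
        assert out[0].reject_reason == "too_long"

    def test_empty_in_empty_out(self):
        assert filter_swings([], 1.0, np.array([])) == []


class TestEndToEnd:
    def test_subthreshold_amplitude_yields_no_swings(self):
        """4 deg peak-to-peak swing: below the 5 deg minimum amplitude."""
        cfg = SynthConfig(duration=30.0, amp_left=2.0, amp_right=2.0, seed=0)
        left, _, _ = generate(cfg)
        res = analyze_arm(left)
        assert res.retained_swings == []

    def test_tremor_immunity(self):
        """A 5 Hz 10 deg/s tremor changes retained amplitudes by < 1%."""
        base = SynthConfig(duration=30.0, amp_left=10.0, amp_right=10.0, seed=0)
        trem = SynthConfig(duration=30.0, amp_left=10.0, amp_right=10.0, seed=0,
                           tremor_amp=10.0, tremor_freq=5.0)
        amps_base = [s.amplitude for s in analyze_arm(generate(base)[0]).retained_swings]
        amps_trem = [s.amplitude for s in analyze_arm(generate(trem)[0]).retained_swings]
        assert len(amps_base) == len(amps_trem)
        np.testing.assert_allclose(amps_trem, amps_base, rtol=0.01)

    def test_determinism(self):
        cfg = SynthConfig(duration=30.0, noise_sd=3.0, amp_jitter_cv=0.1, seed=42)
        a = analyze_arm(generate(cfg)[0]).swings
        b = analyze_arm(generate(cfg)[0]).swings
        assert a == b

    def test_outlier_excursion_flagged_in_pipeline(self, time_60s):
        """One 100 deg excursion amid 20 deg swings trips the outlier rule."""
        omega = 2 * np.pi * 10 * np.cos(2 * np.pi * 1.0 * time_60s)
        burst = (time_60s > 30.1) & (time_60s < 30.6)
        omega = omega + np.where(burst, 600.0 * np.sin(2 * np.pi * 2 * (time_60s - 30.1)), 0.0)
        from conftest import make_recording

        res = analyze_arm(make_recording(omega))
        reasons = {s.reject_reason for s in res.swings}
        assert "outlier" in reasons
        assert sum(s.retained for s in res.swings) > 40
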