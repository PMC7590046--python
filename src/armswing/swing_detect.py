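"""Angle-extrema detection and swing event construction.

A swing is the half-cycle between two consecutive extrema of the detrended
swing angle. Extrema are searched per 3 s window (50% overlap) with a 2 deg
minimum prominence and a minimum same-kind separation of 60% of that
window's cycle time; duplicates from overlapping windows are merged, extrema
outside analyzable samples are dropped, and strict max/min alternation is
enforced by discarding the smaller of two adjacent same-kind extrema.

Swing retention applies, in order: the long-swing rule (duration over twice
the average cycle time), the outlier rule (a bounding extremum larger than
three times the 80th percentile of all extremum magnitudes), the 5 deg
amplitude threshold, and the 10 deg/s peak-velocity threshold. Rejected
swings keep the first rule they tripped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .periodicity import SpectralWindow, analyzable_mask, dominant_frequency
from .preprocess import AngleSignal, SwingAxisSignal


@dataclass
class Extremum:
    sample_index: int
    time: float
    value: float  # signed detrended angle, deg
    kind: str  # "max" or "min"
    prominence: float

    @property
    def magnitude(self) -> float:
        return abs(self.value)


@dataclass
class Swing:
    t_start: float
    t_end: float
    duration: float
    amplitude: float  # |first extremum| + |second extremum|, deg
    peak_omega: float  # signed, deg/s
    direction: str  # "forward" (velocity maximum) or "backward" (minimum)
    start_index: int
    end_index: int
    start_value: float
    end_value: float
    retained: bool = False
    reject_reason: str = "none"


def _window_candidates(
    x: np.ndarray,
    fs: float,
    start: int,
    nw: int,
    prominence: float,
    min_distance_frac: float,
) -> list[tuple[int, str, float, int]]:
    """Extrema candidates (global index, kind, prominence, min-distance) of
    one peak-detection window, using the window's own dominant frequency."""
    seg = x[start : start + nw]
    f_dom = dominant_frequency(seg, fs)
    if not np.isfinite(f_dom) or f_dom <= 0.0:
        return []
    dist = max(1, int(round(min_distance_frac * fs / f_dom)))
    out = []
    for sign, kind in ((1.0, "max"), (-1.0, "min")):
        idx, props = find_peaks(sign * seg, prominence=prominence, distance=dist)
        for i, p in zip(idx, props["prominences"]):
            out.append((start + int(i), kind, float(p), dist))
    return out


def detect_extrema(
    angle: AngleSignal,
    windows: list[SpectralWindow],
    prominence: float = 2.0,
    min_distance_frac: float = 0.6,
    window_s: float = 3.0,
    overlap: float = 0.5,
) -> list[Extremum]:
    """Detect alternating maxima/minima of the detrended angle.

    Peak detection runs per 3 s window with 50% overlap; a peak found by
    several windows is counted once (same-kind detections closer than the
    minimum distance keep the larger magnitude). Extrema on samples not
    covered by any valid spectral window are discarded, and alternation is
    restored by dropping the smaller of two adjacent same-kind extrema.
    """
    if angle.alpha_detrend is None:
        raise ValueError("angle must be detrended before extrema detection")
    x = angle.alpha_detrend
    fs = angle.fs
    nw = int(round(window_s * fs))
    if x.size < nw:
        return []
    hop = max(1, int(round(nw * (1.0 - overlap))))

    candidates: dict[tuple[int, str], tuple[float, int]] = {}
    for start in range(0, x.size - nw + 1, hop):
        for gi, kind, prom, dist in _window_candidates(
            x, fs, start, nw, prominence, min_distance_frac
        ):
            prev = candidates.get((gi, kind))
            if prev is None or prom > prev[0]:
                candidates[(gi, kind)] = (prom, dist)

    # Merge near-duplicate same-kind detections from overlapping windows:
    # two detections of one physical peak closer than the minimum-distance
    # rule keep the larger magnitude (tie: the earlier one).
    merged: list[Extremum] = []
    for kind in ("max", "min"):
        items = sorted(
            (gi, prom, dist) for (gi, k), (prom, dist) in candidates.items() if k == kind
        )
        kept: list[tuple[int, float, int]] = []
        for gi, prom, dist in items:
            if kept and gi - kept[-1][0] < min(dist, kept[-1][2]):
                if abs(x[gi]) > abs(x[kept[-1][0]]):
                    kept[-1] = (gi, prom, dist)
            else:
                kept.append((gi, prom, dist))
        merged.extend(
            Extremum(gi, gi / fs, float(x[gi]), kind, prom) for gi, prom, _ in kept
        )

    mask = analyzable_mask(windows, x.size)
    merged = [e for e in merged if mask[e.sample_index]]
    merged.sort(key=lambda e: e.sample_index)
    return enforce_alternation(merged)


def enforce_alternation(extrema: list[Extremum]) -> list[Extremum]:
    """Restore strict max/min alternation along time.

    Between two maxima only one minimum is allowed and vice versa: whenever
    two same-kind extrema are adjacent, the smaller-magnitude one is
    discarded (tie: the later one)."""
    out = sorted(extrema, key=lambda e: e.sample_index)
    changed = True
    while changed:
        changed = False
        for i in range(len(out) - 1):
            if out[i].kind == out[i + 1].kind:
                drop = i if out[i].magnitude < out[i + 1].magnitude else i + 1
                del out[drop]
                changed = True
                break
    return out


def build_swings(extrema: list[Extremum], sig: SwingAxisSignal) -> list[Swing]:
    """One swing per consecutive extremum pair.

    Amplitude is the sum of the two bounding extremum magnitudes. The peak
    angular velocity is the largest-magnitude value of the swing-direction
    angular velocity inside the closed interval (earliest sample on ties);
    its sign labels the swing forward (maximum) or backward (minimum).
    """
    if len(extrema) < 2:
        return []
    omega = sig.omega_swing
    swings = []
    for e1, e2 in zip(extrema, extrema[1:]):
        seg = omega[e1.sample_index : e2.sample_index + 1]
        k = int(np.argmax(np.abs(seg)))
        peak = float(seg[k])
        swings.append(
            Swing(
                t_start=e1.time,
                t_end=e2.time,
                duration=e2.time - e1.time,
                amplitude=e1.magnitude + e2.magnitude,
                peak_omega=peak,
                direction="forward" if peak >= 0.0 else "backward",
                start_index=e1.sample_index,
                end_index=e2.sample_index,
                start_value=e1.value,
                end_value=e2.value,
            )
        )
    return swings


def filter_swings(
    swings: list[Swing],
    t_mean: float,
    extremum_magnitudes: np.ndarray,
    long_swing_factor: float = 2.0,
    outlier_factor: float = 3.0,
    outlier_percentile: float = 80.0,
    amp_threshold: float = 5.0,
    vel_threshold: float = 10.0,
) -> list[Swing]:
    """Apply the retention rules in order; the first tripped rule is recorded.

    ``extremum_magnitudes`` are the magnitudes of all detected extrema
    (pre-filter, post-alternation); their 80th percentile (linear
    interpolation) anchors the outlier rule.
    """
    mags = np.asarray(extremum_magnitudes, dtype=float)
    outlier_cut = (
        outlier_factor * float(np.percentile(mags, outlier_percentile))
        if mags.size
        else np.inf
    )
    out = []
    for s in swings:
        if s.duration > long_swing_factor * t_mean:
            reason = "too_long"
        elif max(abs(s.start_value), abs(s.end_value)) > outlier_cut:
            reason = "outlier"
        elif s.amplitude < amp_threshold:
            reason = "below_amplitude"
        elif abs(s.peak_omega) < vel_threshold:
            reason = "below_velocity"
        else:
            reason = "none"
        out.append(replace(s, retained=reason == "none", reject_reason=reason))
    return out
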