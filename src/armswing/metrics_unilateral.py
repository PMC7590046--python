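"""Per-arm swing parameters: amplitude, peak velocity, swing-time share,
frequency, and regularity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows as sig_windows

from .periodicity import SpectralWindow
from .preprocess import AngleSignal
from .swing_detect import Swing


@dataclass
class ArmSummary:
    """Summary parameters of one arm over a walking bout.

    Fields are ``None`` when not computable (no retained swings, no valid
    spectral windows, or a bout too short for the regularity window) — never
    silently zero.
    """

    side: str
    n_swings: int
    amplitude_mean: float | None
    peak_omega_mean: float | None
    peak_omega_forward_mean: float | None
    peak_omega_backward_mean: float | None
    pct_swing_time: float | None
    frequency: float | None
    regularity: float | None


def interval_union_duration(intervals: list[tuple[float, float]]) -> float:
    """Total length of the union of closed intervals."""
    if not intervals:
        return 0.0
    total = 0.0
    cur_s, cur_e = None, None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    return total + (cur_e - cur_s)


def regularity(
    angle: AngleSignal,
    window_s: float = 4.5,
    cosine_fraction: float = 0.3,
    overlap: float = 0.99,
    min_lag_s: float = 0.33,
    max_lag_s: float | None = None,
) -> float | None:
    """Similarity of neighboring swings from the windowed autocorrelation.

    The detrended angle is cut into 4.5 s windows advanced by 1% of their
    length, tapered with a Tukey window (cosine fraction 0.3). Each window's
    autocorrelation is normalized by its lag-0 energy (biased estimator, so
    the value never exceeds 1), and the maximum over lags between
    ``min_lag_s`` and half the window is taken; the mean of these maxima,
    clipped to [0, 1], is the regularity. Lags near zero are excluded
    because the lag-0 peak's shoulder is ~1 for any signal; the lower bound
    is the period of the fastest admissible swing (3 Hz). A value of 1 means
    every swing repeats its neighbors exactly.

    Returns ``None`` for bouts shorter than one window.
    """
    if angle.alpha_detrend is None:
        raise ValueError("angle must be detrended before the regularity analysis")
    x = angle.alpha_detrend
    fs = angle.fs
    nw = int(round(window_s * fs))
    if x.size < nw:
        return None
    hop = max(1, int(round((1.0 - overlap) * nw)))
    taper = sig_windows.tukey(nw, cosine_fraction)
    lo = int(round(min_lag_s * fs))
    hi = int(round((window_s / 2.0 if max_lag_s is None else max_lag_s) * fs))
    hi = min(hi, nw - 1)
    nfft = int(2 ** np.ceil(np.log2(2 * nw)))
    maxima = []
    for start in range(0, x.size - nw + 1, hop):
        seg = x[start : start + nw] * taper
        spec = np.fft.rfft(seg, nfft)
        ac = np.fft.irfft(spec * np.conj(spec), nfft)[: nw]
        if ac[0] <= 0.0:
            continue  # zero-energy window carries no swing information
        maxima.append(float(np.max(ac[lo : hi + 1]) / ac[0]))
    if not maxima:
        return None
    return float(np.clip(np.mean(maxima), 0.0, 1.0))


def summarize_arm(
    swings: list[Swing],
    windows: list[SpectralWindow],
    angle: AngleSignal,
    bout_duration: float,
    side: str = "left",
) -> ArmSummary:
    """Aggregate retained swings and spectral windows into the per-arm summary.

    ``pct_swing_time`` is the share of the bout covered by the union of
    retained swing intervals; ``frequency`` is the mean dominant frequency
    over valid spectral windows.
    """
    if bout_duration <= 0.0:
        raise ValueError("bout duration must be positive")
    retained = [s for s in swings if s.retained]
    doms = [w.dominant_freq for w in windows if w.valid]
    freq = float(np.mean(doms)) if doms else None

    if not retained:
        return ArmSummary(side, 0, None, None, None, None, None, freq, regularity(angle))

    fwd = [abs(s.peak_omega) for s in retained if s.direction == "forward"]
    bwd = [abs(s.peak_omega) for s in retained if s.direction == "backward"]
    pct = 100.0 * interval_union_duration(
        [(s.t_start, s.t_end) for s in retained]
    ) / bout_duration
    return ArmSummary(
        side=side,
        n_swings=len(retained),
        amplitude_mean=float(np.mean([s.amplitude for s in retained])),
        peak_omega_mean=float(np.mean([abs(s.peak_omega) for s in retained])),
        peak_omega_forward_mean=float(np.mean(fwd)) if fwd else None,
        peak_omega_backward_mean=float(np.mean(bwd)) if bwd else None,
        pct_swing_time=float(pct),
        frequency=freq,
        regularity=regularity(angle),
    )
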