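"""Short-time spectral gating of the detrended swing angle.

Arm swing is defined as periodic movement between 0.3 and 3 Hz. The
detrended angle is cut into 3 s rectangular windows with 75% overlap; a
window is analyzable only if its dominant (non-DC) frequency lies in the
band and at least 90% of its non-DC spectral power does too. Windows that
fail the gate mark their samples as non-analyzable for the downstream event
detection; a bout with no valid window yields no swing parameters at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AngleSignal


class NoPeriodicMovementError(ValueError):
    """Raised when no spectral window passes the periodicity gate."""


@dataclass
class SpectralWindow:
    start_time: float
    duration: float
    dominant_freq: float
    band_power_fraction: float
    valid: bool
    start_index: int
    n_samples: int


def _window_spectrum(seg: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular-window magnitude-squared spectrum and its frequency grid."""
    mag2 = np.abs(np.fft.rfft(seg)) ** 2
    freqs = np.fft.rfftfreq(seg.size, d=1.0 / fs)
    return freqs, mag2


def dominant_frequency(seg: np.ndarray, fs: float) -> float:
    """Frequency of the largest non-DC spectral magnitude, or NaN if the
    segment has no non-DC power (e.g. a constant)."""
    freqs, mag2 = _window_spectrum(seg, fs)
    if mag2.size < 2 or not np.any(mag2[1:] > 0.0):
        return float("nan")
    return float(freqs[1 + int(np.argmax(mag2[1:]))])


def analyze_windows(
    angle: AngleSignal,
    window_s: float = 3.0,
    overlap: float = 0.75,
    band: tuple[float, float] = (0.3, 3.0),
    power_gate: float = 0.90,
) -> list[SpectralWindow]:
    """Slide FFT windows over the detrended angle and gate each by band power.

    The band-power fraction is the in-band share of the non-DC power
    (band edges inclusive); DC is excluded from numerator and denominator
    because the gate measures periodicity, not offset. Windows advance by
    (1 - overlap) of their length; a trailing remainder shorter than one
    window is dropped. A bout shorter than one window returns an empty list.
    """
    if angle.alpha_detrend is None:
        raise ValueError("angle must be detrended before spectral analysis")
    x = angle.alpha_detrend
    fs = angle.fs
    nw = int(round(window_s * fs))
    if x.size < nw:
        return []
    hop = max(1, int(round(nw * (1.0 - overlap))))
    lo, hi = band
    out: list[SpectralWindow] = []
    for start in range(0, x.size - nw + 1, hop):
        seg = x[start : start + nw]
        freqs, mag2 = _window_spectrum(seg, fs)
        total = float(np.sum(mag2[1:]))
        if total <= 0.0:
            dom, frac = float("nan"), 0.0
        else:
            dom = float(freqs[1 + int(np.argmax(mag2[1:]))])
            in_band = (freqs >= lo) & (freqs <= hi)
            in_band[0] = False
            frac = float(np.sum(mag2[in_band]) / total)
        valid = bool(frac >= power_gate and not np.isnan(dom) and lo <= dom <= hi)
        out.append(
            SpectralWindow(
                start_time=start / fs,
                duration=nw / fs,
                dominant_freq=dom,
                band_power_fraction=frac,
                valid=valid,
                start_index=start,
                n_samples=nw,
            )
        )
    return out


def analyzable_mask(windows: list[SpectralWindow], n_samples: int) -> np.ndarray:
    """Boolean per-sample mask: True where the sample is covered by at least
    one valid spectral window."""
    mask = np.zeros(n_samples, dtype=bool)
    for w in windows:
        if w.valid:
            mask[w.start_index : w.start_index + w.n_samples] = True
    return mask


def mean_cycle_time(windows: list[SpectralWindow]) -> float:
    """Average swing cycle time (s): reciprocal of the mean dominant
    frequency over valid windows."""
    doms = [w.dominant_freq for w in windows if w.valid]
    if not doms:
        raise NoPeriodicMovementError(
            "no periodic movement: no spectral window passed the band-power gate"
        )
    return 1.0 / float(np.mean(doms))
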