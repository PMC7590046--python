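"""Left-versus-right swing parameters: simultaneity, asymmetry, coordination.

Both arms must share a synchronized time base (the reader's job; nothing is
resampled here). Swings of the two arms are "simultaneous" when a direction
change (bounding extremum) of one falls within 500 ms of a direction change
of the other; asymmetry and coordination are only reported when at least
60% of the bout is covered by simultaneous swings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics_unilateral import interval_union_duration
from .preprocess import SwingAxisSignal
from .swing_detect import Swing


@dataclass
class SimultaneousPhases:
    left: list[Swing]
    right: list[Swing]
    intervals: list[tuple[float, float]]
    pct_simultaneous: float


@dataclass
class BilateralSummary:
    """Left-vs-right parameters; asymmetry/coordination fields are ``None``
    unless the 60% simultaneity eligibility gate is passed."""

    pct_simultaneous: float
    eligible: bool
    asi_amplitude: float | None
    asi_amplitude_abs: float | None
    asi_peak_omega: float | None
    asi_peak_omega_abs: float | None
    coordination: float | None


def _direction_change_times(swings: list[Swing]) -> np.ndarray:
    times = set()
    for s in swings:
        if s.retained:
            times.add(s.t_start)
            times.add(s.t_end)
    return np.array(sorted(times))


def _near_any(t: float, events: np.ndarray, tol: float) -> bool:
    if events.size == 0:
        return False
    i = int(np.searchsorted(events, t))
    for j in (i - 1, i):
        if 0 <= j < events.size and abs(events[j] - t) <= tol:
            return True
    return False


def simultaneous_phases(
    left: list[Swing],
    right: list[Swing],
    bout_duration: float,
    tol: float = 0.5,
) -> SimultaneousPhases:
    """Find swings whose direction changes pair up across arms within ``tol``.

    A swing counts as simultaneous if either of its bounding direction
    changes is within ``tol`` seconds of any direction change of the other
    arm. The simultaneity percentage is the bout share covered by the union
    of simultaneous swing intervals from both arms.
    """
    ev_left = _direction_change_times(left)
    ev_right = _direction_change_times(right)
    sim_left = [
        s
        for s in left
        if s.retained
        and (_near_any(s.t_start, ev_right, tol) or _near_any(s.t_end, ev_right, tol))
    ]
    sim_right = [
        s
        for s in right
        if s.retained
        and (_near_any(s.t_start, ev_left, tol) or _near_any(s.t_end, ev_left, tol))
    ]
    intervals = [(s.t_start, s.t_end) for s in sim_left + sim_right]
    pct = 100.0 * interval_union_duration(intervals) / bout_duration
    return SimultaneousPhases(sim_left, sim_right, intervals, float(pct))


def asymmetry_index(L: float, R: float) -> float:
    """Signed asymmetry index (L - R) / max(L, R) x 100.

    0% means identical left and right values; positive means the left value
    is larger. Inputs must be positive (they are means over retained swings,
    which always exceed the detection thresholds).
    """
    if L <= 0.0 or R <= 0.0:
        raise ValueError("asymmetry index requires positive left and right values")
    return (L - R) / max(L, R) * 100.0


def _normalized_xcorr_min(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Minimum over lags -max_lag..max_lag of the cross-correlation
    normalized by the overlapping segments' root energies."""
    best = np.inf
    for m in range(-max_lag, max_lag + 1):
        if m >= 0:
            x, y = a[m:], b[: b.size - m]
        else:
            x, y = a[: a.size + m], b[-m:]
        if x.size < 2:
            continue
        denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
        if denom <= 0.0:
            continue
        best = min(best, float(np.dot(x, y) / denom))
    return best


def coordination(
    sig_left: SwingAxisSignal,
    sig_right: SwingAxisSignal,
    phases: SimultaneousPhases,
    max_lag_s: float = 0.5,
    margin_s: float = 0.5,
) -> float | None:
    """Bilateral coordination from the normalized cross-correlation.

    For every simultaneous swing (of either arm), both arms' swing-direction
    angular velocities over the swing interval extended by ``margin_s`` on
    each side are cross-correlated over lags of 0 +/- ``max_lag_s``,
    normalizing by the overlapping segments' energies. The per-swing score
    is the absolute value of the minimum over lags; the coordination is the
    mean score, clipped to [0, 1]. A value of 1 means the arms swing with
    the same rhythm in exact anti-phase; 0 means no coordination.

    Returns ``None`` when there are no simultaneous swings.

    Note: for swing frequencies at or above 1 Hz the +/- 0.5 s lag range
    spans at least half a period, so in-phase and anti-phase arms both score
    near 1; this is inherent to the definition.
    """
    swings = phases.left + phases.right
    if not swings:
        return None
    fs = sig_left.fs
    if sig_right.fs != fs:
        raise ValueError("left and right signals must share one sampling rate")
    n = min(sig_left.omega_swing.size, sig_right.omega_swing.size)
    max_lag = int(round(max_lag_s * fs))
    scores = []
    for s in swings:
        i0 = max(0, int(round((s.t_start - margin_s) * fs)))
        i1 = min(n - 1, int(round((s.t_end + margin_s) * fs)))
        if i1 - i0 < 2:
            continue
        a = sig_left.omega_swing[i0 : i1 + 1]
        b = sig_right.omega_swing[i0 : i1 + 1]
        m = _normalized_xcorr_min(a, b, max_lag)
        if np.isfinite(m):
            scores.append(abs(m))
    if not scores:
        return None
    return float(np.clip(np.mean(scores), 0.0, 1.0))


def summarize_bilateral(
    left_swings: list[Swing],
    right_swings: list[Swing],
    sig_left: SwingAxisSignal,
    sig_right: SwingAxisSignal,
    bout_duration: float,
    tol: float = 0.5,
    eligibility: float = 0.60,
    max_lag_s: float = 0.5,
    margin_s: float = 0.5,
) -> BilateralSummary:
    """Simultaneity plus, when eligible, asymmetry indices and coordination.

    Asymmetry compares mean amplitude and mean absolute peak velocity over
    the simultaneous swings of each arm only.
    """
    phases = simultaneous_phases(left_swings, right_swings, bout_duration, tol)
    eligible = phases.pct_simultaneous >= 100.0 * eligibility
    asi_amp = asi_vel = coord = None
    if eligible and phases.left and phases.right:
        l_amp = float(np.mean([s.amplitude for s in phases.left]))
        r_amp = float(np.mean([s.amplitude for s in phases.right]))
        l_vel = float(np.mean([abs(s.peak_omega) for s in phases.left]))
        r_vel = float(np.mean([abs(s.peak_omega) for s in phases.right]))
        asi_amp = asymmetry_index(l_amp, r_amp)
        asi_vel = asymmetry_index(l_vel, r_vel)
        coord = coordination(sig_left, sig_right, phases, max_lag_s, margin_s)
    return BilateralSummary(
        pct_simultaneous=phases.pct_simultaneous,
        eligible=bool(eligible),
        asi_amplitude=asi_amp,
        asi_amplitude_abs=abs(asi_amp) if asi_amp is not None else None,
        asi_peak_omega=asi_vel,
        asi_peak_omega_abs=abs(asi_vel) if asi_vel is not None else None,
        coordination=coord,
    )
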