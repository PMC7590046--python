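"""End-to-end orchestration: recording(s) in, bout report out.

Per arm: low-pass filter, swing-axis projection, angle integration and
detrending, spectral gating, extrema detection, swing construction and
retention filtering, then the per-arm summary. When both arms are present
and synchronized, the bilateral simultaneity/asymmetry/coordination block
runs on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .metrics_bilateral import BilateralSummary, summarize_bilateral
from .metrics_unilateral import ArmSummary, summarize_arm
from .periodicity import (
    NoPeriodicMovementError,
    SpectralWindow,
    analyze_windows,
    mean_cycle_time,
)
from .preprocess import (
    AngleSignal,
    GyroRecording,
    NoSwingAxisError,
    SwingAxisSignal,
    detrend_angle,
    integrate_angle,
    lowpass_filter,
    project_swing_axis,
)
from .swing_detect import Swing, build_swings, detect_extrema, filter_swings

log = logging.getLogger("armswing")

STATUS_OK = "ok"
STATUS_NO_PERIODIC = "no periodic movement"


@dataclass
class ArmResult:
    """Everything the pipeline derived for one arm."""

    status: str
    summary: ArmSummary
    swings: list[Swing] = field(default_factory=list)
    windows: list[SpectralWindow] = field(default_factory=list)
    signal: SwingAxisSignal | None = None
    angle: AngleSignal | None = None
    bout_duration: float = 0.0

    @property
    def retained_swings(self) -> list[Swing]:
        return [s for s in self.swings if s.retained]


@dataclass
class BoutResult:
    status: str
    left: ArmResult | None = None
    right: ArmResult | None = None
    bilateral: BilateralSummary | None = None
    bilateral_reason: str = ""
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def _empty_summary(side: str, freq: float | None = None, reg: float | None = None) -> ArmSummary:
    return ArmSummary(side, 0, None, None, None, None, None, freq, reg)


def analyze_arm(rec: GyroRecording, config: AnalysisConfig | None = None) -> ArmResult:
    """Run the full unilateral pipeline on one recording."""
    cfg = config or AnalysisConfig()
    if rec.duration < cfg.fft_window_s:
        raise ValueError(
            f"bout of {rec.duration:.2f} s is shorter than one {cfg.fft_window_s} s window"
        )
    bout = rec.duration
    filtered = lowpass_filter(rec, cfg.cutoff)
    try:
        sig = project_swing_axis(filtered)
    except NoSwingAxisError:
        log.info("%s arm: no swing axis (motionless)", rec.side)
        return ArmResult(STATUS_NO_PERIODIC, _empty_summary(rec.side), bout_duration=bout)
    angle = detrend_angle(integrate_angle(sig))
    windows = analyze_windows(
        angle,
        window_s=cfg.fft_window_s,
        overlap=cfg.fft_overlap_freq,
        band=(cfg.band_low, cfg.band_high),
        power_gate=cfg.power_gate,
    )
    n_valid = sum(w.valid for w in windows)
    log.info("%s arm: %d/%d spectral windows valid", rec.side, n_valid, len(windows))
    try:
        t_mean = mean_cycle_time(windows)
    except NoPeriodicMovementError:
        return ArmResult(
            STATUS_NO_PERIODIC, _empty_summary(rec.side), [], windows, sig, angle, bout
        )
    extrema = detect_extrema(
        angle,
        windows,
        prominence=cfg.prominence,
        min_distance_frac=cfg.min_distance_frac,
        window_s=cfg.fft_window_s,
        overlap=cfg.fft_overlap_peaks,
    )
    swings = filter_swings(
        build_swings(extrema, sig),
        t_mean,
        np.array([e.magnitude for e in extrema]),
        long_swing_factor=cfg.long_swing_factor,
        outlier_factor=cfg.outlier_factor,
        outlier_percentile=cfg.outlier_percentile,
        amp_threshold=cfg.amp_threshold,
        vel_threshold=cfg.vel_threshold,
    )
    reasons = {}
    for s in swings:
        if not s.retained:
            reasons[s.reject_reason] = reasons.get(s.reject_reason, 0) + 1
    log.info(
        "%s arm: %d extrema, %d swings, %d retained, rejections %s",
        rec.side, len(extrema), len(swings), sum(s.retained for s in swings), reasons,
    )
    summary = summarize_arm(swings, windows, angle, bout, side=rec.side)
    return ArmResult(STATUS_OK, summary, swings, windows, sig, angle, bout)


def analyze_bout(
    left: GyroRecording | None,
    right: GyroRecording | None = None,
    config: AnalysisConfig | None = None,
) -> BoutResult:
    """Analyze one or two synchronized arm recordings.

    Bilateral metrics are only computed when both arms are present, on a
    shared time base, and both produced analyzable periodic movement.
    """
    cfg = config or AnalysisConfig()
    if left is None and right is None:
        raise ValueError("at least one arm recording is required")
    res_left = analyze_arm(left, cfg) if left is not None else None
    res_right = analyze_arm(right, cfg) if right is not None else None

    statuses = [r.status for r in (res_left, res_right) if r is not None]
    status = STATUS_OK if STATUS_OK in statuses else STATUS_NO_PERIODIC

    bilateral = None
    reason = ""
    if res_left is None or res_right is None:
        reason = "single_arm"
    elif res_left.status != STATUS_OK or res_right.status != STATUS_OK:
        reason = "no periodic movement in one arm"
    else:
        bout = min(res_left.bout_duration, res_right.bout_duration)
        bilateral = summarize_bilateral(
            res_left.swings,
            res_right.swings,
            res_left.signal,
            res_right.signal,
            bout,
            tol=cfg.simultaneity_tol_s,
            eligibility=cfg.eligibility,
        )
    return BoutResult(status, res_left, res_right, bilateral, reason, cfg)


def report_dict(result: BoutResult) -> dict:
    """Serialize a bout result into the JSON report schema."""

    def arm(r: ArmResult | None):
        if r is None:
            return None
        s = r.summary
        return {
            "status": r.status,
            "n_swings": s.n_swings,
            "amplitude_deg": s.amplitude_mean,
            "peak_angular_velocity_deg_s": s.peak_omega_mean,
            "forward_peak_angular_velocity_deg_s": s.peak_omega_forward_mean,
            "backward_peak_angular_velocity_deg_s": s.peak_omega_backward_mean,
            "pct_walk_with_swinging_motion": s.pct_swing_time,
            "frequency_hz": s.frequency,
            "regularity": s.regularity,
        }

    b = result.bilateral
    bilateral = None
    if b is not None:
        bilateral = {
            "pct_walk_with_simultaneous_swinging": b.pct_simultaneous,
            "eligible": b.eligible,
            "amplitude_asymmetry_index_pct": b.asi_amplitude,
            "abs_amplitude_asymmetry_index_pct": b.asi_amplitude_abs,
            "peak_angular_velocity_asymmetry_index_pct": b.asi_peak_omega,
            "abs_peak_angular_velocity_asymmetry_index_pct": b.asi_peak_omega_abs,
            "coordination": b.coordination,
        }
    return {
        "status": result.status,
        "left": arm(result.left),
        "right": arm(result.right),
        "bilateral": bilateral,
        "bilateral_reason": result.bilateral_reason,
        "config": result.config.to_dict(),
    }
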