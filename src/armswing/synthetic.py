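"""Synthetic bilateral gyroscope recordings with exact ground truth.

The generator emulates quasi-sinusoidal arm swing as seen by wrist
gyroscopes: each arm's swing angle is a sinusoid whose amplitude is redrawn
per half-cycle (lognormal jitter with a stated coefficient of variation),
so the truth tables — swing intervals, per-swing amplitudes and peak
velocities — follow exactly from the generating equations. The analytic
angular-velocity derivative is distributed over the transverse (x, y)
channels by a per-arm mounting rotation about the forearm axis, then
corrupted with the confounds the pipeline must reject: constant rate bias,
white sensor noise, a super-cutoff tremor sinusoid, and an optional
longitudinal (z) turning profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import GyroRecording


@dataclass
class SynthConfig:
    """Generation parameters; amplitudes are half-amplitudes A of the angle
    sinusoid, so one swing's true amplitude is ~2A."""

    fs: float = 200.0
    duration: float = 60.0
    swing_freq: float = 1.0
    amp_left: float = 10.0  # deg
    amp_right: float = 10.0  # deg
    phase_offset: float = np.pi  # rad between arms; pi = anti-phase (normal gait)
    mount_rotation_left: float = 0.0  # rad about z
    mount_rotation_right: float = 0.0
    gyro_bias: float = 0.0  # deg/s, added to every axis
    noise_sd: float = 0.0  # deg/s white noise per axis
    tremor_freq: float = 5.0  # Hz; above the 3 Hz cutoff by default
    tremor_amp: float = 0.0  # deg/s
    turn_profile: np.ndarray | None = None  # z-axis angular velocity, deg/s
    amp_jitter_cv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 2.0 * max(self.swing_freq, self.tremor_freq):
            raise ValueError("fs must exceed twice the highest generated frequency "
                             "(swing_freq/tremor_freq)")
        if self.duration < 3.0:
            raise ValueError("duration must be at least 3 s (one spectral window)")
        for name in ("amp_left", "amp_right", "tremor_amp", "noise_sd", "amp_jitter_cv"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ArmTruth:
    intervals: list[tuple[float, float]]  # (t_start, t_end) of each half-cycle swing
    amplitudes: np.ndarray  # deg, per swing
    peak_velocities: np.ndarray  # deg/s, per swing (magnitude)


@dataclass
class SynthTruth:
    left: ArmTruth
    right: ArmTruth
    asi_amplitude: float
    phase_offset: float


def _arm_truth(
    amps: np.ndarray, freq: float, phi: float, duration: float
) -> ArmTruth:
    """Swing truth from the generating equations.

    Angle extrema sit at phase pi/2 + k*pi (value +/- A_k of the half-cycle
    containing them); the swing between extrema k and k+1 has amplitude
    A_k + A_{k+1} and its velocity peak, at the half-cycle boundary, has
    magnitude 2*pi*f*max(A_k, A_{k+1}).
    """
    intervals, amplitudes, peaks = [], [], []
    k = 0
    while True:
        t0 = (np.pi / 2 + k * np.pi - phi) / (2 * np.pi * freq)
        t1 = (np.pi / 2 + (k + 1) * np.pi - phi) / (2 * np.pi * freq)
        if t0 < 0.0:
            k += 1
            continue
        if t1 > duration or k + 1 >= amps.size:
            break
        intervals.append((t0, t1))
        amplitudes.append(amps[k] + amps[k + 1])
        peaks.append(2 * np.pi * freq * max(amps[k], amps[k + 1]))
        k += 1
    return ArmTruth(intervals, np.array(amplitudes), np.array(peaks))


def _generate_arm(
    cfg: SynthConfig, amp: float, phi: float, rho: float, rng: np.random.Generator,
    side: str,
) -> tuple[GyroRecording, ArmTruth]:
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    phase = 2 * np.pi * cfg.swing_freq * t + phi
    half_cycle = np.floor(phase / np.pi).astype(int)
    half_cycle -= half_cycle.min()
    n_cycles = half_cycle.max() + 2
    if cfg.amp_jitter_cv > 0.0:
        sigma2 = np.log1p(cfg.amp_jitter_cv**2)
        jitter = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n_cycles)
    else:
        jitter = np.ones(n_cycles)
    amps = amp * jitter
    omega = amps[half_cycle] * 2 * np.pi * cfg.swing_freq * np.cos(phase)

    x = omega * np.cos(rho)
    y = omega * np.sin(rho)
    if cfg.tremor_amp > 0.0:
        x = x + cfg.tremor_amp * np.sin(2 * np.pi * cfg.tremor_freq * t)
    z = np.zeros(n)
    if cfg.turn_profile is not None:
        prof = np.asarray(cfg.turn_profile, dtype=float)
        z[: min(n, prof.size)] += prof[: min(n, prof.size)]
    x = x + cfg.gyro_bias
    y = y + cfg.gyro_bias
    z = z + cfg.gyro_bias
    if cfg.noise_sd > 0.0:
        x = x + rng.normal(0.0, cfg.noise_sd, n)
        y = y + rng.normal(0.0, cfg.noise_sd, n)
        z = z + rng.normal(0.0, cfg.noise_sd, n)

    rec = GyroRecording(t=t, omega_x=x, omega_y=y, omega_z=z, fs=cfg.fs,
                        side=side, label="synthetic")
    # Truth amplitudes indexed by half-cycle of the *shifted* phase grid
    phi_eff = phase[0] - np.pi * half_cycle[0] if n else phi
    truth = _arm_truth(amps, cfg.swing_freq, phi_eff, cfg.duration)
    return rec, truth


def generate(config: SynthConfig) -> tuple[GyroRecording, GyroRecording, SynthTruth]:
    """Generate synchronized left/right recordings plus their ground truth.

    Deterministic under a fixed ``config.seed``: the two arms draw from
    independent child streams of the seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_left, rng_right = (np.random.default_rng(s) for s in ss.spawn(2))
    left, truth_left = _generate_arm(
        config, config.amp_left, 0.0, config.mount_rotation_left, rng_left, "left"
    )
    right, truth_right = _generate_arm(
        config, config.amp_right, config.phase_offset, config.mount_rotation_right,
        rng_right, "right",
    )
    mean_l = float(np.mean(truth_left.amplitudes)) if truth_left.amplitudes.size else np.nan
    mean_r = float(np.mean(truth_right.amplitudes)) if truth_right.amplitudes.size else np.nan
    asi = (mean_l - mean_r) / max(mean_l, mean_r) * 100.0
    return left, right, SynthTruth(truth_left, truth_right, float(asi), config.phase_offset)


#: Preset study conditions. Swing frequency 0.9 Hz matches typical walking
#: cadence-coupled arm swing; half-amplitudes give per-swing amplitudes of
#: ~16 deg (slow gait), ~36 deg (brisk gait) and ~17 deg with ~36% left-right
#: asymmetry plus intermittent sub-threshold cycles for the parkinsonian
#: pattern.
_PRESETS: dict[str, dict] = {
    "healthy_slow": dict(
        swing_freq=0.9, amp_left=8.0, amp_right=8.0, amp_jitter_cv=0.05,
        noise_sd=1.0, gyro_bias=0.5, tremor_amp=0.0,
        mount_rotation_left=0.3, mount_rotation_right=-0.2,
    ),
    "healthy_fast": dict(
        swing_freq=0.9, amp_left=18.0, amp_right=18.0, amp_jitter_cv=0.05,
        noise_sd=1.0, gyro_bias=0.5, tremor_amp=0.0,
        mount_rotation_left=0.3, mount_rotation_right=-0.2,
    ),
    "parkinsonian": dict(
        swing_freq=0.9, amp_left=8.5, amp_right=5.44, amp_jitter_cv=0.30,
        noise_sd=2.0, gyro_bias=1.0, tremor_amp=10.0, tremor_freq=5.0,
        mount_rotation_left=0.3, mount_rotation_right=-0.2,
    ),
}


def preset(name: str, **overrides) -> SynthConfig:
    """A documented study-condition configuration by name.

    Known names: ``healthy_slow``, ``healthy_fast``, ``parkinsonian``.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SynthConfig(**params)
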