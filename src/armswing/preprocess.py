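"""Raw gyroscope traces to swing-direction angular velocity and detrended angle.

The wrist gyroscope measures three angular-velocity channels (deg/s) in a
right-handed sensor frame with the z-axis along the forearm's longitudinal
axis. Arm swing is quantified from the transverse (x, y) channels only:
longitudinal rotations (body turns, forearm pronation/supination) are
deliberately excluded. The processing chain implemented here is

1. zero-phase low-pass filtering of all channels (2nd-order Butterworth,
   3 Hz cutoff, applied forward and backward),
2. projection of the (x, y) channels onto their first principal component,
   yielding the scalar swing-direction angular velocity,
3. trapezoidal integration to the swing angle, and
4. drift removal by subtracting a ~1 s symmetric moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt


class NoSwingAxisError(ValueError):
    """Raised when the transverse channels carry no variance (motionless arm)."""


@dataclass
class GyroRecording:
    """One arm's raw 3-axis angular velocity at a fixed sampling rate.

    Units are deg/s throughout; the z-axis is the forearm longitudinal axis.
    """

    t: np.ndarray
    omega_x: np.ndarray
    omega_y: np.ndarray
    omega_z: np.ndarray
    fs: float
    side: str = "left"
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega_x = np.asarray(self.omega_x, dtype=float)
        self.omega_y = np.asarray(self.omega_y, dtype=float)
        self.omega_z = np.asarray(self.omega_z, dtype=float)
        n = self.t.size
        if not (self.omega_x.size == self.omega_y.size == self.omega_z.size == n):
            raise ValueError("time and angular-velocity channels must have equal length")
        if self.fs < 20.0:
            raise ValueError(
                f"sampling rate {self.fs} Hz too low; >= 20 Hz required to resolve "
                "the 3 Hz low-pass and the 0.3-3 Hz swing band"
            )
        if n >= 2:
            dt = np.diff(self.t)
            nominal = 1.0 / self.fs
            if np.any(np.abs(dt - nominal) > 1e-6 * nominal):
                raise ValueError("time stamps are not uniformly spaced at the stated rate")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Bout duration in seconds (sample count over rate)."""
        return self.t.size / self.fs


@dataclass
class SwingAxisSignal:
    """Swing-direction angular velocity: first principal component of (x, y).

    ``loadings`` is the unit vector of weights on the (x, y) channels; its
    sign is fixed by convention (largest-magnitude loading positive) so
    forward/backward labels are reproducible, though not anatomically
    guaranteed.
    """

    omega_swing: np.ndarray
    loadings: np.ndarray
    fs: float
    sign_fixed: bool = True
    t: np.ndarray = field(default=None, repr=False)


@dataclass
class AngleSignal:
    """Integrated swing angle, its moving-average trend, and the detrended angle.

    ``alpha`` is the cumulative trapezoidal integral of the swing-direction
    angular velocity (deg, alpha[0] = 0). ``trend`` and ``alpha_detrend`` are
    filled by :func:`detrend_angle`; ``q`` is the half-window in samples of
    the symmetric moving average (window length 2q+1).
    """

    alpha: np.ndarray
    fs: float
    t: np.ndarray = field(default=None, repr=False)
    trend: np.ndarray | None = None
    alpha_detrend: np.ndarray | None = None
    q: int | None = None

    @property
    def duration(self) -> float:
        return self.alpha.size / self.fs


def lowpass_filter(rec: GyroRecording, cutoff: float = 3.0) -> GyroRecording:
    """Zero-phase 2nd-order Butterworth low-pass on every gyroscope channel.

    The filter is applied forward and backward (``filtfilt``), so the phase
    is exactly zero and the effective magnitude response is the squared
    single-pass response. A pure DC signal passes unchanged.
    """
    if rec.fs <= 2.0 * cutoff:
        raise ValueError(f"sampling rate {rec.fs} Hz must exceed twice the {cutoff} Hz cutoff")
    b, a = butter(2, cutoff, btype="low", fs=rec.fs)
    padlen = 3 * max(len(a), len(b))
    if rec.n_samples <= padlen:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than the zero-phase "
            f"filter warm-up length ({padlen} samples); provide a longer bout"
        )
    return replace(
        rec,
        omega_x=filtfilt(b, a, rec.omega_x),
        omega_y=filtfilt(b, a, rec.omega_y),
        omega_z=filtfilt(b, a, rec.omega_z),
    )


def project_swing_axis(rec_filtered: GyroRecording) -> SwingAxisSignal:
    """Project the transverse (x, y) channels onto their first principal axis.

    The principal direction is the leading eigenvector of the mean-centered
    2x2 covariance of (x, y); the raw (uncentered) channels are projected
    onto it, so a constant rate bias survives here and is removed later by
    the moving-average detrend. The z channel is ignored entirely, which
    makes the result immune to body turns and to the sensor's rotational
    mounting position about the forearm axis.

    Sign convention: the loading of larger magnitude is made positive
    (tie: the x loading is made positive).
    """
    if rec_filtered.n_samples < 2:
        raise ValueError("at least 2 samples required for the swing-axis projection")
    xy = np.column_stack((rec_filtered.omega_x, rec_filtered.omega_y))
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered / (xy.shape[0] - 1)
    if not np.any(cov):
        raise NoSwingAxisError(
            "no swing axis: both transverse channels have zero variance (motionless arm)"
        )
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, -1]  # eigenvalues ascending -> last column is the first PC
    i = int(np.argmax(np.abs(v)))
    if np.isclose(abs(v[0]), abs(v[1])):
        i = 0
    if v[i] < 0:
        v = -v
    return SwingAxisSignal(
        omega_swing=xy @ v,
        loadings=v,
        fs=rec_filtered.fs,
        sign_fixed=True,
        t=rec_filtered.t,
    )


def integrate_angle(sig: SwingAxisSignal) -> AngleSignal:
    """Swing angle (deg) as the cumulative trapezoidal integral of the
    swing-direction angular velocity; alpha(0) = 0."""
    alpha = cumulative_trapezoid(sig.omega_swing, dx=1.0 / sig.fs, initial=0.0)
    return AngleSignal(alpha=alpha, fs=sig.fs, t=sig.t)


def moving_average_weights(q: int) -> np.ndarray:
    """Symmetric moving-average weights of window length 2q+1.

    Half weight (1/4q) at the two window ends, 1/2q elsewhere; the weights
    sum to exactly 1 for any q >= 1. This is the centered moving average of
    even order 2q.
    """
    if q < 1:
        raise ValueError("half-window q must be >= 1")
    w = np.full(2 * q + 1, 1.0 / (2 * q))
    w[0] = w[-1] = 1.0 / (4 * q)
    return w


def detrend_angle(angle: AngleSignal, q: int | None = None) -> AngleSignal:
    """Remove integration drift with a ~1 s symmetric moving average.

    ``q`` defaults to round(fs/2) samples, i.e. a window of (2q+1)/fs
    ~ 1.005 s at 200 Hz. The trend at interior samples (q < n < N-q) is the
    exact weighted average of :func:`moving_average_weights`; the edges are
    handled by replicating the first/last angle value so the outputs keep
    full length and stay index-aligned with the spectral windows.
    """
    if q is None:
        q = int(round(angle.fs / 2.0))
    n = angle.alpha.size
    if n <= 2 * q:
        raise ValueError(
            f"bout too short to detrend: {n} samples <= moving-average window of {2 * q + 1}"
        )
    padded = np.concatenate(
        (np.full(q, angle.alpha[0]), angle.alpha, np.full(q, angle.alpha[-1]))
    )
    trend = np.convolve(padded, moving_average_weights(q), mode="valid")
    return AngleSignal(
        alpha=angle.alpha,
        fs=angle.fs,
        t=angle.t,
        trend=trend,
        alpha_detrend=angle.alpha - trend,
        q=q,
    )
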