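import numpy as np
import pytest

from armswing.preprocess import AngleSignal, GyroRecording, SwingAxisSignal

FS = 200.0


def make_recording(x, y=None, z=None, fs=FS, side="left"):
    """GyroRecording with the given channels (missing channels are zero)."""
    x = np.asarray(x, dtype=float)
    zeros = np.zeros_like(x)
    t = np.arange(x.size) / fs
    return GyroRecording(
        t=t,
        omega_x=x,
        omega_y=zeros if y is None else np.asarray(y, float),
        omega_z=zeros if z is None else np.asarray(z, float),
        fs=fs,
        side=side,
    )


def make_angle(alpha_detrend, fs=FS):
    """AngleSignal with the detrended angle set directly (unit-test shortcut)."""
    alpha_detrend = np.asarray(alpha_detrend, dtype=float)
    return AngleSignal(
        alpha=alpha_detrend,
        fs=fs,
        t=np.arange(alpha_detrend.size) / fs,
        trend=np.zeros_like(alpha_detrend),
        alpha_detrend=alpha_detrend,
        q=int(round(fs / 2)),
    )


def make_signal(omega, fs=FS):
    omega = np.asarray(omega, dtype=float)
    return SwingAxisSignal(
        omega_swing=omega,
        loadings=np.array([1.0, 0.0]),
        fs=fs,
        t=np.arange(omega.size) / fs,
    )


@pytest.fixture
def time_30s():
    return np.arange(0.0, 30.0, 1.0 / FS)


@pytest.fixture
def time_60s():
    return np.arange(0.0, 60.0, 1.0 / FS)
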