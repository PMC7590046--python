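"""Reading and writing the delimited-text formats of the tool.

Input recordings are comma-separated text with a header row: a time column
in seconds (or none, with the sampling rate declared instead) and three
angular-velocity columns. Outputs are a JSON bout report, a per-swing CSV
table, and (from the simulator) a truth JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import GyroRecording
from .swing_detect import Swing
from .synthetic import SynthTruth

DEFAULT_COLUMNS = {"time": "time", "x": "gyro_x", "y": "gyro_y", "z": "gyro_z"}


class GapError(ValueError):
    """Raised when a recording contains NaN runs longer than the gap rule."""


def _nan_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal NaN run."""
    isnan = np.isnan(values)
    runs = []
    start = None
    for i, flag in enumerate(isnan):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, isnan.size - start))
    return runs


def read_gyro_csv(
    path: str | Path,
    columns: dict | None = None,
    units: str = "deg",
    fs: float | None = None,
    side: str = "left",
    max_gap_s: float = 0.25,
) -> GyroRecording:
    """Read one arm's gyroscope recording from a delimited text file.

    ``columns`` maps the roles ``time``/``x``/``y``/``z`` onto the file's
    header names (the ``time`` entry may be ``None`` when ``fs`` is given).
    ``units='rad'`` converts rad/s input to deg/s. Time stamps must be
    monotone and uniform; no resampling is attempted. NaN runs up to
    ``max_gap_s`` are filled by linear interpolation; longer gaps abort with
    a report of their locations.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path)
    needed = [cols[k] for k in ("x", "y", "z")]
    if cols.get("time") is not None and cols["time"] in df.columns:
        t = df[cols["time"]].to_numpy(dtype=float)
    elif fs is not None:
        t = np.arange(len(df)) / fs
    else:
        raise ValueError(
            f"no time column {cols.get('time')!r} in {path} and no sampling rate given"
        )
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing angular-velocity columns {missing} in {path}")
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0.0):
            raise ValueError(f"non-monotone time stamps in {path}")
        if fs is None:
            fs = 1.0 / float(np.median(dt))

    channels = {}
    for key in ("x", "y", "z"):
        v = df[cols[key]].to_numpy(dtype=float)
        runs = [r for r in _nan_runs(v)]
        long_runs = [(s, ln) for s, ln in runs if ln / fs > max_gap_s]
        if long_runs:
            desc = ", ".join(f"{ln / fs:.3f} s at t={t[s]:.3f} s" for s, ln in long_runs)
            raise GapError(
                f"{path}: column {cols[key]!r} has NaN gaps longer than "
                f"{max_gap_s} s ({desc}); segment rejected"
            )
        if runs:
            good = ~np.isnan(v)
            v = np.interp(t, t[good], v[good])
        if units == "rad":
            v = np.degrees(v)
        elif units != "deg":
            raise ValueError(f"unknown units {units!r}; expected 'deg' or 'rad'")
        channels[key] = v
    return GyroRecording(
        t=t, omega_x=channels["x"], omega_y=channels["y"], omega_z=channels["z"],
        fs=float(fs), side=side, label=str(path),
    )


def write_gyro_csv(path: str | Path, rec: GyroRecording) -> None:
    pd.DataFrame(
        {
            "time": rec.t,
            "gyro_x": rec.omega_x,
            "gyro_y": rec.omega_y,
            "gyro_z": rec.omega_z,
        }
    ).to_csv(path, index=False)


def swings_to_frame(swings: list[Swing], side: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "side": side,
            "t_start": [s.t_start for s in swings],
            "t_end": [s.t_end for s in swings],
            "duration": [s.duration for s in swings],
            "amplitude": [s.amplitude for s in swings],
            "peak_omega": [s.peak_omega for s in swings],
            "direction": [s.direction for s in swings],
            "retained": [s.retained for s in swings],
            "reject_reason": [s.reject_reason for s in swings],
        }
    )


def write_truth_json(path: str | Path, truth: SynthTruth) -> None:
    def arm(a):
        return {
            "intervals": [[float(x), float(y)] for x, y in a.intervals],
            "amplitudes": [float(v) for v in a.amplitudes],
            "peak_velocities": [float(v) for v in a.peak_velocities],
        }

    payload = {
        "left": arm(truth.left),
        "right": arm(truth.right),
        "asi_amplitude": float(truth.asi_amplitude),
        "phase_offset": float(truth.phase_offset),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report_json(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
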