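"""Analysis configuration: every tunable of the pipeline in one place.

The defaults are the algorithm's published operating point; all of them can
be overridden from a YAML file or command-line flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    fs_override: float | None = None  # Hz; use when the file has no time column
    units: str = "deg"  # "deg" or "rad": unit of the input angular velocities
    cutoff: float = 3.0  # Hz low-pass cutoff
    band_low: float = 0.3  # Hz, admissible swing band
    band_high: float = 3.0
    power_gate: float = 0.90  # min in-band share of non-DC window power
    fft_window_s: float = 3.0  # s, spectral/peak window length
    fft_overlap_freq: float = 0.75  # overlap of the frequency windows
    fft_overlap_peaks: float = 0.5  # overlap of the peak-detection windows
    prominence: float = 2.0  # deg, min extremum prominence
    min_distance_frac: float = 0.6  # of the per-window cycle time
    long_swing_factor: float = 2.0  # x average cycle time
    outlier_factor: float = 3.0  # x the outlier percentile
    outlier_percentile: float = 80.0
    amp_threshold: float = 5.0  # deg
    vel_threshold: float = 10.0  # deg/s
    regularity_window_s: float = 4.5
    regularity_cosine_fraction: float = 0.3
    regularity_overlap: float = 0.99
    simultaneity_tol_s: float = 0.5
    eligibility: float = 0.60  # min simultaneous fraction for bilateral indices
    max_gap_s: float = 0.25  # longest NaN run repaired by the reader

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
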