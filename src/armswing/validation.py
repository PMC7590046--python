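"""Method-agreement statistics for paired swing measurements.

Used to compare a measured swing series against a reference series of the
same swings (here: pipeline output against synthetic ground truth; in a lab
setting, a wearable against an optical reference). The statistics are the
Bland-Altman systematic error (mean difference, test minus reference), the
random error (half-width of the 95% limits of agreement, 1.96 x SD of the
differences), the mean absolute error, and the root-mean-square error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .swing_detect import Swing


@dataclass
class AgreementStats:
    rmse: float
    systematic_error: float
    random_error: float
    absolute_error: float
    n: int


def agreement(test: np.ndarray, reference: np.ndarray) -> AgreementStats:
    """Bland-Altman agreement statistics on equal-length paired values.

    Differences are test - reference. The random error uses the sample
    standard deviation (n-1 denominator).
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("test and reference must be paired (equal length)")
    if test.size < 2:
        raise ValueError("agreement statistics need at least 2 pairs")
    d = test - reference
    return AgreementStats(
        rmse=float(np.sqrt(np.mean(d**2))),
        systematic_error=float(np.mean(d)),
        random_error=float(1.96 * np.std(d, ddof=1)),
        absolute_error=float(np.mean(np.abs(d))),
        n=int(d.size),
    )


def match_swings(
    detected: list[Swing],
    truth_intervals: list[tuple[float, float]],
    max_offset: float = 0.25,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest-midpoint matching of detected swings to truth intervals.

    Candidate pairs are ranked by midpoint distance and accepted greedily
    while both members are unused and the distance is within ``max_offset``
    seconds. Returns (matches as (detected_idx, truth_idx) pairs, unmatched
    detected indices, unmatched truth indices).
    """
    det_mid = np.array([(s.t_start + s.t_end) / 2.0 for s in detected])
    tru_mid = np.array([(a + b) / 2.0 for a, b in truth_intervals])
    pairs = [
        (abs(det_mid[i] - tru_mid[j]), i, j)
        for i in range(det_mid.size)
        for j in range(tru_mid.size)
        if abs(det_mid[i] - tru_mid[j]) <= max_offset
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        matches.append((i, j))
        used_d.add(i)
        used_t.add(j)
    matches.sort(key=lambda m: m[1])
    unmatched_d = [i for i in range(det_mid.size) if i not in used_d]
    unmatched_t = [j for j in range(tru_mid.size) if j not in used_t]
    return matches, unmatched_d, unmatched_t
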