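"""Quick-look plots of a processed arm."""

from __future__ import annotations

import numpy as np

from .pipeline import ArmResult


def plot_arm(result: ArmResult, ax=None):
    """Detrended swing angle with retained/rejected swing extents.

    Returns the matplotlib axes (created on demand)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    if result.angle is None:
        ax.set_title(f"{result.summary.side}: {result.status}")
        return ax
    fs = result.angle.fs
    t = np.arange(result.angle.alpha.size) / fs
    ax.plot(t, result.angle.alpha_detrend, lw=0.8, color="k", label="detrended angle")
    for s in result.swings:
        color = "tab:green" if s.retained else "tab:red"
        ax.axvspan(s.t_start, s.t_end, color=color, alpha=0.15)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("angle [deg]")
    ax.set_title(
        f"{result.summary.side} arm: {result.summary.n_swings} retained swings"
    )
    ax.legend(loc="upper right", fontsize="small")
    return ax
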