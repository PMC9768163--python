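"""Optional figure helpers over simulation trajectories.

Thin layer above the recorded arrays: spaghetti plots of per-agent
opinions with amplification events marked, and conflict curves with the
uniform-initialization reference level. Requires matplotlib (not a core
dependency).
"""

from __future__ import annotations

import numpy as np

UNIFORM_BASELINE = 1 / np.sqrt(3)


def plot_trajectory(traj, ax=None, ylim=(-2.0, 2.0)):
    """Per-agent opinion curves; red dots mark amplification events, green
    dots broadcast external opinions, grey bands the region outside the
    initial [-1, 1] opinion range."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.arange(traj.opinions.shape[0])
    ax.plot(t, traj.opinions, lw=0.5, alpha=0.6, color="tab:blue")
    rt, ra = np.nonzero(traj.amplified)
    ax.plot(rt, traj.opinions[rt, ra], ".", ms=2, color="tab:red")
    for ts, ext in enumerate(traj.externals):
        if len(ext):
            ax.plot([ts] * len(ext), ext, ".", ms=3, color="tab:green")
    if ylim is not None:
        ax.set_ylim(*ylim)
        ax.axhspan(1.0, ylim[1], color="0.85", zorder=0)
        ax.axhspan(ylim[0], -1.0, color="0.85", zorder=0)
    ax.set_xlabel("timestep")
    ax.set_ylabel("opinion")
    return ax


def plot_conflict(traj, ax=None):
    """Conflict (population opinion SD) over time with the 0.577 uniform
    baseline as a dotted reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(len(traj.conflict)), traj.conflict, color="tab:blue")
    ax.axhline(UNIFORM_BASELINE, ls=":", color="0.5")
    ax.set_xlabel("timestep")
    ax.set_ylabel("conflict (opinion SD)")
    return ax
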