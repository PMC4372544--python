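"""Minimal trajectory plotting (relative abundance vs events/time)."""

from __future__ import annotations

from .core import Trajectory

__all__ = ["plot_trajectory"]


def plot_trajectory(traj: Trajectory, ax=None, **kwargs):
    """Line plot of each taxon's relative abundance along the trajectory.

    Returns the matplotlib Axes.  Extra keyword arguments are forwarded to
    ``Axes.plot``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rel = traj.rel_abundance
    for i, label in enumerate(traj.taxa.labels):
        ax.plot(traj.index, rel[:, i], label=label, **kwargs)
    ax.set_xlabel("events" if traj.kind == "discrete" else "time (diffusion units)")
    ax.set_ylabel("relative abundance")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return ax
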