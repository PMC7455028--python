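"""Static matplotlib figures for runs and analyses."""

from __future__ import annotations

from typing import List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import Snapshot, TrajectoryRecord
from .state import Phenotype

__all__ = [
    "plot_growth_curve",
    "plot_snapshot",
    "plot_trajectory_fan",
    "plot_infiltration_histograms",
]

PHENOTYPE_COLORS = {
    int(Phenotype.PROLIFERATIVE): "#1f77b4",
    int(Phenotype.QUIESCENT): "#ff7f0e",
    int(Phenotype.HYPOXIC): "#9467bd",
    int(Phenotype.NECROTIC): "#7f7f7f",
}


def plot_growth_curve(times, radii, ax=None, **kw):
    """Spheroid radius versus time."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(times, radii, **kw)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("spheroid radius (cell diameters)")
    return ax


def plot_snapshot(snapshot: Snapshot, ax=None):
    """Agent scatter coloured by phenotype; beads in yellow."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for ph, color in PHENOTYPE_COLORS.items():
        m = snapshot.cell_phenotype == ph
        if m.any():
            ax.scatter(*snapshot.cell_pos[m].T, s=6, c=color,
                       label=Phenotype(ph).name.lower())
    if snapshot.bead_pos.shape[0]:
        ax.scatter(*snapshot.bead_pos.T, s=10, c="gold", label="bead")
    ax.set_aspect("equal")
    ax.legend(fontsize=7, loc="upper right")
    ax.set_title(f"t = {snapshot.time:.0f} h")
    return ax


def plot_trajectory_fan(
    trajectories: Sequence[TrajectoryRecord],
    spheroid_radius: Optional[np.ndarray] = None,
    thresholds: Optional[np.ndarray] = None,
    times: Optional[np.ndarray] = None,
    n_show: int = 15,
    ax=None,
):
    """Radial bead trajectories with the spheroid radius and regime threshold."""
    if ax is None:
        _, ax = plt.subplots()
    for tr in trajectories[:n_show]:
        ax.plot(tr.times, tr.r, lw=0.8, alpha=0.8)
    if times is not None and spheroid_radius is not None:
        ax.plot(times, spheroid_radius, "k-", lw=2, label="spheroid radius")
    if times is not None and thresholds is not None:
        ax.plot(times, thresholds, "k--", lw=1.5, label="regime threshold")
    ax.set_xlabel("time since bead addition (h)")
    ax.set_ylabel("radial distance (cell diameters)")
    ax.legend(fontsize=8)
    return ax


def plot_infiltration_histograms(
    snapshots: List[Snapshot], timepoints: Sequence[float], t_added: float,
    bin_width: float = 1.0,
):
    """Panel of bead depth histograms at the requested times after addition."""
    from .analysis import infiltration_histogram

    fig, axes = plt.subplots(1, len(timepoints), figsize=(3 * len(timepoints), 3),
                             sharey=True)
    for ax, tp in zip(np.atleast_1d(axes), timepoints):
        snap = min(snapshots, key=lambda s: abs(s.time - (t_added + tp)))
        edges, freq = infiltration_histogram(snap, bin_width)
        ax.bar(edges[:-1], freq, width=bin_width, align="edge")
        ax.set_title(f"{tp:.0f} h")
        ax.set_xlabel("depth below edge")
    np.atleast_1d(axes)[0].set_ylabel("frequency")
    fig.tight_layout()
    return fig
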