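"""Bead-trajectory summary statistics and spheroid composition metrics.

Bead infiltration has two regimes: near the spheroid edge a bead is
jostled by proliferating cells and moves diffusively; once it is carried
deep enough, the cellular flow created by peripheral proliferation and
central cell death advects it inward at a roughly constant radial speed.
The regime boundary at time t after bead addition is estimated as

    threshold(t) = 0.9 * R(t) - 2 * sqrt(D_est * t)

where R is the spheroid radius and D_est the diffusion coefficient
estimated from the beads' first hours of radial motion (the 0.9 factor
keeps freshly added beads on the Brownian side at t = 0). Per bead, the
waiting time T_wait is the time to first cross this threshold, and the
radial infiltration velocity V_r (inward positive) is the mean radial
speed from that crossing until the bead reaches the necrotic core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .engine import Snapshot, TrajectoryRecord
from .state import Phenotype

__all__ = [
    "BeadSummary",
    "CompositionSummary",
    "PopulationMeans",
    "estimate_D",
    "regime_threshold",
    "summarise_bead",
    "population_means",
    "infiltration_histogram",
    "composition_summary",
    "plateau_onset",
]


@dataclass
class BeadSummary:
    """Derived per-bead statistics (None marks an undefined quantity)."""

    bead_id: int
    t_cross: Optional[float]
    T_wait: Optional[float]
    V_r: Optional[float]
    core_reached: bool = False


@dataclass
class CompositionSummary:
    """Radial compartment structure of one snapshot.

    Widths follow the outermost-minus-innermost convention per phenotype;
    areas use the concentric-annulus approximation pi*(r_out^2 - r_in^2);
    the total area is pi*R^2 with R the spheroid radius.
    """

    widths: Dict[int, float]
    inner: Dict[int, float]
    outer: Dict[int, float]
    areas: Dict[int, float]
    A_total: float
    quiescent_proportion: float

    @property
    def proportions(self) -> Dict[int, float]:
        if self.A_total <= 0:
            return {k: 0.0 for k in self.areas}
        return {k: min(1.0, v / self.A_total) for k, v in self.areas.items()}


@dataclass
class PopulationMeans:
    """Arithmetic means of the defined per-bead statistics."""

    V_r: float
    n_V: int
    T_wait: float
    n_T: int


def estimate_D(trajectories: Sequence[TrajectoryRecord], window: float = 5.0) -> float:
    """Estimate the Brownian coefficient from early radial displacements.

    Averages (dr)^2 / (2 dt) over all beads and all consecutive sample
    intervals whose endpoints lie within ``window`` hours of bead
    addition — the 1D estimator matching an expected displacement of
    2*sqrt(D t). On purely advective motion at speed v it returns the
    documented plug-in bias v^2 dt / 2.
    """
    increments = []
    for traj in trajectories:
        m = traj.times <= window
        t = traj.times[m]
        r = traj.r[m]
        if t.size < 2:
            continue
        dt = np.diff(t)
        dr = np.diff(r)
        increments.append(dr**2 / (2.0 * dt))
    if not increments:
        raise ValueError("no trajectory has >= 2 samples inside the estimation window")
    return float(np.concatenate(increments).mean())


def regime_threshold(R: float, t: float, D_est: float):
    """Brownian/advection regime boundary 0.9 R - 2 sqrt(D_est t), floored at 0."""
    R = np.asarray(R, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("time since bead addition must be nonnegative")
    if np.any(np.asarray(D_est) < 0):
        raise ValueError("D_est must be nonnegative")
    out = np.maximum(0.0, 0.9 * R - 2.0 * np.sqrt(D_est * t))
    return float(out) if out.ndim == 0 else out


def summarise_bead(
    trajectory: TrajectoryRecord,
    thresholds: np.ndarray,
    necrotic_radius: np.ndarray,
    allow_end_fallback: bool = False,
) -> BeadSummary:
    """Segment one bead trajectory into waiting and advection phases.

    ``thresholds`` and ``necrotic_radius`` must be aligned sample-for-
    sample with ``trajectory.times``. The crossing time is the first
    sample with r < threshold; the core-arrival time is the first later
    sample with r <= necrotic radius. With ``allow_end_fallback`` (for
    spheroids that never develop a necrotic core) the trajectory end
    substitutes for core arrival and the summary is flagged.
    """
    t = trajectory.times
    r = trajectory.r
    thresholds = np.asarray(thresholds)
    necrotic_radius = np.asarray(necrotic_radius)
    if t.size == 0:
        raise ValueError("empty trajectory")
    if thresholds.shape != t.shape or necrotic_radius.shape != t.shape:
        raise ValueError("threshold/necrotic series misaligned with trajectory times")

    below = r < thresholds
    if not below.any():
        return BeadSummary(trajectory.bead_id, None, None, None, False)
    i_cross = int(np.argmax(below))
    t_cross = float(t[i_cross])
    T_wait = t_cross - float(t[0])

    in_core = (r <= necrotic_radius) & (np.arange(t.size) >= i_cross)
    if in_core.any():
        i_core = int(np.argmax(in_core))
        core_reached = True
    elif allow_end_fallback:
        i_core = t.size - 1
        core_reached = False
    else:
        return BeadSummary(trajectory.bead_id, t_cross, T_wait, None, False)
    if i_core <= i_cross:
        # already at the core when crossing: no advection phase to average
        return BeadSummary(trajectory.bead_id, t_cross, T_wait, None, core_reached)
    V_r = float((r[i_cross] - r[i_core]) / (t[i_core] - t[i_cross]))
    return BeadSummary(trajectory.bead_id, t_cross, T_wait, V_r, core_reached)


def population_means(summaries: Sequence[BeadSummary]) -> PopulationMeans:
    """Means of V_r and T_wait over beads where each is defined."""
    v = [s.V_r for s in summaries if s.V_r is not None]
    w = [s.T_wait for s in summaries if s.T_wait is not None]
    if not v and not w:
        raise ValueError("no bead has a defined V_r or T_wait")
    if not w:
        raise ValueError("no bead has a defined T_wait")
    if not v:
        raise ValueError("no bead has a defined V_r")
    return PopulationMeans(
        V_r=float(np.mean(v)), n_V=len(v), T_wait=float(np.mean(w)), n_T=len(w)
    )


def infiltration_histogram(snapshot: Snapshot, bin_width: float = 1.0):
    """Relative-frequency histogram of bead depth below the spheroid edge.

    Depth is (spheroid radius - bead radial distance), clipped at zero for
    beads still outside the edge. Returns ``(bin_edges, frequencies)``
    with frequencies summing to 1.
    """
    if snapshot.bead_pos.shape[0] == 0:
        raise ValueError("snapshot contains no beads")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    depth = np.maximum(0.0, snapshot.radius - snapshot.bead_r)
    n_bins = max(1, int(np.ceil(max(depth.max(), bin_width) / bin_width)))
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(depth, bins=edges)
    # depth == last edge falls in the final bin via histogram's closed right edge
    freq = counts / counts.sum()
    return edges, freq


def composition_summary(snapshot: Snapshot) -> CompositionSummary:
    """Concentric-annulus compartment widths, areas and proportions."""
    if snapshot.cell_pos.shape[0] < 3:
        raise ValueError("composition summary requires >= 3 cells")
    r = snapshot.cell_r
    R = snapshot.radius
    widths: Dict[int, float] = {}
    inner: Dict[int, float] = {}
    outer: Dict[int, float] = {}
    areas: Dict[int, float] = {}
    for ph in Phenotype:
        m = snapshot.cell_phenotype == int(ph)
        if m.any():
            r_in = float(r[m].min())
            r_out = float(r[m].max())
        else:
            r_in = r_out = 0.0
        inner[int(ph)] = r_in
        outer[int(ph)] = r_out
        widths[int(ph)] = r_out - r_in
        areas[int(ph)] = np.pi * (r_out**2 - r_in**2)
    A_total = np.pi * R**2
    q = areas[int(Phenotype.QUIESCENT)] / A_total if A_total > 0 else 0.0
    return CompositionSummary(
        widths=widths,
        inner=inner,
        outer=outer,
        areas=areas,
        A_total=float(A_total),
        quiescent_proportion=float(np.clip(q, 0.0, 1.0)),
    )


def plateau_onset(
    times: np.ndarray,
    radii: np.ndarray,
    window: float = 10.0,
    horizon: float = 20.0,
    rel_tol: float = 0.005,
    burn_in: float = 4.0,
) -> Optional[float]:
    """Detect growth saturation on a radius-versus-time curve.

    The curve is smoothed with a trailing rolling mean over ``window``
    hours; the plateau onset is the earliest time t >= burn_in at which
    the smoothed radius changes by less than ``rel_tol`` (relative) over
    the following ``horizon`` hours. Returns None if no plateau is found.
    Growth-curve metrics ignore the initial burn-in during which the
    seeded cells relax into a packed cluster.
    """
    times = np.asarray(times, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if times.size != radii.size or times.size < 3:
        raise ValueError("times and radii must be equal-length series (>= 3 samples)")
    order = np.argsort(times)
    times, radii = times[order], radii[order]
    smooth = np.empty_like(radii)
    for k in range(times.size):
        m = (times <= times[k]) & (times > times[k] - window)
        smooth[k] = radii[m].mean()
    for k in range(times.size):
        t = times[k]
        if t < burn_in:
            continue
        if t + horizon > times[-1]:
            break
        j = int(np.searchsorted(times, t + horizon))
        j = min(j, times.size - 1)
        if smooth[k] > 0 and abs(smooth[j] - smooth[k]) / smooth[k] < rel_tol:
            return float(t)
    return None
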