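"""Main simulation loop and the three experiment protocols.

Protocols: (i) spheroid growth from a seeded disc of cells; (ii) passive
microbead infiltration into a well-developed spheroid; (iii) heritable
labelling of boundary cells. Each timestep updates, in order: spheroid
boundary (alpha-shape) and oxygen field (every ``pde_stride`` steps),
phenotypes, oxygen-gated clocks, necrosis, divisions, sizes, removals,
then assembles forces and advances positions by forward Euler.

Performance notes: the population lives in structure-of-arrays form and
every per-step update is vectorised. The neighbour pair list is cached
with a Verlet skin and rebuilt only when accumulated movement could let an
unseen pair enter the interaction radius (the resulting forces are exactly
those of a fresh neighbour search).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy.spatial import cKDTree

from . import cells as celldyn
from . import mechanics as mech
from . import oxygen as oxy
from .state import (
    BeadArrays,
    CellArrays,
    Phenotype,
    SimulationConfig,
    SpheroidState,
)

__all__ = [
    "Snapshot",
    "TrajectoryRecord",
    "InfiltrationResult",
    "initialise_growth",
    "step",
    "run_growth",
    "add_beads",
    "run_infiltration",
    "add_labels",
    "run_labelled",
    "growth_curve",
    "Simulation",
]

#: Verlet-skin width added to the interaction radius for the cached pair list
_SKIN = 0.6


@dataclass
class Snapshot:
    """State summary at one output time."""

    time: float
    cell_ids: np.ndarray
    cell_pos: np.ndarray
    cell_phenotype: np.ndarray
    cell_s: np.ndarray
    cell_labelled: np.ndarray
    bead_ids: np.ndarray
    bead_pos: np.ndarray
    centroid: np.ndarray
    radius: float
    compartment_outer: Dict[int, float]

    @property
    def cell_r(self) -> np.ndarray:
        """Radial distance of each cell from the snapshot centroid."""
        d = self.cell_pos - self.centroid
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def bead_r(self) -> np.ndarray:
        d = self.bead_pos - self.centroid
        return np.hypot(d[:, 0], d[:, 1])


@dataclass
class TrajectoryRecord:
    """Per-bead radial time series (times relative to bead addition)."""

    bead_id: int
    times: np.ndarray
    r: np.ndarray
    omega: np.ndarray


@dataclass
class InfiltrationResult:
    """Snapshots plus bead trajectories and aligned reference series.

    ``times`` (hours since bead addition), ``spheroid_radius`` and
    ``necrotic_radius`` share the trajectory sampling grid;
    ``necrotic_radius`` is 0 where no necrotic cell exists. Unpacks as
    ``(snapshots, trajectories)`` for convenience.
    """

    snapshots: List[Snapshot]
    trajectories: List[TrajectoryRecord]
    times: np.ndarray
    spheroid_radius: np.ndarray
    necrotic_radius: np.ndarray
    final_state: Optional[SpheroidState] = None

    def __iter__(self):
        return iter((self.snapshots, self.trajectories))


def take_snapshot(state: SpheroidState) -> Snapshot:
    centroid = state.centroid
    d = state.cells.pos - centroid
    r = np.hypot(d[:, 0], d[:, 1]) if len(state.cells) else np.zeros(0)
    outer: Dict[int, float] = {}
    for ph in Phenotype:
        m = state.cells.phenotype == int(ph)
        outer[int(ph)] = float(r[m].max()) if m.any() else 0.0
    return Snapshot(
        time=state.t,
        cell_ids=state.cells.ids.copy(),
        cell_pos=state.cells.pos.copy(),
        cell_phenotype=state.cells.phenotype.copy(),
        cell_s=state.cells.s.copy(),
        cell_labelled=state.cells.labelled.copy(),
        bead_ids=state.beads.ids.copy(),
        bead_pos=state.beads.pos.copy(),
        centroid=centroid.copy(),
        radius=float(r.max()) if r.size else 0.0,
        compartment_outer=outer,
    )


def initialise_growth(cfg: SimulationConfig, rng: np.random.Generator) -> SpheroidState:
    """Seed the growth protocol: cells uniform in a disc, desynchronised.

    Positions are uniform over the disc of radius ``r_init``; each cell
    starts proliferative with cycle clock ~ U(0, 0.75 tau) and assigned
    durations ~ U(0.75 m, 1.25 m) of their respective means.
    """
    n = cfg.n_init_cells
    cells = CellArrays(n)
    radii = cfg.r_init * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    cells.ids = np.arange(n, dtype=np.int64)
    cells.pos = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    cells.phenotype[:] = int(Phenotype.PROLIFERATIVE)
    cells.T_cycle = rng.uniform(0.0, 0.75 * cfg.tau, n)
    cells.tau_i = rng.uniform(0.75 * cfg.tau, 1.25 * cfg.tau, n)
    cells.T_hyp[:] = 0.0
    cells.tau_hyp_i = rng.uniform(0.75 * cfg.tau_hyp, 1.25 * cfg.tau_hyp, n)
    cells.tau_nec_i = rng.uniform(0.75 * cfg.tau_nec, 1.25 * cfg.tau_nec, n)
    cells.s[:] = cfg.R_cell
    cells.s_birth[:] = cfg.R_cell
    cells.t_birth[:] = 0.0
    return SpheroidState(t=0.0, cells=cells, beads=BeadArrays(0), rng=rng, next_cell_id=n)


class Simulation:
    """Stateful stepper wrapping a :class:`SpheroidState` with caches."""

    def __init__(
        self,
        cfg: SimulationConfig,
        state: Optional[SpheroidState] = None,
        rng: Optional[np.random.Generator] = None,
        log_transitions: bool = False,
    ):
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.state = state if state is not None else initialise_growth(cfg, self.rng)
        if self.state.rng is None:
            self.state.rng = self.rng
        self.log_transitions = log_transitions
        self.transitions: list = []
        self.step_count = 0
        self._field: Optional[oxy.OxygenField] = None
        self._pairs: Optional[np.ndarray] = None
        self._drift = np.inf  # accumulated max displacement since pair build
        self._topology_changed = True
        self._omega_cells = np.zeros(0)

    # -- caches ------------------------------------------------------------

    def _refresh_boundary_and_oxygen(self) -> None:
        cfg, state = self.cfg, self.state
        if len(state.cells) == 0:
            state.boundary_ids = np.zeros(0, dtype=np.int64)
            self._field = None
            return
        complex_ = mech.alpha_complex(state.cells.pos, cfg.alpha)
        state.boundary_ids = np.sort(state.cells.ids[complex_[2]])
        fld = self._field
        pts = state.cells.pos
        if len(state.beads):
            pts = np.vstack([pts, state.beads.pos])
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        if (
            fld is None
            or lo[0] < fld.x0 + 1.0
            or lo[1] < fld.y0 + 1.0
            or hi[0] > fld.xmax - 1.0
            or hi[1] > fld.ymax - 1.0
        ):
            fld = oxy.build_mesh(state, cfg.mesh_spacing, cfg.mesh_margin)
            self._field = fld
        oxy.classify_dirichlet(fld, state, cfg.alpha, complex_=complex_)
        oxy.solve_oxygen(fld, state, cfg)

    def _cell_oxygen(self) -> np.ndarray:
        state = self.state
        if self._field is None or self._field.node_values is None:
            return np.full(len(state.cells), self.cfg.omega_inf)
        return oxy.interpolate_fast(self._field, state.cells.pos)

    def _pair_list(self) -> np.ndarray:
        cfg, state = self.cfg, self.state
        if self._pairs is None or self._topology_changed or self._drift >= _SKIN / 2.0:
            pos, _, _, _ = mech._agent_arrays(state)
            if pos.shape[0] >= 2:
                tree = cKDTree(pos)
                self._pairs = tree.query_pairs(cfg.R_int + _SKIN, output_type="ndarray")
            else:
                self._pairs = np.zeros((0, 2), dtype=np.int64)
            self._drift = 0.0
            self._topology_changed = False
        return self._pairs

    # -- one timestep ------------------------------------------------------

    def step(self) -> SpheroidState:
        cfg, state, rng = self.cfg, self.state, self.rng
        if len(state.cells) > 0:
            if self.step_count % cfg.pde_stride == 0 or self._topology_changed:
                self._refresh_boundary_and_oxygen()
            omega = self._cell_oxygen()
            # 1-2: phenotype from oxygen; 3: clocks; 4: necrosis onset
            old_ph = celldyn.update_phenotype_arrays(state.cells, omega, cfg)
            if self.log_transitions:
                self._log_changes(old_ph, "oxygen")
            celldyn.advance_timers_arrays(state.cells, omega, cfg.dt, cfg)
            turned = celldyn.necrose_arrays(state.cells, state.t)
            if self.log_transitions and turned.any():
                for i in np.flatnonzero(turned):
                    self.transitions.append(
                        celldyn.PhenotypeTransition(
                            cell_id=int(state.cells.ids[i]),
                            from_phenotype=Phenotype.HYPOXIC,
                            to_phenotype=Phenotype.NECROTIC,
                            time=state.t,
                            trigger="timer",
                        )
                    )
            # 5: divisions
            divide = state.cells.viable & (state.cells.T_cycle >= state.cells.tau_i)
            if divide.any():
                self._divide(np.flatnonzero(divide))
            # 6: sizes; 7: removals
            celldyn.update_size_arrays(state.cells, state.t, cfg)
            gone = state.cells.s <= 0.0
            if gone.any():
                state.cells.delete(gone)
                self._topology_changed = True
            # mechanics
            pairs = self._pair_list()
            pos, s, scale, is_bead = mech._agent_arrays(state)
            forces = mech._pair_forces_fast(pos, s, scale, is_bead, pairs, cfg, rng)
            forces += mech.random_forces(state, cfg, rng)
            forces += mech.surface_tension_forces(state, cfg)
            mech.advance_positions(state, forces, cfg)
            disp = (cfg.dt / cfg.nu) * forces
            self._drift += float(np.sqrt((disp * disp).sum(axis=1).max())) if disp.size else 0.0
        elif len(state.beads) > 0:
            # beads alone keep jostling (pure Brownian plus bead-bead contact)
            pairs = self._pair_list()
            pos, s, scale, is_bead = mech._agent_arrays(state)
            forces = mech._pair_forces_fast(pos, s, scale, is_bead, pairs, cfg, rng)
            forces += mech.random_forces(state, cfg, rng)
            mech.advance_positions(state, forces, cfg)
            disp = (cfg.dt / cfg.nu) * forces
            self._drift += float(np.sqrt((disp * disp).sum(axis=1).max())) if disp.size else 0.0
        state.t += cfg.dt
        self.step_count += 1
        return state

    def _log_changes(self, old_ph: np.ndarray, trigger: str) -> None:
        state = self.state
        changed = np.flatnonzero(old_ph != state.cells.phenotype)
        for i in changed:
            self.transitions.append(
                celldyn.PhenotypeTransition(
                    cell_id=int(state.cells.ids[i]),
                    from_phenotype=Phenotype(int(old_ph[i])),
                    to_phenotype=Phenotype(int(state.cells.phenotype[i])),
                    time=state.t,
                    trigger=trigger,
                )
            )

    def _divide(self, idx: np.ndarray) -> None:
        cfg, state, rng = self.cfg, self.state, self.rng
        m = idx.size
        cells = state.cells
        theta = rng.uniform(0.0, 2.0 * np.pi, m)
        offset = 0.5 * np.column_stack([np.cos(theta), np.sin(theta)])
        daughters = CellArrays(m)
        daughters.ids = state.next_cell_id + np.arange(m, dtype=np.int64)
        daughters.pos = cells.pos[idx] + offset
        daughters.phenotype = cells.phenotype[idx].copy()
        daughters.T_cycle[:] = 0.0
        daughters.tau_i = rng.uniform(0.75 * cfg.tau, 1.25 * cfg.tau, m)
        daughters.T_hyp[:] = 0.0
        daughters.tau_hyp_i = rng.uniform(0.75 * cfg.tau_hyp, 1.25 * cfg.tau_hyp, m)
        daughters.tau_nec_i = rng.uniform(0.75 * cfg.tau_nec, 1.25 * cfg.tau_nec, m)
        daughters.s[:] = cfg.R_cell / 2.0
        daughters.s_birth[:] = cfg.R_cell / 2.0
        daughters.t_birth[:] = state.t
        daughters.labelled = cells.labelled[idx].copy()
        state.next_cell_id += m
        # parents redraw their cycle duration and reset their clock
        cells.T_cycle[idx] = 0.0
        cells.tau_i[idx] = rng.uniform(0.75 * cfg.tau, 1.25 * cfg.tau, m)
        if cfg.shrink_parent_at_division:
            cells.s[idx] = cfg.R_cell / 2.0
            cells.s_birth[idx] = cfg.R_cell / 2.0
            cells.t_birth[idx] = state.t
        cells.append(daughters)
        self._topology_changed = True

    # -- protocol loops ----------------------------------------------------

    def run(self, duration: float, snapshot_every: Optional[float] = None,
            snapshots: Optional[List[Snapshot]] = None) -> List[Snapshot]:
        cfg = self.cfg
        n_steps = int(round(duration / cfg.dt))
        snap_stride = (
            max(1, int(round(snapshot_every / cfg.dt))) if snapshot_every else None
        )
        out = snapshots if snapshots is not None else []
        if snap_stride is not None and not out:
            out.append(take_snapshot(self.state))
        for k in range(n_steps):
            self.step()
            if snap_stride is not None and (k + 1) % snap_stride == 0:
                snap = take_snapshot(self.state)
                out.append(snap)
                if snap.radius > cfg.radius_cap:
                    raise RuntimeError(
                        f"spheroid radius {snap.radius:.1f} exceeded cap "
                        f"{cfg.radius_cap} at t={self.state.t:.1f} h"
                    )
        return out


def step(
    state: SpheroidState, cfg: SimulationConfig, rng: np.random.Generator
) -> SpheroidState:
    """Advance a bare state by one timestep (stateless convenience wrapper)."""
    sim = Simulation(cfg, state=state, rng=rng)
    return sim.step()


def run_growth(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    return_sim: bool = False,
):
    """Run the growth protocol for ``t_grow`` hours.

    Returns the list of snapshots (cadence ``snapshot_every``); with
    ``return_sim=True`` returns ``(snapshots, Simulation)`` so a caller can
    continue with the infiltration or labelling protocols.
    """
    sim = Simulation(cfg, rng=rng)
    snaps = sim.run(cfg.t_grow, snapshot_every=cfg.snapshot_every)
    return (snaps, sim) if return_sim else snaps


def add_beads(
    state: SpheroidState, cfg: SimulationConfig, rng: np.random.Generator
) -> SpheroidState:
    """Distribute ``n_beads`` microbeads around the spheroid edge.

    ``edge`` placement puts beads at uniformly random angles on the circle
    of radius (spheroid radius + bead radius); ``annulus`` placement draws
    radii uniformly from [R, R+1].
    """
    if cfg.n_beads == 0:
        return state
    if len(state.cells) < 3:
        raise ValueError("cannot add beads to a degenerate spheroid (< 3 cells)")
    R = state.radius
    centroid = state.centroid
    theta = rng.uniform(0.0, 2.0 * np.pi, cfg.n_beads)
    if cfg.bead_placement == "edge":
        radii = np.full(cfg.n_beads, R + cfg.R_cell)
    else:
        radii = rng.uniform(R, R + 1.0, cfg.n_beads)
    beads = BeadArrays(cfg.n_beads)
    beads.ids = np.arange(cfg.n_beads, dtype=np.int64)
    beads.pos = centroid + np.column_stack(
        [radii * np.cos(theta), radii * np.sin(theta)]
    )
    beads.t_added[:] = state.t
    state.beads = beads
    return state


def add_labels(
    state: SpheroidState, cfg: SimulationConfig, rng: np.random.Generator
) -> SpheroidState:
    """Mark ``n_labels`` randomly chosen boundary cells with a heritable label."""
    if cfg.n_labels == 0:
        return state
    idx = state.boundary_indices
    if idx.size == 0:
        _, _, bidx = mech.alpha_complex(state.cells.pos, cfg.alpha)
        state.boundary_ids = np.sort(state.cells.ids[bidx])
        idx = state.boundary_indices
    if idx.size < cfg.n_labels:
        raise ValueError(
            f"only {idx.size} boundary cells available for {cfg.n_labels} labels"
        )
    chosen = rng.choice(idx, size=cfg.n_labels, replace=False)
    state.cells.labelled[chosen] = True
    return state


def _necrotic_outer_radius(state: SpheroidState) -> float:
    m = ~state.cells.viable
    if not m.any():
        return 0.0
    d = state.cells.pos[m] - state.centroid
    return float(np.hypot(d[:, 0], d[:, 1]).max())


def run_infiltration(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> InfiltrationResult:
    """Growth, then bead addition, then ``t_beads`` hours of tracking.

    Bead radial positions (distance from the current centroid), local
    oxygen, the spheroid radius and the necrotic outer radius are sampled
    every ``traj_every`` hours starting at bead addition.
    """
    snaps, sim = run_growth(cfg, rng=rng, return_sim=True)
    state = sim.state
    add_beads(state, cfg, sim.rng)
    sim._topology_changed = True

    n_steps = int(round(cfg.t_beads / cfg.dt))
    rec_stride = max(1, int(round(cfg.traj_every / cfg.dt)))
    snap_stride = max(1, int(round(cfg.snapshot_every / cfg.dt)))
    t0 = state.t
    times: List[float] = []
    radius_series: List[float] = []
    necrotic_series: List[float] = []
    bead_r: List[np.ndarray] = []
    bead_omega: List[np.ndarray] = []

    def record() -> None:
        times.append(state.t - t0)
        radius_series.append(state.radius)
        necrotic_series.append(_necrotic_outer_radius(state))
        if len(state.beads):
            d = state.beads.pos - state.centroid
            bead_r.append(np.hypot(d[:, 0], d[:, 1]))
            if sim._field is not None and sim._field.node_values is not None:
                inside = sim._field.contains(state.beads.pos)
                om = np.full(len(state.beads), cfg.omega_inf)
                if inside.any():
                    om[inside] = oxy.interpolate(sim._field, state.beads.pos[inside])
                bead_omega.append(om)
            else:
                bead_omega.append(np.full(len(state.beads), cfg.omega_inf))
        else:
            bead_r.append(np.zeros(0))
            bead_omega.append(np.zeros(0))

    record()
    for k in range(n_steps):
        sim.step()
        if (k + 1) % rec_stride == 0:
            record()
        if (k + 1) % snap_stride == 0:
            snaps.append(take_snapshot(state))

    t_arr = np.asarray(times)
    trajectories = [
        TrajectoryRecord(
            bead_id=int(bid),
            times=t_arr.copy(),
            r=np.array([row[i] for row in bead_r]),
            omega=np.array([row[i] for row in bead_omega]),
        )
        for i, bid in enumerate(state.beads.ids)
    ]
    return InfiltrationResult(
        snapshots=snaps,
        trajectories=trajectories,
        times=t_arr,
        spheroid_radius=np.asarray(radius_series),
        necrotic_radius=np.asarray(necrotic_series),
        final_state=state,
    )


def run_labelled(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> List[Snapshot]:
    """Growth, then label boundary cells, then ``t_beads`` further hours."""
    snaps, sim = run_growth(cfg, rng=rng, return_sim=True)
    add_labels(sim.state, cfg, sim.rng)
    sim.run(cfg.t_beads, snapshot_every=cfg.snapshot_every, snapshots=snaps)
    return snaps


def growth_curve(snapshots: List[Snapshot]):
    """(times, radii) arrays from a snapshot list."""
    t = np.array([s.time for s in snapshots])
    r = np.array([s.radius for s in snapshots])
    return t, r
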