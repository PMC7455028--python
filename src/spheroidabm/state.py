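"""Domain types, unit conventions, configuration and the RNG contract.

All quantities are dimensionless: lengths are measured in cell diameters
(one diameter corresponds to approximately 20 micrometres), times in hours,
and oxygen is scaled so that the far-field (culture medium) level is 1.
Converters to SI units are provided for reporting but are never used
internally.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

__all__ = [
    "Phenotype",
    "SimulationConfig",
    "DEFAULTS",
    "make_config",
    "draw_duration",
    "Cell",
    "Microbead",
    "CellArrays",
    "BeadArrays",
    "SpheroidState",
    "to_micrometres",
    "to_seconds",
]

#: one cell diameter in micrometres
MICRONS_PER_DIAMETER = 20.0


def to_micrometres(length: float) -> float:
    """Convert a dimensionless length (cell diameters) to micrometres."""
    return length * MICRONS_PER_DIAMETER


def to_seconds(time: float) -> float:
    """Convert a dimensionless time (hours) to seconds."""
    return time * 3600.0


class Phenotype(IntEnum):
    """Tumour-cell phenotype compartments.

    A cell is PROLIFERATIVE while local oxygen exceeds the quiescence
    threshold, QUIESCENT between the hypoxia and quiescence thresholds,
    HYPOXIC at or below the hypoxia threshold, and NECROTIC (absorbing)
    once its hypoxia timer expires.
    """

    PROLIFERATIVE = 0
    QUIESCENT = 1
    HYPOXIC = 2
    NECROTIC = 3


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameter set for a simulation, in dimensionless units.

    Phenotype / kinetics
    --------------------
    omega_q : oxygen threshold for quiescence, in (0, 1].
    omega_h : oxygen threshold for hypoxia, in [0, omega_q].
    tau : mean cell-cycle duration (h); per-cell durations ~ U(0.75t, 1.25t).
    tau_hyp : mean hypoxic duration before necrosis onset (h).
    tau_nec : mean necrotic degradation duration (h).

    Mechanics
    ---------
    mu, mu_bead : spring stiffness for cell-involving and bead-bead pairs.
    lam : decay rate of the adhesive branch of the spring law.
    nu : drag coefficient (force = nu * velocity in the overdamped limit).
    beta : magnitude of the inward surface-tension force on boundary cells.
    D_rand : random-motion diffusion coefficient (diameter^2 / h).
    R_cell : equilibrium cell spring radius (0.5 diameters by convention).
    R_int : interaction cutoff distance between agent centres.

    Oxygen
    ------
    D_oxy : oxygen diffusion coefficient.
    kappa : per-cell oxygen consumption rate (point-sink strength).
    omega_inf : boundary oxygen level (1 by the nondimensionalisation).
    mesh_spacing : oxygen grid node spacing.
    mesh_margin : domain margin beyond the outermost agent.
    pde_stride : timesteps between oxygen re-solves (and boundary updates).

    Protocol
    --------
    dt : timestep (h); 1/120 h corresponds to 30 s.
    n_init_cells, r_init : initial seeding (cells uniform in a disc).
    t_grow : growth phase duration (h).
    n_beads, t_beads : bead count and infiltration duration (h).
    n_labels : number of boundary cells to mark in the labelling protocol.
    seed : RNG seed; a single seeded generator is threaded everywhere.
    """

    omega_q: float = 0.5
    omega_h: float = 0.3
    tau: float = 16.0
    tau_hyp: float = 8.0
    tau_nec: float = 8.0

    mu: float = 15.0
    mu_bead: float = 15.0
    lam: float = 5.0
    nu: float = 1.0
    beta: float = 1.4
    D_rand: float = 0.005
    R_cell: float = 0.5
    R_int: float = 1.5

    D_oxy: float = 1.0
    kappa: float = 0.125
    omega_inf: float = 1.0
    mesh_spacing: float = 0.5
    mesh_margin: float = 3.0
    pde_stride: int = 1

    dt: float = 1.0 / 120.0
    n_init_cells: int = 300
    r_init: float = 5.0
    t_grow: float = 300.0
    n_beads: int = 100
    t_beads: float = 100.0
    n_labels: int = 50
    seed: int = 0

    alpha: float = 0.5
    snapshot_every: float = 1.0
    traj_every: float = 0.5
    shrink_parent_at_division: bool = False
    bead_placement: str = "edge"
    radius_cap: float = 80.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.omega_h <= self.omega_q <= 1.0):
            raise ConfigError(
                f"thresholds must satisfy 0 <= omega_h <= omega_q <= 1, "
                f"got omega_h={self.omega_h}, omega_q={self.omega_q}"
            )
        if self.omega_q <= 0.0:
            raise ConfigError("omega_q must be positive")
        for name in (
            "tau",
            "tau_hyp",
            "tau_nec",
            "mu",
            "mu_bead",
            "nu",
            "R_cell",
            "R_int",
            "D_oxy",
            "kappa",
            "omega_inf",
            "mesh_spacing",
            "dt",
            "alpha",
        ):
            if getattr(self, name) <= 0.0:
                raise ConfigError(f"{name} must be strictly positive")
        for name in ("lam", "beta", "D_rand", "mesh_margin"):
            if getattr(self, name) < 0.0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.R_int < 2.0 * self.R_cell:
            raise ConfigError("R_int must be at least one cell diameter (2*R_cell)")
        if self.pde_stride < 1:
            raise ConfigError("pde_stride must be >= 1")
        if self.bead_placement not in ("edge", "annulus"):
            raise ConfigError("bead_placement must be 'edge' or 'annulus'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return make_config(d)


#: the documented default parameter set (see docs/methods.md for provenance)
DEFAULTS = SimulationConfig()

_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}


def make_config(overrides: Optional[dict] = None, **kwargs) -> SimulationConfig:
    """Build a configuration from the documented defaults plus overrides.

    Parameters may be given as a mapping and/or as keyword arguments
    (keywords win). Unknown names raise ``ConfigError``; invariant
    violations raise ``ConfigError`` as well.
    """
    merged: dict = {}
    if overrides:
        merged.update(overrides)
    merged.update(kwargs)
    unknown = set(merged) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown configuration parameter(s): {sorted(unknown)}")
    return SimulationConfig(**merged)


def draw_duration(mean: float, rng: np.random.Generator) -> float:
    """Sample a duration uniformly from [0.75*mean, 1.25*mean].

    Per-cell cycle, hypoxia and degradation durations are drawn this way so
    that `mean` stays the population average while cells desynchronise.
    """
    if mean <= 0:
        raise ValueError(f"duration mean must be positive, got {mean}")
    return float(rng.uniform(0.75 * mean, 1.25 * mean))


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    """A single tumour cell (scalar view; simulations use ``CellArrays``)."""

    id: int
    pos: np.ndarray
    phenotype: Phenotype
    T_cycle: float
    tau_i: float
    T_hyp: float
    tau_hyp_i: float
    tau_nec_i: float
    s_i: float
    spring_scale: float = 1.0
    t_birth: float = 0.0
    t_necrosis: Optional[float] = None
    labelled: bool = False
    s_birth: float = 0.5
    s_onset: Optional[float] = None


@dataclass
class Microbead:
    """An inert microbead: never divides, never consumes oxygen."""

    id: int
    pos: np.ndarray
    t_added: float = 0.0


class CellArrays:
    """Structure-of-arrays container for the cell population.

    Engine-internal updates are vectorised over these columns; ``view`` and
    ``set_cell`` bridge to the scalar :class:`Cell` API. Ids are assigned in
    increasing order and never reused.
    """

    COLUMNS = (
        "ids",
        "pos",
        "phenotype",
        "T_cycle",
        "tau_i",
        "T_hyp",
        "tau_hyp_i",
        "tau_nec_i",
        "s",
        "spring_scale",
        "t_birth",
        "t_necrosis",
        "labelled",
        "s_birth",
        "s_onset",
    )

    def __init__(self, n: int = 0):
        self.ids = np.zeros(n, dtype=np.int64)
        self.pos = np.zeros((n, 2), dtype=np.float64)
        self.phenotype = np.zeros(n, dtype=np.int8)
        self.T_cycle = np.zeros(n, dtype=np.float64)
        self.tau_i = np.ones(n, dtype=np.float64)
        self.T_hyp = np.zeros(n, dtype=np.float64)
        self.tau_hyp_i = np.ones(n, dtype=np.float64)
        self.tau_nec_i = np.ones(n, dtype=np.float64)
        self.s = np.full(n, 0.5, dtype=np.float64)
        self.spring_scale = np.ones(n, dtype=np.float64)
        self.t_birth = np.zeros(n, dtype=np.float64)
        self.t_necrosis = np.full(n, np.nan, dtype=np.float64)
        self.labelled = np.zeros(n, dtype=bool)
        self.s_birth = np.full(n, 0.5, dtype=np.float64)
        self.s_onset = np.full(n, np.nan, dtype=np.float64)

    def __len__(self) -> int:
        return self.ids.size

    @property
    def viable(self) -> np.ndarray:
        """Boolean mask of non-necrotic cells."""
        return self.phenotype != int(Phenotype.NECROTIC)

    def view(self, i: int) -> Cell:
        """Scalar view of cell at index ``i`` (a copy, not a live view)."""
        t_nec = self.t_necrosis[i]
        s_on = self.s_onset[i]
        return Cell(
            id=int(self.ids[i]),
            pos=self.pos[i].copy(),
            phenotype=Phenotype(int(self.phenotype[i])),
            T_cycle=float(self.T_cycle[i]),
            tau_i=float(self.tau_i[i]),
            T_hyp=float(self.T_hyp[i]),
            tau_hyp_i=float(self.tau_hyp_i[i]),
            tau_nec_i=float(self.tau_nec_i[i]),
            s_i=float(self.s[i]),
            spring_scale=float(self.spring_scale[i]),
            t_birth=float(self.t_birth[i]),
            t_necrosis=None if np.isnan(t_nec) else float(t_nec),
            labelled=bool(self.labelled[i]),
            s_birth=float(self.s_birth[i]),
            s_onset=None if np.isnan(s_on) else float(s_on),
        )

    def set_cell(self, i: int, cell: Cell) -> None:
        self.ids[i] = cell.id
        self.pos[i] = cell.pos
        self.phenotype[i] = int(cell.phenotype)
        self.T_cycle[i] = cell.T_cycle
        self.tau_i[i] = cell.tau_i
        self.T_hyp[i] = cell.T_hyp
        self.tau_hyp_i[i] = cell.tau_hyp_i
        self.tau_nec_i[i] = cell.tau_nec_i
        self.s[i] = cell.s_i
        self.spring_scale[i] = cell.spring_scale
        self.t_birth[i] = cell.t_birth
        self.t_necrosis[i] = np.nan if cell.t_necrosis is None else cell.t_necrosis
        self.labelled[i] = cell.labelled
        self.s_birth[i] = cell.s_birth
        self.s_onset[i] = np.nan if cell.s_onset is None else cell.s_onset

    def append(self, other: "CellArrays") -> None:
        for name in self.COLUMNS:
            if name in ("pos",):
                setattr(self, name, np.vstack([getattr(self, name), getattr(other, name)]))
            elif name in ("s", "spring_scale", "T_cycle", "tau_i", "T_hyp", "tau_hyp_i",
                          "tau_nec_i", "t_birth", "t_necrosis", "s_birth", "s_onset",
                          "ids", "phenotype", "labelled"):
                setattr(self, name, np.concatenate([getattr(self, name), getattr(other, name)]))

    def delete(self, mask: np.ndarray) -> None:
        """Drop cells where ``mask`` is True, preserving order."""
        keep = ~mask
        for name in self.COLUMNS:
            setattr(self, name, getattr(self, name)[keep])


class BeadArrays:
    """Structure-of-arrays container for microbeads."""

    def __init__(self, n: int = 0):
        self.ids = np.zeros(n, dtype=np.int64)
        self.pos = np.zeros((n, 2), dtype=np.float64)
        self.t_added = np.zeros(n, dtype=np.float64)

    def __len__(self) -> int:
        return self.ids.size

    def view(self, i: int) -> Microbead:
        return Microbead(
            id=int(self.ids[i]), pos=self.pos[i].copy(), t_added=float(self.t_added[i])
        )


@dataclass
class SpheroidState:
    """Full simulation state: time, cells, beads, boundary cache, RNG."""

    t: float = 0.0
    cells: CellArrays = field(default_factory=CellArrays)
    beads: BeadArrays = field(default_factory=BeadArrays)
    boundary_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    rng: Optional[np.random.Generator] = None
    next_cell_id: int = 0

    @property
    def centroid(self) -> np.ndarray:
        """Mean position over all cells (live or necrotic)."""
        if len(self.cells) == 0:
            return np.zeros(2)
        return self.cells.pos.mean(axis=0)

    @property
    def radius(self) -> float:
        """Spheroid radius: max distance of any cell centre from the centroid."""
        if len(self.cells) == 0:
            return 0.0
        d = np.linalg.norm(self.cells.pos - self.centroid, axis=1)
        return float(d.max())

    @property
    def boundary_indices(self) -> np.ndarray:
        """Indices (into the current arrays) of cached boundary cells."""
        if self.boundary_ids.size == 0 or len(self.cells) == 0:
            return np.zeros(0, dtype=np.int64)
        # ids are sorted ascending by construction
        idx = np.searchsorted(self.cells.ids, self.boundary_ids)
        ok = idx < len(self.cells)
        idx, bids = idx[ok], self.boundary_ids[ok]
        return idx[self.cells.ids[idx] == bids]
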