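"""Phenotype switching, oxygen-gated timers, division, necrosis and removal.

The state machine allows PROLIFERATIVE <-> QUIESCENT <-> HYPOXIC and
HYPOXIC -> NECROTIC only; necrosis is absorbing. Threshold conventions at
equality: oxygen exactly at the quiescence threshold means quiescent, and
exactly at the hypoxia threshold means hypoxic (both thresholds are
inclusive on the low-oxygen side).

The scalar functions below operate on a single :class:`~.state.Cell`; the
simulation engine applies the identical logic vectorised over
:class:`~.state.CellArrays` via the ``*_arrays`` kernels, and the test
suite checks the two paths agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .state import Cell, CellArrays, Phenotype, SimulationConfig, SpheroidState, draw_duration

__all__ = [
    "PhenotypeTransition",
    "ALLOWED_TRANSITIONS",
    "update_phenotype",
    "advance_timers",
    "maybe_divide",
    "maybe_necrose",
    "update_size",
    "remove_dead",
    "phenotype_from_oxygen",
]

#: legal phenotype transitions (from, to)
ALLOWED_TRANSITIONS = frozenset(
    {
        (Phenotype.PROLIFERATIVE, Phenotype.QUIESCENT),
        (Phenotype.QUIESCENT, Phenotype.PROLIFERATIVE),
        (Phenotype.QUIESCENT, Phenotype.HYPOXIC),
        (Phenotype.HYPOXIC, Phenotype.QUIESCENT),
        (Phenotype.HYPOXIC, Phenotype.NECROTIC),
    }
)


@dataclass
class PhenotypeTransition:
    """One logged phenotype change."""

    cell_id: int
    from_phenotype: Phenotype
    to_phenotype: Phenotype
    time: float
    trigger: str  # 'oxygen' or 'timer'


def phenotype_from_oxygen(omega, cfg: SimulationConfig):
    """Viable phenotype implied by a local oxygen level (vectorised).

    proliferative if omega > omega_q; quiescent if omega_h < omega <=
    omega_q; hypoxic if omega <= omega_h.
    """
    omega = np.asarray(omega)
    out = np.full(omega.shape, int(Phenotype.QUIESCENT), dtype=np.int8)
    out[omega > cfg.omega_q] = int(Phenotype.PROLIFERATIVE)
    out[omega <= cfg.omega_h] = int(Phenotype.HYPOXIC)
    return out if out.ndim else np.int8(out)


def update_phenotype(cell: Cell, omega_local: float, cfg: SimulationConfig) -> Cell:
    """Instantaneous oxygen-driven phenotype switch for a viable cell.

    A hypoxic cell whose oxygen recovers above the hypoxia threshold
    returns to quiescence and its hypoxia timer resets to zero. Necrotic
    cells are left untouched (with a warning): necrosis is absorbing.
    """
    if cell.phenotype == Phenotype.NECROTIC:
        warnings.warn("update_phenotype called on a necrotic cell (no-op)", stacklevel=2)
        return cell
    if not (0.0 <= omega_local <= cfg.omega_inf + 1e-12):
        raise ValueError(f"oxygen level out of range: {omega_local}")
    new = Phenotype(int(phenotype_from_oxygen(omega_local, cfg)))
    if cell.phenotype == Phenotype.HYPOXIC and new != Phenotype.HYPOXIC:
        cell.T_hyp = 0.0
    cell.phenotype = new
    return cell


def advance_timers(cell: Cell, omega_local: float, dt: float, cfg: SimulationConfig) -> Cell:
    """Advance the oxygen-gated cycle and hypoxia clocks by one step.

    Heaviside gates: T_cycle += dt iff omega > omega_q; T_hyp += dt iff
    omega <= omega_h; and T_hyp resets to 0 whenever omega > omega_h.
    Necrotic cells are frozen.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cell.phenotype == Phenotype.NECROTIC:
        return cell
    if omega_local > cfg.omega_q:
        cell.T_cycle += dt
    if omega_local <= cfg.omega_h:
        cell.T_hyp += dt
    else:
        cell.T_hyp = 0.0
    return cell


def maybe_divide(
    cell: Cell, state: SpheroidState, cfg: SimulationConfig, rng: np.random.Generator
) -> Optional[Cell]:
    """Divide when the cycle clock reaches its assigned duration.

    The daughter is placed half a cell diameter from the parent in a
    uniformly random direction, both cells redraw their cycle durations
    and reset their clocks, the daughter starts at half spring radius and
    grows to full size over one hour, and the daughter inherits the
    heritable label. Returns the daughter, or None if no division occurred.
    """
    if cell.phenotype == Phenotype.NECROTIC:
        return None
    if cell.T_cycle < cell.tau_i:
        return None
    theta = rng.uniform(0.0, 2.0 * np.pi)
    offset = 0.5 * np.array([np.cos(theta), np.sin(theta)])
    cell.T_cycle = 0.0
    cell.tau_i = draw_duration(cfg.tau, rng)
    if cfg.shrink_parent_at_division:
        cell.s_i = cfg.R_cell / 2.0
        cell.s_birth = cfg.R_cell / 2.0
        cell.t_birth = state.t
    daughter = Cell(
        id=state.next_cell_id,
        pos=cell.pos + offset,
        phenotype=cell.phenotype,
        T_cycle=0.0,
        tau_i=draw_duration(cfg.tau, rng),
        T_hyp=0.0,
        tau_hyp_i=draw_duration(cfg.tau_hyp, rng),
        tau_nec_i=draw_duration(cfg.tau_nec, rng),
        s_i=cfg.R_cell / 2.0,
        spring_scale=1.0,
        t_birth=state.t,
        labelled=cell.labelled,
        s_birth=cfg.R_cell / 2.0,
    )
    state.next_cell_id += 1
    return daughter


def maybe_necrose(cell: Cell, cfg: SimulationConfig, t: float = 0.0) -> Cell:
    """Irreversible necrosis once the hypoxia clock reaches its threshold.

    The oxygen sink switches off (the solver skips necrotic cells), the
    cycle clock freezes, and the spring radius begins its linear decay
    from its value at onset.
    """
    if cell.phenotype == Phenotype.NECROTIC:
        return cell
    if cell.T_hyp >= cell.tau_hyp_i:
        cell.phenotype = Phenotype.NECROTIC
        cell.t_necrosis = t
        cell.s_onset = cell.s_i
    return cell


def update_size(cell: Cell, t: float, cfg: SimulationConfig) -> Cell:
    """Linear size dynamics: newborn growth and necrotic decay.

    Newborns ramp from their birth radius to ``R_cell`` over one hour.
    Necrotic cells shrink linearly from their radius at necrosis onset to
    zero over their assigned degradation time, and the springs attached to
    them weaken at the same relative rate.
    """
    if cell.phenotype == Phenotype.NECROTIC:
        if cell.t_necrosis is None or cell.s_onset is None:
            raise ValueError("necrotic cell lacks onset bookkeeping")
        frac = max(0.0, 1.0 - (t - cell.t_necrosis) / cell.tau_nec_i)
        cell.s_i = cell.s_onset * frac
        cell.spring_scale = frac
    else:
        age = t - cell.t_birth
        ramp = min(1.0, max(0.0, age))
        cell.s_i = cell.s_birth + (cfg.R_cell - cell.s_birth) * ramp
        cell.spring_scale = 1.0
    return cell


def remove_dead(state: SpheroidState) -> SpheroidState:
    """Delete fully degraded cells (spring radius zero). Ids never reused."""
    if len(state.cells) == 0:
        return state
    gone = state.cells.s <= 0.0
    if gone.any():
        state.cells.delete(gone)
    return state


# ---------------------------------------------------------------------------
# Vectorised kernels used by the engine (same semantics as the scalar API)
# ---------------------------------------------------------------------------


def update_phenotype_arrays(cells: CellArrays, omega, cfg: SimulationConfig) -> np.ndarray:
    """Vectorised phenotype update for viable cells; returns the old codes."""
    old = cells.phenotype.copy()
    viable = cells.viable
    new = phenotype_from_oxygen(omega, cfg)
    left_hypoxia = viable & (old == int(Phenotype.HYPOXIC)) & (new != int(Phenotype.HYPOXIC))
    cells.T_hyp[left_hypoxia] = 0.0
    cells.phenotype = np.where(viable, new, old).astype(np.int8)
    return old


def advance_timers_arrays(cells: CellArrays, omega, dt: float, cfg: SimulationConfig) -> None:
    """Vectorised oxygen-gated clock update (viable cells only)."""
    omega = np.asarray(omega)
    viable = cells.viable
    cells.T_cycle[viable & (omega > cfg.omega_q)] += dt
    hyp = viable & (omega <= cfg.omega_h)
    cells.T_hyp[hyp] += dt
    cells.T_hyp[viable & (omega > cfg.omega_h)] = 0.0


def necrose_arrays(cells: CellArrays, t: float) -> np.ndarray:
    """Vectorised necrosis onset; returns the mask of cells that turned."""
    turn = cells.viable & (cells.T_hyp >= cells.tau_hyp_i)
    if turn.any():
        cells.phenotype[turn] = int(Phenotype.NECROTIC)
        cells.t_necrosis[turn] = t
        cells.s_onset[turn] = cells.s[turn]
    return turn


def update_size_arrays(cells: CellArrays, t: float, cfg: SimulationConfig) -> None:
    """Vectorised newborn-growth / necrotic-decay size update."""
    nec = ~cells.viable
    if nec.any():
        frac = 1.0 - (t - cells.t_necrosis[nec]) / cells.tau_nec_i[nec]
        frac = np.clip(frac, 0.0, 1.0)
        cells.s[nec] = cells.s_onset[nec] * frac
        cells.spring_scale[nec] = frac
    via = ~nec
    if via.any():
        ramp = np.clip(t - cells.t_birth[via], 0.0, 1.0)
        cells.s[via] = cells.s_birth[via] + (cfg.R_cell - cells.s_birth[via]) * ramp
        cells.spring_scale[via] = 1.0
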