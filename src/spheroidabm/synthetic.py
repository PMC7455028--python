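"""Synthetic generators for benchmarking the analysis layer.

These generators produce data in exactly the schemas emitted by the
simulator — parametric two-phase bead trajectories, concentric-ring
snapshots, and mock parameter sweeps — with known ground truth, so the
analysis and inference stack can be validated independently of the
agent-based simulator. They emulate the *shapes* of simulator output
only: no oxygen field, mechanics or cell kinetics are involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .engine import Snapshot, TrajectoryRecord
from .state import Phenotype

__all__ = [
    "SyntheticTrajectorySpec",
    "gen_trajectories",
    "gen_ring_snapshot",
    "gen_mock_sweep",
    "MockSweepRecord",
]


@dataclass
class SyntheticTrajectorySpec:
    """Stated world for two-phase synthetic bead trajectories.

    Each bead starts at radius ``R0``, moves by radial 1D Brownian motion
    with coefficient ``D_true`` until its switch time (drawn uniformly
    from [0.75, 1.25] times ``t_switch_mean``, or exactly ``t_switch_mean``
    when ``t_switch_spread`` is 0), then drifts inward at ``v_true`` until
    it reaches the core radius ``r_core``, where it stays.
    """

    n_beads: int = 100
    D_true: float = 0.05
    v_true: float = 0.1
    t_switch_mean: float = 20.0
    t_switch_spread: float = 0.25
    R0: float = 14.0
    r_core: float = 4.0
    dt_sample: float = 0.5
    duration: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_core >= self.R0:
            raise ValueError("core radius must be smaller than the spheroid radius")
        for name in ("n_beads", "dt_sample", "duration", "R0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.D_true, self.v_true, self.t_switch_mean, self.t_switch_spread) < 0:
            raise ValueError("rates and times must be nonnegative")


def gen_trajectories(
    spec: SyntheticTrajectorySpec, rng: np.random.Generator
) -> List[TrajectoryRecord]:
    """Generate the trajectories described by ``spec``."""
    n_samples = int(round(spec.duration / spec.dt_sample)) + 1
    times = spec.dt_sample * np.arange(n_samples)
    lo = 1.0 - spec.t_switch_spread
    hi = 1.0 + spec.t_switch_spread
    switches = spec.t_switch_mean * rng.uniform(lo, hi, spec.n_beads)
    sigma = np.sqrt(2.0 * spec.D_true * spec.dt_sample)
    out: List[TrajectoryRecord] = []
    for b in range(spec.n_beads):
        r = np.empty(n_samples)
        r[0] = spec.R0
        noise = sigma * rng.standard_normal(n_samples - 1)
        for k in range(1, n_samples):
            if times[k] <= switches[b]:
                r[k] = r[k - 1] + noise[k - 1]
            else:
                r[k] = max(spec.r_core, r[k - 1] - spec.v_true * spec.dt_sample)
        omega = np.clip(r / spec.R0, 0.0, 1.0)  # schema filler, monotone in r
        out.append(TrajectoryRecord(bead_id=b, times=times.copy(), r=r, omega=omega))
    return out


def gen_ring_snapshot(
    ring_radii: Dict[int, float],
    cells_per_ring: int,
    rng: np.random.Generator,
    time: float = 0.0,
) -> Snapshot:
    """Snapshot with cells placed on concentric phenotype rings.

    ``ring_radii`` maps phenotype codes to ring radii, which must be
    ordered necrotic < hypoxic < quiescent < proliferative where present.
    Angles are random but exactly mean-zero in pairs so the centroid stays
    at the origin and composition ground truth is exact.
    """
    known = [int(p) for p in Phenotype]
    radii_in_order = [ring_radii[p] for p in sorted(ring_radii, reverse=True)]
    # reverse phenotype code order = necrotic, hypoxic, quiescent, proliferative
    if any(b <= a for a, b in zip(radii_in_order, radii_in_order[1:])):
        raise ValueError(
            "ring radii must increase from necrotic out to proliferative"
        )
    if any(p not in known for p in ring_radii):
        raise ValueError("unknown phenotype code in ring_radii")
    pos_list, ph_list = [], []
    for ph, radius in ring_radii.items():
        theta = rng.uniform(0.0, 2.0 * np.pi, cells_per_ring)
        theta = np.concatenate([theta, theta + np.pi])  # antipodal pairs
        pos_list.append(radius * np.column_stack([np.cos(theta), np.sin(theta)]))
        ph_list.append(np.full(2 * cells_per_ring, ph, dtype=np.int8))
    pos = np.vstack(pos_list)
    ph = np.concatenate(ph_list)
    n = pos.shape[0]
    d = np.hypot(pos[:, 0], pos[:, 1])
    return Snapshot(
        time=time,
        cell_ids=np.arange(n, dtype=np.int64),
        cell_pos=pos,
        cell_phenotype=ph,
        cell_s=np.full(n, 0.5),
        cell_labelled=np.zeros(n, dtype=bool),
        bead_ids=np.zeros(0, dtype=np.int64),
        bead_pos=np.zeros((0, 2)),
        centroid=np.zeros(2),
        radius=float(d.max()),
        compartment_outer={
            p: float(d[ph == p].max()) if (ph == p).any() else 0.0 for p in known
        },
    )


@dataclass
class MockSweepRecord:
    """One mock sweep entry with known smooth feature maps."""

    run_id: int
    tau: float
    omega_q: float
    T_wait: float
    V_r: float
    prop_prolif: float
    prop_quiescent: float
    prop_hypoxic: float
    prop_necrotic: float
    seed: int


def _mock_maps(tau: np.ndarray, omega_q: np.ndarray):
    """Smooth noiseless maps (tau, omega_q) -> features and compositions.

    Chosen to mimic the directionality of the simulator: waiting time
    grows with the cycle length, infiltration speed falls with both the
    cycle length and the quiescence threshold, and the quiescent fraction
    grows with the threshold. The coefficients keep the
    (tau, omega_q) -> (T_wait, V_r) map invertible over the default
    parameter ranges, so noiseless recovery is identifiable.
    """
    T_wait = 0.6 * tau + 3.0 * omega_q
    V_r = 2.4 / tau + 0.5 * (1.0 - omega_q)
    q = np.clip(0.9 * omega_q - 0.004 * tau, 0.0, 1.0)
    p = np.clip(0.55 * (1.0 - omega_q), 0.0, 1.0)
    h = np.clip(0.25 - 0.15 * omega_q, 0.0, 1.0)
    n = np.clip(1.0 - q - p - h, 0.0, 1.0)
    return T_wait, V_r, q, p, h, n


def gen_mock_sweep(
    n: int, noise: float, rng: np.random.Generator,
    tau_range=(8.0, 32.0), omega_q_range=(0.31, 0.8),
) -> List[MockSweepRecord]:
    """Mock sweep dataset with controllable noise on the features."""
    if n < 2:
        raise ValueError("a sweep needs at least 2 records")
    tau = rng.uniform(*tau_range, n)
    omega_q = rng.uniform(*omega_q_range, n)
    T_wait, V_r, q, p, h, m = _mock_maps(tau, omega_q)
    T_wait = T_wait + noise * rng.standard_normal(n) * 5.0
    V_r = V_r + noise * rng.standard_normal(n) * 0.05
    return [
        MockSweepRecord(
            run_id=i,
            tau=float(tau[i]),
            omega_q=float(omega_q[i]),
            T_wait=float(T_wait[i]),
            V_r=float(V_r[i]),
            prop_prolif=float(p[i]),
            prop_quiescent=float(q[i]),
            prop_hypoxic=float(h[i]),
            prop_necrotic=float(m[i]),
            seed=i,
        )
        for i in range(n)
    ]
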