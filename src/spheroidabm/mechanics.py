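"""Forces and overdamped motion for cells and microbeads.

Agents interact through pairwise centre-to-centre springs: a logarithmic
repulsive branch under compression and an exponentially decaying adhesive
branch under extension (bead-bead pairs repel only). Boundary cells,
identified by the alpha-shape of the cell centres, feel an inward surface
tension. All agents feel a random force calibrated so that the induced
displacement is Brownian with diffusion coefficient ``D_rand``. Inertia is
neglected: velocity = net force / drag, integrated with forward Euler.

Sign convention for the pair scalar: positive = attraction (the force on
agent i points toward agent j); the magnitude in the spring law is the
absolute value. This convention is fixed here and used consistently.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError

from .state import SimulationConfig, SpheroidState

try:  # optional fast path; the numpy path below is the reference
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap


__all__ = [
    "pair_force_scalar",
    "mechanical_forces",
    "random_forces",
    "alpha_complex",
    "alpha_shape_boundary",
    "surface_tension_forces",
    "advance_positions",
]

#: relative overlap at which the repulsive branch is clamped (the log law
#: diverges at full interpenetration x = -s_ij)
_CLAMP_FRACTION = 0.99


def pair_force_scalar(dist, s_ij, kind: str, cfg: SimulationConfig):
    """Signed spring-force scalar for one (or many) agent pairs.

    Parameters
    ----------
    dist : centre-to-centre distance(s), >= 0.
    s_ij : rest length(s), sum of the two agents' spring radii.
    kind : 'cell-cell', 'cell-bead' or 'bead-bead'. Pairs involving a cell
        use the adhesive/repulsive law with stiffness ``mu``; bead-bead
        pairs use stiffness ``mu_bead`` and have no adhesive branch.

    Returns
    -------
    Signed scalar(s): positive = attraction, negative = repulsion. Nearly
    full interpenetration is clamped to the value of the repulsive branch
    at ``x = -0.99 s_ij`` with a warning.
    """
    if kind not in ("cell-cell", "cell-bead", "bead-bead"):
        raise ValueError(f"unknown pair kind: {kind}")
    dist = np.asarray(dist, dtype=np.float64)
    s_ij = np.asarray(s_ij, dtype=np.float64)
    if np.any(s_ij <= 0):
        raise ValueError("rest length s_ij must be positive")
    x = dist - s_ij
    clamped = x < -_CLAMP_FRACTION * s_ij
    if np.any(clamped):
        warnings.warn("near-full interpenetration: repulsion clamped", stacklevel=2)
        x = np.where(clamped, -_CLAMP_FRACTION * s_ij, x)
    mu = cfg.mu_bead if kind == "bead-bead" else cfg.mu
    with np.errstate(divide="ignore", invalid="ignore"):
        repulsive = mu * s_ij * np.log1p(x / s_ij)
    if kind == "bead-bead":
        adhesive = np.zeros_like(repulsive)
    else:
        adhesive = cfg.mu * x * np.exp(-cfg.lam * x / s_ij)
    out = np.where(x < 0, repulsive, adhesive)
    return out if out.ndim else float(out)


def _agent_arrays(state: SpheroidState):
    """Concatenate cells then beads into flat agent arrays."""
    nc, nb = len(state.cells), len(state.beads)
    pos = np.vstack([state.cells.pos, state.beads.pos]) if nb else state.cells.pos
    s = np.concatenate([state.cells.s, np.full(nb, 0.5)]) if nb else state.cells.s
    scale = (
        np.concatenate([state.cells.spring_scale, np.ones(nb)])
        if nb
        else state.cells.spring_scale
    )
    is_bead = np.zeros(nc + nb, dtype=bool)
    is_bead[nc:] = True
    return pos, s, scale, is_bead


def _pair_forces_from_pairs(
    pos, s, scale, is_bead, pairs, cfg: SimulationConfig, rng=None
):
    """Accumulate equal-and-opposite spring forces for the given pair list."""
    n = pos.shape[0]
    forces = np.zeros((n, 2))
    if pairs.shape[0] == 0:
        return forces
    i, j = pairs[:, 0], pairs[:, 1]
    d = pos[j] - pos[i]
    dist = np.hypot(d[:, 0], d[:, 1])
    within = dist < cfg.R_int
    i, j, d, dist = i[within], j[within], d[within], dist[within]
    if i.size == 0:
        return forces
    zero = dist == 0.0
    if np.any(zero):
        # coincident agents: random direction, clamped repulsion magnitude
        rng = rng if rng is not None else np.random.default_rng()
        theta = rng.uniform(0.0, 2.0 * np.pi, int(zero.sum()))
        d[zero] = np.column_stack([np.cos(theta), np.sin(theta)])
        dist = np.where(zero, 1.0, dist)
    u = d / dist[:, None]

    s_ij = s[i] + s[j]
    x = np.where(zero, -_CLAMP_FRACTION * s_ij, dist - s_ij)
    x = np.maximum(x, -_CLAMP_FRACTION * s_ij)
    both_beads = is_bead[i] & is_bead[j]
    mu = np.where(both_beads, cfg.mu_bead, cfg.mu)
    repulsive = mu * s_ij * np.log1p(x / s_ij)
    adhesive = np.where(both_beads, 0.0, cfg.mu * x * np.exp(-cfg.lam * x / s_ij))
    scalar = np.where(x < 0, repulsive, adhesive)
    # degrading necrotic cells weaken the springs attached to them
    scalar = scalar * scale[i] * scale[j]

    fvec = scalar[:, None] * u  # force on i, toward j when positive
    forces[:, 0] = np.bincount(i, weights=fvec[:, 0], minlength=n) - np.bincount(
        j, weights=fvec[:, 0], minlength=n
    )
    forces[:, 1] = np.bincount(i, weights=fvec[:, 1], minlength=n) - np.bincount(
        j, weights=fvec[:, 1], minlength=n
    )
    return forces


@_njit(cache=False)
def _pair_kernel(pos, s, scale, is_bead, pairs, R_int, mu, mu_bead, lam, clamp_frac):
    """Compiled pair-force accumulation (coincident agents are skipped;
    the engine never produces them because daughters are offset at birth)."""
    n = pos.shape[0]
    out = np.zeros((n, 2))
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dist = np.sqrt(dx * dx + dy * dy)
        if dist >= R_int or dist <= 0.0:
            continue
        sij = s[i] + s[j]
        x = dist - sij
        if x < -clamp_frac * sij:
            x = -clamp_frac * sij
        bb = is_bead[i] and is_bead[j]
        if x < 0.0:
            m = mu_bead if bb else mu
            f = m * sij * np.log(1.0 + x / sij)
        else:
            f = 0.0 if bb else mu * x * np.exp(-lam * x / sij)
        f *= scale[i] * scale[j]
        ux = dx / dist
        uy = dy / dist
        out[i, 0] += f * ux
        out[i, 1] += f * uy
        out[j, 0] -= f * ux
        out[j, 1] -= f * uy
    return out


def _pair_forces_fast(pos, s, scale, is_bead, pairs, cfg, rng=None):
    """Engine fast path: numba kernel when available, else the numpy path."""
    if HAVE_NUMBA:
        if pairs.shape[0] == 0:
            return np.zeros((pos.shape[0], 2))
        return _pair_kernel(
            pos, s, scale, is_bead, pairs,
            cfg.R_int, cfg.mu, cfg.mu_bead, cfg.lam, _CLAMP_FRACTION,
        )
    return _pair_forces_from_pairs(pos, s, scale, is_bead, pairs, cfg, rng)


def mechanical_forces(
    state: SpheroidState, cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Net spring force on every agent (cells first, then beads).

    Every unordered pair closer than ``R_int`` contributes equal-and-
    opposite forces along the centre-to-centre line, so the sum over agents
    vanishes exactly.
    """
    pos, s, scale, is_bead = _agent_arrays(state)
    if pos.shape[0] < 2:
        return np.zeros((pos.shape[0], 2))
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cfg.R_int, output_type="ndarray")
    return _pair_forces_from_pairs(pos, s, scale, is_bead, pairs, cfg, rng)


def random_forces(
    state: SpheroidState, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random force whose induced per-step displacement is Brownian.

    The displacement over one step is force*dt/nu, so drawing
    force = nu*sqrt(2*D_rand/dt)*xi (xi standard normal, per component)
    gives displacement variance 2*D_rand*dt per component regardless of dt.
    """
    if cfg.dt <= 0:
        raise ValueError("dt must be positive")
    n = len(state.cells) + len(state.beads)
    if cfg.D_rand == 0.0:
        # still consume draws so the force sequence is seed-stable
        return np.zeros((n, 2))
    amp = cfg.nu * np.sqrt(2.0 * cfg.D_rand / cfg.dt)
    return amp * rng.standard_normal((n, 2))


def alpha_complex(positions: np.ndarray, alpha: float = 0.5):
    """Delaunay triangulation filtered by the alpha-shape criterion.

    A triangle belongs to the complex when its circumradius is at most the
    probe-disc radius ``1/alpha`` (the classical convention in which larger
    alpha sharpens the shape and the probe disc has radius 1/alpha; with
    the default alpha = R_cell = 0.5 the probe radius is one cell
    diameter's worth, 2 length units). A deterministic tie-break includes
    triangles with circumradius <= 1/alpha + 1e-12.

    Returns ``(tri, kept, boundary_idx)`` where ``tri`` is the Delaunay
    object (or None for degenerate inputs), ``kept`` a boolean mask over
    simplices, and ``boundary_idx`` the sorted indices of boundary points.
    """
    positions = np.asarray(positions, dtype=np.float64)
    n = positions.shape[0]
    if n == 0:
        raise ValueError("alpha shape of an empty point set")
    if n < 3:
        return None, np.zeros(0, dtype=bool), np.arange(n)
    try:
        tri = Delaunay(positions)
    except QhullError:
        # collinear / degenerate: everything is boundary
        return None, np.zeros(0, dtype=bool), np.arange(n)
    simplices = tri.simplices
    a = positions[simplices[:, 0]]
    b = positions[simplices[:, 1]]
    c = positions[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)
    probe = 1.0 / alpha
    kept = circumradius <= probe + 1e-12

    if not kept.any():
        return tri, kept, np.arange(n)
    # boundary edges appear in exactly one kept triangle (hash edge pairs
    # into int64 keys: cheaper than a lexicographic row-wise unique)
    kept_simplices = simplices[kept]
    edges = np.vstack(
        [kept_simplices[:, [0, 1]], kept_simplices[:, [1, 2]], kept_simplices[:, [0, 2]]]
    )
    lo = edges.min(axis=1).astype(np.int64)
    hi = edges.max(axis=1).astype(np.int64)
    keys = lo * np.int64(n) + hi
    uniq, counts = np.unique(keys, return_counts=True)
    single = uniq[counts == 1]
    on_boundary = np.zeros(n, dtype=bool)
    on_boundary[single // n] = True
    on_boundary[single % n] = True
    # points in no kept triangle are singular boundary points
    in_complex = np.zeros(n, dtype=bool)
    in_complex[kept_simplices.ravel()] = True
    on_boundary |= ~in_complex
    return tri, kept, np.flatnonzero(on_boundary).astype(np.int64)


def alpha_shape_boundary(positions: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Sorted indices of points on the alpha-shape boundary."""
    _, _, boundary_idx = alpha_complex(positions, alpha)
    return boundary_idx


def surface_tension_forces(state: SpheroidState, cfg: SimulationConfig) -> np.ndarray:
    """Inward surface-tension force on boundary cells only.

    Each boundary cell receives ``-beta`` times the unit vector from the
    centroid toward the cell; interior cells and beads receive nothing. A
    boundary cell coincident with the centroid gets zero force.
    """
    n = len(state.cells) + len(state.beads)
    forces = np.zeros((n, 2))
    if cfg.beta == 0.0 or len(state.cells) == 0:
        return forces
    idx = state.boundary_indices
    if idx.size == 0:
        return forces
    centroid = state.centroid
    d = state.cells.pos[idx] - centroid
    r = np.hypot(d[:, 0], d[:, 1])
    ok = r > 0
    forces[idx[ok]] = -cfg.beta * d[ok] / r[ok, None]
    return forces


def advance_positions(
    state: SpheroidState, forces: np.ndarray, cfg: SimulationConfig
) -> SpheroidState:
    """Forward-Euler update of the overdamped dynamics: x += dt/nu * F.

    ``forces`` rows are cells first then beads, matching the force
    assemblers. Non-finite results abort with the offending agent named.
    """
    nc = len(state.cells)
    disp = (cfg.dt / cfg.nu) * forces
    if not np.all(np.isfinite(disp)):
        bad = int(np.flatnonzero(~np.isfinite(disp).all(axis=1))[0])
        kind = "cell" if bad < nc else "bead"
        raise FloatingPointError(
            f"non-finite displacement for {kind} row {bad} at t={state.t:.4f}"
        )
    state.cells.pos = state.cells.pos + disp[:nc]
    if len(state.beads):
        state.beads.pos = state.beads.pos + disp[nc:]
    return state
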