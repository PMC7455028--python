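"""Quasi-steady oxygen field with point sinks at viable cell centres.

Oxygen equilibrates in seconds while cells divide over hours, so the
reaction-diffusion equation reduces to the elliptic problem

    0 = D_oxy * laplacian(omega) - kappa * omega * sum_i delta(x - x_i)

on a square domain containing the spheroid, with omega held at the
far-field level ``omega_inf`` at every mesh node outside the spheroid
(outside the alpha-shape of the cell centres). The Laplacian is
discretised with the standard 5-point stencil on a regular grid, which for
this operator coincides with linear finite elements on a regular
triangulation. Each viable cell deposits its sink onto the 4 surrounding
nodes with bilinear weights, so the sink operator is the transpose of the
interpolation operator and the system matrix stays symmetric positive
definite. The sink is linear in omega and folded into the matrix (never
lagged), which preserves positivity unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .state import SimulationConfig, SpheroidState

try:  # optional compiled fast path for per-step interpolation
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap


__all__ = [
    "OxygenField",
    "build_mesh",
    "classify_dirichlet",
    "solve_oxygen",
    "interpolate",
    "SolverError",
]


class SolverError(RuntimeError):
    """Raised when the oxygen linear system cannot be solved reliably."""


@dataclass
class OxygenField:
    """Regular square grid of oxygen values.

    Nodes are at ``(x0 + i*spacing, y0 + j*spacing)`` for ``i in [0, nx)``,
    ``j in [0, ny)``. ``node_values`` is stored flattened with x fastest
    (row index ``j*nx + i``). ``dirichlet_mask`` marks nodes held at the
    far-field oxygen level.
    """

    x0: float
    y0: float
    spacing: float
    nx: int
    ny: int
    node_values: Optional[np.ndarray] = None
    dirichlet_mask: Optional[np.ndarray] = None
    _laplacian: Optional[sp.csr_matrix] = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def node_coords(self) -> np.ndarray:
        """(n_nodes, 2) array of node positions, x fastest."""
        xs = self.x0 + self.spacing * np.arange(self.nx)
        ys = self.y0 + self.spacing * np.arange(self.ny)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    @property
    def xmax(self) -> float:
        return self.x0 + self.spacing * (self.nx - 1)

    @property
    def ymax(self) -> float:
        return self.y0 + self.spacing * (self.ny - 1)

    def contains(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        return (
            (pos[:, 0] >= self.x0)
            & (pos[:, 0] <= self.xmax)
            & (pos[:, 1] >= self.y0)
            & (pos[:, 1] <= self.ymax)
        )

    def laplacian(self) -> sp.csr_matrix:
        """Scale-free 5-point stiffness matrix (diag 4, neighbours -1).

        Homogeneous Neumann closure at the domain edge; in practice every
        edge node is Dirichlet (the domain margin exceeds the spheroid), so
        the closure never influences the solution.
        """
        if self._laplacian is None:
            ex = np.ones(self.nx)
            ey = np.ones(self.ny)
            Lx = sp.diags([-ex[:-1], 2 * ex, -ex[:-1]], [-1, 0, 1], format="lil")
            Ly = sp.diags([-ey[:-1], 2 * ey, -ey[:-1]], [-1, 0, 1], format="lil")
            # Neumann: edge rows see only one neighbour
            Lx[0, 0] = Lx[-1, -1] = 1.0
            Ly[0, 0] = Ly[-1, -1] = 1.0
            Ix = sp.identity(self.nx)
            Iy = sp.identity(self.ny)
            self._laplacian = (sp.kron(Iy, Lx) + sp.kron(Ly, Ix)).tocsr()
        return self._laplacian


def build_mesh(state: SpheroidState, spacing: float, margin: float) -> OxygenField:
    """Build a square grid covering every cell position plus ``margin``.

    The domain is the bounding square of the agents (cells and any beads)
    expanded by ``margin``, snapped outward to a whole number of spacings.
    """
    if spacing <= 0:
        raise ValueError(f"mesh spacing must be positive, got {spacing}")
    if len(state.cells) == 0:
        raise ValueError("cannot build an oxygen mesh for a state with no cells")
    pts = state.cells.pos
    if len(state.beads) > 0:
        pts = np.vstack([pts, state.beads.pos])
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    side = float(max(hi - lo))
    n = int(np.ceil(side / spacing)) + 1
    centre = (lo + hi) / 2.0
    half = spacing * (n - 1) / 2.0
    return OxygenField(
        x0=float(centre[0] - half),
        y0=float(centre[1] - half),
        spacing=float(spacing),
        nx=n,
        ny=n,
    )


def classify_dirichlet(field: OxygenField, state: SpheroidState, alpha: float = 0.5,
                       complex_=None) -> np.ndarray:
    """Mark nodes outside the spheroid, where oxygen is held at omega_inf.

    A node is *inside* the spheroid when it lies in (or on the edge of) the
    outer alpha-shape polygon of the cell centres: in a triangle of the
    alpha-complex, or in a cavity fully enclosed by the complex (a vacated
    necrotic core is still interior tissue space, not culture medium).
    All other nodes are Dirichlet. With fewer than 3 cells every node is
    Dirichlet.
    """
    from scipy import ndimage

    from .mechanics import alpha_complex

    mask = np.ones(field.n_nodes, dtype=bool)
    if len(state.cells) < 3:
        field.dirichlet_mask = mask
        return mask
    if complex_ is None:
        complex_ = alpha_complex(state.cells.pos, alpha)
    tri, kept, _ = complex_
    if tri is None or not kept.any():
        field.dirichlet_mask = mask
        return mask
    simplex = tri.find_simplex(field.node_coords)
    in_complex = simplex >= 0
    in_complex[in_complex] = kept[simplex[in_complex]]
    # flood-fill: outside = not-in-complex nodes connected to the domain edge
    grid = (~in_complex).reshape(field.ny, field.nx)
    labels, _ = ndimage.label(grid)
    edge_labels = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    edge_labels = edge_labels[edge_labels != 0]
    outside = np.isin(labels, edge_labels).ravel()
    field.dirichlet_mask = outside
    return outside


def _sink_weights(field: OxygenField, positions: np.ndarray):
    """Bilinear deposition of each point onto its 4 enclosing nodes.

    Returns (rows of 4 node indices, rows of 4 weights).
    """
    fx = (positions[:, 0] - field.x0) / field.spacing
    fy = (positions[:, 1] - field.y0) / field.spacing
    ix = np.clip(np.floor(fx).astype(np.int64), 0, field.nx - 2)
    iy = np.clip(np.floor(fy).astype(np.int64), 0, field.ny - 2)
    tx = fx - ix
    ty = fy - iy
    base = iy * field.nx + ix
    nodes = np.column_stack([base, base + 1, base + field.nx, base + field.nx + 1])
    w = np.column_stack([(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty])
    return nodes, w


def solve_oxygen(
    field: OxygenField,
    state: SpheroidState,
    config: SimulationConfig,
) -> OxygenField:
    """Solve the quasi-steady oxygen problem and set ``field.node_values``.

    Sinks are placed only at viable (non-necrotic) cell centres; necrotic
    cells and microbeads consume nothing. The solution obeys the discrete
    maximum principle: 0 < omega <= omega_inf everywhere.
    """
    if field.dirichlet_mask is None:
        raise ValueError("dirichlet_mask must be set before solving (classify_dirichlet)")
    mask = field.dirichlet_mask
    omega_inf = config.omega_inf
    values = np.full(field.n_nodes, omega_inf, dtype=np.float64)

    viable_pos = state.cells.pos[state.cells.viable]
    unknown = ~mask
    if viable_pos.shape[0] == 0 or not unknown.any():
        field.node_values = values
        return field
    if not field.contains(viable_pos).all():
        raise ValueError("viable cell outside the oxygen domain; rebuild the mesh")

    A = config.D_oxy * field.laplacian()
    nodes, w = _sink_weights(field, viable_pos)
    nc = viable_pos.shape[0]
    rows = np.repeat(np.arange(nc), 4)
    W = sp.csr_matrix(
        (w.ravel(), (rows, nodes.ravel())), shape=(nc, field.n_nodes)
    )
    A = (A + config.kappa * (W.T @ W)).tocsr()

    # eliminate Dirichlet nodes by masking rows/columns in place:
    #   M = Du A Du + Dd,   b = -omega_inf * Du (A d) + omega_inf * d
    # where Du/Dd are diagonal indicators of unknown/Dirichlet nodes. This
    # avoids expensive sparse fancy indexing and keeps the matrix SPD.
    u = unknown.astype(np.float64)
    d = mask.astype(np.float64)
    Ad = A @ d
    row_of = np.repeat(np.arange(field.n_nodes), np.diff(A.indptr))
    M = A.copy()
    M.data = M.data * u[row_of] * u[M.indices]
    M = M + sp.diags(d)
    b = -omega_inf * (u * Ad) + omega_inf * d
    try:
        sol = spla.spsolve(M.tocsc(), b)
    except Exception as exc:  # pragma: no cover - scipy backend specific
        raise SolverError(f"sparse oxygen solve failed: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise SolverError("oxygen solve produced non-finite values (singular system?)")
    resid = np.linalg.norm(M @ sol - b)
    scale = max(np.linalg.norm(b), 1.0)
    if resid / scale > 1e-8:
        raise SolverError(f"oxygen solve residual too large: {resid / scale:.2e}")
    # guard against roundoff excursions beyond the maximum principle
    if sol.min() < -1e-9 or sol.max() > omega_inf + 1e-9:
        raise SolverError(
            f"maximum principle violated: omega in [{sol.min()}, {sol.max()}]"
        )
    field.node_values = np.clip(sol, 0.0, omega_inf)
    return field


@_njit(cache=False)
def _interp_kernel(values, x0, y0, inv_h, nx, ny, pos):
    n = pos.shape[0]
    out = np.empty(n)
    for k in range(n):
        fx = (pos[k, 0] - x0) * inv_h
        fy = (pos[k, 1] - y0) * inv_h
        ix = int(np.floor(fx))
        iy = int(np.floor(fy))
        if ix < 0:
            ix = 0
        elif ix > nx - 2:
            ix = nx - 2
        if iy < 0:
            iy = 0
        elif iy > ny - 2:
            iy = ny - 2
        tx = fx - ix
        ty = fy - iy
        base = iy * nx + ix
        out[k] = (
            values[base] * (1 - tx) * (1 - ty)
            + values[base + 1] * tx * (1 - ty)
            + values[base + nx] * (1 - tx) * ty
            + values[base + nx + 1] * tx * ty
        )
    return out


def interpolate_fast(field: OxygenField, pos: np.ndarray) -> np.ndarray:
    """Bilinear interpolation without bounds checking (engine-internal;
    callers guarantee positions lie inside the domain)."""
    if HAVE_NUMBA:
        return _interp_kernel(
            field.node_values, field.x0, field.y0, 1.0 / field.spacing,
            field.nx, field.ny, pos,
        )
    nodes, w = _sink_weights(field, pos)
    return (field.node_values[nodes] * w).sum(axis=1)


def field_to_frame(field: OxygenField):
    """Field dump as a (node_x, node_y, omega) table for CSV export."""
    import pandas as pd

    if field.node_values is None:
        raise ValueError("field has no values; call solve_oxygen first")
    coords = field.node_coords
    return pd.DataFrame(
        {"node_x": coords[:, 0], "node_y": coords[:, 1], "omega": field.node_values}
    )


def interpolate(field: OxygenField, pos: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the oxygen field at one or many positions.

    Scalar in, scalar out; (n, 2) in, (n,) out. Positions outside the
    domain raise ``ValueError``.
    """
    if field.node_values is None:
        raise ValueError("field has no values; call solve_oxygen first")
    single = np.asarray(pos).ndim == 1
    p = np.atleast_2d(np.asarray(pos, dtype=np.float64))
    if not field.contains(p).all():
        raise ValueError("position outside the oxygen domain")
    nodes, w = _sink_weights(field, p)
    vals = (field.node_values[nodes] * w).sum(axis=1)
    return float(vals[0]) if single else vals
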