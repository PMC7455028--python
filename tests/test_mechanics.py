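"""Spring law, force assembly, alpha-shape boundary and overdamped motion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spheroidabm as sab
from spheroidabm.mechanics import (
    advance_positions,
    alpha_shape_boundary,
    mechanical_forces,
    pair_force_scalar,
    random_forces,
    surface_tension_forces,
)
from spheroidabm.state import BeadArrays, make_config

from conftest import make_state


def _unit_cfg():
    return make_config({"mu": 1.0, "mu_bead": 1.0, "lam": 1.0})


class TestPairForceScalar:
    def test_continuity_at_zero_overlap(self):
        cfg = _unit_cfg()
        for kind in ("cell-cell", "cell-bead", "bead-bead"):
            assert pair_force_scalar(1.0, 1.0, kind, cfg) == pytest.approx(0.0)

    def test_adhesive_branch_closed_form(self):
        # mu=1, s=1, lam=1, x=0.5 -> 0.5 * e^{-0.5}
        cfg = _unit_cfg()
        assert pair_force_scalar(1.5, 1.0, "cell-cell", cfg) == pytest.approx(
            0.5 * np.exp(-0.5)
        )

    def test_repulsive_branch_closed_form(self):
        # mu=1, s=1, x=-0.5 -> log(0.5), negative (repulsion)
        cfg = _unit_cfg()
        assert pair_force_scalar(0.5, 1.0, "cell-cell", cfg) == pytest.approx(
            np.log(0.5)
        )

    def test_bead_bead_no_adhesion(self):
        cfg = _unit_cfg()
        assert pair_force_scalar(1.5, 1.0, "bead-bead", cfg) == 0.0
        # but compression resists
        assert pair_force_scalar(0.5, 1.0, "bead-bead", cfg) < 0.0

    def test_adhesive_maximum_at_s_over_lam(self):
        """The adhesion peaks at overlap x = s_ij / lam (closed form)."""
        cfg = make_config({"mu": 2.0, "lam": 5.0})
        s_ij = 1.0
        x_star = s_ij / cfg.lam
        f_star = pair_force_scalar(s_ij + x_star, s_ij, "cell-cell", cfg)
        xs = np.linspace(0.0, 1.0, 400)
        fs = pair_force_scalar(s_ij + xs, np.full_like(xs, s_ij), "cell-cell", cfg)
        assert f_star == pytest.approx(fs.max(), rel=1e-4)
        assert f_star == pytest.approx(cfg.mu * x_star * np.exp(-1.0))

    def test_full_interpenetration_clamped(self):
        cfg = _unit_cfg()
        with pytest.warns(UserWarning):
            f = pair_force_scalar(0.0001, 1.0, "cell-cell", cfg)
        assert f == pytest.approx(np.log(1.0 - 0.99))


class TestMechanicalForces:
    def test_rest_separation_zero_force(self, cfg):
        state = make_state([[0.0, 0.0], [1.0, 0.0]])  # s_ij = 0.5+0.5 = 1
        f = mechanical_forces(state, cfg)
        assert np.allclose(f, 0.0, atol=1e-14)

    def test_newtons_third_law_sum_zero(self, cfg, rng):
        state = make_state(rng.uniform(-2, 2, (20, 2)))
        f = mechanical_forces(state, cfg)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)

    @pytest.mark.parametrize("n", [2, 5, 30])
    def test_matches_brute_force_oracle(self, cfg, n):
        """Neighbour-list assembly == O(n^2) direct pair summation."""
        rng = np.random.default_rng(n)
        state = make_state(rng.uniform(-3, 3, (n, 2)))
        f = mechanical_forces(state, cfg)

        brute = np.zeros((n, 2))
        pos = state.cells.pos
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[j] - pos[i]
                dist = np.hypot(*d)
                if dist >= cfg.R_int or dist == 0:
                    continue
                scalar = pair_force_scalar(dist, 1.0, "cell-cell", cfg)
                fv = scalar * d / dist
                brute[i] += fv
                brute[j] -= fv
        assert np.allclose(f, brute, atol=1e-12)

    def test_attraction_points_toward_neighbour(self, cfg):
        state = make_state([[0.0, 0.0], [1.3, 0.0]])  # stretched: adhesive
        f = mechanical_forces(state, cfg)
        assert f[0, 0] > 0 and f[1, 0] < 0

    def test_necrotic_spring_scale_weakens_force(self, cfg):
        state = make_state([[0.0, 0.0], [1.3, 0.0]])
        f_full = mechanical_forces(state, cfg)
        state.cells.spring_scale[0] = 0.5
        f_weak = mechanical_forces(state, cfg)
        assert np.allclose(f_weak, 0.5 * f_full)


class TestRandomForces:
    def test_zero_coefficient_zero_force(self, rng):
        cfg = make_config({"D_rand": 0.0})
        state = make_state(rng.uniform(-1, 1, (5, 2)))
        assert np.all(random_forces(state, cfg, rng) == 0.0)

    def test_brownian_displacement_variance(self):
        """Per-component MSD grows as 2 D t for an isolated agent."""
        cfg = make_config({"D_rand": 0.02})
        state = make_state([[0.0, 0.0]])
        rng = np.random.default_rng(5)
        n_steps = 20_000
        disp = np.zeros(2)
        sq = []
        for _ in range(n_steps):
            f = random_forces(state, cfg, rng)
            disp = disp + (cfg.dt / cfg.nu) * f[0]
            sq.append(disp @ disp)
        t = n_steps * cfg.dt
        expected = 4.0 * cfg.D_rand * t  # 2 components x 2Dt
        # single path: compare time-average slope loosely (3 sigma-ish)
        msd_rate = np.polyfit(cfg.dt * np.arange(1, n_steps + 1), sq, 1)[0]
        assert msd_rate == pytest.approx(4.0 * cfg.D_rand, rel=0.25)

    def test_seeded_determinism(self, cfg):
        state = make_state([[0.0, 0.0], [1.0, 1.0]])
        f1 = random_forces(state, cfg, np.random.default_rng(9))
        f2 = random_forces(state, cfg, np.random.default_rng(9))
        assert np.array_equal(f1, f2)


def _brute_alpha_boundary(points, probe):
    """Empty-disc oracle: p is a boundary point iff some disc of radius
    ``probe`` through p and a companion (or p alone for isolated points)
    contains no other point in its interior."""
    pts = np.asarray(points, float)
    n = len(pts)
    boundary = set()
    for i in range(n):
        # isolated: no neighbour within 2*probe
        d = np.hypot(*(pts - pts[i]).T)
        others = np.delete(np.arange(n), i)
        if (d[others] > 2 * probe).all():
            boundary.add(i)
    for i in range(n):
        for j in range(i + 1, n):
            pij = pts[j] - pts[i]
            dist = np.hypot(*pij)
            if dist > 2 * probe or dist == 0:
                continue
            mid = (pts[i] + pts[j]) / 2
            h = np.sqrt(probe**2 - (dist / 2) ** 2)
            perp = np.array([-pij[1], pij[0]]) / dist
            for centre in (mid + h * perp, mid - h * perp):
                dd = np.hypot(*(pts - centre).T)
                mask = np.ones(n, bool)
                mask[[i, j]] = False
                if (dd[mask] > probe - 1e-9).all():
                    boundary.update((i, j))
    return np.array(sorted(boundary))


class TestAlphaShape:
    def test_three_points_all_boundary(self):
        idx = alpha_shape_boundary(np.array([[0, 0], [1, 0], [0, 1.0]]), alpha=0.5)
        assert set(idx) == {0, 1, 2}

    def test_hexagon_with_centre(self):
        """Unit hexagon ring + centre at alpha = R_cell: centre interior."""
        th = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.vstack([np.column_stack([np.cos(th), np.sin(th)]), [[0.0, 0.0]]])
        idx = alpha_shape_boundary(pts, alpha=0.5)
        assert set(idx) == {0, 1, 2, 3, 4, 5}

    def test_collinear_points_all_boundary(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        idx = alpha_shape_boundary(pts, alpha=0.5)
        assert set(idx) == set(range(5))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_empty_disc_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-3, 3, (25, 2))
        idx = alpha_shape_boundary(pts, alpha=0.5)
        oracle = _brute_alpha_boundary(pts, probe=2.0)  # probe radius = 1/alpha
        assert np.array_equal(idx, oracle)


class TestSurfaceTension:
    def test_boundary_cell_pulled_toward_centroid(self):
        cfg = make_config({"beta": 1.0})
        state = make_state([[3.0, 0.0], [0.0, 0.0], [-3.0, 0.0], [0.0, 3.0], [0.0, -3.0]])
        state.cells.pos -= state.centroid  # centroid at origin
        state.boundary_ids = np.array([0], dtype=np.int64)
        f = surface_tension_forces(state, cfg)
        assert np.allclose(f[0], [-1.0, 0.0])
        assert np.allclose(f[1:], 0.0)

    def test_beta_zero_no_contribution(self, rng):
        cfg = make_config({"beta": 0.0})
        state = make_state(rng.uniform(-2, 2, (10, 2)))
        state.boundary_ids = state.cells.ids.copy()
        assert np.all(surface_tension_forces(state, cfg) == 0.0)

    def test_symmetric_ring_net_zero(self):
        cfg = make_config({"beta": 2.0})
        th = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        state = make_state(4.0 * np.column_stack([np.cos(th), np.sin(th)]))
        state.boundary_ids = state.cells.ids.copy()
        f = surface_tension_forces(state, cfg)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)
        # each cell pulled inward with magnitude beta
        assert np.allclose(np.hypot(f[:, 0], f[:, 1]), 2.0)


class TestAdvancePositions:
    def test_zero_force_no_motion(self, cfg):
        state = make_state([[1.0, 2.0]])
        advance_positions(state, np.zeros((1, 2)), cfg)
        assert np.allclose(state.cells.pos, [[1.0, 2.0]])

    def test_euler_closed_form_constant_force(self):
        cfg = make_config({"nu": 2.0})
        state = make_state(np.zeros((0, 2)))
        beads = BeadArrays(1)
        state.beads = beads
        F = np.array([[3.0, -1.0]])
        for _ in range(60):
            advance_positions(state, F, cfg)
        expected = 60 * cfg.dt * F[0] / cfg.nu
        assert np.allclose(state.beads.pos[0], expected)

    def test_halved_dt_doubled_steps_identical(self):
        F = np.array([[1.0, 0.5]])
        cfg1 = make_config({"dt": 1 / 120})
        cfg2 = make_config({"dt": 1 / 240})
        s1 = make_state([[0.0, 0.0]])
        s2 = make_state([[0.0, 0.0]])
        for _ in range(10):
            advance_positions(s1, F, cfg1)
        for _ in range(20):
            advance_positions(s2, F, cfg2)
        assert np.allclose(s1.cells.pos, s2.cells.pos)

    def test_nonfinite_force_rejected(self, cfg):
        state = make_state([[0.0, 0.0]])
        with pytest.raises(FloatingPointError):
            advance_positions(state, np.array([[np.nan, 0.0]]), cfg)


class TestRelaxationFixedPoint:
    def test_cluster_reaches_mechanical_fixed_point(self):
        """With no noise, tension or growth, springs relax to rest."""
        cfg = make_config({"beta": 0.0, "D_rand": 0.0})
        rng = np.random.default_rng(2)
        state = make_state(rng.uniform(-1.5, 1.5, (12, 2)))
        last = None
        for _ in range(4000):
            f = mechanical_forces(state, cfg)
            before = state.cells.pos.copy()
            advance_positions(state, f, cfg)
            last = np.abs(state.cells.pos - before).max()
        assert last < 1e-7
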