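"""Phenotype state machine, oxygen-gated clocks, division, necrosis, sizes."""

import numpy as np
import pytest

from spheroidabm.cells import (
    ALLOWED_TRANSITIONS,
    advance_timers,
    advance_timers_arrays,
    maybe_divide,
    maybe_necrose,
    necrose_arrays,
    phenotype_from_oxygen,
    remove_dead,
    update_phenotype,
    update_phenotype_arrays,
    update_size,
    update_size_arrays,
)
from spheroidabm.state import Cell, Phenotype, make_config

from conftest import make_state


def _cell(phenotype=Phenotype.PROLIFERATIVE, **kw):
    defaults = dict(
        id=0,
        pos=np.zeros(2),
        phenotype=phenotype,
        T_cycle=0.0,
        tau_i=16.0,
        T_hyp=0.0,
        tau_hyp_i=8.0,
        tau_nec_i=8.0,
        s_i=0.5,
        s_birth=0.5,
    )
    defaults.update(kw)
    return Cell(**defaults)


class TestUpdatePhenotype:
    def test_oxygen_exactly_at_quiescence_threshold(self, cfg):
        # the quiescence threshold is inclusive: omega == omega_q -> quiescent
        cell = update_phenotype(_cell(), cfg.omega_q, cfg)
        assert cell.phenotype == Phenotype.QUIESCENT

    def test_full_oxygen_proliferative(self, cfg):
        cell = update_phenotype(_cell(Phenotype.QUIESCENT), 1.0, cfg)
        assert cell.phenotype == Phenotype.PROLIFERATIVE

    def test_hypoxia_threshold_inclusive(self, cfg):
        cell = update_phenotype(_cell(), cfg.omega_h, cfg)
        assert cell.phenotype == Phenotype.HYPOXIC

    def test_recovery_from_hypoxia_resets_clock(self, cfg):
        cell = _cell(Phenotype.HYPOXIC, T_hyp=3.0)
        cell = update_phenotype(cell, cfg.omega_h + 1e-6, cfg)
        assert cell.phenotype == Phenotype.QUIESCENT
        assert cell.T_hyp == 0.0

    def test_necrotic_is_noop_with_warning(self, cfg):
        cell = _cell(Phenotype.NECROTIC, t_necrosis=1.0, s_onset=0.5)
        with pytest.warns(UserWarning):
            out = update_phenotype(cell, 1.0, cfg)
        assert out.phenotype == Phenotype.NECROTIC

    def test_all_oxygen_transitions_legal(self, cfg):
        """Any oxygen-driven switch is in the legal transition set."""
        levels = [0.0, cfg.omega_h, 0.4, cfg.omega_q, 0.9, 1.0]
        for start in (Phenotype.PROLIFERATIVE, Phenotype.QUIESCENT, Phenotype.HYPOXIC):
            for omega in levels:
                new = Phenotype(int(phenotype_from_oxygen(omega, cfg)))
                if new != start:
                    # the state machine routes P<->H via Q implicitly in one
                    # step only when oxygen jumps across both thresholds;
                    # each elementary hop must be legal
                    hops = {
                        (Phenotype.PROLIFERATIVE, Phenotype.HYPOXIC): [
                            (Phenotype.PROLIFERATIVE, Phenotype.QUIESCENT),
                            (Phenotype.QUIESCENT, Phenotype.HYPOXIC),
                        ],
                        (Phenotype.HYPOXIC, Phenotype.PROLIFERATIVE): [
                            (Phenotype.HYPOXIC, Phenotype.QUIESCENT),
                            (Phenotype.QUIESCENT, Phenotype.PROLIFERATIVE),
                        ],
                    }.get((start, new), [(start, new)])
                    for hop in hops:
                        assert hop in ALLOWED_TRANSITIONS


class TestAdvanceTimers:
    def test_cycle_runs_above_quiescence_threshold(self, cfg):
        cell = advance_timers(_cell(), 0.9, cfg.dt, cfg)
        assert cell.T_cycle == pytest.approx(cfg.dt)
        assert cell.T_hyp == 0.0

    def test_between_thresholds_neither_clock_runs(self, cfg):
        cell = _cell(Phenotype.QUIESCENT, T_cycle=1.0, T_hyp=2.0)
        cell = advance_timers(cell, 0.4, cfg.dt, cfg)
        assert cell.T_cycle == 1.0
        assert cell.T_hyp == 0.0  # reset above the hypoxia threshold

    def test_hypoxic_accumulation_exact(self, cfg):
        cell = _cell(Phenotype.HYPOXIC)
        for _ in range(7):
            cell = advance_timers(cell, 0.1, cfg.dt, cfg)
        assert cell.T_hyp == pytest.approx(7 * cfg.dt)

    def test_scalar_and_vectorised_paths_agree(self, cfg, rng):
        state = make_state(rng.uniform(-1, 1, (40, 2)))
        state.cells.phenotype = rng.integers(0, 3, 40).astype(np.int8)
        state.cells.T_cycle = rng.uniform(0, 10, 40)
        state.cells.T_hyp = rng.uniform(0, 4, 40)
        omega = rng.uniform(0, 1, 40)

        expected = []
        for i in range(40):
            c = state.cells.view(i)
            c = advance_timers(c, omega[i], cfg.dt, cfg)
            expected.append((c.T_cycle, c.T_hyp))
        advance_timers_arrays(state.cells, omega, cfg.dt, cfg)
        got = list(zip(state.cells.T_cycle, state.cells.T_hyp))
        assert np.allclose(got, expected)

    def test_phenotype_paths_agree(self, cfg, rng):
        state = make_state(rng.uniform(-1, 1, (40, 2)))
        state.cells.phenotype = rng.integers(0, 3, 40).astype(np.int8)
        state.cells.T_hyp = rng.uniform(0, 4, 40)
        omega = rng.uniform(0, 1, 40)
        expected_ph, expected_Th = [], []
        for i in range(40):
            c = update_phenotype(state.cells.view(i), omega[i], cfg)
            expected_ph.append(int(c.phenotype))
            expected_Th.append(c.T_hyp)
        update_phenotype_arrays(state.cells, omega, cfg)
        assert list(state.cells.phenotype) == expected_ph
        assert np.allclose(state.cells.T_hyp, expected_Th)


class TestDivision:
    def test_no_division_before_clock_expires(self, cfg, rng):
        state = make_state([[0.0, 0.0]])
        cell = _cell(T_cycle=10.0, tau_i=16.0)
        assert maybe_divide(cell, state, cfg, rng) is None

    def test_daughter_placed_half_diameter_away(self, cfg, rng):
        state = make_state([[1.0, 2.0]])
        cell = _cell(pos=np.array([1.0, 2.0]), T_cycle=16.0, tau_i=16.0)
        daughter = maybe_divide(cell, state, cfg, rng)
        assert daughter is not None
        assert np.hypot(*(daughter.pos - cell.pos)) == pytest.approx(0.5)

    def test_both_cells_reset_and_redraw(self, cfg, rng):
        state = make_state([[0.0, 0.0]])
        cell = _cell(T_cycle=17.0, tau_i=16.0)
        daughter = maybe_divide(cell, state, cfg, rng)
        assert cell.T_cycle == 0.0 and daughter.T_cycle == 0.0
        assert 0.75 * cfg.tau <= cell.tau_i <= 1.25 * cfg.tau
        assert 0.75 * cfg.tau <= daughter.tau_i <= 1.25 * cfg.tau
        # only the daughter is born small by default
        assert daughter.s_i == cfg.R_cell / 2.0
        assert cell.s_i == cfg.R_cell

    def test_label_is_heritable(self, cfg, rng):
        state = make_state([[0.0, 0.0]])
        cell = _cell(T_cycle=16.0, tau_i=16.0, labelled=True)
        daughter = maybe_divide(cell, state, cfg, rng)
        assert daughter.labelled


class TestNecrosis:
    def test_threshold_equality_triggers(self, cfg):
        cell = _cell(Phenotype.HYPOXIC, T_hyp=8.0, tau_hyp_i=8.0)
        cell = maybe_necrose(cell, cfg, t=100.0)
        assert cell.phenotype == Phenotype.NECROTIC
        assert cell.t_necrosis == 100.0

    def test_below_threshold_stays_hypoxic(self, cfg):
        cell = _cell(Phenotype.HYPOXIC, T_hyp=8.0 - cfg.dt, tau_hyp_i=8.0)
        assert maybe_necrose(cell, cfg).phenotype == Phenotype.HYPOXIC

    def test_necrosis_is_absorbing(self, cfg):
        cell = _cell(Phenotype.HYPOXIC, T_hyp=9.0, tau_hyp_i=8.0)
        cell = maybe_necrose(cell, cfg, t=0.0)
        with pytest.warns(UserWarning):
            cell = update_phenotype(cell, 1.0, cfg)
        assert cell.phenotype == Phenotype.NECROTIC

    def test_vectorised_necrosis_matches(self, cfg, rng):
        state = make_state(rng.uniform(-1, 1, (20, 2)))
        state.cells.phenotype[:] = int(Phenotype.HYPOXIC)
        state.cells.T_hyp = rng.uniform(6, 10, 20)
        state.cells.tau_hyp_i[:] = 8.0
        turned = necrose_arrays(state.cells, t=5.0)
        assert np.array_equal(turned, state.cells.T_hyp >= 8.0)
        assert np.all(state.cells.t_necrosis[turned] == 5.0)


class TestSizes:
    def test_newborn_ramp_midpoint(self, cfg):
        cell = _cell(s_i=0.25, s_birth=0.25, t_birth=10.0)
        cell = update_size(cell, 10.5, cfg)
        assert cell.s_i == pytest.approx(0.75 * cfg.R_cell)

    def test_mature_cell_unchanged(self, cfg):
        cell = _cell(s_i=0.5, s_birth=0.5, t_birth=0.0)
        assert update_size(cell, 50.0, cfg).s_i == cfg.R_cell

    def test_necrotic_decay_reaches_zero(self, cfg):
        cell = _cell(Phenotype.NECROTIC, t_necrosis=20.0, s_onset=0.5, tau_nec_i=8.0)
        cell = update_size(cell, 28.0, cfg)
        assert cell.s_i == 0.0
        assert cell.spring_scale == 0.0

    def test_vectorised_sizes_match(self, cfg, rng):
        state = make_state(rng.uniform(-1, 1, (30, 2)))
        state.cells.phenotype[:15] = int(Phenotype.NECROTIC)
        state.cells.t_necrosis[:15] = rng.uniform(0, 5, 15)
        state.cells.s_onset[:15] = 0.5
        state.cells.t_birth[15:] = rng.uniform(5, 7, 15)
        state.cells.s_birth[15:] = 0.25
        t = 7.0
        expected = [update_size(state.cells.view(i), t, cfg).s_i for i in range(30)]
        update_size_arrays(state.cells, t, cfg)
        assert np.allclose(state.cells.s, expected)


class TestRemoval:
    def test_no_zero_size_no_change(self, rng):
        state = make_state(rng.uniform(-1, 1, (5, 2)))
        remove_dead(state)
        assert len(state.cells) == 5

    def test_zero_size_cell_removed(self, rng):
        state = make_state(rng.uniform(-1, 1, (5, 2)))
        state.cells.s[2] = 0.0
        gone_id = state.cells.ids[2]
        remove_dead(state)
        assert len(state.cells) == 4
        assert gone_id not in state.cells.ids
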