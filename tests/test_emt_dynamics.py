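"""Tether-dynamics hazards, prohibition gates, and the EMT state machine."""

import math

import numpy as np
import pytest

from gastrusim.emt_dynamics import (
    direction_change_probability,
    emt_conversion_probability,
    reversion_probability,
    untether_probability,
    vertical_step,
)
from gastrusim.mathkit import logistic_probability, per_tick_probability
from gastrusim.model_state import Params, SimulationLog, initialize_embryo


def small_state(seed=7):
    p = Params()
    p.n_initial_epiblast = 40
    p.n_initial_sae = 4
    return initialize_embryo(p, seed=seed)


class TestEmtHazard:
    def test_midpoint(self):
        assert logistic_probability(8.0, Params().emt.logistic) == pytest.approx(
            0.02 + 0.979 / 2.0, abs=1e-12
        )

    def test_base_rate_of_ingression(self):
        # the low-N_eff regime: ~0.0203/hr
        p0 = logistic_probability(0.0, Params().emt.logistic)
        assert p0 == pytest.approx(0.02 + 0.979 / (1 + math.exp(8.0)), abs=1e-12)

    def test_high_effect_value(self):
        assert logistic_probability(10.0, Params().emt.logistic) == pytest.approx(
            0.02 + 0.979 / (1 + math.exp(-2.0)), abs=1e-12
        )

    def test_non_epithelium_rejected(self):
        state = small_state()
        cell = state.cells[0]
        cell.kind = "emt"
        with pytest.raises(ValueError):
            emt_conversion_probability(cell, state)


class TestDirectionChange:
    def test_descending_midpoint(self):
        assert direction_change_probability(-5.0, "descending", Params()) == pytest.approx(0.2)

    def test_descending_deep_asymptote(self):
        assert direction_change_probability(-1e6, "descending", Params()) == 0.0

    def test_ascending_deep_asymptote(self):
        assert direction_change_probability(-1e6, "ascending", Params()) == pytest.approx(0.8)


class TestReversion:
    def _emt_cell(self, state, z, tethered=True):
        cell = state.cells[0]
        cell.kind = "emt"
        cell.tethered = tethered
        cell.vertical_direction = "descending"
        cell.z = z
        return cell

    def test_midpoint_value(self):
        state = small_state()
        for c in state.cells:
            c.nodal_positive = False
        cell = self._emt_cell(state, z=-5.0)
        assert reversion_probability(cell, state) == pytest.approx(0.60, abs=1e-12)

    def test_untethered_prohibited_at_any_depth(self):
        state = small_state()
        for z in (-1.0, -5.0, -15.0, -50.0):
            cell = self._emt_cell(state, z=z, tethered=False)
            assert reversion_probability(cell, state) == 0.0

    def test_below_bm_prohibited(self):
        state = small_state()
        cell = self._emt_cell(state, z=-10.5)
        assert reversion_probability(cell, state) == 0.0

    def test_nodal_threshold_prohibits(self):
        state = small_state()
        for c in state.cells:
            c.nodal_positive = False
        cell = self._emt_cell(state, z=-5.0)
        assert reversion_probability(cell, state) > 0
        # a disinhibited Nodal-positive cell has level >= 1.0 (self term)
        from gastrusim.lower_layer import LowerLayer

        state.lower = LowerLayer(disc_radius=state.lower.disc_radius, front_y=1e9)
        cell.nodal_positive = True
        state.invalidate_tessellation()
        assert reversion_probability(cell, state) == 0.0


class TestUntether:
    def test_prohibited_above_bm(self):
        assert untether_probability(-8.0, Params()) == 0.0
        assert untether_probability(-10.0, Params()) == 0.0
        assert untether_probability(0.0, Params()) == 0.0

    def test_midpoint(self):
        assert untether_probability(-12.5, Params()) == pytest.approx(0.4995, abs=1e-12)

    def test_increases_with_depth(self):
        p = Params()
        vals = [untether_probability(z, p) for z in (-10.5, -12.0, -15.0, -20.0, -30.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.999, abs=1e-6)


class TestVerticalStep:
    def test_reverting_cell_restores_epithelium_and_states(self):
        state = small_state()
        for c in state.cells:
            c.nodal_positive = False
        cell = state.cells[0]
        cell.kind = "emt"
        cell.tethered = True
        cell.vertical_direction = "ascending"
        cell.z = -1.0
        cell.wntpcp_positive = True
        cell.oi_axis = np.array([1.0, 0.0])
        log = SimulationLog()
        # force the reversion draw to succeed deterministically
        class AlwaysLow:
            def random(self, *a):
                return 0.0 if not a else np.zeros(a[0])

        state.rng = AlwaysLow()
        vertical_step(cell, state, log)
        assert cell.kind == "epithelium"
        assert cell.z == 0.0
        assert cell.wntpcp_positive  # signalling states survive reversion
        assert any(e["event"] == "reversion" for e in log.events)

    def test_terminal_meso_loses_positivity(self):
        state = small_state()
        cell = state.cells[0]
        cell.kind = "emt"
        cell.tethered = False
        cell.vertical_direction = "descending"
        cell.z = -24.0
        cell.nodal_positive = True
        cell.wntpcp_positive = True
        log = SimulationLog()
        vertical_step(cell, state, log)
        assert cell.kind == "meso"
        assert not cell.nodal_positive and not cell.wntpcp_positive
        assert any(e["event"] == "meso" for e in log.events)

    def test_plane_is_a_ceiling(self):
        state = small_state()
        for c in state.cells:
            c.nodal_positive = True  # level >= threshold: no reversion draw
        cell = state.cells[0]
        cell.kind = "emt"
        cell.tethered = True
        cell.vertical_direction = "ascending"
        cell.z = -0.5

        class NeverFlip:
            def random(self, *a):
                return 0.999999 if not a else np.full(a[0], 0.999999)

        state.rng = NeverFlip()
        vertical_step(cell, state)
        assert cell.z == 0.0

    def test_kind_transition_dag(self):
        """epithelium -> t-emt -> {epithelium, u-emt}; u-emt -> meso only."""
        state = small_state(seed=1)
        rng = np.random.default_rng(0)
        state.rng = rng
        for c in state.cells:
            c.nodal_positive = False
        transitions = set()
        cell = state.cells[0]
        cell.kind = "emt"
        cell.tethered = True
        cell.vertical_direction = "descending"
        for _ in range(400):
            before = (cell.kind, cell.tethered)
            vertical_step(cell, state)
            after = (cell.kind, cell.tethered)
            if before != after:
                transitions.add((before, after))
            if cell.kind == "meso":
                vertical_step(cell, state) if cell.kind == "emt" else None
                break
            if cell.kind == "epithelium":
                cell.kind = "emt"
                cell.tethered = True
                cell.vertical_direction = "descending"
                cell.z = 0.0
        allowed = {
            (("emt", True), ("epithelium", False)),
            (("emt", True), ("emt", False)),
            (("emt", False), ("meso", False)),
        }
        assert transitions <= allowed


class TestCommunityEffectOccupancy:
    def test_ingression_completion_rises_with_neighbour_effect(self):
        """Monte-Carlo: N_eff = 8 completes >10x more ingressions than N_eff = 0."""
        p = Params()
        rng = np.random.default_rng(42)
        dt = p.dt_hr

        def completed_fraction(n_eff, n_cells=3000, ticks=36):
            p_start = per_tick_probability(
                logistic_probability(n_eff, p.emt.logistic), dt
            )
            # follow independent cells through start -> bobbing -> untether
            done = 0
            for _ in range(n_cells):
                z, kind, tethered, direction = 0.0, "epithelium", False, None
                for _ in range(ticks):
                    if kind == "epithelium":
                        if rng.random() < p_start:
                            kind, tethered, direction = "emt", True, "descending"
                        continue
                    if tethered:
                        p_flip = per_tick_probability(
                            direction_change_probability(z, direction, p), dt
                        )
                        if rng.random() < p_flip:
                            direction = "ascending" if direction == "descending" else "descending"
                        z += p.vertical_speed_um_per_tick * (1 if direction == "ascending" else -1)
                        z = min(z, 0.0)
                        # reversion gated off when the community is active
                        if n_eff < 1.0 and z >= p.bm_depth_um:
                            p_rev = per_tick_probability(
                                logistic_probability(z, p.reversion), dt
                            )
                            if rng.random() < p_rev:
                                kind, tethered, z = "epithelium", False, 0.0
                                continue
                        if z < p.bm_depth_um:
                            p_unt = per_tick_probability(untether_probability(z, p), dt)
                            if rng.random() < p_unt:
                                tethered = False
                    else:
                        z -= p.vertical_speed_um_per_tick
                        if z <= p.meso_depth_um:
                            done += 1
                            break
            return done / n_cells

        low = completed_fraction(0.0)
        high = completed_fraction(8.0)
        assert high > 10 * max(low, 1e-4)
        # the low regime really is the base-rate regime: a few per cent over 6 h
        assert low < 0.05
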