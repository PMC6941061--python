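import math

import numpy as np
import pytest

from rcm import (ConsumptionModel, DiffusionOperator, PatchState,
                 compute_flow_cascade, convective_renewal, po2_to_content,
                 preset_parameters)
from rcm.oxygen_dynamics import consumption_step
from rcm.perfusion import FlowState
from rcm.units import MS_PER_MIN

from conftest import mini_grid


def _state(q_values) -> PatchState:
    return PatchState(q=np.asarray(q_values, dtype=float))


def _flow(params):
    return compute_flow_cascade(params)


class TestConvection:
    def test_feed_is_a_fixed_point(self, params0):
        grid = mini_grid("C", params0)
        q_feed = po2_to_content(params0.PTC_feed)
        state = _state([q_feed])
        convective_renewal(grid, state, _flow(params0), params0, 0.4, 0.0)
        assert state.q[0] == pytest.approx(q_feed)

    def test_single_tick_renewal_from_empty(self, params0):
        # 40 % renewal toward a 56 mmHg feed (75.04 amol) -> 30.02 amol
        grid = mini_grid("C", params0)
        state = _state([0.0])
        convective_renewal(grid, state, _flow(params0), params0, 0.4, 0.0)
        assert state.q[0] == pytest.approx(30.016)

    def test_ischemia_changes_nothing(self, params0):
        grid = mini_grid("CL", params0)
        state = _state([12.0, 34.0])
        convective_renewal(grid, state, _flow(params0.replace(RBF=0.0)),
                           params0, 0.0, 0.0)
        assert state.q.tolist() == [12.0, 34.0]

    def test_factor_outside_unit_interval_rejected(self, params0):
        grid = mini_grid("C", params0)
        with pytest.raises(ValueError):
            convective_renewal(grid, _state([0.0]), _flow(params0),
                               params0, 1.2, 0.0)

    def test_budget_terms_balance(self, params0):
        grid = mini_grid("CL", params0)
        state = _state([10.0, 20.0])
        before = state.q.sum()
        p = params0.replace(Hb_active=False)
        terms = convective_renewal(grid, state, _flow(p), p, 0.3, 0.1)
        assert state.q.sum() - before == pytest.approx(
            terms["convective_in"] - terms["convective_out"])


class TestDiffusion:
    def test_unidirectional_flow_magnitude(self, params0, two_epi):
        # (1/10 µm) * 1.1 µm²/ms * 800 µm² * 0.075 amol/µm³ = 6.6 amol/ms
        op = DiffusionOperator.from_grid(two_epi, params0)
        outflow_rate = -op.matrix[0, 0]
        assert outflow_rate * 75.0 == pytest.approx(6.6)

    def test_equal_concentrations_exchange_nothing(self, params0, two_epi):
        op = DiffusionOperator.from_grid(two_epi, params0)
        state = _state([75.0, 75.0])
        op.step(state, 1.0)
        assert state.q.tolist() == pytest.approx([75.0, 75.0])

    def test_closed_system_conserves_oxygen(self, params0):
        grid = mini_grid("ELI\nCEE", params0)
        op = DiffusionOperator.from_grid(grid, params0)
        state = _state([10.0, 80.0, 5.0, 40.0, 0.0, 25.0])
        total = state.q.sum()
        for _ in range(10_000):
            op.step(state, 0.5)
        assert state.q.sum() == pytest.approx(total, rel=1e-12)
        # closed boundaries: everything relaxes to the common mean
        assert state.q == pytest.approx(np.full(6, total / 6), abs=1e-6)

    def test_two_patch_relaxation_matches_closed_form(self, params0, two_epi):
        # dΔq/dt = -2k Δq with k = D*S/(L*V); trajectory within 1 %
        op = DiffusionOperator.from_grid(two_epi, params0)
        k = 1.1 * 800 / (10 * 1000)
        tick = 0.1
        state = _state([100.0, 0.0])
        for n in (1, 10, 50, 100):
            state = _state([100.0, 0.0])
            for _ in range(n):
                op.step(state, tick)
            expected = 100.0 * math.exp(-2 * k * n * tick)
            # within 1 % of the initial amplitude at every checkpoint
            assert state.q[0] - state.q[1] == pytest.approx(expected, abs=1.0)

    def test_stability_check_names_the_admissible_tick(self, params0):
        grid = mini_grid("EL\nLE", params0)
        op = DiffusionOperator.from_grid(grid, params0)
        with pytest.raises(ValueError, match="admissible tick"):
            op.check_stability(20.0)


class TestConsumption:
    def test_zero_oxygen_zero_consumption(self, params0, grid1540):
        model = ConsumptionModel.from_grid(grid1540, _flow(params0), params0)
        state = _state(np.zeros(grid1540.n_patches))
        consumed = model.step(state, 1.0)
        assert consumed == 0.0
        assert (state.q == 0.0).all()

    def test_half_maximal_at_km(self, params0):
        grid = mini_grid("E", params0)
        model = ConsumptionModel.from_grid(grid, _flow(params0), params0)
        q_km = params0.Km  # 1 µM == 1 amol in a 1000 µm³ patch
        state = _state([q_km])
        consumed = model.step(state, 1e-3)  # tiny tick: rate, not depletion
        assert consumed == pytest.approx(0.5 * model.jmax[0] * 1e-3, rel=1e-3)

    def test_transport_cost_magnitude(self, params0, grid1540):
        # 0.33/4.5 * 0.81/1.15 * 1.92e5 amol/min ~ 9.9e3 amol/min per patch
        model = ConsumptionModel.from_grid(grid1540, _flow(params0), params0)
        jtna_per_min = model.jtna_per_epi * MS_PER_MIN
        assert jtna_per_min == pytest.approx(9.90e3, rel=5e-3)

    def test_consumption_floors_at_zero(self, params0):
        grid = mini_grid("E", params0)
        model = ConsumptionModel.from_grid(grid, _flow(params0), params0)
        state = _state([1e-6])
        consumed = model.step(state, 20.0)
        assert consumed <= 1e-6
        assert state.q[0] >= 0.0

    def test_lum_patches_do_not_consume(self, params0):
        grid = mini_grid("LE", params0)
        model = ConsumptionModel.from_grid(grid, _flow(params0), params0)
        assert model.jmax[0] == 0.0
        assert model.jmax[1] > 0.0

    def test_muscle_override(self, params0):
        grid = mini_grid("EE", params0)
        grid.muscle_qo2 = 3.0
        model = ConsumptionModel.from_grid(grid, _flow(params0), params0)
        assert model.jmax[0] == pytest.approx(0.05)
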