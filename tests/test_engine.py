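import math

import numpy as np
import pytest

from rcm import Protocol, Simulation, TissueSpec, build_tissue, run_transient
from rcm.engine import MAX_STEADY_TICKS


class TestProtocol:
    def test_ischemia_zeroes_flow(self):
        assert Protocol.ischemia().overrides == {"RBF": 0.0}

    def test_anoxemia_zeroes_feeds(self):
        assert Protocol.anoxemia().overrides == {"PTC_feed": 0.0,
                                                 "LUM_feed": 0.0}

    def test_negative_switch_time_rejected(self):
        with pytest.raises(ValueError):
            Protocol(switch_time_ms=-1.0)


class TestStep:
    def test_dead_model_stays_at_zero(self, params0, grid1540):
        p = params0.replace(RBF=0.0, PTC_feed=0.0, LUM_feed=0.0,
                            JmaxHK_epi=0.0, Jmax_cap=0.0, Jmax_int=0.0,
                            Hb_active=False)
        sim = Simulation(p, grid1540)
        sim.run_ticks(50)
        assert (sim.state.q == 0.0).all()

    def test_determinism(self, params0, grid1540):
        a = Simulation(params0, grid1540)
        b = Simulation(params0, grid1540)
        a.run_ticks(200)
        b.run_ticks(200)
        assert a.state.q.tobytes() == b.state.q.tobytes()
        assert a.monitor.tissue_po2 == b.monitor.tissue_po2

    def test_oxygen_budget_closes_each_tick(self, params0, grid1540):
        sim = Simulation(params0, grid1540)
        sim.run_ticks(300)
        assert sim.budget_residual < 1e-9

    def test_budget_closes_without_hemoglobin(self, params0, grid1540):
        sim = Simulation(params0.replace(Hb_active=False), grid1540)
        sim.run_ticks(300)
        assert sim.budget_residual < 1e-9

    def test_capillaries_equilibrate_to_feed_within_milliseconds(
            self, params0, grid1540):
        sim = Simulation(params0, grid1540)
        sim.run_ticks(20)
        assert sim.mean_po2("PTC") == pytest.approx(params0.PTC_feed, abs=3.0)

    def test_compartment_equilibration_ordering(self, params0, grid1540):
        # capillaries fill first, then lumina, then epithelium, and the
        # low-consuming interstitium last
        sim = Simulation(params0, grid1540, sample_interval_ms=5.0)
        sim.run_to_steady_state()
        mon = sim.monitor
        t = np.asarray(mon.times_ms)

        def rise_half_time(series):
            v = np.asarray(series)
            final = v[-1]
            return float(np.interp(0.5 * final, v, t))

        halves = {k: rise_half_time(mon.compartment_po2[k])
                  for k in ("PTC", "LUM", "EPI", "INT")}
        assert halves["PTC"] < halves["LUM"] <= halves["EPI"] < halves["INT"]
        assert halves["PTC"] <= 10.0


class TestSteadyState:
    def test_reaches_steady_state_quickly(self, params0, grid1540):
        sim = Simulation(params0, grid1540)
        sst = sim.run_to_steady_state()
        assert sim.tick_count < MAX_STEADY_TICKS
        assert 20.0 < sst < 60.0

    def test_operator_order_robustness(self, params0):
        # permuting hemoglobin and consumption within the tick moves the
        # steady state only by the first-order splitting error: below the
        # 0.1 mmHg tick-convergence bound at 0.5 ms, and at most twice
        # that at the default 1 ms tick
        from rcm import TissueSpec, build_tissue
        permuted = ("convection", "consumption", "diffusion", "hb")
        diffs = {}
        for tick in (1.0, 0.5):
            p = params0.replace(tick=tick)
            g = build_tissue(TissueSpec.from_name("1540"), p)
            a = Simulation(p, g).run_to_steady_state()
            b = Simulation(p, g, operator_order=permuted).run_to_steady_state()
            diffs[tick] = abs(a - b)
        assert diffs[0.5] < 0.1
        assert diffs[1.0] < 0.2

    def test_zero_everything_is_zero(self, params0, grid1540):
        p = params0.replace(PTC_feed=0.0, LUM_feed=0.0, JmaxHK_epi=0.0,
                            Jmax_cap=0.0, Jmax_int=0.0, frPR=0.0,
                            Hb_active=False)
        sim = Simulation(p, grid1540)
        sst = sim.run_to_steady_state()
        assert sst == pytest.approx(0.0, abs=1e-9)


class TestClamping:
    def test_clamped_patches_hold_their_po2(self, params0, grid1540):
        proto = Protocol(name="custom", clamps=[(0, 100.0), (33, 100.0)])
        sim = Simulation(params0, grid1540, proto)
        sim.run_ticks(100)
        po2 = sim.po2()
        assert po2[0] == pytest.approx(100.0)
        assert po2[33] == pytest.approx(100.0)
        assert sim.budget_residual < 1e-9

    def test_high_po2_source_has_local_influence_only(self, params0,
                                                      grid1540):
        base = Simulation(params0, grid1540)
        base.run_to_steady_state()
        proto = Protocol(name="custom", clamps=[(16 * 32 + 16, 100.0)])
        clamped = Simulation(params0, grid1540, proto)
        clamped.run_to_steady_state()
        dpo2 = clamped.po2() - base.po2()
        yy, xx = np.mgrid[0:32, 0:32]
        dist = np.hypot(yy - 16, xx - 16).ravel() * 10.0  # µm
        far = dist > 60.0
        assert np.abs(dpo2[far]).max() < 2.0


class TestTransient:
    def test_ischemic_decay_and_halving(self, paramsstar, grid1540):
        p = paramsstar.replace(Hb_active=False)
        res = run_transient(p, grid1540, Protocol.ischemia(),
                            horizon_ms=5_000.0)
        assert res.halved("tissue_po2") and res.halved("ptc_po2")
        assert 0.05 < res.t50["tissue_po2"] < 2.0
        assert res.t10["tissue_po2"] > res.t50["tissue_po2"]

    def test_hemoglobin_slows_the_ischemic_decay(self, paramsstar, grid1540):
        short = 800.0  # ms, enough to separate the two decays
        with_hb = Simulation(paramsstar, grid1540)
        with_hb.run_to_steady_state()
        with_hb.apply_overrides({"RBF": 0.0})
        no_hb = Simulation(paramsstar.replace(Hb_active=False), grid1540)
        no_hb.run_to_steady_state()
        no_hb.apply_overrides({"RBF": 0.0})
        n = round(short / paramsstar.tick)
        with_hb.run_ticks(n)
        no_hb.run_ticks(n)
        assert with_hb.mean_po2() > no_hb.mean_po2() + 5.0

    def test_never_halving_reports_beyond_horizon(self, params0, grid1540):
        # protocol that changes nothing: no variable ever halves
        proto = Protocol(name="custom", overrides={"RBF": params0.RBF})
        res = run_transient(params0, grid1540, proto, horizon_ms=100.0)
        assert math.isinf(res.t50["tissue_po2"])

    def test_anoxemic_washout_is_fast(self, paramsstar, grid1540):
        res = run_transient(paramsstar, grid1540, Protocol.anoxemia(),
                            horizon_ms=2_000.0, sample_interval_ms=2.0)
        assert res.t50["tissue_po2"] < 0.2     # tens of ms
        assert res.t50["ptc_po2"] < res.t50["tissue_po2"]
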