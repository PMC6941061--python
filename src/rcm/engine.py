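"""Tick loop, run protocols, steady-state detection and monitors.

A tick applies, in fixed order: (1) convective renewal of the perfused
patches, (2) hemoglobin kinetics on capillary patches, (3) lattice
diffusion, (4) consumption.  The order is a numerical choice; at the
default 1 ms tick the operators are near-commuting and permuting them
moves the steady state by far less than model accuracy.

Runs start from all-zero oxygen with capillary hemoglobin initialized
at the equilibrium saturation of the capillary feed.  Steady state is
declared when no compartment-mean PO₂ moves by more than 0.01 mmHg over
a trailing 100 ms window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .oxygen_dynamics import (ConsumptionModel, DiffusionOperator, PatchState,
                              convective_renewal, make_patch_state)
from .hemoglobin import hb_exchange_step
from .parameters import ParameterSet, po2_to_content
from .perfusion import FlowState, compute_flow_cascade, flow_factors
from .tissue import EPI, INT, LUM, PTC, TYPE_NAMES, TissueGrid

log = logging.getLogger(__name__)

MAX_STEADY_TICKS = 10_000
DIVERGENCE_PO2 = 200.0
STEADY_WINDOW_MS = 100.0
STEADY_TOL_MMHG = 0.01
MODEL_ACCURACY_MMHG = 2.2   # propagated parametric model accuracy


@dataclass
class Protocol:
    """A run protocol: optional input switch at a given time, plus clamps.

    ``overrides`` are ParameterSet fields applied at ``switch_time_ms``
    (e.g. ``{"RBF": 0.0}`` for ischemia, zero feeds for anoxemia).
    ``clamps`` is a list of (flat patch index, PO₂ mmHg) held fixed.
    """

    name: str = "steady"
    switch_time_ms: float = 0.0
    overrides: dict = field(default_factory=dict)
    clamps: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.switch_time_ms < 0:
            raise ValueError("switch time must be >= 0")
        if self.name not in ("steady", "ischemia", "anoxemia", "custom"):
            raise ValueError(f"unknown protocol {self.name!r}")

    @classmethod
    def ischemia(cls, switch_time_ms: float = 0.0) -> "Protocol":
        return cls(name="ischemia", switch_time_ms=switch_time_ms,
                   overrides={"RBF": 0.0})

    @classmethod
    def anoxemia(cls, switch_time_ms: float = 0.0) -> "Protocol":
        return cls(name="anoxemia", switch_time_ms=switch_time_ms,
                   overrides={"PTC_feed": 0.0, "LUM_feed": 0.0})


@dataclass
class Monitor:
    """Sampled time series of compartment means."""

    sample_interval_ms: float = 10.0
    times_ms: list = field(default_factory=list)
    tissue_po2: list = field(default_factory=list)
    compartment_po2: dict = field(default_factory=lambda: {
        "PTC": [], "EPI": [], "LUM": [], "INT": []})
    hb_sat: list = field(default_factory=list)
    qo2_total: list = field(default_factory=list)   # amol/ms

    def as_dict(self) -> dict:
        out = {"time_ms": np.asarray(self.times_ms),
               "tissue_po2": np.asarray(self.tissue_po2),
               "hb_sat": np.asarray(self.hb_sat),
               "qo2_total": np.asarray(self.qo2_total)}
        for k, v in self.compartment_po2.items():
            out[f"{k}_po2"] = np.asarray(v)
        return out


class Simulation:
    """One configured model instance: grid + parameters + protocol."""

    DEFAULT_ORDER = ("convection", "hb", "diffusion", "consumption")

    def __init__(self, params: ParameterSet, grid: TissueGrid,
                 protocol: Protocol | None = None,
                 sample_interval_ms: float = 10.0,
                 operator_order: tuple[str, ...] | None = None) -> None:
        self.operator_order = operator_order or self.DEFAULT_ORDER
        if set(self.operator_order) != set(self.DEFAULT_ORDER):
            raise ValueError(f"operator order must permute {self.DEFAULT_ORDER}")
        self.params = params
        self.grid = grid
        self.protocol = protocol or Protocol()
        self.flow: FlowState = compute_flow_cascade(params)
        self.cff, self.tff = flow_factors(self.flow, params, grid)
        self.diffusion = DiffusionOperator.from_grid(grid, params)
        self.diffusion.check_stability(params.tick)
        self.consumption = ConsumptionModel.from_grid(grid, self.flow, params)
        self.state: PatchState = make_patch_state(grid, params)
        self.tick_count = 0
        self.switched = False
        self.monitor = Monitor(sample_interval_ms=sample_interval_ms)
        self._masks = {name: grid.mask(code)
                       for code, name in TYPE_NAMES.items()}
        self._clamp_idx = np.asarray([i for i, _ in self.protocol.clamps],
                                     dtype=int)
        self._clamp_q = np.asarray(
            [po2_to_content(p, grid.volume_um3, params.alpha)
             for _, p in self.protocol.clamps])
        self._apply_clamps()
        self.budget_residual = 0.0     # worst relative closure error seen
        self._record()

    # -- bookkeeping -----------------------------------------------------
    @property
    def time_ms(self) -> float:
        return self.tick_count * self.params.tick

    def _apply_clamps(self) -> float:
        if self._clamp_idx.size == 0:
            return 0.0
        before = self.state.q[self._clamp_idx].sum()
        self.state.q[self._clamp_idx] = self._clamp_q
        return float(self._clamp_q.sum() - before)

    def _total_o2(self) -> float:
        total = float(self.state.q.sum())
        if self.state.hb is not None and self.params.Hb_active:
            total += float(self.state.hb.bound_o2.sum())
        return total

    def po2(self) -> np.ndarray:
        return self.state.po2(self.grid, self.params)

    def mean_po2(self, compartment: str | None = None) -> float:
        po2 = self.po2()
        if compartment is None:
            return float(po2.mean())       # equal patch volumes
        mask = self._masks[compartment]
        return float(po2[mask].mean()) if mask.any() else math.nan

    def _record(self) -> None:
        mon = self.monitor
        mon.times_ms.append(self.time_ms)
        po2 = self.po2()
        mon.tissue_po2.append(float(po2.mean()))
        for name, mask in self._masks.items():
            mon.compartment_po2[name].append(
                float(po2[mask].mean()) if mask.any() else math.nan)
        sat = (float(self.state.hb.sat.mean())
               if self.state.hb is not None else math.nan)
        mon.hb_sat.append(sat)
        mon.qo2_total.append(
            float(self.consumption.rate_now(self.state).sum()))

    # -- the tick ---------------------------------------------------------
    def step(self) -> None:
        """Advance one tick, enforcing budget closure and sanity checks."""
        params, grid, state = self.params, self.grid, self.state
        total_before = self._total_o2()

        conv = {"convective_in": 0.0, "convective_out": 0.0,
                "bound_convective_net": 0.0}
        consumed = 0.0
        for op in self.operator_order:
            if op == "convection":
                conv = convective_renewal(grid, state, self.flow, params,
                                          self.cff, self.tff)
            elif op == "hb":
                if state.hb is not None and params.Hb_active:
                    ptc = self._masks["PTC"]
                    dq = hb_exchange_step(state.hb, state.q[ptc], params,
                                          grid.volume_um3)
                    state.q[ptc] += dq
            elif op == "diffusion":
                self.diffusion.step(state, params.tick)
            elif op == "consumption":
                consumed = self.consumption.step(state, params.tick)
        clamp_adjust = self._apply_clamps()

        if np.isnan(state.q).any() or (state.q < -1e-9).any():
            bad = int(np.argmin(state.q)) if not np.isnan(state.q).any() \
                else int(np.flatnonzero(np.isnan(state.q))[0])
            ny, nx = grid.shape
            raise RuntimeError(
                f"invalid oxygen content at tick {self.tick_count + 1}, "
                f"patch ({bad // nx}, {bad % nx})")

        total_after = self._total_o2()
        expected = (total_before + conv["convective_in"]
                    - conv["convective_out"] + conv["bound_convective_net"]
                    - consumed + clamp_adjust)
        scale = max(abs(total_after), 1.0)
        residual = abs(total_after - expected) / scale
        self.budget_residual = max(self.budget_residual, residual)

        self.tick_count += 1
        if self.tick_count % max(
                1, round(self.monitor.sample_interval_ms / params.tick)) == 0:
            self._record()

    def apply_overrides(self, overrides: dict) -> None:
        """Apply input overrides (RBF, feeds, Hb flag) mid-run."""
        self.params = self.params.replace(**overrides)
        self.flow = compute_flow_cascade(self.params)
        self.cff, self.tff = flow_factors(self.flow, self.params, self.grid)
        if self.params.tna_follows_flow or self.grid.muscle_qo2 is not None:
            self.consumption = ConsumptionModel.from_grid(
                self.grid, self.flow, self.params)
        # default: TNa is held at its pre-transition value — local
        # reabsorption proceeds for some time after flow stops.
        self.switched = True

    # -- runs --------------------------------------------------------------
    def run_ticks(self, n: int) -> None:
        for _ in range(n):
            self.step()

    def run_to_steady_state(self, max_ticks: int = MAX_STEADY_TICKS) -> float:
        """Iterate until compartment means settle; returns mean tissue PO₂."""
        window = max(1, round(STEADY_WINDOW_MS
                              / self.monitor.sample_interval_ms))
        while self.tick_count < max_ticks:
            self.step()
            po2_max = float(self.po2().max())
            if po2_max > DIVERGENCE_PO2:
                raise RuntimeError(
                    f"divergence: PO2 reached {po2_max:.1f} mmHg")
            n = len(self.monitor.times_ms)
            if n > window and self.tick_count % 10 == 0:
                settled = True
                series = ([self.monitor.tissue_po2]
                          + list(self.monitor.compartment_po2.values()))
                for s in series:
                    vals = [v for v in (s[-1], s[-1 - window]) if not math.isnan(v)]
                    if len(vals) == 2 and abs(vals[0] - vals[1]) > STEADY_TOL_MMHG:
                        settled = False
                        break
                if settled:
                    return self.mean_po2()
        log.warning("steady state not reached within %d ticks", max_ticks)
        return self.mean_po2()


@dataclass
class TransientResult:
    """Half-times and sampled series after an input switch."""

    baseline: dict
    t50: dict            # seconds; inf if never halved within horizon
    t50_error: dict      # seconds; model accuracy / local slope
    t10: dict            # time to 10 % of baseline, seconds
    horizon_s: float
    monitor: Monitor

    def halved(self, key: str) -> bool:
        return math.isfinite(self.t50[key])


def run_to_steady_state(params: ParameterSet, grid: TissueGrid,
                        protocol: Protocol | None = None) -> Simulation:
    """Build a simulation and run it to steady state."""
    sim = Simulation(params, grid, protocol)
    sim.run_to_steady_state()
    return sim


def run_transient(params: ParameterSet, grid: TissueGrid,
                  protocol: Protocol,
                  horizon_ms: float = 30_000.0,
                  sample_interval_ms: float = 10.0) -> TransientResult:
    """Steady state, then apply the protocol's switch and track decays.

    Tracks mean tissue PO₂, mean capillary PO₂ and mean hemoglobin
    saturation; half-times (and times to 10 %) are interpolated between
    samples.  Half-time uncertainty is estimated as the model accuracy
    (2.2 mmHg) divided by the local slope of the decay at the crossing.
    """
    sim = Simulation(params, grid, Protocol(clamps=protocol.clamps),
                     sample_interval_ms=sample_interval_ms)
    sim.run_to_steady_state()
    if protocol.switch_time_ms > 0:
        sim.run_ticks(round(protocol.switch_time_ms / params.tick))
    baseline = {"tissue_po2": sim.mean_po2(),
                "ptc_po2": sim.mean_po2("PTC"),
                "hb_sat": (float(sim.state.hb.sat.mean())
                           if sim.state.hb is not None and params.Hb_active
                           else math.nan)}
    sim.apply_overrides(protocol.overrides)

    switch_time = sim.time_ms
    sample_ticks = max(1, round(sample_interval_ms / params.tick))
    times = [0.0]
    series: dict[str, list[float]] = {k: [v] for k, v in baseline.items()}
    horizon_ticks = round(horizon_ms / params.tick)
    done_frac = 0.05   # stop once every tracked variable fell this low
    for k in range(0, horizon_ticks, sample_ticks):
        sim.run_ticks(sample_ticks)
        times.append(sim.time_ms - switch_time)
        series["tissue_po2"].append(sim.mean_po2())
        series["ptc_po2"].append(sim.mean_po2("PTC"))
        series["hb_sat"].append(float(sim.state.hb.sat.mean())
                                if sim.state.hb is not None else math.nan)
        if all(_below(series[k2], baseline[k2], done_frac)
               for k2 in series):
            break

    t50, t50_err, t10 = {}, {}, {}
    t_arr = np.asarray(times)
    for key, vals in series.items():
        v = np.asarray(vals)
        b = baseline[key]
        if not math.isfinite(b) or b <= 0:
            t50[key] = t50_err[key] = t10[key] = math.nan
            continue
        t50[key], slope = _crossing(t_arr, v, 0.5 * b)
        t10[key], _ = _crossing(t_arr, v, 0.1 * b)
        t50_err[key] = (MODEL_ACCURACY_MMHG / abs(slope) / 1000.0
                        if slope and math.isfinite(t50[key]) else math.nan)
        t50[key] /= 1000.0
        t10[key] /= 1000.0
    return TransientResult(baseline=baseline, t50=t50, t50_error=t50_err,
                           t10=t10, horizon_s=horizon_ms / 1000.0,
                           monitor=sim.monitor)


def _below(vals: list[float], baseline: float, frac: float) -> bool:
    return (not math.isfinite(baseline)) or baseline <= 0 \
        or vals[-1] <= frac * baseline


def _crossing(t: np.ndarray, v: np.ndarray, level: float):
    """First downward crossing of ``level``: (time, local slope per ms)."""
    idx = np.flatnonzero(v <= level)
    if idx.size == 0:
        return math.inf, math.nan
    i = int(idx[0])
    if i == 0:
        return 0.0, math.nan
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    slope = (v1 - v0) / (t1 - t0)
    return float(t0 + (level - v0) / slope), float(slope)
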