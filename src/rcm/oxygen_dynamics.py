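"""Per-tick oxygen field operators: convective renewal, lattice
diffusion, and Michaelis-Menten consumption.

All three operators act on a flat array of per-patch oxygen contents
(amol).  Diffusion uses unidirectional flows driven by the source
concentration, as the model defines them; for equal patch volumes this
is algebraically identical to gradient-driven net flux.  All flows are
computed synchronously from start-of-tick contents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .hemoglobin import HbState, hb_equilibrium_saturation, hb_step, make_hb_state
from .parameters import ParameterSet, content_to_po2, po2_to_content
from .perfusion import FlowState, flow_factors, sodium_transport_per_patch
from .tissue import EPI, INT, LUM, PTC, TissueGrid
from .units import MS_PER_MIN, mm_min_to_amol_ms

PATCH_DISTANCE_UM = 10.0  # centre-to-centre lattice distance L


@dataclass
class PatchState:
    """Oxygen contents for every patch plus hemoglobin for the PTC subset."""

    q: np.ndarray                   # amol, flat (n_patches,)
    hb: HbState | None = None
    clamp_mask: np.ndarray | None = None   # patches with externally fixed PO₂
    clamp_q: np.ndarray | None = None

    def po2(self, grid: TissueGrid, params: ParameterSet) -> np.ndarray:
        return content_to_po2(self.q, grid.volume_um3, params.alpha)


def make_patch_state(grid: TissueGrid, params: ParameterSet,
                     initial_po2: float = 0.0) -> PatchState:
    q = np.full(grid.n_patches,
                po2_to_content(initial_po2, grid.volume_um3, params.alpha),
                dtype=float)
    hb = make_hb_state(grid.count(PTC), params, grid.volume_um3)
    return PatchState(q=q, hb=hb)


# ---------------------------------------------------------------------------
# convection


def convective_renewal(grid: TissueGrid, state: PatchState, flow: FlowState,
                       params: ParameterSet,
                       cff: float, tff: float) -> dict[str, float]:
    """Renew PTC and LUM contents toward their feeds; returns budget terms.

    Each perfused patch exchanges the renewal fraction of its volume
    with feed fluid per tick: q ← q + F·(q_feed − q).  Inflowing blood
    carries hemoglobin at the equilibrium saturation of the feed PO₂,
    so PTC saturation is renewed the same way.
    """
    for name, f in (("CFF", cff), ("TFF", tff)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} = {f} outside [0, 1]")
    q = state.q
    ptc = grid.mask(PTC)
    lum = grid.mask(LUM)
    q_feed_ptc = po2_to_content(params.PTC_feed, grid.volume_um3, params.alpha)
    q_feed_lum = po2_to_content(params.LUM_feed, grid.volume_um3, params.alpha)

    dissolved_out = cff * q[ptc].sum() + tff * q[lum].sum()
    d_ptc = cff * (q_feed_ptc - q[ptc])
    d_lum = tff * (q_feed_lum - q[lum])
    q[ptc] += d_ptc
    q[lum] += d_lum
    dissolved_in = (cff * q_feed_ptc * int(ptc.sum())
                    + tff * q_feed_lum * int(lum.sum()))

    bound_net = 0.0
    if state.hb is not None and params.Hb_active and cff > 0.0:
        s_feed = hb_equilibrium_saturation(params.PTC_feed, params)
        ds = cff * (s_feed - state.hb.sat)
        bound_net = (state.hb.o2_per_carrier * state.hb.hbt
                     * ds.sum() / 100.0)
        state.hb.sat = state.hb.sat + ds
    return {"convective_in": dissolved_in,
            "convective_out": dissolved_out,
            "bound_convective_net": bound_net}


# ---------------------------------------------------------------------------
# diffusion


@dataclass
class DiffusionOperator:
    """Precomputed synchronous Fick operator for a grid.

    For every ordered neighbour pair the unidirectional flow is
    J(i→j) = (1/L)·D̄ij·Sij·[O₂]i (amol/ms) with [O₂]i = qi/Vi; the net
    per-tick update is the sum of inflows minus outflows.  The operator
    is the sparse matrix A with dq = (A q)·tick; its row sums are zero,
    so total content is conserved to machine precision.
    """

    matrix: sp.csr_matrix
    max_outflow_fraction: float   # per ms, stability measure

    @classmethod
    def from_grid(cls, grid: TissueGrid, params: ParameterSet) -> "DiffusionOperator":
        if grid.edges_i is None:
            grid.build_edges(params)
        n = grid.n_patches
        # per-edge rate per unit content of the source patch, 1/ms
        k = (grid.edge_diffusivity * grid.edge_surface
             / (PATCH_DISTANCE_UM * grid.volume_um3))
        i, j = grid.edges_i, grid.edges_j
        rows = np.concatenate([j, i, i, j])
        cols = np.concatenate([i, j, i, j])
        vals = np.concatenate([k, k, -k, -k])
        a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        outflow = np.zeros(n)
        np.add.at(outflow, i, k)
        np.add.at(outflow, j, k)
        return cls(matrix=a, max_outflow_fraction=float(outflow.max()))

    def check_stability(self, tick: float) -> None:
        frac = self.max_outflow_fraction * tick
        if frac > 1.0:
            raise ValueError(
                f"diffusion unstable: worst patch would export {frac:.2f} of "
                f"its content per tick; maximum admissible tick is "
                f"{1.0 / self.max_outflow_fraction:.3f} ms")

    def step(self, state: PatchState, tick: float) -> None:
        state.q += (self.matrix @ state.q) * tick


def diffusion_step(grid: TissueGrid, state: PatchState,
                   params: ParameterSet,
                   operator: DiffusionOperator | None = None) -> None:
    """One synchronous diffusion tick (convenience wrapper)."""
    op = operator or DiffusionOperator.from_grid(grid, params)
    op.check_stability(params.tick)
    op.step(state, params.tick)


# ---------------------------------------------------------------------------
# consumption


@dataclass
class ConsumptionModel:
    """Per-patch maximal consumption rates (amol/ms), Michaelis-Menten gated.

    PTC patches consume through their endothelial crown; INT patches at
    the low interstitial housekeeping rate; EPI patches combine
    housekeeping with the sodium-transport-coupled cost

        JTNa = (0.33 / PO2ratio) · (frTC / fBIC) · TNa

    where 0.33 is the ATP per transported Na⁺ of the Na/K pump,
    PO2ratio the ATP yield per O₂, frTC the pump-driven fraction and
    fBIC the bicarbonate-coupled reabsorption proceeding at no oxygen
    cost.  Every term is gated by M = [O₂]/(Km + [O₂]) and floored so a
    patch can never be driven below zero content.
    """

    jmax: np.ndarray          # amol/ms per patch (housekeeping + transport)
    km_amol: float            # Km expressed as patch content, amol
    jtna_per_epi: float       # transport component alone, amol/ms

    @classmethod
    def from_grid(cls, grid: TissueGrid, flow: FlowState,
                  params: ParameterSet) -> "ConsumptionModel":
        v = grid.volume_um3
        t = grid.flat_types
        jmax = np.zeros(grid.n_patches)
        if grid.muscle_qo2 is not None:
            jmax[t == EPI] = mm_min_to_amol_ms(grid.muscle_qo2, v)
            jtna = 0.0
        else:
            jmax[t == EPI] = mm_min_to_amol_ms(params.JmaxHK_epi, v)
            tna = sodium_transport_per_patch(flow, params, grid)  # amol/min
            jtna = (0.33 / params.PO2ratio) * (params.frTC / params.fBIC) \
                * tna / MS_PER_MIN
            jmax[t == EPI] += jtna
        jmax[t == PTC] = mm_min_to_amol_ms(
            params.Jmax_cap * params.crown_volume_fraction(), v)
        jmax[t == INT] = mm_min_to_amol_ms(params.Jmax_int, v)
        # [O₂] µM == amol per 1000 µm³ patch; store Km as content
        km_amol = params.Km * v / 1000.0
        return cls(jmax=jmax, km_amol=km_amol, jtna_per_epi=jtna)

    def step(self, state: PatchState, tick: float) -> float:
        """Consume one tick; returns total O₂ actually consumed (amol)."""
        q = state.q
        m = q / (self.km_amol + q)
        desired = self.jmax * m * tick
        consumed = np.minimum(desired, q)
        q -= consumed
        return float(consumed.sum())

    def rate_now(self, state: PatchState, mask: np.ndarray | None = None):
        """Instantaneous consumption rate (amol/ms) per patch."""
        q = state.q
        m = q / (self.km_amol + q)
        r = self.jmax * m
        return r if mask is None else r[mask]


def consumption_step(grid: TissueGrid, state: PatchState, flow: FlowState,
                     params: ParameterSet,
                     model: ConsumptionModel | None = None) -> float:
    """One consumption tick (convenience wrapper)."""
    mdl = model or ConsumptionModel.from_grid(grid, flow, params)
    return mdl.step(state, params.tick)
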