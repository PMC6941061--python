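"""Perfusion cascade, sodium transport and convective flow factors.

The dependent flows are a purely algebraic cascade from renal blood
flow down to the per-capillary and per-tubule volumetric flows:

    CBF    = RBF · frCBF                         cortical blood flow
    OpNe   = Ntot · frNCtx                       operational nephrons
    SNGBF  = 1e6 · CBF / OpNe                    glomerular blood flow, nL/min
    SNEABF = SNGBF · [1 − FF·(1 − Hta)]          efferent arteriolar flow
    SNGFR  = SNGBF − SNEABF                      filtration rate
    SNAPR  = frPR · SNGFR                        absolute proximal reabsorption
    CVF    = SNEABF/fCapBr + 0.5·SNAPR/fCapBr    capillary volumetric flow
    TVF    = SNGFR − 0.5·SNAPR                   tubular volumetric flow

Reabsorbed fluid is returned to the capillaries at tubule mid-length,
hence the 0.5 factors.  Sodium transport follows from the filtered load,
scaled to one epithelial patch of a tubule section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ParameterSet
from .tissue import TissueGrid
from .units import UM3_PER_MS_PER_NL_MIN

#: Bibliographical reference values (BV°) for the dependent flow
#: quantities, used by the flow-verification ratio table.  CVF° and
#: SNGFR° are stated in the source literature directly; the entries
#: marked provisional are literature-plausible rat values.
BV0_FLOWS = {
    "CBF": {"value": 4.8, "units": "mL/min/gkw", "provisional": True},
    "SNGBF": {"value": 180.0, "units": "nL/min", "provisional": True},
    "SNEABF": {"value": 145.0, "units": "nL/min", "provisional": True},
    "SNGFR": {"value": 33.0, "units": "nL/min", "provisional": False},
    "SNAPR": {"value": 17.0, "units": "nL/min", "provisional": True},
    "CVF": {"value": 20.0, "units": "nL/min", "provisional": False},
    "TVF": {"value": 20.0, "units": "nL/min", "provisional": True},
    "SNFLNa": {"value": 4.7e9, "units": "amol/min", "provisional": True},
    "wkGFR": {"value": 0.9, "units": "mL/min/gkw", "provisional": True},
}


@dataclass(frozen=True)
class FlowState:
    """All dependent perfusion quantities for one parameter set."""

    CBF: float       # mL·min⁻¹·gkw⁻¹
    OpNe: float      # gkw⁻¹
    SNGBF: float     # nL/min
    SNEABF: float    # nL/min
    SNGFR: float     # nL/min
    SNAPR: float     # nL/min
    CVF: float       # nL/min
    TVF: float       # nL/min
    SNFLNa: float    # amol/min
    wkGFR: float     # mL·min⁻¹·gkw⁻¹, back-calculated

    def __post_init__(self) -> None:
        if not (0.0 <= self.SNGFR <= self.SNGBF + 1e-12):
            raise ValueError("flow cascade violated 0 <= SNGFR <= SNGBF")
        if self.SNAPR > self.SNGFR + 1e-12:
            raise ValueError("flow cascade violated SNAPR <= SNGFR")
        if self.CVF < 0 or self.TVF < 0:
            raise ValueError("negative volumetric flow")


def compute_flow_cascade(params: ParameterSet) -> FlowState:
    """Evaluate the algebraic flow cascade for ``params``."""
    CBF = params.RBF * params.frCBF
    OpNe = params.Ntot * params.frNCtx
    if CBF == 0.0:
        return FlowState(0.0, OpNe, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    if OpNe == 0.0:
        raise ZeroDivisionError("OpNe = 0 with RBF > 0: no nephrons to carry flow")
    SNGBF = 1.0e6 * CBF / OpNe
    SNEABF = SNGBF * (1.0 - params.FF * (1.0 - params.Hta))
    SNGFR = SNGBF - SNEABF
    SNAPR = params.frPR * SNGFR
    CVF = SNEABF / params.fCapBr + 0.5 * SNAPR / params.fCapBr
    TVF = SNGFR - 0.5 * SNAPR
    SNFLNa = 1.0e6 * SNGFR * params.Nap
    wkGFR = SNGFR * OpNe * 1.0e-6
    return FlowState(CBF, OpNe, SNGBF, SNEABF, SNGFR, SNAPR, CVF, TVF,
                     SNFLNa, wkGFR)


def sodium_transport_per_patch(flow: FlowState, params: ParameterSet,
                               grid: TissueGrid) -> float:
    """Na⁺ reabsorption assigned to one EPI patch, amol/min.

    The reabsorbed fraction of the filtered load is distributed over the
    epithelial patches of one 10 µm tubule section (12 for 40 µm outer
    diameter, 16 for 50 µm) and over the tubule length.
    """
    n_epi = grid.epi_per_section
    return (params.frPR * flow.SNFLNa / n_epi
            * (10.0 / params.TubLength))


def flow_factors(flow: FlowState, params: ParameterSet,
                 grid: TissueGrid) -> tuple[float, float]:
    """Per-tick volume renewal fractions (CFF, TFF) for PTC and LUM patches.

    CFF = capFactor·CVF·tick/Vcap and TFF = TVF·tick/(nLUM·Vlum), with
    flows converted from nL/min to µm³/ms.  Raises if either factor
    exceeds 1 at the configured tick (the tick is then too coarse).
    """
    v = grid.volume_um3
    cff = (params.capFactor * flow.CVF * UM3_PER_MS_PER_NL_MIN
           * params.tick / v)
    tff = (flow.TVF * UM3_PER_MS_PER_NL_MIN * params.tick
           / (grid.lum_per_section * v))
    for name, f in (("CFF", cff), ("TFF", tff)):
        if not 0.0 <= f <= 1.0:
            max_tick = params.tick / f
            raise ValueError(
                f"{name} = {f:.3f} outside [0, 1] at tick = {params.tick} ms; "
                f"use a tick <= {max_tick:.3f} ms")
    return cff, tff


def apparent_capillary_velocity(flow: FlowState,
                                params: ParameterSet) -> float:
    """Apparent capillary "blood fluid" velocity, mm/s.

    The per-capillary volumetric flow divided by the capillary
    cross-section; in patch units µm/ms, numerically equal to mm/s.
    """
    if params.Rc <= 0:
        raise ValueError("Rc must be > 0")
    area = math.pi * params.Rc**2
    return (params.capFactor * flow.CVF * UM3_PER_MS_PER_NL_MIN) / area


def capillary_residence_time_ms(flow: FlowState, params: ParameterSet,
                                grid: TissueGrid) -> float:
    """Mean O₂ residence time in one PTC patch, ms (volume / renewal rate)."""
    rate = params.capFactor * flow.CVF * UM3_PER_MS_PER_NL_MIN
    return math.inf if rate == 0 else grid.volume_um3 / rate


def flow_state_dict(flow: FlowState) -> dict[str, float]:
    return {k: getattr(flow, k) for k in
            ("CBF", "OpNe", "SNGBF", "SNEABF", "SNGFR", "SNAPR",
             "CVF", "TVF", "SNFLNa", "wkGFR")}
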