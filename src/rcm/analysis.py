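"""Local parametric sensitivity, input/output slopes, hemoglobin
contribution and flow-verification tables.

All analyses are one-at-a-time, local, and built on steady-state runs
of the full simulation; nothing here introduces randomness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .engine import Simulation
from .parameters import ParameterSet
from .perfusion import BV0_FLOWS, compute_flow_cascade, flow_state_dict
from .tissue import TissueGrid, TissueSpec, build_tissue

log = logging.getLogger(__name__)

#: Bibliographical standard deviations for error propagation (mmHg output
#: error = half output spread across ±1 SD).  Entries without a main-text
#: SD are provisional.
PARAMETER_SD = {
    "frPR": {"sd": 0.10, "provisional": True},
    "frTC": {"sd": 0.20, "provisional": False},   # 0.81 ± 0.20
    "JmaxHK_epi": {"sd": 0.8, "provisional": False},  # 1.9 ± 0.8 mM/min
    "Jmax_cap": {"sd": 1.1, "provisional": False},    # 1.2 ± 1.1 mM/min
    "Km": {"sd": 1.0, "provisional": False},          # 1.1 ± 1.0 µM
    "TubLength": {"sd": 2000.0, "provisional": True},
    "PO2ratio": {"sd": 0.5, "provisional": True},
    "fBIC": {"sd": 0.15, "provisional": True},
    "alpha": {"sd": 0.1, "provisional": True},
}


@dataclass
class SensitivityResult:
    parameter: str
    rsc: float                    # relative sensitivity coefficient
    propagated_error: float       # mmHg, nan when no SD is tabulated
    sweep_values: list = field(default_factory=list)
    sweep_sstpo2: list = field(default_factory=list)


def steady_state_po2(params: ParameterSet, grid: TissueGrid | None = None,
                     spec: TissueSpec | None = None) -> float:
    """Mean tissue PO₂ at steady state for ``params`` (fresh run)."""
    if grid is None:
        grid = build_tissue(spec or TissueSpec.from_name("1540"), params)
    sim = Simulation(params, grid)
    return sim.run_to_steady_state()


def _rebuild(params: ParameterSet, grid: TissueGrid) -> TissueGrid:
    # Geometry-bearing parameters (surfaces, diffusivities) live on the
    # grid edges, so perturbed runs rebuild the tissue when possible.
    if grid.spec is not None:
        return build_tissue(grid.spec, params)
    grid.build_edges(params)
    return grid


def rsc(param_name: str, params: ParameterSet, grid: TissueGrid,
        delta_frac: float = 0.2,
        sst_fn=None, compute_error: bool = True) -> SensitivityResult:
    """Relative sensitivity coefficient of steady-state tissue PO₂.

    Central difference: RSC = [(P(p+Δp) − P(p−Δp))/P(p)] / (2Δp/p) with
    Δp = delta_frac·p.  The propagated error is |P(p+SD) − P(p−SD)|/2
    when a bibliographical SD is tabulated.  ``sst_fn`` may replace the
    steady-state evaluator (used for analytic stubs in tests).
    """
    p0 = getattr(params, param_name)
    if not isinstance(p0, (int, float)) or isinstance(p0, bool):
        raise TypeError(f"parameter {param_name!r} is not numeric")
    if p0 == 0:
        raise ValueError(
            f"parameter {param_name!r} is 0; a relative perturbation is "
            "undefined — perturb with an absolute Δp instead")

    def sst(p: ParameterSet) -> float:
        if sst_fn is not None:
            return sst_fn(p)
        return steady_state_po2(p, _rebuild(p, grid))

    center = sst(params)
    dp = delta_frac * p0
    hi = sst(params.replace(**{param_name: p0 + dp}))
    lo = sst(params.replace(**{param_name: p0 - dp}))
    coeff = ((hi - lo) / center) / (2.0 * dp / p0) if center else math.nan

    err = math.nan
    sd_entry = PARAMETER_SD.get(param_name) if compute_error else None
    if sd_entry is not None:
        sd = sd_entry["sd"]
        p_lo = max(p0 - sd, 0.0)
        p_hi = p0 + sd
        if param_name in ParameterSet.FRACTION_FIELDS:
            p_hi = min(p_hi, 1.0)
        e_hi = sst(params.replace(**{param_name: p_hi}))
        e_lo = sst(params.replace(**{param_name: p_lo}))
        err = abs(e_hi - e_lo) / 2.0
    return SensitivityResult(parameter=param_name, rsc=coeff,
                             propagated_error=err,
                             sweep_values=[p0 - dp, p0, p0 + dp],
                             sweep_sstpo2=[lo, center, hi])


def io_slopes(params: ParameterSet, grid: TissueGrid,
              rbf_levels=(5.3,), delta_mmhg: float = 4.0) -> dict:
    """d(sstPO₂)/d(feed PO₂) per input per RBF level, mmHg/mmHg.

    Central differences around the configured reference feeds, holding
    the other feed fixed.
    """
    out: dict[float, dict[str, float]] = {}
    for rbf in rbf_levels:
        base = params.replace(RBF=rbf)
        slopes = {}
        for feed_key, label in (("PTC_feed", "PTC"), ("LUM_feed", "LUM")):
            ref = getattr(base, feed_key)
            hi = steady_state_po2(base.replace(**{feed_key: ref + delta_mmhg}),
                                  grid)
            lo = steady_state_po2(base.replace(**{feed_key: ref - delta_mmhg}),
                                  grid)
            slopes[label] = (hi - lo) / (2.0 * delta_mmhg)
        out[rbf] = slopes
    return out


def delta_hb(params: ParameterSet, grid: TissueGrid,
             rbf: float | None = None) -> float:
    """Hemoglobin contribution to steady-state tissue PO₂, mmHg.

    Two otherwise identical steady-state runs, hemoglobin active versus
    deactivated.
    """
    base = params if rbf is None else params.replace(RBF=rbf)
    with_hb = steady_state_po2(base.replace(Hb_active=True), grid)
    without = steady_state_po2(base.replace(Hb_active=False), grid)
    return with_hb - without


def verify_flows(params: ParameterSet, bv_table: dict | None = None) -> dict:
    """Ratios of simulated dependent flows to their reference values.

    Returns per-quantity ratios plus their mean and SD; quantities
    missing from the reference table are omitted with a warning.
    """
    bv = bv_table if bv_table is not None else BV0_FLOWS
    flows = flow_state_dict(compute_flow_cascade(params))
    ratios = {}
    for name, sim_value in flows.items():
        if name == "OpNe":
            continue
        entry = bv.get(name)
        if entry is None or not entry.get("value"):
            log.warning("no reference value for %s; ratio omitted", name)
            continue
        ratios[name] = sim_value / entry["value"]
    vals = np.asarray(list(ratios.values()))
    return {"ratios": ratios,
            "mean": float(vals.mean()) if vals.size else math.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else math.nan}
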