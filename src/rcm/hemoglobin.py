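"""Hemoglobin-O₂ association/dissociation kinetics for capillary patches.

Saturation-dependent pseudo-kinetics: the saturation
S (%) relaxes toward the Hill equilibrium S/(100-S) = (PO₂/P50)^nHill
with a saturation-dependent cooperativity index and a saturation-
dependent rate scale.  Dissociation is driven by the pressure scale
α·P50 and the saturated fraction; association by α·PO₂ and the
unsaturated fraction.  The oxygen freed or bound per tick transfers
4 O₂ per tetramer between the bound pool and the dissolved pool.

The association rate as printed in the source multiplies by the
saturated fraction; that form has no fixed point on the Hill curve
(its equilibrium is independent of S), so the unsaturated fraction
(100 − S) is used by default — this reproduces 50 % saturation at P50,
which the model's own reconstructed saturation curve displays.  The
printed form remains available behind ``hb_literal_association``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterSet

log = logging.getLogger(__name__)

_S_CLAMP = (0.1, 99.9)  # nHill endpoint evaluation (varies only ~2.58-2.60)


def hill_coefficient(sat):
    """Saturation-dependent Hill cooperativity index.

    nHill(S) = (2.635·S² − 274.042·S) / (S² − 104.1·S − 31.32), with S
    clamped to [0.1, 99.9] to avoid the degenerate endpoints.
    Scalar or ndarray.
    """
    s = np.clip(sat, *_S_CLAMP)
    num = 2.635 * s**2 - 274.042 * s
    den = s**2 - 104.1 * s - 31.32
    return num / den


def kc_rate(sat):
    """Pseudo-velocity rate scale k'c(S) = 6.325·exp(2.88697·0.011537·S).

    Monotonically increasing from 6.325 at S = 0.  Scalar or ndarray.
    """
    s = np.asarray(sat, dtype=float)
    out = 6.325 * np.exp(2.88697 * 0.011537 * s)
    return float(out) if np.isscalar(sat) else out


@dataclass
class HbState:
    """Saturation (%) and tetramer content (amol) of the PTC patches."""

    sat: np.ndarray                 # %, in [0, 100], one entry per PTC patch
    hbt: float                      # tetramer content per patch, amol
    o2_per_carrier: float = 4.0     # O₂ bound per carrier unit

    @property
    def bound_o2(self) -> np.ndarray:
        """Bound O₂ per PTC patch, amol."""
        return self.o2_per_carrier * self.hbt * self.sat / 100.0


def make_hb_state(n_ptc: int, params: ParameterSet,
                  volume_um3: float = 1000.0) -> HbState:
    sat0 = hb_equilibrium_saturation(params.PTC_feed, params)
    o2pc = 1.0 if params.hb_monomer_literal else 4.0
    return HbState(sat=np.full(n_ptc, sat0, dtype=float),
                   hbt=params.hbt_per_patch(volume_um3),
                   o2_per_carrier=o2pc)


def hb_rates_pct(sat, po2, params: ParameterSet):
    """Dissociation and association rates, % saturation per ms.

    α enters the power terms in mM/mmHg.
    """
    alpha_mm = params.alpha / 1000.0
    n = hill_coefficient(sat)
    kc = kc_rate(sat)
    jdiss = kc * (alpha_mm * params.P50) ** n * sat
    free = sat if params.hb_literal_association else (100.0 - sat)
    jasso = kc * (alpha_mm * np.maximum(po2, 0.0)) ** n * free
    return jdiss, jasso


def hb_step(state: HbState, po2, params: ParameterSet,
            q_available=None) -> np.ndarray:
    """Advance saturation one tick; return ΔqO₂ (amol) added to dissolved O₂.

    The saturation Euler step is clamped to [0, 100] and the oxygen
    released is computed from the realized saturation change, so the
    dissolved + bound budget closes exactly even when clamping.
    A clamp overshoot beyond 1 % logs a too-coarse-tick warning.
    If ``q_available`` (dissolved amol per patch) is given, association
    is additionally capped so it can never overdraw the dissolved pool.
    """
    if not params.Hb_active:
        return np.zeros_like(state.sat)
    jdiss, jasso = hb_rates_pct(state.sat, po2, params)
    new_sat = state.sat + (jasso - jdiss) * params.tick
    overshoot = np.maximum(new_sat - 100.0, -new_sat).max(initial=0.0)
    if overshoot > 1.0:
        log.warning("Hb saturation overshoot %.2f%% in one tick; "
                    "tick = %g ms is too coarse", overshoot, params.tick)
    clamped = np.clip(new_sat, 0.0, 100.0)
    # never step past the equilibrium at the imposed PO₂ (monotone relaxation)
    s_eq = equilibrium_saturation_vec(po2, params)
    s_eq = np.broadcast_to(s_eq, np.shape(state.sat)) \
        if np.shape(s_eq) != np.shape(state.sat) else s_eq
    clamped = np.clip(clamped, np.minimum(state.sat, s_eq),
                      np.maximum(state.sat, s_eq))
    if q_available is not None:
        ds_max = 100.0 * np.asarray(q_available) \
            / (state.o2_per_carrier * state.hbt)
        clamped = np.minimum(clamped, state.sat + ds_max)
    dq = -state.o2_per_carrier * state.hbt * (clamped - state.sat) / 100.0
    state.sat = clamped
    return dq


def equilibrium_saturation_vec(po2, params: ParameterSet) -> np.ndarray:
    """Vectorized fixed point of the rate equations at fixed PO₂ (%)."""
    po2 = np.atleast_1d(np.asarray(po2, dtype=float))
    lo = np.zeros_like(po2)
    hi = np.full_like(po2, 100.0)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        jd, ja = hb_rates_pct(mid, po2, params)
        up = ja > jd
        lo = np.where(up, mid, lo)
        hi = np.where(up, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(po2 <= 0.0, 0.0, out)


def hb_exchange_step(state: HbState, q_dissolved: np.ndarray,
                     params: ParameterSet,
                     volume_um3: float = 1000.0) -> np.ndarray:
    """One tick of the coupled Hb-dissolved O₂ exchange in PTC patches.

    Returns ΔqO₂ (amol) to add to the dissolved pool.  The saturation
    moves by at most the Euler rate of the association/dissociation
    equations, but never past the local mass-conserving equilibrium
    (the joint fixed point at constant dissolved + bound O₂).  The
    projection is required for stability: the bound pool is two orders
    of magnitude larger than the dissolved pool, so a raw explicit step
    at millisecond ticks overshoots and oscillates.  Away from the
    projection the step is exactly the printed kinetics.
    """
    if not params.Hb_active:
        return np.zeros_like(state.sat)
    q = np.asarray(q_dissolved, dtype=float)
    sat = state.sat
    c = state.o2_per_carrier * state.hbt          # amol per 100 % saturation
    total = q + c * sat / 100.0

    # joint equilibrium S*: dissolved po2 evaluated on the conserved total
    lo = np.zeros_like(sat)
    hi = np.minimum(100.0, 100.0 * total / c)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        q_mid = np.maximum(total - c * mid / 100.0, 0.0)
        po2_mid = q_mid * 1000.0 / (params.alpha * volume_um3)
        jd, ja = hb_rates_pct(mid, po2_mid, params)
        up = ja > jd
        lo = np.where(up, mid, lo)
        hi = np.where(up, hi, mid)
    s_star = 0.5 * (lo + hi)

    po2_now = q * 1000.0 / (params.alpha * volume_um3)
    jdiss, jasso = hb_rates_pct(sat, po2_now, params)
    s_euler = sat + (jasso - jdiss) * params.tick
    new_sat = np.clip(s_euler, np.minimum(sat, s_star),
                      np.maximum(sat, s_star))
    dq = -c * (new_sat - sat) / 100.0
    state.sat = new_sat
    return dq


def hb_equilibrium_saturation(po2: float, params: ParameterSet) -> float:
    """Fixed point of the association/dissociation rates at ``po2``, %.

    Solves S = 100·r/(1+r) with r = (PO₂/P50)^nHill(S) self-consistently
    by bisection on g(S) = Jasso%(S) − Jdiss%(S) to |ΔS| < 1e-6.
    """
    if po2 < 0:
        raise ValueError("po2 must be >= 0")
    if po2 == 0.0:
        return 0.0

    def g(s: float) -> float:
        jd, ja = hb_rates_pct(s, po2, params)
        return float(ja - jd)

    lo, hi = 0.0, 100.0
    if g(lo) <= 0.0:
        return 0.0
    if g(hi) >= 0.0:
        return 100.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def saturation_curve(params: ParameterSet, po2_values=None) -> np.ndarray:
    """(PO₂, equilibrium saturation) table for the dissociation curve."""
    if po2_values is None:
        po2_values = np.arange(0.0, 121.0, 1.0)
    sats = [hb_equilibrium_saturation(float(p), params) for p in po2_values]
    return np.column_stack([po2_values, sats])
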