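"""Typed registry of model constants and configuration loading.

Two presets are shipped:

``rcm0``
    The reference configuration: every constant at its bibliographical
    reference value (rat, healthy adult).
``rcmstar``
    The physiologically adjusted configuration.  It differs from the
    reference in exactly five entries: total tubule length (10,400 →
    12,400 µm), fractional reabsorption (0.51 → 0.75), transcellular
    Na⁺ fraction (0.81 → 0.56), bicarbonate factor (1.15 → 1.5) and
    oxidative-phosphorylation ATP/O₂ stoichiometry (4.5 → 5.5).

Config files are flat TOML key-value documents whose keys are the
:class:`ParameterSet` field names.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

log = logging.getLogger(__name__)

PRESET_ALIASES = {
    "rcm0": "rcm0",
    "rcm°": "rcm0",
    "rcmstar": "rcmstar",
    "rcm*": "rcmstar",
}


@dataclass
class ParameterSet:
    """All named model constants, in their documented units.

    Flows and feeds are run inputs but live here so that one object
    fully determines a simulation.
    """

    # -- run inputs -------------------------------------------------------
    RBF: float = 5.3            # renal blood flow, mL·min⁻¹·gkw⁻¹ (FU)
    PTC_feed: float = 56.0      # capillary feed PO₂, mmHg
    LUM_feed: float = 40.0      # luminal feed PO₂, mmHg

    # -- perfusion cascade ------------------------------------------------
    frCBF: float = 0.90         # cortical fraction of RBF
    Ntot: float = 32400.0       # nephron number per gkw
    # Calibrated so OpNe = 27,000 gkw⁻¹ and SNGFR ≈ 33 nL/min at reference RBF.
    frNCtx: float = 27000.0 / 32400.0
    FF: float = 0.34            # filtration fraction
    Hta: float = 0.45           # arterial hematocrit
    frPR: float = 0.51          # fractional proximal reabsorption
    fCapBr: float = 6.0         # capillary branching factor
    capFactor: float = 1.0      # capillary hemodynamic factor (residence time)

    # -- sodium transport and consumption ---------------------------------
    Nap: float = 142.0          # plasma Na⁺, mmol/L
    frTC: float = 0.81          # transcellular Na⁺ fraction
    fBIC: float = 1.15          # bicarbonate factor (pump-free reabsorption)
    PO2ratio: float = 4.5       # Oxphos ATP/O₂ stoichiometry
    Km: float = 1.1             # cytochrome-oxidase Km for O₂, µmol/L
    JmaxHK_epi: float = 1.9     # housekeeping consumption, mM-EPI/min
    Jmax_cap: float = 1.2       # endothelial specific consumption, mM/min
    Jmax_int: float = 0.5       # interstitial consumption, mM-INT/min
    endo_thickness: float = 0.75  # endothelial crown thickness, µm

    # -- hemoglobin --------------------------------------------------------
    Hb4RBC: float = 5.2         # tetramer Hb in red cells, mmol/L-RBC
    P50: float = 36.8           # Hb half-saturation PO₂, mmHg
    Hb_active: bool = True
    hb_literal_association: bool = False  # Eq-18-as-printed compatibility
    hb_monomer_literal: bool = False      # monomeric-Hbt compatibility

    # -- oxygen physics ----------------------------------------------------
    alpha: float = 1.34         # O₂ solubility, µM/mmHg
    D_PTC: float = 1.40e-5      # O₂ diffusivity, cm²/s
    D_LUM: float = 2.80e-5
    D_EPI: float = 1.10e-5
    D_INT: float = 2.20e-5

    # -- geometry ----------------------------------------------------------
    bbmf: float = 2000.0        # EPI-LUM exchange surface, µm²
    ppsa: float = 800.0         # EPI-EPI exchange surface, µm²
    pcsa: float = 157.0         # PTC-EPI exchange surface, µm² (at Rc = 5.0)
    pcsint: float = 39.0        # PTC-INT exchange surface, µm²
    Rc: float = 5.0             # capillary radius, µm
    TubLength: float = 10400.0  # effective tubule length, µm

    # -- execution ---------------------------------------------------------
    tick: float = 1.0           # step duration, ms
    tna_follows_flow: bool = False  # recompute TNa when flow changes

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    #: Fields constrained to [0, 1].
    FRACTION_FIELDS = ("frCBF", "frNCtx", "FF", "Hta", "frPR", "frTC")

    def validate(self) -> None:
        """Enforce hard invariants; raise ValueError on violation."""
        for name in self.FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v!r} must lie in [0, 1]")
        for name in ("RBF", "PTC_feed", "LUM_feed", "Ntot", "fCapBr",
                     "capFactor", "Nap", "fBIC", "PO2ratio", "Km",
                     "JmaxHK_epi", "Jmax_cap", "Jmax_int", "Hb4RBC", "P50",
                     "alpha", "D_PTC", "D_LUM", "D_EPI", "D_INT", "bbmf",
                     "ppsa", "pcsa", "pcsint", "Rc", "TubLength",
                     "endo_thickness"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{name} = {v!r} is not a finite number")
            if v < 0:
                raise ValueError(f"{name} = {v!r} must be >= 0")
        if not 0.0 < self.tick <= 20.0:
            raise ValueError(f"tick = {self.tick!r} must lie in (0, 20] ms")
        self._warn_if_implausible()

    # Plausible ranges (soft): overrides outside them are accepted with a
    # logged warning.
    _PLAUSIBLE = {
        "RBF": (0.0, 12.0), "PTC_feed": (0.0, 150.0), "LUM_feed": (0.0, 150.0),
        "FF": (0.2, 0.45), "Hta": (0.3, 0.55), "P50": (20.0, 50.0),
        "PO2ratio": (3.0, 6.5), "Nap": (120.0, 160.0),
        "TubLength": (5000.0, 20000.0), "Rc": (2.0, 10.0),
    }

    def _warn_if_implausible(self) -> None:
        for name, (lo, hi) in self._PLAUSIBLE.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                log.warning("%s = %g outside plausible range [%g, %g]",
                            name, v, lo, hi)

    # -- derived quantities ---------------------------------------------
    def hbt_per_patch(self, volume_um3: float = 1000.0) -> float:
        """Hemoglobin per PTC patch, amol.

        Tetramer reading by default: Hb4RBC (mmol/L-RBC) scaled by
        hematocrit gives 2340 amol per reference patch, so the factor 4
        in the Hb oxygen-balance yields a blood O₂ capacity of 9360
        amol/patch (≈ 9.4 mM), the physiological value.  The literal
        "monomeric" reading (4x that amount, capacity 4x physiological)
        is available via ``hb_monomer_literal``.
        """
        # mmol/L = 1000 µM; 1 µM = 1 amol per 1000 µm³
        hbt = self.Hb4RBC * 1000.0 * self.Hta * volume_um3 / 1000.0
        if self.hb_monomer_literal:
            hbt *= 4.0
        return hbt

    def crown_volume_fraction(self) -> float:
        """Endothelial crown fraction of a PTC patch.

        The capillary wall (thickness ``endo_thickness``) is the
        consuming component of a PTC patch; its volume fraction scales
        the specific endothelial rate onto the whole patch.
        """
        h = min(self.endo_thickness, self.Rc)
        ring = math.pi * (self.Rc**2 - (self.Rc - h) ** 2)
        return ring * 10.0 / 1000.0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


#: RCM* differs from the reference in exactly these five entries.
RCMSTAR_ADJUSTMENTS = {
    "TubLength": 12400.0,
    "frPR": 0.75,
    "frTC": 0.56,
    "fBIC": 1.5,
    "PO2ratio": 5.5,
}

_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)}
_BOOL_FIELDS = {f.name for f in dataclasses.fields(ParameterSet)
                if f.type == "bool"}


def preset_parameters(preset: str = "rcm0") -> ParameterSet:
    """Return a fresh ParameterSet for ``preset`` ('rcm0' or 'rcmstar')."""
    key = PRESET_ALIASES.get(preset.lower())
    if key is None:
        raise ValueError(f"unknown preset {preset!r}; expected rcm0 or rcmstar")
    ps = ParameterSet()
    if key == "rcmstar":
        ps = ps.replace(**RCMSTAR_ADJUSTMENTS)
    return ps


def load_parameters(config_source: str | Path | Mapping[str, Any] | None = None,
                    preset: str = "rcm0",
                    overrides: Mapping[str, Any] | None = None) -> ParameterSet:
    """Build a validated ParameterSet from a preset plus overrides.

    ``config_source`` may be a TOML file path or a mapping; ``overrides``
    (e.g. from repeated ``--set key=value`` CLI flags) are applied last.
    Unknown keys and non-numeric values raise; values outside the soft
    plausible ranges are accepted with a logged warning.
    """
    ps = preset_parameters(preset)
    merged: dict[str, Any] = {}
    if config_source is not None:
        if isinstance(config_source, Mapping):
            merged.update(config_source)
        else:
            with open(config_source, "rb") as fh:
                doc = tomllib.load(fh)
            doc.pop("preset", None)
            merged.update(doc)
    if overrides:
        merged.update(overrides)

    clean: dict[str, Any] = {}
    for key, value in merged.items():
        if key not in _FIELD_NAMES:
            raise KeyError(f"unknown parameter {key!r}")
        if key in _BOOL_FIELDS:
            clean[key] = _coerce_bool(key, value)
        else:
            try:
                clean[key] = float(value)
            except (TypeError, ValueError):
                raise ValueError(f"parameter {key!r}: non-numeric value {value!r}")
    return ps.replace(**clean)


def _coerce_bool(key: str, value: Any) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        s = value.strip().lower()
        if s in ("true", "1", "yes", "on"):
            return True
        if s in ("false", "0", "no", "off"):
            return False
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    raise ValueError(f"parameter {key!r}: expected a boolean, got {value!r}")


# -- oxygen content <-> partial pressure -------------------------------


def po2_to_content(po2: float, volume: float = 1000.0,
                   alpha: float = 1.34) -> float:
    """Dissolved O₂ content (amol) of a patch at ``po2`` mmHg.

    1 amol per 1000-µm³ patch equals 1 µM, so content = α·PO₂·V/1000.
    """
    if po2 < 0:
        raise ValueError(f"po2 = {po2!r} must be >= 0")
    if volume <= 0:
        raise ValueError(f"volume = {volume!r} must be > 0")
    return alpha * po2 * volume / 1000.0


def content_to_po2(content, volume: float = 1000.0, alpha: float = 1.34):
    """Inverse of :func:`po2_to_content`; accepts scalars or arrays."""
    return content * 1000.0 / (alpha * volume)
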