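"""Deterministic construction of cortical tissue grids.

The model tissue is a 32 x 32 lattice of 10 x 10 x 10 µm patches of four
types: peritubular capillary (PTC), tubular epithelium (EPI), tubule
lumen (LUM) and interstitium (INT).  Six named variants combine an
outer tubule diameter (40 or 50 µm) with a capillary/tubule count ratio
(1.0, 1.5 or 2.0); the reference tissue is "1540" (ratio 1.5, 40 µm).

Tubules are laid out as square blocks — a one-patch-thick EPI perimeter
around a LUM core (4x4 block: 12 EPI + 4 LUM; 5x5 block: 16 EPI +
9 LUM) — on a regular lattice separated by one-patch interstitial
corridors; for the 40 µm variants pairs of blocks abut at the row ends
so that the tubule volume fraction falls inside the morphometric band
(60-80 % v/v).  Capillary patches are placed singly in the corridors,
on cells adjacent to at least one EPI patch, at even strides along the
row-major scan so they are spread through the slab.  Grid boundaries
are closed (no-flux): the slab sits between two cortical radial
arteries and no boundary exchange is defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterSet

# Patch type codes (array values) and map characters.
PTC, EPI, LUM, INT = 0, 1, 2, 3
TYPE_CHARS = {PTC: "C", EPI: "E", LUM: "L", INT: "I"}
CHAR_TYPES = {v: k for k, v in TYPE_CHARS.items()}
TYPE_NAMES = {PTC: "PTC", EPI: "EPI", LUM: "LUM", INT: "INT"}

GRID_SIDE = 32
PATCH_SIZE_UM = 10.0
PATCH_VOLUME_UM3 = 1000.0
DEFAULT_ESA_UM2 = 100.0

#: Block-start columns/rows for each outer tubule diameter (µm).
_BLOCK_STARTS = {
    40: (0, 4, 9, 14, 19, 24, 28),   # 7 blocks of 4, four 1-patch corridors
    50: (0, 6, 12, 18, 24),          # 5 blocks of 5 at pitch 6
}
_BLOCK_SIZE = {40: 4, 50: 5}
#: Patches per tubule section.
EPI_PER_SECTION = {40: 12, 50: 16}
LUM_PER_SECTION = {40: 4, 50: 9}

VALID_RATIOS = (1.0, 1.5, 2.0)
VALID_DIAMETERS = (40, 50)

#: Morphometric acceptance bands for a built tissue.
TUBULE_FRACTION_BAND = (0.60, 0.80)
CAPILLARY_DENSITY_BAND = (250.0, 1110.0)  # per mm²


@dataclass(frozen=True)
class TissueSpec:
    """A named tissue variant: Nc/Nt ratio x outer tubule diameter."""

    nc_nt_ratio: float = 1.5
    orTub_diameter: int = 40
    variant: str = "renal"   # or "muscle"

    def __post_init__(self) -> None:
        if self.nc_nt_ratio not in VALID_RATIOS:
            raise ValueError(f"nc_nt_ratio must be one of {VALID_RATIOS}")
        if self.orTub_diameter not in VALID_DIAMETERS:
            raise ValueError(f"orTub_diameter must be one of {VALID_DIAMETERS}")
        if self.variant not in ("renal", "muscle"):
            raise ValueError("variant must be 'renal' or 'muscle'")

    @property
    def name(self) -> str:
        """Name code: ratio x 10 concatenated with diameter, e.g. '1540'."""
        return f"{int(self.nc_nt_ratio * 10)}{self.orTub_diameter}"

    @classmethod
    def from_name(cls, name: str, variant: str = "renal") -> "TissueSpec":
        name = name.strip()
        if len(name) != 4 or not name.isdigit():
            raise ValueError(f"bad tissue name {name!r}; expected e.g. '1540'")
        return cls(nc_nt_ratio=int(name[:2]) / 10.0,
                   orTub_diameter=int(name[2:]), variant=variant)


def esa_lookup(type_a: int, type_b: int, params: ParameterSet) -> float:
    """Effective exchange surface (µm²) between two adjacent patch types.

    Symmetric and total over type pairs; the default contact surface is
    100 µm², scaled for the special pairs (brush-border EPI-LUM contact,
    lateral EPI-EPI folding, capillary wall contacts).  The PTC-EPI
    value already embodies the 2-fold adjustment at Rc = 5.0.
    """
    pair = frozenset((type_a, type_b))
    if pair == frozenset((EPI, LUM)):
        return params.bbmf
    if pair == frozenset((EPI,)):
        return params.ppsa
    if pair == frozenset((PTC, EPI)):
        return params.pcsa
    if pair == frozenset((PTC, INT)):
        return params.pcsint
    return DEFAULT_ESA_UM2


def _diffusivities_um2_ms(params: ParameterSet) -> dict[int, float]:
    from .units import cm2_s_to_um2_ms
    return {PTC: cm2_s_to_um2_ms(params.D_PTC),
            EPI: cm2_s_to_um2_ms(params.D_EPI),
            LUM: cm2_s_to_um2_ms(params.D_LUM),
            INT: cm2_s_to_um2_ms(params.D_INT)}


@dataclass
class TissueGrid:
    """A typed patch lattice with edge exchange surfaces and diffusivities.

    ``types`` is an (ny, nx) int array; edges are the unordered Von
    Neumann adjacencies, stored once as index pairs into the flattened
    lattice, with per-edge surface (µm²) and mean diffusivity (µm²/ms).
    """

    types: np.ndarray
    spec: TissueSpec | None = None
    volume_um3: float = PATCH_VOLUME_UM3
    epi_per_section: int = 12
    lum_per_section: int = 4
    sections: list[dict] = field(default_factory=list)
    #: uniform EPI consumption override for muscle variants, mM/min
    muscle_qo2: float | None = None

    edges_i: np.ndarray = field(default=None, repr=False)
    edges_j: np.ndarray = field(default=None, repr=False)
    edge_surface: np.ndarray = field(default=None, repr=False)
    edge_diffusivity: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.types = np.asarray(self.types, dtype=np.int8)

    # -- basic views -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.types.shape

    @property
    def n_patches(self) -> int:
        return self.types.size

    @property
    def flat_types(self) -> np.ndarray:
        return self.types.ravel()

    def mask(self, type_code: int) -> np.ndarray:
        return self.flat_types == type_code

    def count(self, type_code: int) -> int:
        return int(np.count_nonzero(self.flat_types == type_code))

    # -- edges --------------------------------------------------------------
    def build_edges(self, params: ParameterSet) -> None:
        """Enumerate Von Neumann adjacencies with surfaces/diffusivities."""
        ny, nx = self.shape
        t = self.types
        d_of = _diffusivities_um2_ms(params)
        ei, ej, surf, diff = [], [], [], []

        def add(y0, x0, y1, x1):
            a, b = y0 * nx + x0, y1 * nx + x1
            ta, tb = int(t[y0, x0]), int(t[y1, x1])
            ei.append(a)
            ej.append(b)
            surf.append(esa_lookup(ta, tb, params))
            diff.append(0.5 * (d_of[ta] + d_of[tb]))

        for y in range(ny):
            for x in range(nx):
                if x + 1 < nx:
                    add(y, x, y, x + 1)
                if y + 1 < ny:
                    add(y, x, y + 1, x)
        self.edges_i = np.asarray(ei, dtype=np.int64)
        self.edges_j = np.asarray(ej, dtype=np.int64)
        self.edge_surface = np.asarray(surf, dtype=float)
        self.edge_diffusivity = np.asarray(diff, dtype=float)

    # -- invariant checks ---------------------------------------------------
    def check_adjacency_rules(self) -> None:
        """LUM touches only LUM/EPI; PTC never touches LUM."""
        ny, nx = self.shape
        t = self.types
        for y in range(ny):
            for x in range(nx):
                for dy, dx in ((0, 1), (1, 0)):
                    y2, x2 = y + dy, x + dx
                    if y2 >= ny or x2 >= nx:
                        continue
                    pair = {int(t[y, x]), int(t[y2, x2])}
                    if LUM in pair and not pair <= {LUM, EPI}:
                        raise ValueError(
                            f"illegal adjacency {pair} at ({y},{x})-({y2},{x2})")

    def morphometry(self) -> dict:
        """Per-type counts, volume fractions, capillary density, Nc/Nt."""
        n = self.n_patches
        counts = {TYPE_NAMES[c]: self.count(c) for c in (PTC, EPI, LUM, INT)}
        area_mm2 = (self.shape[0] * self.shape[1]
                    * (PATCH_SIZE_UM * 1e-3) ** 2)
        n_tub = len(self.sections)
        report = {
            "counts": counts,
            "fractions": {k: v / n for k, v in counts.items()},
            "tubule_fraction": (counts["EPI"] + counts["LUM"]) / n,
            "n_tubules": n_tub,
            "n_capillaries": counts["PTC"],
            "capillary_density_mm2": counts["PTC"] / area_mm2,
            "nc_nt_ratio": counts["PTC"] / n_tub if n_tub else math.nan,
        }
        return report

    # -- serialization -------------------------------------------------------
    def to_text_map(self) -> str:
        rows = ("".join(TYPE_CHARS[int(c)] for c in row) for row in self.types)
        return "\n".join(rows) + "\n"

    @classmethod
    def from_text_map(cls, text: str, *, params: ParameterSet | None = None,
                      spec: TissueSpec | None = None,
                      epi_per_section: int = 12,
                      lum_per_section: int = 4) -> "TissueGrid":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        try:
            types = np.array([[CHAR_TYPES[ch] for ch in ln] for ln in lines],
                             dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"unknown tissue map character {exc}") from exc
        grid = cls(types=types, spec=spec, epi_per_section=epi_per_section,
                   lum_per_section=lum_per_section)
        if params is not None:
            grid.build_edges(params)
        return grid


# -- construction ------------------------------------------------------------


def _corridor_layout(diameter: int) -> tuple[np.ndarray, list[dict]]:
    """Type array with tubule blocks placed, everything else INT."""
    size = _BLOCK_SIZE[diameter]
    starts = _BLOCK_STARTS[diameter]
    types = np.full((GRID_SIDE, GRID_SIDE), INT, dtype=np.int8)
    sections: list[dict] = []
    for ys in starts:
        for xs in starts:
            epi_idx, lum_idx = [], []
            for y in range(ys, ys + size):
                for x in range(xs, xs + size):
                    on_rim = (y in (ys, ys + size - 1)
                              or x in (xs, xs + size - 1))
                    types[y, x] = EPI if on_rim else LUM
                    (epi_idx if on_rim else lum_idx).append(y * GRID_SIDE + x)
            sections.append({"epi": epi_idx, "lum": lum_idx})
    return types, sections


def _capillary_sites(types: np.ndarray) -> list[int]:
    """Row-major list of INT cells adjacent to at least one EPI patch."""
    ny, nx = types.shape
    sites = []
    for y in range(ny):
        for x in range(nx):
            if types[y, x] != INT:
                continue
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < ny and 0 <= x2 < nx and types[y2, x2] == EPI:
                    sites.append(y * nx + x)
                    break
    return sites


def build_tissue(spec: TissueSpec, params: ParameterSet) -> TissueGrid:
    """Construct a tissue grid for ``spec`` (deterministic, no randomness).

    Raises ValueError listing the violated morphometric constraint if the
    spec's targets cannot be met on the 32x32 grid.
    """
    if spec.variant == "muscle":
        return build_muscle_variant(spec, params)

    diameter = spec.orTub_diameter
    types, sections = _corridor_layout(diameter)
    n_tub = len(sections)
    area_mm2 = GRID_SIDE * GRID_SIDE * (PATCH_SIZE_UM * 1e-3) ** 2

    n_cap = round(spec.nc_nt_ratio * n_tub)
    # Respect the capillary areal density floor while staying within the
    # ±0.1 tolerance on the realized count ratio.
    while (n_cap / area_mm2 < CAPILLARY_DENSITY_BAND[0]
           and abs((n_cap + 1) / n_tub - spec.nc_nt_ratio) <= 0.1):
        n_cap += 1

    sites = _capillary_sites(types)
    if n_cap > len(sites):
        raise ValueError(
            f"tissue {spec.name}: needs {n_cap} capillaries but only "
            f"{len(sites)} corridor sites adjacent to epithelium exist")
    picks = [sites[(k * len(sites)) // n_cap] for k in range(n_cap)]
    for idx in picks:
        types[idx // GRID_SIDE, idx % GRID_SIDE] = PTC

    grid = TissueGrid(types=types, spec=spec,
                      epi_per_section=EPI_PER_SECTION[diameter],
                      lum_per_section=LUM_PER_SECTION[diameter],
                      sections=sections)
    grid.build_edges(params)
    grid.check_adjacency_rules()
    _check_morphometry(grid, spec)
    return grid


def _check_morphometry(grid: TissueGrid, spec: TissueSpec) -> None:
    rep = grid.morphometry()
    lo, hi = TUBULE_FRACTION_BAND
    if not lo <= rep["tubule_fraction"] <= hi:
        raise ValueError(
            f"tissue {spec.name}: tubule volume fraction "
            f"{rep['tubule_fraction']:.3f} outside [{lo}, {hi}]")
    lo, hi = CAPILLARY_DENSITY_BAND
    if not lo <= rep["capillary_density_mm2"] <= hi:
        raise ValueError(
            f"tissue {spec.name}: capillary density "
            f"{rep['capillary_density_mm2']:.0f} mm^-2 outside [{lo}, {hi}]")
    if abs(rep["nc_nt_ratio"] - spec.nc_nt_ratio) > 0.1:
        raise ValueError(
            f"tissue {spec.name}: realized Nc/Nt {rep['nc_nt_ratio']:.2f} "
            f"differs from spec {spec.nc_nt_ratio} by more than 0.1")


def build_muscle_variant(spec: TissueSpec, params: ParameterSet,
                         qo2_mm_min: float = 3.0) -> TissueGrid:
    """Muscle-oriented counterpart of a renal tissue.

    Same capillary layout as the renal tissue; every LUM patch is
    re-typed EPI (muscle fibers), a uniform consumption ``qo2_mm_min``
    is assigned to all EPI patches, and there is no tubular flow.
    """
    renal = build_tissue(TissueSpec(spec.nc_nt_ratio, spec.orTub_diameter,
                                    "renal"), params)
    types = renal.types.copy()
    types[types == LUM] = EPI
    grid = TissueGrid(types=types,
                      spec=TissueSpec(spec.nc_nt_ratio, spec.orTub_diameter,
                                      "muscle"),
                      epi_per_section=renal.epi_per_section,
                      lum_per_section=renal.lum_per_section,
                      sections=[], muscle_qo2=qo2_mm_min)
    grid.build_edges(params)
    return grid


def all_variant_names() -> list[str]:
    return [f"{int(r * 10)}{d}" for r in VALID_RATIOS for d in VALID_DIAMETERS]
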