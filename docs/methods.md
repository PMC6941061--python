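# Methods

`rcm` reimplements, from its published equations and parameter values,
a tick-based cell–tissue model of oxygenation in the rat renal cortex
(the "RCM" family of configurations: the reference setting `rcm0` and
the physiologically adjusted `rcmstar`). This note records the model
assumptions, the parameters that matter, the numerical choices made
where the published description is silent or internally inconsistent,
and what the implementation does and does not reproduce.

## Model and assumptions

The cortex is idealized as a 2D slab, 320 × 320 µm by 10 µm thick,
discretized into 1024 cubic patches of four types: peritubular
capillary (PTC), proximal-tubule epithelium (EPI), tubule lumen (LUM)
and interstitium (INT). The slab sits between two cortical radial
arteries; glomeruli, arterioles, larger vessels and lymphatics are not
represented, and grid boundaries are closed (no-flux). Capillary and
tubular flows are non-resistive volume renewals orthogonal to the
slab: each perfused patch exchanges a fixed volume fraction per tick
with its feed fluid, computed from the perfusion cascade (flows are
lumped at tubule/capillary mid-length, which is why half of the
proximally reabsorbed volume is added to capillary flow and subtracted
from tubular flow). Erythrocytes are not individualized: hemoglobin is
treated as homogeneously distributed in capillary "blood", and there
is no Bohr modulation of P₅₀. There is no ATP pool, no metabolic
regulation, no tubuloglomerular feedback, and no pressure-driven
collapse of tubules or capillaries under zero flow.

Timescale: milliseconds to tens of seconds — convection, Hb kinetics,
diffusion and consumption. Minutes-scale phenomena (ATP depletion,
regulation, injury) are out of scope.

## Parameters

All constants live in `rcm.parameters.ParameterSet` with their units;
the main ones, with reference defaults:

| name | meaning | default | units |
| --- | --- | --- | --- |
| RBF | renal blood flow | 5.3 | mL·min⁻¹·gkw⁻¹ |
| PTC_feed / LUM_feed | feed PO₂, blood / filtrate | 56 / 40 | mmHg |
| frCBF | cortical fraction of RBF | 0.90 | — |
| Ntot, frNCtx | nephrons per gkw, operational fraction | 32 400, 0.833 | — |
| FF, Hta | filtration fraction, arterial hematocrit | 0.34, 0.45 | — |
| frPR | fractional proximal reabsorption | 0.51 (0.75*) | — |
| fCapBr | capillaries per efferent arteriole | 6 | — |
| Nap | plasma Na⁺ | 142 | mmol/L |
| frTC, fBIC | transcellular Na⁺ fraction, bicarbonate factor | 0.81, 1.15 (0.56, 1.5*) | — |
| PO2ratio | Oxphos ATP/O₂ yield | 4.5 (5.5*) | — |
| Km | cytochrome-oxidase Km for O₂ | 1.1 | µM |
| JmaxHK_epi / Jmax_cap / Jmax_int | housekeeping consumption | 1.9 / 1.2 / 0.5 | mM·min⁻¹ |
| Hb4RBC, P50 | tetramer Hb in RBC, half-saturation PO₂ | 5.2 mmol/L-RBC, 36.8 mmHg | |
| alpha | O₂ solubility | 1.34 | µM/mmHg |
| D_PTC/D_LUM/D_EPI/D_INT | O₂ diffusivities | 1.4/2.8/1.1/2.2 ×10⁻⁵ | cm²/s |
| bbmf/ppsa/pcsa/pcsint | exchange surfaces | 2000/800/157/39 | µm² |
| Rc, TubLength | capillary radius, effective tubule length | 5 µm, 10 400 µm (12 400*) |
| tick | step duration | 1 | ms |

(*) the five adjusted (`rcmstar`) values.

Derived constants and their rationale:

- `frNCtx = 27 000/32 400`: calibrated once so that single-nephron
  GFR at reference inputs is 33 nL/min, the value the published
  configuration works with. `frCBF = 0.90` (not separately published;
  chosen as the conventional cortical share of renal flow).
- Hemoglobin per PTC patch is stored as **tetramer** content,
  `Hb4RBC·Hct·V/1000 = 2340 amol`, so that the factor 4 in the Hb
  oxygen balance yields a blood O₂ capacity of 9360 amol/patch
  (≈ 9.4 mM), the physiological value. The published description labels this
  quantity "monomeric hemoglobin equivalent"; taking that literally
  together with the factor 4 gives four times the physiological blood
  O₂ capacity, so the tetramer reading is the default and the literal
  one sits behind `hb_monomer_literal`.
- `Jmax_cap` is a specific endothelial rate (1.2 mM/min) scaled by the
  endothelial crown volume fraction of a PTC patch,
  π(Rc² − (Rc−h)²)·10/1000 ≈ 0.218 with wall thickness h = 0.75 µm
  (midpoint of the reported 0.5–1 µm).
- `Jmax_int = 0.5 mM/min` is a placeholder constrained by the
  requirement that non-epithelial consumption stay below 5 % of the
  total (it contributes ~1 %).
- The association rate of the Hb kinetics uses the **unsaturated**
  fraction (100 − S). The printed form multiplies by S, which has no
  fixed point on the Hill curve (its equilibrium would not depend on
  saturation); with (100 − S) the fixed point is exactly the Hill
  relation, reproducing 50 % saturation at P₅₀ — which the published
  model's own reconstructed saturation curve displays. The printed form is
  available behind `hb_literal_association`.
- The transport oxygen cost reads the printed "0.33·P/O₂" factor as
  0.33/(ATP:O₂) — ATP per pumped Na⁺ divided by ATP per O₂ — and
  applies the bicarbonate factor as a divisor of the transcellular
  flux (bicarbonate-coupled reabsorption proceeds at no oxygen cost).
  Both readings are fixed by units and by the published transport-QO₂
  verification value (≈10 mM-EPI/min at reference settings).
- The volumetric-flow conversion "1/6·10⁻²" is read as 1/(6×10⁻²)
  = 16.67 µm³/ms per nL/min; dimensional analysis and the ~2 ms
  capillary residence time it implies both confirm it.

## Tissue generator

The original tissues were hand-edited in a level editor and are not
available; `rcm.tissue.build_tissue` replaces them with a
deterministic constructive algorithm targeting the same morphometric
bands: tubule volume fraction 60–80 %, capillary areal density
250–1110 mm⁻², realized N꜀/Nₜ within ±0.1 of the requested ratio.

For 40 µm tubules, seven 4×4 blocks per row/column are placed at
starts (0, 4, 9, 14, 19, 24, 28) — pairs of blocks abut at the row
ends, leaving four one-patch corridors — giving 49 tubule sections and
a tubule fraction of 0.766. For 50 µm tubules, five 5×5 blocks at
pitch 6 give 25 sections (fraction 0.61). Capillaries are single
patches placed on corridor cells adjacent to at least one EPI patch,
selected at even strides along the row-major scan so they are spread
uniformly through the slab; the capillary count is round(ratio × Nₜ),
raised within the ±0.1 ratio tolerance if the areal density would fall
below 250 mm⁻² (this affects only the "1050" variant). The reference
"1540" tissue has 74 capillaries (723 mm⁻²) and volume fractions
PTC/EPI/LUM/INT = 0.072/0.574/0.191/0.162.

A muscle-oriented variant keeps the capillary layout, re-types every
LUM patch as EPI, assigns a uniform configurable consumption
(default 3 mM/min) and has no tubular flow; it exists to show that the
weak hemoglobin contribution to tissue PO₂ is a renal feature, not an
artifact (with capillary velocities reduced into the muscle range, the
Hb contribution rises to several mmHg).

What the generator does **not** emulate: the cortical labyrinth's
irregular geometry, axial continuity of tubules and capillaries,
segmental (S1/S2/S3) heterogeneity, and any histological randomness —
layouts are perfectly periodic. Tests passing on these tissues
therefore validate the transport/consumption physics on a regular
geometry, not the geometric statistics of real cortex.

## Numerics

- **Tick execution order**: convective renewal → hemoglobin → diffusion
  → consumption, all operators synchronous within the tick (computed
  from start-of-tick contents where the published equations say so).
  The order is not prescribed by the published description; splitting is first-order,
  and permuting hemoglobin and consumption moves the steady state by
  0.14 mmHg at the default 1 ms tick (0.07 at 0.5 ms) — far below the
  model's parametric accuracy (±2.2 mmHg).
- **Hemoglobin integration**: the bound pool (9360 amol/patch) is two
  orders of magnitude larger than the dissolved pool (~75 amol), so a
  raw explicit Euler step of the rate equations at a 1 ms tick
  overshoots the joint equilibrium roughly three-fold and oscillates.
  The exchange is therefore integrated as an *equilibrium-projected*
  Euler step: saturation moves at the rate the kinetic equations give,
  but never past the local mass-conserving fixed point (found by
  vectorized bisection on the conserved dissolved + bound total).
  Away from the projection the step is exactly the printed kinetics;
  at quasi-equilibrium the scheme reduces to Hb tracking the local
  PO₂, which is the physically expected regime (Hb kinetics are fast
  relative to the transport timescales).
- **Diffusion stability** is checked at setup: the worst patch's total
  outflow fraction per tick must not exceed 1 (at reference parameters
  the maximum is 0.84 at 1 ms; the error message names the admissible
  tick). Because every operator is linear in the tick, the fixed point
  is tick-independent: halving the tick moves the steady state by
  ~0.01 mmHg.
- **Floors and clamps**: consumption can never overdraw a patch (it
  consumes at most the available content); Hb association can never
  overdraw the dissolved pool; saturation is clamped to [0, 100] and
  the oxygen transferred is computed from the *realized* saturation
  change, so the per-tick oxygen budget (dissolved + bound, convective
  in/out, consumed, clamped) closes to machine precision (asserted at
  ≤10⁻⁹ relative in tests). Patches clamped to a fixed PO₂ (the
  high-PO₂-source experiments) are re-imposed after the four operators
  and accounted separately in the budget.
- **Steady state** is declared when no compartment-mean PO₂ moves by
  more than 0.01 mmHg over a trailing 100 ms window (reference runs
  settle in ~0.5–0.7 s of simulated time); runs abort on NaN, negative
  content, or PO₂ > 200 mmHg.
- **Half-times** (t₅₀, and time-to-10 %) are linearly interpolated
  between 10 ms samples; their uncertainty is estimated as the model
  accuracy (2.2 mmHg) divided by the local decay slope at the
  crossing. A variable that never halves within the horizon reports
  t₅₀ = ∞. Under ischemia the per-patch sodium-transport load is held
  at its pre-transition value by default (local reabsorption continues
  for some time after filtration stops); `tna_follows_flow = true`
  restores the strict algebraic coupling to SNGFR.
- **Sensitivity analysis** uses the standard central-difference
  relative sensitivity coefficient,
  RSC = [(P(p+Δp) − P(p−Δp))/P(p)] / (2Δp/p) with Δp = 0.2 p
  (the published formula contains a typographical duplication of the
  "+Δp" term); propagated errors are half the output spread across
  ±1 SD of the parameter, with ±SD excursions clipped to the valid
  range for fraction-valued parameters.

## What the implementation reproduces, and what it does not

All *differential* and *dynamic* published behaviours reproduce well
(values below are what this package computes at its defaults):

- hemoglobin contributes ~0.25 mmHg to tissue PO₂ at reference flow,
  rising steeply under partial ischemia (~10 mmHg at 0.2 FU) and in
  muscle-like tissues (~3.6 mmHg);
- luminal feed dominates the control of tissue PO₂ at reference flow
  (slopes ≈ 0.76 vs 0.24 mmHg/mmHg for LUM vs PTC), with the ranking
  inverted under deep ischemia (0.19 vs 0.79);
- equilibrium Hb saturation is 74.8 % at 56 mmHg with the half-point
  at P₅₀;
- ischemic half-times: tissue ≈ 3.0 s and capillary ≈ 4.8 s with
  hemoglobin, 0.41 s and 0.32 s without (a 7–15× acceleration);
  anoxemic half-times ~27 ms (tissue) and ~5 ms (capillary);
- compartments equilibrate in the order PTC (ms) ≪ LUM ≪ EPI ≪ INT.

Two families of published numbers are **not** recovered, and we record
this as an internal inconsistency of the published description rather
than a tunable defect:

1. **Absolute steady-state levels.** This implementation computes
   tissue PO₂ of 40.4 / 41.7 / 53.5 mmHg for the reference, adjusted,
   and equal-feed configurations, where the published values are
   34.2 / 35.9 / 48.9 — a nearly constant +5–6 mmHg offset, while the
   *differences* between configurations track the published ones
   (+1.3 vs +1.7; +11.8 vs +13.0). The offset is forced by the printed
   transport coefficients: carrying one tubule section's consumption
   (12 × 0.197 amol/ms) through its eight brush-border contacts
   (conductance D̄·S/(L·V) = 0.39 ms⁻¹ each) requires a lumen–epithelium
   gradient of only ~0.6 mmHg, whereas the published compartment
   profiles show ~4 mmHg. No faithful reading of the printed surfaces,
   diffusivities, lattice distance or consumption rates yields the
   larger gradients.
2. **The low-flow knee.** Because the transport-coupled consumption
   scales down with RBF while hemoglobin-carried renewal capacity
   remains above the housekeeping floor, tissue PO₂ here stays nearly
   flat down to ~0.01 FU and collapses only at effectively zero flow,
   whereas the published response declines steeply below ~1 FU. This
   is the same inconsistency seen from the supply side.

Related verification quantities: whole-slab epithelial consumption at
reference settings computes 6.6 mM·min⁻¹ of cortex (published ≈7.7;
the difference is the epithelial volume fraction, which cannot reach
the implied 0.64 without violating the 60–80 % tubule band), the
transport cost 9.9 mM-EPI/min (≈10.2), and the apparent capillary
velocity 5.4 mm/s (≈5, from a per-capillary flow of 25.3 nL/min
against the quoted ~23).

## Known limitations

2D geometry with broken axial continuity (likely overestimating the
luminal share of delivery); no capillary hemodynamics beyond the
phenomenological `capFactor`; no pressure/resistance network, so
zero-flow states do not collapse vessels; regular synthetic tissues;
single lumped proximal segment; operator splitting at first order in
the tick. Problem sizes used throughout (32 × 32 patches, steady runs
of a few hundred to a few thousand 1 ms ticks, transients up to 30 s)
keep any analysis in this package at desk scale.
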