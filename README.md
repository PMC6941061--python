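# rcm — oxygen dynamics in the rat renal cortex at the cell-tissue level

`rcm` is a deterministic, tick-based simulator of oxygen delivery,
diffusion and consumption in an idealized slab of rat kidney cortex.
It is aimed at renal physiologists and modellers who want a
tissue-level, histologically resolved counterpart to whole-organ or
single-nephron oxygenation models: the slab distinguishes peritubular
capillaries (PTC), proximal-tubule epithelium (EPI), tubule lumina
(LUM) and interstitium (INT), so questions like *"how much oxygen do
the tubule lumina deliver compared with the capillaries?"* or *"how
fast does cortical PO₂ collapse when perfusion stops?"* can be asked of
the model directly.

## The model

The tissue is a 32 × 32 lattice of 10 × 10 × 10 µm patches
(320 × 320 × 10 µm, ~1 nL). Tubule cross-sections are square blocks —
an epithelial ring around a luminal core (12 EPI + 4 LUM patches for
40 µm outer diameter; 16 + 9 for 50 µm) — separated by interstitial
corridors in which single-patch capillaries are placed. Six variants
combine the capillary/tubule count ratio N꜀/Nₜ ∈ {1.0, 1.5, 2.0} with
the outer tubule diameter ∈ {40, 50} µm; the reference tissue is
"1540" (1.5, 40 µm).

Each 1 ms tick applies four operators to the per-patch oxygen contents
q (amol; 1 amol per patch = 1 µM; PO₂ = q/(α·V) with solubility
α = 1.34 µM/mmHg):

1. **Convective renewal.** An algebraic cascade distributes renal
   blood flow (RBF, mL·min⁻¹·gkw⁻¹) down to per-capillary and
   per-tubule volumetric flows: SNGBF = 10⁶·RBF·frCBF/OpNe,
   SNEABF = SNGBF·[1 − FF(1 − Hct)], SNGFR = SNGBF − SNEABF,
   CVF = (SNEABF + ½·frPR·SNGFR)/f_br, TVF = SNGFR(1 − ½·frPR).
   Perfused patches exchange the corresponding volume fraction per
   tick with their feed (PO₂ 56 mmHg for capillary blood, 40 mmHg for
   glomerular filtrate, at reference).
2. **Hemoglobin kinetics** (PTC only). Saturation S relaxes toward the
   Hill equilibrium S/(100−S) = (PO₂/P₅₀)^n with P₅₀ = 36.8 mmHg and a
   saturation-dependent cooperativity n(S) and rate scale k′c(S);
   each tetramer carries 4 O₂ (blood capacity ≈ 9.4 mM).
3. **Fick diffusion** on the lattice: J(i→j) = D̄ᵢⱼ·Sᵢⱼ·[O₂]ᵢ/L over
   effective exchange surfaces Sᵢⱼ (brush-border EPI–LUM 2000 µm²,
   EPI–EPI 800, PTC–EPI 157, PTC–INT 39, default 100).
4. **Michaelis–Menten consumption** (Km = 1.1 µM): housekeeping rates
   per compartment plus the sodium-reabsorption cost of the epithelium,
   J_TNa = (0.33/r_ATP:O₂)·(frTC/fBIC)·T_Na, where T_Na is the
   filtered-load share reabsorbed by one epithelial patch.

Inputs are RBF and the two feed PO₂ values; the primary output is the
volume-weighted mean tissue PO₂ (tPO₂), per-compartment means, and —
under ischemia (RBF → 0) or anoxemia (feeds → 0) — decay half-times.
Two parameter presets are shipped: the reference configuration `rcm0`
and the physiologically adjusted `rcmstar` (longer effective tubule,
higher total reabsorption, lower transcellular fraction, larger
bicarbonate factor, higher ATP/O₂ yield).

## Worked example

```sh
$ rcm run --preset rcmstar --tissue 1540 --rbf 5.3 --ptc 56 --lum 40 -o out
steady-state tissue PO2 = 41.71 mmHg
wrote out/manifest.json
```

The run starts from zero oxygen everywhere and integrates until no
compartment mean moves by more than 0.01 mmHg over 100 ms (~0.6 s of
simulated time). `out/timeseries.csv` holds the sampled compartment
means; the final line shows the steady state —

```
time_ms,tPO2_mmHg,PTC_PO2_mmHg,EPI_PO2_mmHg,LUM_PO2_mmHg,INT_PO2_mmHg,Hb_sat_pct,QO2_total_amol_per_ms
580.0,41.71,55.26,40.10,40.03,43.34,74.77,70.78
```

— capillaries sit ~0.7 mmHg below their feed with hemoglobin ~75 %
saturated, the lumina hold ≈ 40 mmHg, and the epithelium runs a few
mmHg lower, consuming ≈ 71 amol/ms slab-wide (≈ 4.1 mM·min⁻¹ of
cortex). `out/po2_snapshot.tsv` is the final 32 × 32 PO₂ map.

The flow cascade and its comparison against reference rat values:

```sh
$ rcm flows --preset rcm0
quantity        value ratio_to_reference
   SNGBF 1.766667e+02           0.981481
   SNGFR 3.303667e+01           1.001111
     CVF 2.534239e+01           1.267120
     TVF 2.461232e+01           1.230616
   ...
mean ratio 1.049 ± 0.114
```

Other subcommands: `rcm tissue build` (tissue maps and morphometry
reports), `rcm run --protocol ischemia` (transients and half-times),
`rcm sa` (relative sensitivity coefficients), `rcm io-scan` /
`rcm dhb-scan` (feed-slope and hemoglobin-contribution tables),
`rcm hbcurve` (the equilibrium saturation curve).

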