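# eadclump

Monodomain simulations of how a clump of EAD-capable human ventricular
myocytes triggers premature ventricular complexes (PVCs), and the analysis
pipeline that quantifies when it does.

The myocyte is the O'Hara–Rudy (2011) endocardial human ventricular model
with the fast Na⁺ current replaced by the Ten Tusscher–Panfilov (2006)
formulation (14-current roster, no late Na⁺ current).  EAD-capable cells
are created by scaling I_CaL up (×4) and I_Kr down (×0.21 for "type-I"
growing-oscillation APs, ×0.12 for "type-II" decaying, non-repolarizing
APs).  Passive fibroblasts (C_f = 6.3 pF, G_f = 4 nS — or 2/4 nS piecewise
at −20 mV — resting potential E_f) couple to myocytes through a linear gap
conductance (default 8 nS).  Tissue is an isotropic monodomain sheet
(D = 0.0012 cm²/ms, dx = 0.02 cm, dt = 0.02 ms, forward Euler with a
conservative face-averaged 5-point Laplacian, no-flux boundaries,
inexcitable point obstacles for diffuse fibrosis); the nominal planar
conduction velocity is 64.5 cm/s.

## Layout

| module | contents |
|---|---|
| `eadclump.cell_models` | ionic model kernel, myocyte/fibroblast/composite types, single-cell pacing |
| `eadclump.tissue_solver` | `TissueGrid`/`TissueState`, diffusion operator, jitted stepping kernel, recorders, `run_simulation` |
| `eadclump.scenario_generator` | circular clumps, seeded fibrosis masks, fibroblast attachment maps, the four 280-cell cable patterns |
| `eadclump.protocols` | periodic asymmetric pacing, cable end pacing, S1–S2 cross-field spiral initiation, sensor placement |
| `eadclump.analysis` | AP/EAD detection and type-I/II classification, conduction velocity, PVC counting, averaged power spectra with periodic/quasiperiodic peak indexing |
| `eadclump.cli_experiments` | named figure-level experiments, sweeps, and the `eadclump` CLI |

## CLI

```bash
eadclump run fig12 --scale reduced --seed 0 --out out/fig12
eadclump run fig4  --scale full  --out out/fig4      # 15-s, 448x448 (hours)
eadclump sweep P_f --values 0,15,30,60 --scale reduced --out pf.csv
eadclump generate --radius-cm 2.0 --pf 15 --seed 3 --out out/scenario
```

Experiments run at two scales.  `full` is the study geometry
(448×448 sites ≙ 8.96×8.96 cm², 19.2×19.2 cm² for spirals; 15 s of
pacing) — single-process runs that take hours each and are meant for
offline reproduction.  `reduced` is a desk-scale proxy: single-cell and
280-cell-cable experiments run unchanged, while 2D clump experiments
shrink to a 4×400-site strip in which a cross-strip EAD band stands in
for the circular clump (5 s of pacing).  The reduced scale preserves the
qualitative claims (which pattern/size/coupling/fibrosis configurations
do or do not trigger PVCs), not the full-scale absolute counts.

## Notes

- Gating variables are integrated with the exact exponential
  (Rush–Larsen) update; plain forward Euler is unconditionally unstable
  for the TP06 m-gate (τ_m < 1 µs near rest) at dt = 0.02 ms.  Voltage,
  concentration, and CaMK equations use forward Euler.
- The tissue kernel reads all voltage-only rate factors from a 0.01-mV
  lookup table; a unit test pins it to the analytic single-cell path.
- The diffusion constant is 0.0012 cm²/ms (the value consistent with a
  65 cm/s conduction velocity), not cm²/s.
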