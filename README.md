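# cryobank

Computational pipeline for whole-organ cryopreservation by **vitrification and
nanowarming**: loading a kidney with cryoprotective agent (CPA) by vascular
perfusion, cooling it to an ice-free glassy state, rewarming it volumetrically
via RF-excited iron-oxide nanoparticles (IONPs), and assessing the organ's
function afterwards. The package is aimed at cryobiology and organ-preservation
researchers who need reproducible, testable implementations of the standard
calculations in this workflow — protocol arithmetic, membrane mass transport,
thermal-history and DSC analysis, micro-CT radiodensity classification,
normothermic-perfusion metrics, and post-transplant outcome statistics — plus a
deterministic synthetic-data generator so every stage can be exercised without
instrument data.

## What it computes

**Perfusion protocols** (`cryobank.protocol`). CPA loading/unloading schedules
are piecewise concentration–time functions built from flush/ramp/hold/step/IONP
segments with pressure and temperature setpoints. Ramp durations are derived as
|Δc|/|rate|; e.g. the standard VMP loading schedule (20-min carrier flush,
0 → 5 M at 50 mM/min, 10-min hold, 25-min step at full-strength 8.4 M) totals
155 min, and the unloading schedule (15-min hold at 4.2 M + 300 mM mannitol,
ramp to 0 at −35 mM/min with mannitol at −2.5 mM/min, 30-min flush) totals
165 min. A strict >45% unloading/loading flow-ratio QC flags IONP aggregation.

**Mass transport** (`cryobank.transport`). The kidney is modeled as parallel
Krogh cylinder units — a capillary of radius r_c inside a tissue annulus —
exchanging water and CPA across a composite membrane by the Kedem–Katchalsky
equations:

    Jv = Lp (Δp − σ R T Δc_CPA − R T Δc_impermeant)
    Js = ω R T Δc_CPA + (1 − σ) c̄ Jv

with Lp = 1.5×10⁻¹⁴ m³/(N·s), ω = 7.0×10⁻¹³ mol/(N·s), σ = 0.1. Each axial
capillary segment advects the inlet concentration and exchanges with a
well-mixed extravascular compartment; the integrator is adaptive implicit and
tracks solute mass balance to ~10⁻¹⁵ relative error. In the σ = 1, ω = 0 limit
the tissue compartment obeys the Boyle–van't Hoff relation (V ∝ 1/osmolality).

**Thermal analysis** (`cryobank.thermal`). Cooling/warming logs are scored by
their mean rate through the ice-formation risk zone between the melting point
(Tm = −40.8 °C) and the glass transition (Tg = −128.3 °C) of VMP, and checked
strictly against the critical cooling/warming rates (CCR 2 °C/min, CWR
~50 °C/min). DSC ice fractions come from baseline-corrected trapezoidal
integration of the crystallization event; CCR/CWR are interpolated on a log₁₀
ice-fraction scale (threshold 0.5%). The controlled-rate-freezer program
(0 → −122 °C at −40 °C/min, 25-min anneal, −122 → −150 °C at −5 °C/min, 10-min
hold) is represented and evaluable at any time point.

**Micro-CT** (`cryobank.microct`). Raw volumes are calibrated to Hounsfield
units against water/air reference tubes (water → 0 HU, air → −1000 HU exactly),
per-region means/SDs are computed over a label mask, and regions or voxels are
classified vitrified (≥ threshold, default 400 HU) vs frozen; a
gradient/connected-component heuristic screens for planar low-HU
discontinuities suggestive of cracking. Voxel grids are (z, y, x), 0-based,
voxel-center coordinates.

**NMP metrics & statistics** (`cryobank.nmp`). From normothermic machine
perfusion time series: mass-normalized vascular resistance P/(Q/m), dissolved-
oxygen-only oxygen consumption rate, glucose consumption
(c_art − c_ven)·Q/m, lactate production, and UV/P creatinine clearance. Group
comparison follows a normality/variance-gated tree: Shapiro–Wilk → Levene →
ANOVA + Tukey HSD or Welch ANOVA + Games–Howell; non-normal data go to
Kruskal–Wallis with Holm-adjusted pairwise Mann–Whitney tests.

**Transplant outcomes** (`cryobank.outcomes`). 30-day daily-lab trajectories
are summarized by creatinine landmarks (peak value/day, first day below
2.0 mg/dL from the peak onward, terminal value), day −1-normalized weight, and
a pluggable UV/P eGFR; groups are compared per day with Wilcoxon rank-sum or
t-tests, and storage-duration effects screened with Kendall's tau-b.

**Synthetic data** (`cryobank.synthetic`). Pure-function generators (same seed
→ byte-identical output) for temperature logs, thermograms with exact-area
exotherms, CT phantoms with reference tubes, per-group NMP traces, and
transplant lab cohorts.

## Worked example

```python
from cryobank import protocol as pr, transport as tr, thermal as th
from cryobank import synthetic as syn, microct as ct

load = pr.vmp_loading_protocol()
print(load.total_duration())        # 155.0  (min)
print(load.concentration_at(70.0))  # 2500.0 (mM, on the 50 mM/min ramp)

h = tr.simulate_perfusion(load, tr.KroghGeometry(),
                          tr.MembraneParams(area_scale=50.0), flow=1.0, dt=1.0)
print(round(h.final_mean_tissue_concentration, 1))  # 8113.8 (mM)
print(f"{h.mass_balance_residual():.2e}")           # 6.26e-16

log = syn.gen_temperature_log(-20.5, 0, -150, noise_sd=0.5, seed=1)
fit = th.fit_rate(log)                       # rate through [Tg, Tm]
chk = th.check_against_critical(fit.mean_rate, 2.0)
print(round(fit.mean_rate, 2), round(chk.margin, 2), chk.passed)
# -20.51 10.26 True

ph = syn.gen_ct_phantom(syn.vitrified_kidney_phantom_regions(), seed=1)
hu = ct.calibrate_hu(ph.raw, ph.water_roi, ph.air_roi)
rep = ct.region_stats(hu, ph.labels, names=ph.names, threshold_hu=400.0)
for r in rep.regions:
    print(r.name, round(r.mean_hu, 1), r.state)
# kidney 507.0 vitrified
# fat 268.3 frozen
```

The simulated final tissue concentration approaches the 8.4 M (8400 mM)
full-strength plateau; the cooling log passes the CCR check with a 10×
margin; and the calibrated phantom recovers the generating radiodensity
distributions, classifying the kidney vitrified and the icy perihilar fat
frozen.

## Command line

Every module has a thin CLI (`cryobank --help`): `protocol
validate|duration|plot|flow-qc`, `transport simulate`, `thermal
rate|check|icefrac|critical`, `ct calibrate|stats|classify|cracks`, `nmp
metrics|compare`, `outcomes summarize|compare|correlate`, and `cryobank synth
<scenario> --seed N --out DIR` to materialize any shipped scenario (cooling,
warming, dsc, ct_vitrified, ct_ionp, nmp, transplant) in the same file formats
the analysis commands read.

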