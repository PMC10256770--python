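# Methods

This note records the models, numerical choices and open design decisions
behind each module, in the spirit of a model-documentation page: what is
assumed, what is configurable, and what the synthetic-data tests do and do not
demonstrate about real data.

## Units and conventions

Concentrations are millimolar throughout; since 1 mM = 1 mol/m³, values feed
the SI flux equations unchanged. Pressures are mmHg at the interface
(converted to Pa internally, 1 mmHg = 133.322 Pa), temperatures °C (K
internally), times minutes at the protocol level and seconds for logger data.
Voxel grids are (z, y, x), 0-based, isotropic voxel size in mm, physical
coordinates at voxel centers. "5 M" and "8.4 M" CPA strengths map to 5000 and
8400 mM.

## Perfusion protocols

A protocol is an ordered list of segments. Ramps carry a signed rate in
mM/min and derive their duration as |c_end − c_start|/|rate|; all other kinds
carry an explicit duration and a constant concentration. Validation rejects
zero-rate ramps, sign-inconsistent rates, and any concentration discontinuity
between adjacent segments that is not an explicit `step`. Step segments are
right-continuous: the stepped value holds on [start, end), which matches the
semantics of abruptly switching the perfusate to full strength. The protocol
end evaluates to the final segment's end value.

Adjunct solutes (mannitol during unloading) ride on the same timeline as a
parallel piecewise function; a stated adjunct rate must reproduce the host
segment's duration. IONP co-perfusion is a dedicated `ionp` segment with a
constant-flow setpoint (default 0.5 mL/min); its default duration is 4.5 min,
taken as the final minutes of the full-strength step so the loading total is
unchanged. The duration is configurable because instrument practice varies
between 4 and 5 min. IONPs are treated as non-permeating: they never enter
the membrane flux equations.

The flow-QC rule (unloading flow must exceed 45% of loading flow) uses a
strict inequality: a ratio of exactly 0.45 fails.

## Krogh-cylinder / Kedem–Katchalsky transport

The organ is idealized as `n_units` identical parallel Krogh cylinders; one
representative unit is simulated. The capillary (radius 3.5 µm, unit length
1 mm) is discretized into `n_axial` (default 10) flow-through compartments in
series; each exchanges with a single well-mixed extravascular annulus
(outer radius 20 µm) across a composite membrane:

* volume flux: Jv = Lp (Δp − σ R T Δc_CPA − R T Δc_imp)
* solute flux: Js = ω R T Δc_CPA + (1 − σ) c̄ Jv

with positive fluxes directed vasculature → tissue, ideal van't Hoff osmotic
pressure (osmotic coefficient 1), and c̄ the arithmetic-mean membrane CPA
concentration (a log-mean option exists). The hydrostatic term uses the
protocol pressure setpoint on the vascular side and 0 in the tissue.
Impermeant osmolytes are a fixed vascular carrier osmolality (default
300 mM) and a conserved mole count per tissue compartment, so tissue
impermeant concentration varies inversely with compartment volume — this is
what produces the Boyle–van't Hoff equilibrium in the σ = 1, ω = 0 limit.

State per axial segment: vascular concentration, tissue solute content, and
tissue volume (relative to its initial value); two additional states
accumulate cumulative inlet and outlet moles so the solute balance closes by
construction and any right-hand-side inconsistency appears as a nonzero
residual. Axial flow attenuates by the volume flux taken up in each segment.
The system is integrated with BDF (rtol 1e-8, atol 1e-9 on concentrations),
segment by segment so protocol breakpoints are never stepped over; an event
terminates the solve with a diagnostic if any tissue compartment shrinks
below 2% of its initial volume. The integrator is deterministic.

Geometry defaults are documented assumptions, not measured values: no
capillary geometry for this preparation is published alongside the transport
coefficients. Likewise it is not stated whether the published ω and Lp are
normalized per capillary-wall area; `MembraneParams.area_scale` multiplies
the geometric exchange area to absorb that ambiguity. With `area_scale = 1`
the tissue-loading time constant is ≈ 570 min, far slower than the 10-min
osmotic-equilibration hold in the loading schedule, so analyses that need
equilibration on protocol timescales should set `area_scale` explicitly
(tests use 50–500). Temperature is the protocol segment temperature; no
Arrhenius scaling of Lp/ω is applied because only single-temperature values
are available.

Protocol comparison reports, per protocol, the final volume-weighted mean
tissue CPA concentration and the exposure integral (and time) of that mean
above user-supplied thresholds — the quantities that trade loading
completeness against toxicity. No toxicity cost model is included.

## Thermal analysis and DSC

The mean rate through the crystallization risk zone is (T_low − T_high)
divided by the time between the first crossings of the window bounds
(default [Tg, Tm] = [−128.3, −40.8] °C), linearly interpolated between
samples, signed negative for cooling. Instantaneous rates are central
differences after a 5-sample moving-average smoother (window configurable).
Critical-rate checks are strict (margin = |rate|/critical must exceed 1);
the "~" in a nominal CWR of ~50 °C/min is ignored and the point value used.

Ice fraction: a linear baseline is fit to the leading/trailing 10% of the
scan (assumed event-free), subtracted, and the event integrated over
temperature by the trapezoid rule; dividing by the scan rate converts
(W/g)·°C to J/g, reported as % of a reference latent heat and clipped to
[0, 100]. The reference latent heat defaults to 335 J/g (pure-water value);
the true latent heat of a partially vitrified CPA solution is lower and
composition-dependent, so absolute ice fractions for real thermograms should
supply a calibrated reference. Baseline invariance under a constant offset
is exact because the baseline fit absorbs constants.

CCR/CWR are obtained by interpolating log₁₀(ice fraction) linearly against
scan rate and solving for the threshold crossing (default threshold 0.5%,
configurable and recorded in every result); thresholds outside the measured
range are linearly extrapolated and flagged. The controlled-rate-freezer
program is a continuity-checked piecewise-linear setpoint trajectory; the
standard vitrification program spans 43.65 min.

## Micro-CT

Calibration is the affine map HU(x) = 1000·(x − mean_water)/(mean_water −
mean_air) from the water/air reference-tube ROI means, which by construction
sends the water ROI mean to 0 HU and the air ROI mean to −1000 HU exactly and
is invariant under any affine rescaling of the raw intensities. Region SDs
are population SDs (ddof 0). The vitrified/frozen voxel and region rule is
mean ≥ threshold → vitrified, with a default of 400 HU chosen as a round
midpoint between observed vitrified kidney (~507 HU) and icy fat (~267 HU)
radiodensities; it is a heuristic, is configurable, and must be shifted
upward for IONP-loaded scans whose radiodensity is elevated throughout.

The crack screen is deliberately conservative: voxels below a low-HU
threshold adjacent to high gradient magnitude (the high-gradient mask is
dilated one voxel, since central differences vanish in the middle of a
1-voxel-thick feature) are grouped into connected components; each component
is scored by PCA of its voxel coordinates, and components that are planar or
linear (planarity ≥ 0.5) and span at least `min_extent_mm` along their
principal axis are reported. It formalizes a visual inspection step and is
not a fracture-mechanics model.

## NMP metrics and statistics

Vascular resistance is mass-normalized as pressure/(flow per gram),
mmHg/(mL/min/g) — the unit string "mmHg/mL/min × g" is read this way
deliberately, and the choice is worth noting because the bare string is
ambiguous. The oxygen consumption rate assumes an acellular perfusate, so
only dissolved oxygen carries: OCR = ΔpO2 · solubility · (Q/1000)/m with
solubility defaulting to 1.4 µmol/(L·mmHg) at 37 °C (configurable; the
appropriate constant depends on perfusate composition). Glucose consumption
is (c_art − c_ven)·Q/m (mmol/L × mL/min ≡ µmol/min); lactate production uses
the venous−arterial difference. Creatinine clearance is UV/P per organ, with
urine flow taken as the volume increment over the sampling interval.

Group comparison: Shapiro–Wilk per group (constant groups are routed
non-parametric; groups of n < 3 do not block the parametric path), then
Levene; equal variance → one-way ANOVA with Tukey HSD, unequal → Welch ANOVA
with Games–Howell; any non-normal group → Kruskal–Wallis with pairwise
Mann–Whitney and Holm adjustment (the adjustment method is a package choice).
The report always records the path taken, the normality/Levene p-values, the
omnibus test and the adjusted pairwise p-values.

A caution on small groups: with n = 4 per group, the exact two-sided
Mann–Whitney p-value cannot go below 2/70 ≈ 0.029 (≈ 0.29 after Holm across
ten pairs) and Games–Howell against a high-variance group has ~3 degrees of
freedom, so adjusted significance at the 0.001 level is not attainable on the
non-parametric or unequal-variance paths at that size; the property tests
therefore assert the qualitative group ordering at n = 4 and formal
significance at a powered size (n = 50).

## Transplant outcomes

Creatinine landmarks: peak value and day; "first day below threshold"
(default 2.0 mg/dL) is evaluated from the peak day onward — the
time-to-normalization reading — because the pre-transplant baseline is itself
below threshold and would otherwise satisfy the criterion trivially; for a
series whose maximum is its first value this reduces to the first recorded
day. No interpolation between days; strictly-below on the first qualifying
day. Missing values are left missing (available-case analysis, no
imputation). Weight is normalized to the day −1 baseline. eGFR is a pluggable
callable with a UV/P default, intended to be sanity-checked against the
normal range for healthy rats (median 1.5, IQR 1.0–2.2 mL/min) rather than
asserted numerically. Longitudinal two-group tests default to Wilcoxon
rank-sum with a per-variable override map (t-test for potassium and
hemoglobin); storage-duration screens use Kendall tau-b with the exact null
for n ≤ 10 (ties fall back to the asymptotic method), and constant inputs are
flagged degenerate rather than raised.

## Synthetic data

Generators are pure functions of (parameters, seed) using a dedicated PCG64
stream, so identical calls are byte-identical. They emulate the statistical
structure the analyses assume, not the instruments:

* Temperature logs: 1-s cadence, exact linear segments plus Gaussian probe
  noise (default SD 0.5 °C), optional annealing plateau. They contain no
  sensor lag, quantization, or the curvature of real organ thermal histories.
* Thermograms: flat baseline plus a Gaussian exotherm whose integrated area
  is exactly the target fraction of the reference latent heat. Real DSC
  events are asymmetric with sloping baselines; passing tests show the
  integration and baseline correction are self-consistent, not that the
  instrument model is realistic.
* CT phantoms: per-region Gaussian HU in boxes, affinely mapped to a raw
  scanner scale, with water/air tubes (SD 5 HU) so calibration is exercised
  end to end. Default region values follow the reported vitrified-kidney
  scans: IONP-free kidney 507 ± 30 HU with icy fat 267 ± 104 HU; IONP-loaded
  solution/cortex/outer/inner medulla 768 ± 20, 628 ± 15, 656 ± 20,
  560 ± 18 HU. There is no partial-volume blur, beam hardening, or anatomy.
* NMP traces: 10-min cadence over 40 min; minute-40 endpoint metrics are
  drawn per kidney from the group Normal(mean, SD) endpoint distributions
  (resistance for control / 24-h cold-stored / VMP-only / nanowarmed / VS55:
  18.8 ± 4.1, 24.9 ± 2.6, 27.5 ± 3.4, 31.3 ± 3.6, 372 ± 131 mmHg/(mL/min/g);
  n = 4 per group in the study conditions), with smooth within-run
  interpolation (resistance relaxes exponentially to its endpoint) and
  pressure held in the 90–110 mmHg window. Variation is modeled at the
  endpoint level, not mechanistically, because recovery of group endpoint
  summaries is what the downstream statistics consume.
* Transplant cohorts: each animal gets a persistent creatinine set point
  (~N(0.55, 0.08), clipped to 0.4–0.8 mg/dL); controls stay near it, while
  nanowarmed recipients rise linearly to a peak of ~4.5 mg/dL on day 2–3,
  decay exponentially through 2.0 mg/dL around days 17–21, and settle back to
  their own baseline within ~4 days of the crossing — so late-day group
  comparisons are genuinely null, matching the observed convergence.
  Potassium, pH, bicarbonate and pCO2 excursions resolve by day 15, lactate
  by ~day 9, and a ~10% excess weight gain resolves by days 10–12. The
  piecewise rise/two-phase-decay shape is an artifact choice; only the
  landmarks are anchored to observation. Storage durations (1–100 days) are
  drawn independently of severity, so storage-outcome correlations are null
  by construction.

## Problem sizes and determinism

The shipped analyses and tests run at desk scale: phantoms of 48×64×64
voxels (1e5-voxel kidney region), 200-kidney NMP cohorts for recovery
checks, 100-replicate conservation sweeps with 3 axial segments, and
200-replicate noisy-rate sweeps. Every stochastic test and the acceptance
script derive all randomness from explicit integer seeds; the transport
solver and all analysis operations are deterministic.

## Known limitations

No radial diffusion inside the tissue annulus (membrane-limited exchange
only); no viscosity-coupled flow solver (measured flow is an input); no CPA
toxicity model; no heat-transfer or electromagnetic/SAR model of nanowarming
(rates are analyzed, not predicted); no tomographic reconstruction or
beam-hardening correction; no survival analysis for the 30-day cohorts. The
synthetic generators are statistical emulators — agreement of the pipeline
with their parameters demonstrates correctness of the estimators, not
fidelity of the underlying biology.
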