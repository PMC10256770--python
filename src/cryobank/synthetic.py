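"""Synthetic fixtures with the statistical structure the analysis expects.

Every generator is a pure function of its parameters and seed (same seed,
byte-identical output), producing the same objects and file formats the
analysis modules consume:

* temperature logs: 1-s cadence linear cooling/warming plus Gaussian probe
  noise (default SD 0.5 degC), optional annealing plateau;
* DSC thermograms: flat baseline plus a Gaussian crystallization exotherm
  whose integrated area is an exact target fraction of the reference latent
  heat;
* micro-CT phantoms: per-region Gaussian radiodensity in a raw intensity
  scale affinely related to HU, with water/air reference tubes so calibration
  is exercised end to end;
* NMP traces: per-kidney 10-min-cadence series whose minute-40 endpoint
  metrics are drawn from the group Normal(mean, SD) endpoint distributions
  (variation modeled at the endpoint level, not mechanistically);
* 30-day transplant lab trajectories: near-normal controls vs nanowarmed
  recipients with a creatinine peak on day 2-3, exponential-like decline
  crossing 2.0 mg/dL around days 17-21, terminal 0.4-0.8 mg/dL, and
  correlated potassium/pH/bicarbonate excursions resolving by day 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .microct import RawVolume, box_roi
from .outcomes import LabSeries
from .thermal import TemperatureLog, Thermogram

__all__ = [
    "NMP_GROUP_PARAMS",
    "KidneyRun",
    "CTRegionSpec",
    "CTPhantom",
    "SyntheticError",
    "gen_temperature_log",
    "gen_thermogram",
    "gen_ct_phantom",
    "vitrified_kidney_phantom_regions",
    "ionp_kidney_phantom_regions",
    "gen_nmp_timeseries",
    "gen_transplant_labs",
]


class SyntheticError(ValueError):
    """Raised on inconsistent generator parameters."""


# ---------------------------------------------------------------------------
# Temperature logs

def gen_temperature_log(
    rate: float,
    T_start: float,
    T_end: float,
    noise_sd: float = 0.5,
    seed: int = 0,
    anneal_at: float | None = None,
    anneal_min: float = 0.0,
    probe: str = "synthetic",
) -> TemperatureLog:
    """Linear cooling/warming trajectory at 1-s cadence with Gaussian noise.

    ``rate`` is degC/min, signed (negative = cooling); an optional plateau of
    ``anneal_min`` minutes is inserted when the trajectory reaches
    ``anneal_at``.
    """
    if rate == 0:
        raise SyntheticError("rate must be nonzero")
    if noise_sd < 0:
        raise SyntheticError("noise_sd must be >= 0")
    if (T_end - T_start) * rate < 0:
        raise SyntheticError("rate sign inconsistent with T_start -> T_end")
    rng = np.random.default_rng(seed)
    rate_s = rate / 60.0
    pieces: list[np.ndarray] = []

    def linear(T0, T1):
        n = int(round(abs(T1 - T0) / abs(rate_s)))
        return T0 + rate_s * np.arange(n + 1) if n > 0 else np.array([T0])

    if anneal_at is not None and min(T_start, T_end) < anneal_at < max(T_start, T_end):
        a = linear(T_start, anneal_at)
        plateau = np.full(int(round(anneal_min * 60.0)), anneal_at)
        b = linear(anneal_at, T_end)
        temp = np.concatenate([a, plateau, b[1:]])
    else:
        temp = linear(T_start, T_end)
    if noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, size=temp.size)
    temp = np.clip(temp, -200.0, 50.0)
    return TemperatureLog(time_s=np.arange(temp.size, dtype=float), temp_C=temp,
                          probe=probe)


# ---------------------------------------------------------------------------
# DSC thermograms

def gen_thermogram(
    ice_fraction_target: float,
    reference_latent_heat: float = 335.0,
    seed: int = 0,
    scan_rate: float = 5.0,
    direction: str = "cooling",
    T_range: tuple[float, float] = (-150.0, -20.0),
    peak_T: float = -70.0,
    peak_width: float = 5.0,
    baseline: float = 0.05,
    noise_sd: float = 0.0,
    n_points: int = 1301,
) -> Thermogram:
    """Thermogram whose crystallization exotherm integrates to an exact target.

    The event is a Gaussian centered at ``peak_T`` (degC) with SD
    ``peak_width``; its amplitude is chosen so the baseline-corrected area,
    divided by the scan rate, equals ``ice_fraction_target`` % of
    ``reference_latent_heat``. ``noise_sd`` (W/g) adds Gaussian measurement
    noise.
    """
    if not 0.0 <= ice_fraction_target <= 100.0:
        raise SyntheticError("ice fraction target must lie in [0, 100] %")
    rng = np.random.default_rng(seed)
    lo, hi = min(T_range), max(T_range)
    T = np.linspace(lo, hi, n_points)
    energy = ice_fraction_target / 100.0 * reference_latent_heat  # J/g
    area_WC = energy * (scan_rate / 60.0)  # (W/g)*degC under the peak
    amp = area_WC / (peak_width * np.sqrt(2.0 * np.pi))
    q = baseline + amp * np.exp(-0.5 * ((T - peak_T) / peak_width) ** 2)
    if noise_sd > 0:
        q = q + rng.normal(0.0, noise_sd, size=q.size)
    if direction == "cooling":
        T, q = T[::-1], q[::-1]
    return Thermogram(
        temp_C=T, heatflow_W_per_g=q, scan_rate=scan_rate, direction=direction,
        reference_latent_heat=reference_latent_heat,
    )


# ---------------------------------------------------------------------------
# Micro-CT phantoms

@dataclass(frozen=True)
class CTRegionSpec:
    label: int
    name: str
    mean_hu: float
    sd_hu: float
    box: tuple[slice, slice, slice]


@dataclass
class CTPhantom:
    raw: RawVolume
    labels: np.ndarray
    water_roi: tuple[slice, slice, slice] | None
    air_roi: tuple[slice, slice, slice] | None
    regions: tuple[CTRegionSpec, ...]
    names: dict[int, str]


def vitrified_kidney_phantom_regions() -> list[CTRegionSpec]:
    """Vitrified IONP-free kidney (507 +/- 30 HU) with icy perihilar fat
    (267 +/- 104 HU); the kidney box holds 1e5 voxels."""
    return [
        CTRegionSpec(1, "kidney", 507.0, 30.0, box_roi((4, 44), (4, 54), (4, 54))),
        CTRegionSpec(2, "fat", 267.0, 104.0, box_roi((4, 44), (4, 54), (55, 61))),
    ]


def ionp_kidney_phantom_regions() -> list[CTRegionSpec]:
    """Vitrified IONP-loaded kidney: surrounding solution, cortex, outer and
    inner medulla at their shifted radiodensities."""
    return [
        CTRegionSpec(1, "solution", 768.0, 20.0, box_roi((4, 44), (2, 54), (2, 12))),
        CTRegionSpec(2, "cortex", 628.0, 15.0, box_roi((4, 44), (2, 54), (14, 30))),
        CTRegionSpec(3, "outer_medulla", 656.0, 20.0, box_roi((4, 44), (2, 54), (32, 44))),
        CTRegionSpec(4, "inner_medulla", 560.0, 18.0, box_roi((4, 44), (2, 54), (46, 56))),
    ]


def gen_ct_phantom(
    regions: Sequence[CTRegionSpec],
    include_refs: bool = True,
    seed: int = 0,
    shape: tuple[int, int, int] = (48, 64, 64),
    voxel_size_mm: float = 0.061,
    raw_slope: float = 0.8,
    raw_offset: float = 1200.0,
    background_hu: float = -800.0,
    background_sd_hu: float = 10.0,
    ref_sd_hu: float = 5.0,
) -> CTPhantom:
    """3-D phantom with per-region Gaussian radiodensity.

    Voxels are generated in HU and mapped to a raw scanner scale by
    ``raw = raw_slope * HU + raw_offset``, so the calibration step is
    nontrivial. With ``include_refs`` a water tube (0 HU) and an air tube
    (-1000 HU) are placed along the top of the grid. Overlapping region boxes
    are rejected.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    hu = rng.normal(background_hu, background_sd_hu, size=shape)
    labels = np.zeros(shape, dtype=np.int32)
    occupancy = np.zeros(shape, dtype=bool)
    water_roi = air_roi = None
    boxes = [(f"region {r.name!r}", r.box) for r in regions]
    if include_refs:
        water_roi = box_roi((0, 3), (2, 12), (2, 30))
        air_roi = box_roi((0, 3), (2, 12), (34, 62))
        boxes += [("water tube", water_roi), ("air tube", air_roi)]
    for desc, box in boxes:
        sel = np.zeros(shape, dtype=bool)
        sel[box] = True
        if not sel.any():
            raise SyntheticError(f"{desc}: empty box")
        if (occupancy & sel).any():
            raise SyntheticError(f"{desc}: box overlaps another region")
        occupancy |= sel
    for r in regions:
        n = int(np.prod([s.stop - s.start for s in r.box]))
        hu[r.box] = rng.normal(r.mean_hu, r.sd_hu, size=n).reshape(
            [s.stop - s.start for s in r.box]
        )
        labels[r.box] = r.label
    if include_refs:
        for roi, mean in ((water_roi, 0.0), (air_roi, -1000.0)):
            n = int(np.prod([s.stop - s.start for s in roi]))
            hu[roi] = rng.normal(mean, ref_sd_hu, size=n).reshape(
                [s.stop - s.start for s in roi]
            )
    raw = raw_slope * hu + raw_offset
    return CTPhantom(
        raw=RawVolume(data=raw, voxel_size_mm=voxel_size_mm),
        labels=labels,
        water_roi=water_roi,
        air_roi=air_roi,
        regions=tuple(regions),
        names={r.label: r.name for r in regions},
    )


# ---------------------------------------------------------------------------
# NMP traces

# Minute-40 endpoint distributions per treatment group: vascular resistance
# (mmHg/(mL/min/g)) mean/SD, plus plausible metabolic endpoints. n = 4
# kidneys per group in the study conditions.
NMP_GROUP_PARAMS: dict[str, dict] = {
    "control":    {"resistance": (18.8, 4.1), "ocr": (1.10, 0.15),
                   "crcl": (0.50, 0.10), "urine_rate": (0.40, 0.08)},
    "cold_24h":   {"resistance": (24.9, 2.6), "ocr": (0.95, 0.15),
                   "crcl": (0.40, 0.10), "urine_rate": (0.35, 0.08)},
    "vmp":        {"resistance": (27.5, 3.4), "ocr": (0.90, 0.15),
                   "crcl": (0.35, 0.08), "urine_rate": (0.35, 0.08)},
    "nanowarmed": {"resistance": (31.3, 3.6), "ocr": (0.85, 0.15),
                   "crcl": (0.30, 0.08), "urine_rate": (0.35, 0.08)},
    "vs55":       {"resistance": (372.0, 131.0), "ocr": (0.20, 0.08),
                   "crcl": (0.03, 0.02), "urine_rate": (0.05, 0.02)},
}


@dataclass
class KidneyRun:
    kidney_id: str
    group: str
    mass_g: float
    samples: pd.DataFrame  # PERFUSION_COLUMNS rows at 10-min cadence


def gen_nmp_timeseries(
    group: str,
    n_kidneys: int = 4,
    seed: int = 0,
    params: dict | None = None,
    duration_min: float = 40.0,
    cadence_min: float = 10.0,
    mass_mean_g: float = 2.0,
    mass_sd_g: float = 0.15,
) -> list[KidneyRun]:
    """Per-kidney perfusion time series for one treatment group.

    Minute-40 endpoint metrics are drawn from the group's Normal(mean, SD)
    endpoint distributions; within a run, channels interpolate smoothly toward
    the endpoint (resistance relaxes exponentially from an elevated start) and
    pressure is held within the 90-110 mmHg window. With SD = 0 and
    ``n_kidneys = 1`` the endpoint metrics equal the group means exactly.
    """
    if n_kidneys < 1:
        raise SyntheticError("n_kidneys must be >= 1")
    p = dict(NMP_GROUP_PARAMS.get(group, NMP_GROUP_PARAMS["control"]))
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 1e-9, cadence_min)
    runs: list[KidneyRun] = []
    p_cr = 50.0  # perfusate creatinine, mg/dL (0.5 g/L supplement)
    glu_art = 5.54  # mmol/L perfusate glucose
    for i in range(n_kidneys):
        mass = max(float(rng.normal(mass_mean_g, mass_sd_g)), 0.5)
        r40 = max(float(rng.normal(*p["resistance"])), 1.0)
        ocr40 = max(float(rng.normal(*p["ocr"])), 0.0)
        crcl40 = max(float(rng.normal(*p["crcl"])), 0.0)
        urate40 = max(float(rng.normal(*p["urine_rate"])), 0.0)
        pressure = rng.uniform(95.0, 105.0, size=t.size)
        pressure[-1] = float(rng.uniform(98.0, 102.0))
        resistance = r40 * (1.0 + 0.4 * np.exp(-t / 12.0))
        resistance[-1] = r40
        flow = pressure * mass / resistance
        po2_art = np.full(t.size, 500.0)
        dpo2 = ocr40 * mass * 1000.0 / (1.4 * np.maximum(flow, 1e-3))
        po2_ven = np.clip(po2_art - dpo2 * (1 - 0.5 * np.exp(-t / 10.0)), 30.0, None)
        glu_cons = ocr40 * 0.25  # umol/(min g), loosely tied to aerobic activity
        glu_ven = np.clip(glu_art - glu_cons * mass / np.maximum(flow, 1e-3), 0.1, None)
        lactate = 0.5 + 1.0 * (1 - np.exp(-t / 25.0)) * (1.5 if group == "vs55" else 1.0)
        ph = 7.15 + 0.25 * (1 - np.exp(-t / 12.0))
        urine_inc = np.concatenate([[0.0], np.full(t.size - 1, urate40 * cadence_min)])
        uflow = urate40
        u_cr = crcl40 * p_cr / uflow if uflow > 0 else 0.0
        df = pd.DataFrame(
            {
                "time_min": t,
                "pressure_mmHg": pressure,
                "flow_mL_min": flow,
                "pO2_art_mmHg": po2_art,
                "pO2_ven_mmHg": po2_ven,
                "glucose_art_mM": glu_art,
                "glucose_ven_mM": glu_ven,
                "lactate_ven_mM": lactate,
                "ph_ven": ph,
                "urine_increment_mL": urine_inc,
                "urine_creatinine_mg_dL": u_cr,
                "perfusate_creatinine_mg_dL": p_cr,
                "na_mM": rng.normal(141.0, 1.0, size=t.size),
                "k_mM": rng.normal(4.7, 0.15, size=t.size),
                "cl_mM": rng.normal(102.0, 1.0, size=t.size),
            }
        )
        runs.append(KidneyRun(kidney_id=f"{group}_{i+1}", group=group, mass_g=mass,
                              samples=df))
    return runs


# ---------------------------------------------------------------------------
# Transplant lab trajectories

def _creatinine_curve(days: np.ndarray, baseline: float, peak: float,
                      peak_day: int, cross_day: float, terminal: float,
                      threshold: float = 2.0, settle_days: float = 4.0) -> np.ndarray:
    """Rise to a peak, then two-phase exponential decline: through
    ``threshold`` at ``cross_day``, then settling to ``terminal`` (near the
    normal range) within ``settle_days`` after the crossing."""
    tau1 = (cross_day - peak_day) / np.log(peak / threshold)
    # second phase reaches within ~15% of terminal by settle_days past crossing
    tau2 = settle_days / np.log((threshold - terminal) / (0.15 * (threshold - terminal)))
    out = np.empty_like(days, dtype=float)
    for i, d in enumerate(days):
        if d <= 0:
            out[i] = baseline
        elif d <= peak_day:
            out[i] = baseline + (peak - baseline) * d / peak_day
        elif d <= cross_day:
            out[i] = peak * np.exp(-(d - peak_day) / tau1)
        else:
            out[i] = terminal + (threshold - terminal) * np.exp(-(d - cross_day) / tau2)
    return out


def _excursion(days: np.ndarray, baseline: float, peak_delta: float,
               peak_day: float, resolve_day: float) -> np.ndarray:
    """Smooth excursion from baseline peaking near ``peak_day`` and decayed to
    <5% of the peak by ``resolve_day``."""
    tau = (resolve_day - peak_day) / 3.0
    out = np.full(days.shape, baseline, dtype=float)
    post = days > 0
    d = days[post].astype(float)
    rise = np.clip(d / peak_day, 0.0, 1.0)
    decay = np.where(d > peak_day, np.exp(-(d - peak_day) / tau), 1.0)
    out[post] = baseline + peak_delta * rise * decay
    return out


def gen_transplant_labs(
    group: str,
    n_animals: int = 5,
    seed: int = 0,
    n_days: int = 30,
    noise_scale: float = 1.0,
    peak_mean: float = 4.5,
    peak_sd: float = 0.5,
    cross_day_mean: float = 19.0,
    cross_day_sd: float = 1.0,
) -> list[LabSeries]:
    """30-day daily-lab cohorts for control or nanowarmed recipients.

    Controls stay near-normal throughout. Nanowarmed recipients show the
    initial-graft-dysfunction shape: creatinine peaking on day 2-3, declining
    past 2.0 mg/dL around days 17-21 and ending at 0.4-0.8 mg/dL, with
    correlated hyperkalemia and partially compensated metabolic acidosis
    resolving by day 15, a transient ~10% excess weight gain resolving by days
    10-12, and hemoglobin dipping then recovering. ``noise_scale`` scales all
    per-day measurement noise (0 gives the deterministic shapes); storage
    durations are drawn from 1-100 days for the nanowarmed group.
    """
    if n_animals < 1:
        raise SyntheticError("n_animals must be >= 1")
    rng = np.random.default_rng(seed)
    days = np.arange(-1, n_days + 1)
    nanowarmed = group == "nanowarmed"
    out: list[LabSeries] = []
    for i in range(n_animals):
        # persistent per-animal creatinine set point, shared by both groups;
        # nanowarmed trajectories converge back to it (terminal in 0.4-0.8)
        baseline_cr = float(np.clip(rng.normal(0.55, 0.08), 0.4, 0.8))
        storage = float(rng.integers(1, 101)) if nanowarmed else 0.0
        if nanowarmed:
            peak = float(np.clip(rng.normal(peak_mean, peak_sd), 3.0, 6.5))
            peak_day = int(rng.choice([2, 3]))
            cross = float(np.clip(rng.normal(cross_day_mean, cross_day_sd), 17.0, 21.0))
            term = baseline_cr
            cr = _creatinine_curve(days, baseline_cr, peak, peak_day, cross, term)
            k = _excursion(days, 4.6, 2.0, peak_day, 15.0)
            ph = _excursion(days, 7.40, -0.15, peak_day, 15.0)
            hco3 = _excursion(days, 25.0, -7.0, peak_day, 15.0)
            pco2 = _excursion(days, 40.0, -8.0, peak_day, 15.0)
            lact = _excursion(days, 1.0, 1.5, peak_day, 9.0)
            excess = _excursion(days, 0.0, 0.10, 4.0, 11.0)
        else:
            cr = np.full(days.shape, baseline_cr)
            k = np.full(days.shape, 4.6)
            ph = np.full(days.shape, 7.40)
            hco3 = np.full(days.shape, 25.0)
            pco2 = np.full(days.shape, 40.0)
            lact = np.full(days.shape, 1.0)
            excess = np.zeros(days.shape)
        hgb = 14.0 - 3.0 * np.exp(-0.5 * ((days - 3.0) / 2.5) ** 2) + 0.04 * np.clip(
            days, 0, None
        )
        base_weight = float(rng.normal(490.0, 20.0))
        growth = 1.0 + 0.004 * np.clip(days + 1, 0, None)
        weight = base_weight * growth * (1.0 + excess)
        ns = noise_scale
        data = pd.DataFrame(
            {
                "creatinine": np.maximum(
                    cr + rng.normal(0, 0.05 * ns, days.size), 0.1),
                "potassium": k + rng.normal(0, 0.15 * ns, days.size),
                "ph": ph + rng.normal(0, 0.02 * ns, days.size),
                "hco3": hco3 + rng.normal(0, 0.5 * ns, days.size),
                "pco2": pco2 + rng.normal(0, 1.0 * ns, days.size),
                "lactate": np.maximum(
                    lact + rng.normal(0, 0.1 * ns, days.size), 0.1),
                "hemoglobin": hgb + rng.normal(0, 0.3 * ns, days.size),
                "weight": weight + rng.normal(0, 2.0 * ns, days.size),
            },
            index=pd.Index(days, name="day"),
        )
        out.append(
            LabSeries(animal_id=f"{group}_{i+1}", group=group, data=data,
                      storage_days=storage)
        )
    return out
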