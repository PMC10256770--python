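"""Normothermic machine perfusion (NMP) functional metrics and group statistics.

A kidney perfused ex vivo at 37 degC with an oxygenated acellular perfusate is
assessed through hemodynamics (mass-normalized vascular resistance), oxygen
and substrate turnover, and urine production / creatinine clearance. Group
comparisons follow a normality/variance-gated decision tree: Shapiro-Wilk per
group, then Levene -> ANOVA with Tukey HSD (equal variance) or Welch ANOVA
with Games-Howell (unequal variance); non-normal data fall back to
Kruskal-Wallis with pairwise Mann-Whitney tests, Holm-adjusted.

Unit conventions: pressure mmHg, flow mL/min, mass g, concentrations mmol/L,
pO2 mmHg, creatinine mg/dL. Vascular resistance is pressure divided by
flow-per-gram, i.e. mmHg/(mL/min/g), written "mmHg/mL/min x g" on plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "O2_SOLUBILITY_DEFAULT",
    "NMPError",
    "NMPMetrics",
    "GroupComparison",
    "vascular_resistance",
    "substrate_flux",
    "creatinine_clearance",
    "oxygen_consumption",
    "compute_metrics",
    "group_compare",
    "PERFUSION_COLUMNS",
]

# Dissolved O2 in aqueous perfusate at 37 degC, umol/(L mmHg). The perfusate
# is acellular, so only dissolved oxygen carries.
O2_SOLUBILITY_DEFAULT = 1.4

PERFUSION_COLUMNS = [
    "time_min", "pressure_mmHg", "flow_mL_min", "pO2_art_mmHg", "pO2_ven_mmHg",
    "glucose_art_mM", "glucose_ven_mM", "lactate_ven_mM", "ph_ven",
    "urine_increment_mL", "urine_creatinine_mg_dL", "perfusate_creatinine_mg_dL",
    "na_mM", "k_mM", "cl_mM",
]


class NMPError(ValueError):
    """Raised on invalid perfusion inputs."""


def vascular_resistance(pressure: float, flow: float, mass: float) -> float:
    """Mass-normalized vascular resistance, mmHg/(mL/min/g): P / (Q / m)."""
    if mass <= 0:
        raise NMPError("kidney mass must be > 0 g")
    if flow <= 0:
        raise NMPError("flow must be > 0 mL/min (zero flow = infinite resistance)")
    return pressure / (flow / mass)


def substrate_flux(c_art: float, c_ven: float, flow: float, mass: float) -> float:
    """Arteriovenous substrate flux, umol/(min g): (c_art - c_ven) * flow / mass.

    mmol/L x mL/min is umol/min, so no unit factor is needed. Positive values
    mean consumption; pass venous and arterial swapped for production (e.g.
    lactate).
    """
    if mass <= 0:
        raise NMPError("kidney mass must be > 0 g")
    return (c_art - c_ven) * flow / mass


def creatinine_clearance(u_cr: float, urine_flow: float, p_cr: float) -> float:
    """Creatinine clearance, mL/min: U x V / P."""
    if p_cr <= 0:
        raise NMPError("perfusate creatinine must be > 0 mg/dL")
    return u_cr * urine_flow / p_cr


def oxygen_consumption(
    pO2_art: float,
    pO2_ven: float,
    flow: float,
    mass: float,
    solubility: float = O2_SOLUBILITY_DEFAULT,
) -> float:
    """Oxygen consumption rate, umol O2/(min g), dissolved-oxygen-only:

        OCR = (pO2_art - pO2_ven) * solubility * (flow / 1000) / mass
    """
    if mass <= 0:
        raise NMPError("kidney mass must be > 0 g")
    if solubility <= 0:
        raise NMPError("oxygen solubility must be > 0")
    return (pO2_art - pO2_ven) * solubility * (flow / 1000.0) / mass


@dataclass
class NMPMetrics:
    """Endpoint metrics of one perfusion run (typically at minute 40)."""

    kidney_mass_g: float
    cumulative_urine_mL: float
    urine_series_mL: pd.Series  # cumulative, indexed by time_min
    creatinine_clearance_mL_min: float
    vascular_resistance: float  # mmHg/(mL/min/g)
    ocr_umol_min_g: float
    glucose_consumption_umol_min_g: float
    lactate_production_umol_min_g: float

    def to_dict(self) -> dict:
        return {
            "kidney_mass_g": self.kidney_mass_g,
            "cumulative_urine_mL": self.cumulative_urine_mL,
            "creatinine_clearance_mL_min": self.creatinine_clearance_mL_min,
            "vascular_resistance_mmHg_per_mL_min_g": self.vascular_resistance,
            "ocr_umol_min_g": self.ocr_umol_min_g,
            "glucose_consumption_umol_min_g": self.glucose_consumption_umol_min_g,
            "lactate_production_umol_min_g": self.lactate_production_umol_min_g,
        }


def compute_metrics(
    samples: pd.DataFrame,
    mass: float,
    solubility: float = O2_SOLUBILITY_DEFAULT,
    lactate_baseline_mM: float = 0.0,
) -> NMPMetrics:
    """Derive endpoint NMP metrics from a perfusion time series.

    ``samples`` has one row per sampling time with PERFUSION_COLUMNS (missing
    channels may be absent; the corresponding metrics are NaN). Urine flow per
    interval is the volume increment divided by the interval length; endpoint
    metrics use the final sample.
    """
    if mass <= 0:
        raise NMPError("kidney mass must be > 0 g")
    if samples.empty:
        raise NMPError("empty perfusion series")
    df = samples.sort_values("time_min")
    last = df.iloc[-1]
    cum_urine = (
        df["urine_increment_mL"].fillna(0.0).cumsum()
        if "urine_increment_mL" in df
        else pd.Series(np.nan, index=df.index)
    )
    cum_urine.index = df["time_min"].to_numpy()
    res = vascular_resistance(last["pressure_mmHg"], last["flow_mL_min"], mass)
    ocr = glu = lac = crcl = float("nan")
    if {"pO2_art_mmHg", "pO2_ven_mmHg"} <= set(df.columns):
        ocr = oxygen_consumption(
            last["pO2_art_mmHg"], last["pO2_ven_mmHg"], last["flow_mL_min"], mass,
            solubility,
        )
    if {"glucose_art_mM", "glucose_ven_mM"} <= set(df.columns):
        glu = substrate_flux(
            last["glucose_art_mM"], last["glucose_ven_mM"], last["flow_mL_min"], mass
        )
    if "lactate_ven_mM" in df.columns:
        lac = substrate_flux(
            last["lactate_ven_mM"], lactate_baseline_mM, last["flow_mL_min"], mass
        )
    if {"urine_increment_mL", "urine_creatinine_mg_dL",
        "perfusate_creatinine_mg_dL"} <= set(df.columns):
        t = df["time_min"].to_numpy()
        dt = t[-1] - t[-2] if t.size >= 2 else np.nan
        uflow = last["urine_increment_mL"] / dt if dt and dt > 0 else np.nan
        if np.isfinite(uflow):
            crcl = creatinine_clearance(
                last["urine_creatinine_mg_dL"], uflow, last["perfusate_creatinine_mg_dL"]
            )
    return NMPMetrics(
        kidney_mass_g=mass,
        cumulative_urine_mL=float(cum_urine.iloc[-1]),
        urine_series_mL=cum_urine,
        creatinine_clearance_mL_min=float(crcl),
        vascular_resistance=float(res),
        ocr_umol_min_g=float(ocr),
        glucose_consumption_umol_min_g=float(glu),
        lactate_production_umol_min_g=float(lac),
    )


# ---------------------------------------------------------------------------
# Group comparison decision tree

@dataclass
class GroupComparison:
    path: str  # "anova-tukey" | "welch-games-howell" | "kruskal-wilcoxon"
    normality_p: dict[str, float]
    levene_p: float | None
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, p_adj

    def pairwise_p(self, g1: str, g2: str) -> float:
        pw = self.pairwise
        row = pw[((pw.group1 == g1) & (pw.group2 == g2))
                 | ((pw.group1 == g2) & (pw.group2 == g1))]
        if row.empty:
            raise KeyError((g1, g2))
        return float(row.iloc[0]["p_adj"])

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "normality_p": self.normality_p,
            "levene_p": self.levene_p,
            "omnibus": {"test": self.omnibus_test, "stat": self.omnibus_stat,
                        "p": self.omnibus_p},
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # degenerate/constant sample: treat as decidedly non-normal
    if x.size < 3:
        return 1.0  # too small to assess; do not block the parametric path
    return float(stats.shapiro(x).pvalue)


def group_compare(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Compare >= 2 groups with the normality/variance-gated decision tree.

    Returns the chosen path, omnibus test and Holm/Tukey/Games-Howell
    adjusted pairwise p-values.
    """
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(data) < 2:
        raise NMPError("need at least 2 groups")
    for k, v in data.items():
        if v.size < 2:
            raise NMPError(f"group {k!r} has fewer than 2 observations")
    names = list(data)
    arrays = [data[k] for k in names]
    normality = {k: _shapiro_p(v) for k, v in data.items()}
    all_normal = all(p > alpha for p in normality.values())

    if all_normal:
        lev = float(stats.levene(*arrays).pvalue)
        if lev > alpha:
            f = stats.f_oneway(*arrays)
            tk = stats.tukey_hsd(*arrays)
            rows = [
                {"group1": names[i], "group2": names[j],
                 "p_adj": float(tk.pvalue[i, j])}
                for i in range(len(names)) for j in range(i + 1, len(names))
            ]
            return GroupComparison(
                path="anova-tukey", normality_p=normality, levene_p=lev,
                omnibus_test="anova", omnibus_stat=float(f.statistic),
                omnibus_p=float(f.pvalue), pairwise=pd.DataFrame(rows),
            )
        import pingouin as pg

        long = pd.DataFrame(
            {"value": np.concatenate(arrays),
             "group": np.repeat(names, [a.size for a in arrays])}
        )
        w = pg.welch_anova(data=long, dv="value", between="group")
        gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        rows = [
            {"group1": r["A"], "group2": r["B"], "p_adj": float(r["pval"])}
            for _, r in gh.iterrows()
        ]
        return GroupComparison(
            path="welch-games-howell", normality_p=normality, levene_p=lev,
            omnibus_test="welch-anova", omnibus_stat=float(w["F"].iloc[0]),
            omnibus_p=float(w["p_unc"].iloc[0]), pairwise=pd.DataFrame(rows),
        )

    from statsmodels.stats.multitest import multipletests

    kw = stats.kruskal(*arrays)
    raw, pairs = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(stats.mannwhitneyu(arrays[i], arrays[j],
                                         alternative="two-sided").pvalue)
            raw.append(p)
            pairs.append((names[i], names[j]))
    adj = multipletests(raw, method="holm")[1]
    rows = [
        {"group1": a, "group2": b, "p_adj": float(p)}
        for (a, b), p in zip(pairs, adj)
    ]
    return GroupComparison(
        path="kruskal-wilcoxon", normality_p=normality, levene_p=None,
        omnibus_test="kruskal-wallis", omnibus_stat=float(kw.statistic),
        omnibus_p=float(kw.pvalue), pairwise=pd.DataFrame(rows),
    )
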