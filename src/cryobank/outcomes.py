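"""Post-transplant outcome analysis over 30-day daily-lab trajectories.

Each recipient contributes a LabSeries: daily serum creatinine, venous
chemistries, hemoglobin and body weight from the pre-transplant baseline
(day -1) through day 30, with group label (control vs nanowarmed) and
cryostorage duration. Summaries follow the clinically meaningful landmarks of
the creatinine curve: its peak (height and day), the first day it drops
strictly below a normalization threshold (default 2.0 mg/dL), and its
terminal value. Cross-group tests are Wilcoxon rank-sum by default with a
per-variable override map (t-test for potassium and hemoglobin), and the
relation between storage duration and outcome is screened with Kendall's
tau-b (exact p for small n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LAB_VARIABLES",
    "DEFAULT_TEST_MAP",
    "OutcomesError",
    "LabSeries",
    "CreatinineSummary",
    "OutcomeSummary",
    "LongitudinalTest",
    "KendallResult",
    "creatinine_summary",
    "normalize_weight",
    "longitudinal_compare",
    "storage_correlation",
    "summarize",
    "egfr_uvp",
    "lab_series_to_long",
    "long_to_lab_series",
]

LAB_VARIABLES = [
    "creatinine", "potassium", "ph", "hco3", "pco2", "lactate", "hemoglobin",
    "weight",
]

# Per-variable two-group test assignment; anything not listed uses Wilcoxon
# rank-sum. Potassium and hemoglobin are compared by t-test.
DEFAULT_TEST_MAP = {"potassium": "ttest", "hemoglobin": "ttest"}


class OutcomesError(ValueError):
    """Raised on malformed lab series."""


@dataclass
class LabSeries:
    """Daily labs for one transplant recipient, indexed by postoperative day."""

    animal_id: str
    group: str  # "control" | "nanowarmed"
    data: pd.DataFrame  # index: day (-1 ... 30); columns from LAB_VARIABLES
    storage_days: float = 0.0

    def __post_init__(self):
        if self.data.empty:
            raise OutcomesError("empty lab series")
        days = self.data.index.to_numpy()
        if np.any(np.diff(days) <= 0):
            raise OutcomesError("days must be strictly increasing")
        if -1 not in self.data.index:
            raise OutcomesError("baseline day -1 is required")

    def value(self, day: int, variable: str) -> float:
        if variable not in self.data.columns or day not in self.data.index:
            return float("nan")
        return float(self.data.loc[day, variable])


@dataclass(frozen=True)
class CreatinineSummary:
    peak_value: float  # mg/dL
    peak_day: int
    first_day_below: int | None  # None = never normalized (sentinel)
    terminal_value: float
    threshold: float = 2.0


@dataclass
class OutcomeSummary:
    creatinine: CreatinineSummary
    weight_ratio: pd.Series  # normalized to day -1
    egfr_mL_min: float | None = None


def creatinine_summary(s: LabSeries, threshold: float = 2.0) -> CreatinineSummary:
    """Peak creatinine (value and day), time to normalization, terminal value.

    "First day below" is the first day, from the peak day onward, with
    creatinine strictly below ``threshold`` (None if never): the
    time-to-normalization landmark. Scanning starts at the peak so that the
    normal pre-transplant baseline does not trivially satisfy the criterion;
    for a series whose maximum is its first value (e.g. a flat normal
    trajectory) this reduces to the first recorded day. Missing values are
    skipped."""
    cr = s.data["creatinine"].dropna()
    if cr.empty:
        raise OutcomesError("no creatinine values recorded")
    peak_day = int(cr.idxmax())
    post = cr.loc[peak_day:]
    below = post.index[post < threshold]
    return CreatinineSummary(
        peak_value=float(cr.max()),
        peak_day=peak_day,
        first_day_below=int(below[0]) if len(below) else None,
        terminal_value=float(cr.iloc[-1]),
        threshold=threshold,
    )


def normalize_weight(s: LabSeries) -> pd.Series:
    """Daily body weight divided by the day -1 baseline weight."""
    if "weight" not in s.data.columns:
        raise OutcomesError("no weight recorded")
    w = s.data["weight"]
    baseline = w.loc[-1]
    if not np.isfinite(baseline) or baseline <= 0:
        raise OutcomesError("missing or non-positive baseline (day -1) weight")
    return w / baseline


def egfr_uvp(urine_cr_mg_dL: float, urine_flow_mL_min: float,
             serum_cr_mg_dL: float) -> float:
    """Conventional UV/P estimate of GFR, mL/min."""
    if serum_cr_mg_dL <= 0:
        raise OutcomesError("serum creatinine must be > 0")
    return urine_cr_mg_dL * urine_flow_mL_min / serum_cr_mg_dL


def summarize(
    s: LabSeries,
    threshold: float = 2.0,
    egfr: Callable[[LabSeries], float] | None = None,
) -> OutcomeSummary:
    """Full outcome summary; ``egfr`` is a pluggable callable on the series."""
    return OutcomeSummary(
        creatinine=creatinine_summary(s, threshold=threshold),
        weight_ratio=normalize_weight(s),
        egfr_mL_min=float(egfr(s)) if egfr is not None else None,
    )


@dataclass(frozen=True)
class LongitudinalTest:
    test: str  # "wilcoxon" | "ttest"
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    day: int
    variable: str


def _group_values(group: Iterable[LabSeries], day: int, variable: str) -> np.ndarray:
    vals = [s.value(day, variable) for s in group]
    arr = np.array([v for v in vals if np.isfinite(v)])
    return arr


def longitudinal_compare(
    a: Iterable[LabSeries],
    b: Iterable[LabSeries],
    day: int,
    variable: str,
    test: str | None = None,
    test_map: dict[str, str] | None = None,
) -> LongitudinalTest:
    """Two-group comparison of one variable on one day (available cases only).

    The test is chosen from ``test_map`` (default: Wilcoxon rank-sum, t-test
    for the variables in DEFAULT_TEST_MAP) unless given explicitly.
    """
    tm = DEFAULT_TEST_MAP if test_map is None else test_map
    chosen = test or tm.get(variable, "wilcoxon")
    xa = _group_values(a, day, variable)
    xb = _group_values(b, day, variable)
    if xa.size == 0 or xb.size == 0:
        raise OutcomesError(f"no observations for {variable!r} on day {day}")
    if chosen == "ttest":
        r = stats.ttest_ind(xa, xb)
    elif chosen == "wilcoxon":
        r = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    else:
        raise OutcomesError(f"unknown test {chosen!r}")
    return LongitudinalTest(
        test=chosen, statistic=float(r.statistic), pvalue=float(r.pvalue),
        n_a=int(xa.size), n_b=int(xb.size), day=day, variable=variable,
    )


@dataclass(frozen=True)
class KendallResult:
    tau: float
    pvalue: float
    n: int
    degenerate: bool = False  # constant input; tau undefined


def storage_correlation(
    storage_days: Sequence[float], outcome: Sequence[float]
) -> KendallResult:
    """Kendall tau-b between cryostorage duration and an outcome measure.

    Uses the exact null distribution for n <= 10 (no ties); a constant input
    vector is flagged as degenerate rather than raising.
    """
    x = np.asarray(storage_days, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size != y.size or x.size < 3:
        raise OutcomesError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return KendallResult(tau=float("nan"), pvalue=float("nan"), n=int(x.size),
                             degenerate=True)
    method = "exact" if x.size <= 10 else "auto"
    try:
        r = stats.kendalltau(x, y, variant="b", method=method)
    except ValueError:  # exact method unavailable with ties
        r = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return KendallResult(tau=float(r.statistic), pvalue=float(r.pvalue), n=int(x.size))


# ---------------------------------------------------------------------------
# Long-format CSV IO: animal_id, group, storage_days, day, variable, value

def lab_series_to_long(series: Iterable[LabSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for day, rec in s.data.iterrows():
            for var, val in rec.items():
                if pd.isna(val):
                    continue
                rows.append(
                    {"animal_id": s.animal_id, "group": s.group,
                     "storage_days": s.storage_days, "day": int(day),
                     "variable": var, "value": float(val)}
                )
    return pd.DataFrame(rows)


def long_to_lab_series(df: pd.DataFrame) -> list[LabSeries]:
    out = []
    for (aid, grp), sub in df.groupby(["animal_id", "group"], sort=True):
        wide = sub.pivot_table(index="day", columns="variable", values="value")
        wide = wide.sort_index()
        storage = float(sub["storage_days"].iloc[0]) if "storage_days" in sub else 0.0
        out.append(LabSeries(animal_id=str(aid), group=str(grp), data=wide,
                             storage_days=storage))
    return out
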