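"""Thermal-history and DSC analysis for vitrification and rewarming.

Cooling/warming logs are checked against the zone of ice-formation risk
between the melting point (Tm = -40.8 degC) and the glass transition
(Tg = -128.3 degC) of the CPA: a protocol succeeds when the mean rate through
that window exceeds the critical cooling rate (CCR) on the way down and the
critical warming rate (CWR) on the way up. Ice fractions are computed from
DSC thermograms by baseline-corrected integration of the crystallization
event, and CCR/CWR are interpolated from (rate, ice-fraction) curves on a
log10 ice-fraction scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TM_VMP",
    "TG_VMP",
    "TemperatureLog",
    "ThermalLandmarks",
    "Thermogram",
    "CriticalRates",
    "RateFit",
    "CriticalCheck",
    "CriticalRateEstimate",
    "FreezerStep",
    "FreezerProgram",
    "ThermalError",
    "fit_rate",
    "check_against_critical",
    "ice_fraction",
    "critical_rate",
    "freezer_setpoints",
    "vitrification_freezer_program",
]

TM_VMP = -40.8  # degC, melting temperature of VMP in kidney tissue
TG_VMP = -128.3  # degC, glass transition temperature


class ThermalError(ValueError):
    """Raised on malformed thermal inputs."""


@dataclass(frozen=True)
class ThermalLandmarks:
    Tg: float = TG_VMP
    Tm: float = TM_VMP

    def __post_init__(self):
        if not self.Tg < self.Tm:
            raise ThermalError("require Tg < Tm")


@dataclass
class TemperatureLog:
    """Probe thermal history sampled at ~1 s cadence."""

    time_s: np.ndarray
    temp_C: np.ndarray
    probe: str = ""

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        if self.time_s.shape != self.temp_C.shape or self.time_s.ndim != 1:
            raise ThermalError("time and temperature must be 1-D arrays of equal length")
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ThermalError("time must be strictly increasing")
        if np.any(self.temp_C < -200) or np.any(self.temp_C > 50):
            raise ThermalError("temperatures outside plausible range [-200, 50] degC")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "temp_C": self.temp_C})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, probe: str = "") -> "TemperatureLog":
        return cls(df["time_s"].to_numpy(), df["temp_C"].to_numpy(), probe=probe)


@dataclass
class Thermogram:
    """DSC scan: heat flow vs temperature at a fixed scan rate."""

    temp_C: np.ndarray
    heatflow_W_per_g: np.ndarray
    scan_rate: float  # degC/min, magnitude
    direction: str = "cooling"  # or "warming"
    reference_latent_heat: float = 335.0  # J/g

    def __post_init__(self):
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        self.heatflow_W_per_g = np.asarray(self.heatflow_W_per_g, dtype=float)
        if self.temp_C.shape != self.heatflow_W_per_g.shape:
            raise ThermalError("temperature and heat-flow arrays must match")
        if self.direction not in ("cooling", "warming"):
            raise ThermalError("direction must be 'cooling' or 'warming'")
        d = np.diff(self.temp_C)
        if self.direction == "cooling" and np.any(d >= 0):
            raise ThermalError("cooling scan temperature must be strictly decreasing")
        if self.direction == "warming" and np.any(d <= 0):
            raise ThermalError("warming scan temperature must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temp_C": self.temp_C, "heatflow_W_per_g": self.heatflow_W_per_g}
        )


@dataclass(frozen=True)
class CriticalRates:
    CCR: float  # degC/min
    CWR: float  # degC/min
    ice_fraction_threshold: float = 0.5  # %

    def __post_init__(self):
        if self.CCR <= 0 or self.CWR <= 0:
            raise ThermalError("critical rates must be > 0")


# ---------------------------------------------------------------------------
# Rate fitting and protocol checks

@dataclass
class RateFit:
    mean_rate: float  # degC/min, signed (negative = cooling)
    inst_rate: np.ndarray  # degC/min, on the log's time base
    t_enter: float  # s, first crossing of the window bound entered first
    t_exit: float  # s, first crossing of the other bound


def _first_crossing(t: np.ndarray, x: np.ndarray, level: float) -> float:
    """First time x crosses `level`, linearly interpolated; NaN if never."""
    s = x - level
    if s[0] == 0:
        return float(t[0])
    sign_change = np.nonzero(s[:-1] * s[1:] <= 0)[0]
    if sign_change.size == 0:
        return float("nan")
    i = sign_change[0]
    if s[i + 1] == s[i]:
        return float(t[i])
    return float(t[i] + (t[i + 1] - t[i]) * (-s[i]) / (s[i + 1] - s[i]))


def fit_rate(
    log: TemperatureLog,
    T_high: float = TM_VMP,
    T_low: float = TG_VMP,
    smooth_window: int = 5,
) -> RateFit:
    """Mean and instantaneous temperature rates through the [T_low, T_high] window.

    The mean rate is (T_high - T_low) divided by the elapsed time between the
    first crossings of the two bounds, signed by direction (negative for
    cooling). Instantaneous rates are central differences on a moving-average
    smoothed series.
    """
    if not T_low < T_high:
        raise ThermalError("require T_low < T_high")
    t, x = log.time_s, log.temp_C
    if t.size < 2:
        raise ThermalError("log too short")
    t_hi = _first_crossing(t, x, T_high)
    t_lo = _first_crossing(t, x, T_low)
    if np.isnan(t_hi) or np.isnan(t_lo):
        missing = T_high if np.isnan(t_hi) else T_low
        raise ThermalError(f"log never crosses {missing} degC")
    if t_lo == t_hi:
        raise ThermalError("window crossings coincide; cannot fit a rate")
    mean_rate = (T_low - T_high) / (t_lo - t_hi) * 60.0  # negative when cooling
    w = max(int(smooth_window), 1)
    if w > 1 and x.size >= w:
        kernel = np.ones(w) / w
        sm = np.convolve(x, kernel, mode="same")
        # edges of 'same' convolution are biased; fall back to raw values there
        half = w // 2
        sm[:half] = x[:half]
        sm[-half:] = x[-half:]
    else:
        sm = x
    inst = np.gradient(sm, t) * 60.0
    if mean_rate < 0:
        t_enter, t_exit = t_hi, t_lo
    else:
        t_enter, t_exit = t_lo, t_hi
    return RateFit(mean_rate=float(mean_rate), inst_rate=inst, t_enter=t_enter, t_exit=t_exit)


@dataclass(frozen=True)
class CriticalCheck:
    passed: bool
    margin: float  # |rate| / critical
    rate: float
    critical: float


def check_against_critical(rate: float, critical: float) -> CriticalCheck:
    """Strict pass test: |rate| must exceed the critical rate."""
    if critical <= 0:
        raise ThermalError("critical rate must be > 0")
    margin = abs(rate) / critical
    return CriticalCheck(passed=margin > 1.0, margin=margin, rate=rate, critical=critical)


# ---------------------------------------------------------------------------
# DSC ice fractions and critical-rate interpolation

def ice_fraction(t: Thermogram, baseline_fraction: float = 0.1) -> float:
    """Ice fraction (%) from a DSC thermogram.

    A linear baseline is fit to the leading/trailing ``baseline_fraction`` of
    the scan (assumed event-free), subtracted, and the crystallization event
    integrated over temperature by the trapezoid rule. Division by the scan
    rate converts the area to J/g, reported as a percentage of the reference
    latent heat and clipped to [0, 100].
    """
    if t.reference_latent_heat <= 0:
        raise ThermalError("reference latent heat must be > 0")
    if t.scan_rate <= 0:
        raise ThermalError("scan rate must be > 0")
    T = t.temp_C
    q = t.heatflow_W_per_g
    order = np.argsort(T)
    T, q = T[order], q[order]
    n = T.size
    k = max(int(np.ceil(baseline_fraction * n)), 2)
    idx = np.concatenate([np.arange(k), np.arange(n - k, n)])
    coeff = np.polyfit(T[idx], q[idx], 1)
    corrected = q - np.polyval(coeff, T)
    area_WC = abs(np.trapezoid(corrected, T))  # (W/g) * degC
    energy = area_WC / (t.scan_rate / 60.0)  # J/g
    frac = 100.0 * energy / t.reference_latent_heat
    return float(np.clip(frac, 0.0, 100.0))


@dataclass(frozen=True)
class CriticalRateEstimate:
    rate: float  # degC/min
    threshold: float  # % ice fraction defining "critical"
    extrapolated: bool


def critical_rate(
    points: Sequence[tuple[float, float]],
    threshold: float = 0.5,
) -> CriticalRateEstimate:
    """Critical rate from measured (scan rate, ice fraction %) pairs.

    Ice fraction must be monotone non-increasing in rate. log10(ice fraction)
    is interpolated linearly against rate and the crossing of ``threshold``
    returned; a crossing outside the measured range is linearly extrapolated
    and flagged.
    """
    if len(points) < 2:
        raise ThermalError("need at least 2 (rate, ice fraction) points")
    if threshold <= 0:
        raise ThermalError("threshold must be > 0 %")
    pts = sorted((float(r), float(f)) for r, f in points)
    rates = np.array([p[0] for p in pts])
    fracs = np.array([p[1] for p in pts])
    if np.any(np.diff(fracs) > 0):
        raise ThermalError("ice fraction must be monotone non-increasing in rate")
    if np.any(fracs <= 0):
        raise ThermalError("ice fractions must be > 0 for log interpolation")
    exact = np.isclose(fracs, threshold)
    if np.any(exact):
        return CriticalRateEstimate(
            rate=float(rates[np.argmax(exact)]), threshold=threshold, extrapolated=False
        )
    y = np.log10(fracs)
    target = np.log10(threshold)
    extrapolated = not (y.min() <= target <= y.max())
    # y decreases with rate; fit between the bracketing pair (or end pair).
    if target > y[0]:
        i = 0
    elif target < y[-1]:
        i = len(y) - 2
    else:
        i = int(np.nonzero((y[:-1] >= target) & (y[1:] <= target))[0][0])
    slope = (rates[i + 1] - rates[i]) / (y[i + 1] - y[i])
    rate = rates[i] + (target - y[i]) * slope
    return CriticalRateEstimate(rate=float(rate), threshold=threshold,
                                extrapolated=bool(extrapolated))


# ---------------------------------------------------------------------------
# Controlled-rate freezer program

@dataclass(frozen=True)
class FreezerStep:
    kind: str  # "ramp" | "hold"
    start: float  # degC
    end: float  # degC (== start for hold)
    rate: float | None = None  # degC/min, ramp
    duration: float | None = None  # min, hold (derived for ramp)

    def resolved(self) -> "FreezerStep":
        if self.kind == "ramp":
            if self.rate is None or self.rate == 0:
                raise ThermalError("ramp step requires a nonzero rate")
            if (self.end - self.start) * self.rate < 0:
                raise ThermalError("ramp rate sign inconsistent with direction")
            d = abs(self.end - self.start) / abs(self.rate)
            return FreezerStep(self.kind, self.start, self.end, self.rate, d)
        if self.kind == "hold":
            if self.start != self.end:
                raise ThermalError("hold step requires start == end")
            if self.duration is None or self.duration < 0:
                raise ThermalError("hold step requires duration >= 0")
            return self
        raise ThermalError(f"unknown freezer step kind {self.kind!r}")


@dataclass
class FreezerProgram:
    steps: tuple[FreezerStep, ...]

    def __post_init__(self):
        resolved = []
        prev_end = None
        for s in self.steps:
            r = s.resolved()
            if prev_end is not None and not np.isclose(r.start, prev_end):
                raise ThermalError("freezer setpoint trajectory must be continuous")
            prev_end = r.end
            resolved.append(r)
        self.steps = tuple(resolved)

    @property
    def boundaries(self) -> np.ndarray:
        durs = [s.duration for s in self.steps]
        return np.concatenate([[0.0], np.cumsum(durs)]) if durs else np.array([0.0])

    def total_duration(self) -> float:
        return float(self.boundaries[-1])

    def setpoint_at(self, t: float) -> float:
        total = self.total_duration()
        if t < 0 or t > total:
            raise ThermalError(f"t = {t} min outside program span [0, {total}]")
        b = self.boundaries
        i = int(np.searchsorted(b, t, side="right") - 1)
        i = min(i, len(self.steps) - 1)
        s = self.steps[i]
        if s.kind == "hold" or s.duration == 0:
            return s.start
        frac = (t - b[i]) / s.duration
        return s.start + frac * (s.end - s.start)


def freezer_setpoints(program: FreezerProgram, t) -> float | np.ndarray:
    """Piecewise-linear chamber setpoint (degC) at time(s) ``t`` in minutes."""
    if np.ndim(t) == 0:
        return program.setpoint_at(float(t))
    return np.array([program.setpoint_at(float(ti)) for ti in np.asarray(t)])


def vitrification_freezer_program() -> FreezerProgram:
    """Controlled-rate freezer program used for kidney vitrification:
    0 -> -122 degC at -40 degC/min, 25-min anneal just above Tg, -122 -> -150
    at -5 degC/min, then a 10-min hold at the storage temperature."""
    return FreezerProgram(
        steps=(
            FreezerStep("ramp", 0.0, -122.0, rate=-40.0),
            FreezerStep("hold", -122.0, -122.0, duration=25.0),
            FreezerStep("ramp", -122.0, -150.0, rate=-5.0),
            FreezerStep("hold", -150.0, -150.0, duration=10.0),
        )
    )
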