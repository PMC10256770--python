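"""Krogh-cylinder perfusion transport with Kedem-Katchalsky membrane fluxes.

The kidney is idealized as many identical parallel Krogh units: a central
capillary of radius ``capillary_radius`` surrounded by a tissue annulus out to
``tissue_radius``. Within each unit the capillary is discretized into
``n_axial`` flow-through compartments; each exchanges water and CPA with a
single well-mixed extravascular compartment across a composite membrane
described by the Kedem-Katchalsky (KK) equations with hydraulic conductivity
``Lp``, solute permeability ``omega`` and reflection coefficient ``sigma``.

Concentrations are handled in mM, which is numerically identical to mol/m^3,
so van't Hoff osmotic pressures are simply ``R*T*c``. Positive fluxes are
directed from the vasculature into the extravascular space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .protocol import Protocol

__all__ = [
    "R_GAS",
    "MMHG_TO_PA",
    "MembraneParams",
    "KroghGeometry",
    "TransportHistory",
    "TransportError",
    "kk_fluxes",
    "simulate_perfusion",
    "equilibration_time",
    "compare_protocols",
]

R_GAS = 8.314462618  # J/(mol K)
MMHG_TO_PA = 133.322387415


class TransportError(RuntimeError):
    """Raised on invalid membrane/geometry inputs or solver divergence."""


@dataclass(frozen=True)
class MembraneParams:
    """KK membrane coefficients (per unit membrane area).

    ``area_scale`` multiplies the geometric exchange area; it absorbs the
    unknown normalization of the published coefficients (whether they are
    already per capillary-wall area) without touching Lp/omega themselves.
    """

    Lp: float = 1.5e-14  # hydraulic conductivity, m^3/(N s) per m^2
    omega: float = 7.0e-13  # solute permeability, mol/(N s) per m^2
    sigma: float = 0.1  # reflection coefficient
    area_scale: float = 1.0
    mean_concentration: str = "arithmetic"  # or "log"

    def __post_init__(self):
        if self.Lp <= 0:
            raise TransportError("Lp must be > 0")
        if self.omega < 0:
            raise TransportError("omega must be >= 0")
        if not 0.0 <= self.sigma <= 1.0:
            raise TransportError("sigma must lie in [0, 1]")
        if self.area_scale <= 0:
            raise TransportError("area_scale must be > 0")


@dataclass(frozen=True)
class KroghGeometry:
    """Geometry of one Krogh unit and the count of parallel units per organ."""

    capillary_radius: float = 3.5e-6  # m
    tissue_radius: float = 20e-6  # m
    unit_length: float = 1e-3  # m
    n_axial: int = 10
    n_units: int = 800_000

    def __post_init__(self):
        if not self.tissue_radius > self.capillary_radius > 0:
            raise TransportError("require tissue_radius > capillary_radius > 0")
        if self.n_axial < 1 or self.n_units < 1:
            raise TransportError("n_axial and n_units must be >= 1")

    @property
    def exchange_area_per_length(self) -> float:
        """Membrane area per unit capillary length, 2*pi*r_c (m^2/m)."""
        return 2.0 * np.pi * self.capillary_radius

    @property
    def segment_length(self) -> float:
        return self.unit_length / self.n_axial

    @property
    def segment_area(self) -> float:
        return self.exchange_area_per_length * self.segment_length

    @property
    def vascular_volume_per_segment(self) -> float:
        return np.pi * self.capillary_radius**2 * self.segment_length

    @property
    def extravascular_volume_per_segment(self) -> float:
        return np.pi * (self.tissue_radius**2 - self.capillary_radius**2) * self.segment_length


def kk_fluxes(
    delta_p: float,
    c_vasc,
    c_extra,
    c_imp_vasc,
    c_imp_extra,
    m: MembraneParams,
    T: float,
):
    """Kedem-Katchalsky volume and solute fluxes across the exchange membrane.

    Parameters
    ----------
    delta_p : hydrostatic pressure difference vascular - extravascular, Pa.
    c_vasc, c_extra : permeating CPA concentrations, mM (= mol/m^3).
    c_imp_vasc, c_imp_extra : impermeant osmolyte concentrations, mM.
    m : membrane coefficients.
    T : absolute temperature, K.

    Returns
    -------
    (Jv, Js) : volume flux m/s and solute flux mol/(m^2 s), positive from
    vasculature to tissue.

        Jv = Lp (dp - sigma R T (c_v - c_e) - R T (ci_v - ci_e))
        Js = omega R T (c_v - c_e) + (1 - sigma) cbar Jv
    """
    if T <= 0:
        raise TransportError("temperature must be > 0 K")
    c_vasc = np.asarray(c_vasc, dtype=float)
    c_extra = np.asarray(c_extra, dtype=float)
    if np.any(c_vasc < 0) or np.any(c_extra < 0) or np.any(
        np.asarray(c_imp_vasc) < 0
    ) or np.any(np.asarray(c_imp_extra) < 0):
        raise TransportError("concentrations must be non-negative")
    rt = R_GAS * T
    dc = c_vasc - c_extra
    d_imp = np.asarray(c_imp_vasc, dtype=float) - np.asarray(c_imp_extra, dtype=float)
    Jv = m.Lp * (delta_p - m.sigma * rt * dc - rt * d_imp)
    if m.mean_concentration == "log":
        with np.errstate(divide="ignore", invalid="ignore"):
            cbar = np.where(
                np.isclose(c_vasc, c_extra) | (c_vasc <= 0) | (c_extra <= 0),
                0.5 * (c_vasc + c_extra),
                dc / np.log(np.maximum(c_vasc, 1e-300) / np.maximum(c_extra, 1e-300)),
            )
    else:
        cbar = 0.5 * (c_vasc + c_extra)
    Js = m.omega * rt * dc + (1.0 - m.sigma) * cbar * Jv
    if np.ndim(Jv) == 0:
        return float(Jv), float(Js)
    return Jv, Js


@dataclass
class TransportHistory:
    """Sampled trajectory of a perfusion simulation (one representative unit)."""

    time_min: np.ndarray
    c_vasc: np.ndarray  # (t, n_axial), mM
    c_extra: np.ndarray  # (t, n_axial), mM
    v_extra_rel: np.ndarray  # (t, n_axial), V/V0
    c_inlet: np.ndarray  # mM
    c_outlet: np.ndarray  # mM
    moles_in: np.ndarray  # cumulative inlet CPA, scaled mol/m^3 * V0-equivalents
    moles_out: np.ndarray
    geometry: KroghGeometry
    membrane: MembraneParams

    def mean_tissue_concentration(self, idx: int = -1) -> float:
        """Volume-weighted mean extravascular CPA concentration (mM)."""
        m = self.c_extra[idx] * self.v_extra_rel[idx]
        return float(m.sum() / self.v_extra_rel[idx].sum())

    @property
    def final_mean_tissue_concentration(self) -> float:
        return self.mean_tissue_concentration(-1)

    def mean_tissue_series(self) -> np.ndarray:
        return (self.c_extra * self.v_extra_rel).sum(axis=1) / self.v_extra_rel.sum(axis=1)

    def mass_balance_residual(self) -> float:
        """Relative CPA mass-balance residual |in - out - accumulated| / in."""
        g = self.geometry
        ratio = g.vascular_volume_per_segment / g.extravascular_volume_per_segment
        acc_extra = (self.c_extra[-1] * self.v_extra_rel[-1]).sum() - (
            self.c_extra[0] * self.v_extra_rel[0]
        ).sum()
        acc_vasc = (self.c_vasc[-1].sum() - self.c_vasc[0].sum()) * ratio
        net_in = self.moles_in[-1] - self.moles_out[-1]
        denom = max(abs(self.moles_in[-1]), 1e-12)
        return float(abs(net_in - acc_extra - acc_vasc) / denom)

    def to_frame(self) -> pd.DataFrame:
        """Long-format history: time_min, segment, c_vasc_mM, c_extra_mM, V_extra_rel."""
        n = self.c_vasc.shape[1]
        rows = []
        for j in range(n):
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.time_min,
                        "segment": j,
                        "c_vasc_mM": self.c_vasc[:, j],
                        "c_extra_mM": self.c_extra[:, j],
                        "V_extra_rel": self.v_extra_rel[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _flow_callable(flow, protocol: Protocol) -> Callable[[float], float]:
    if callable(flow):
        return flow
    const = float(flow)

    def f(t: float) -> float:
        try:
            i, _ = protocol.segment_at(t)
            fs = protocol.segments[i].flow_setpoint
        except Exception:
            fs = None
        return fs if fs is not None else const

    return f


def simulate_perfusion(
    p: Protocol,
    g: KroghGeometry | None = None,
    m: MembraneParams | None = None,
    flow: float | Callable[[float], float] = 1.0,
    dt: float = 0.5,
    c_imp_vasc: float = 300.0,
    c_imp_extra0: float = 300.0,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> TransportHistory:
    """Simulate CPA/water exchange for a protocol on one representative unit.

    Parameters
    ----------
    p : perfusion protocol driving inlet concentration, pressure and temperature.
    g, m : geometry and membrane coefficients (documented defaults if omitted).
    flow : total organ arterial flow in mL/min (constant or callable of time);
        segments with an explicit flow setpoint (IONP co-perfusion) override it.
    dt : output sampling interval, min.
    c_imp_vasc : impermeant osmolality of the carrier on the vascular side, mM.
    c_imp_extra0 : initial impermeant osmolality of the extravascular space, mM
        (impermeant moles are conserved thereafter).

    The integrator is adaptive implicit (BDF) and deterministic. Solute mass
    balance is tracked via cumulative inlet/outlet integrals carried as
    additional states.
    """
    if dt <= 0:
        raise TransportError("dt must be > 0")
    g = g or KroghGeometry()
    m = m or MembraneParams()
    n = g.n_axial
    A = g.segment_area * m.area_scale
    V_vasc = g.vascular_volume_per_segment
    V0 = g.extravascular_volume_per_segment
    flow_of_t = _flow_callable(flow, p)

    total = p.total_duration()
    if total == 0 or not p.segments:
        z = np.zeros((1, n))
        return TransportHistory(
            time_min=np.array([0.0]),
            c_vasc=z.copy(),
            c_extra=z.copy(),
            v_extra_rel=np.ones((1, n)),
            c_inlet=np.array([0.0]),
            c_outlet=np.array([0.0]),
            moles_in=np.array([0.0]),
            moles_out=np.array([0.0]),
            geometry=g,
            membrane=m,
        )

    n_imp = c_imp_extra0  # impermeant "moles" per V0 (scaled concentration units)

    def rhs(t_s: float, y: np.ndarray, t_offset_min: float, seg_idx: int):
        t_min = t_offset_min + t_s / 60.0
        seg = p.segments[seg_idx]
        cv = np.maximum(y[:n], 0.0)
        me = np.maximum(y[n : 2 * n], 0.0)
        v = np.maximum(y[2 * n : 3 * n], 1e-6)
        ce = me / v
        c_in = p.concentration_at(min(t_min, total))
        T_K = seg.temperature + 273.15
        dp = seg.pressure_setpoint * MMHG_TO_PA
        Jv, Js = kk_fluxes(dp, cv, ce, c_imp_vasc, n_imp / v, m, T_K)
        q_ml_min = max(flow_of_t(min(t_min, total)), 0.0)
        Q0 = q_ml_min * 1e-6 / 60.0 / g.n_units  # m^3/s per unit
        Q = Q0 - np.cumsum(Jv * A)
        Q = np.maximum(Q, 0.0)
        Q_up = np.concatenate([[Q0], Q[:-1]])
        c_up = np.concatenate([[c_in], cv[:-1]])
        dcv = (Q_up * c_up - Q * cv - Js * A) / V_vasc
        dme = Js * A / V0
        dv = Jv * A / V0
        dMin = Q0 * c_in / V0
        dMout = Q[-1] * cv[-1] / V0
        return np.concatenate([dcv, dme, dv, [dMin, dMout]])

    y = np.concatenate([np.zeros(n), np.zeros(n), np.ones(n), [0.0, 0.0]])
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    b = p.boundaries
    vasc_ratio = V_vasc / V0

    for si, seg in enumerate(p.segments):
        t0, t1 = b[si], b[si + 1]
        if t1 <= t0:
            continue
        span_s = (t1 - t0) * 60.0
        t_eval = np.arange(0.0, span_s + 1e-9, dt * 60.0)
        if t_eval[-1] < span_s - 1e-9:
            t_eval = np.append(t_eval, span_s)

        def vol_floor(t_s, yy, *_args):
            return np.min(yy[2 * n : 3 * n]) - 0.02

        vol_floor.terminal = True

        sol = solve_ivp(
            rhs,
            (0.0, span_s),
            y,
            method="BDF",
            t_eval=t_eval,
            args=(t0, si),
            rtol=rtol,
            atol=atol,
            events=vol_floor,
        )
        if sol.status == 1:
            t_ev = t0 + sol.t_events[0][0] / 60.0
            bad = int(np.argmin(sol.y_events[0][0][2 * n : 3 * n]))
            raise TransportError(
                f"extravascular volume collapsed at t = {t_ev:.2f} min, segment {bad}"
            )
        if not sol.success:
            raise TransportError(f"solver failed in protocol segment {si}: {sol.message}")
        times.append(t0 + sol.t / 60.0)
        states.append(sol.y)
        y = sol.y[:, -1]

    t_all = np.concatenate([tt if i == 0 else tt[1:] for i, tt in enumerate(times)])
    y_all = np.hstack([ss if i == 0 else ss[:, 1:] for i, ss in enumerate(states)])
    cv = y_all[:n].T
    me = y_all[n : 2 * n].T
    v = y_all[2 * n : 3 * n].T
    c_in_rec = np.array([p.concentration_at(min(t, total)) for t in t_all])
    return TransportHistory(
        time_min=t_all,
        c_vasc=cv,
        c_extra=me / v,
        v_extra_rel=v,
        c_inlet=c_in_rec,
        c_outlet=cv[:, -1].copy(),
        moles_in=y_all[3 * n],
        moles_out=y_all[3 * n + 1],
        geometry=g,
        membrane=m,
    )


def equilibration_time(h: TransportHistory, fraction: float) -> float:
    """First time (min) the volume-weighted mean tissue CPA concentration
    reaches ``fraction`` of the inlet plateau (the maximum inlet concentration
    seen); ``inf`` if never reached.
    """
    if not 0.0 < fraction <= 1.0:
        raise TransportError("fraction must lie in (0, 1]")
    if h.time_min.size == 0:
        raise TransportError("empty history")
    plateau = float(np.max(h.c_inlet))
    if plateau <= 0:
        return 0.0
    target = fraction * plateau
    mean = h.mean_tissue_series()
    hit = np.nonzero(mean >= target)[0]
    if hit.size == 0:
        return float("inf")
    i = hit[0]
    if i == 0:
        return float(h.time_min[0])
    # linear interpolation between the bracketing samples
    t0, t1 = h.time_min[i - 1], h.time_min[i]
    m0, m1 = mean[i - 1], mean[i]
    if m1 == m0:
        return float(t1)
    return float(t0 + (target - m0) / (m1 - m0) * (t1 - t0))


@dataclass
class ProtocolComparison:
    """Per-protocol final tissue CPA and exposure above concentration thresholds."""

    reports: dict[str, dict]

    def to_dict(self) -> dict:
        return self.reports


def _exposure(h: TransportHistory, thresholds: Sequence[float]) -> dict:
    mean = h.mean_tissue_series()
    t = h.time_min
    out = {}
    for thr in thresholds:
        above = mean > thr
        time_above = float(np.trapezoid(above.astype(float), t))
        integral = float(np.trapezoid(np.where(above, mean, 0.0), t))
        out[float(thr)] = {"time_above_min": time_above,
                           "exposure_mM_min": integral}
    return out


def compare_protocols(
    a: Protocol,
    b: Protocol,
    g: KroghGeometry | None = None,
    m: MembraneParams | None = None,
    thresholds: Sequence[float] = (),
    flow: float | Callable[[float], float] = 1.0,
    dt: float = 0.5,
    **sim_kwargs,
) -> ProtocolComparison:
    """Simulate two protocols under identical geometry/membrane and report the
    final mean tissue CPA concentration and exposure integrals of the mean
    tissue concentration above each threshold."""
    reports = {}
    for key, proto in (("a", a), ("b", b)):
        h = simulate_perfusion(proto, g, m, flow=flow, dt=dt, **sim_kwargs)
        reports[key] = {
            "name": proto.name,
            "final_tissue_mM": h.final_mean_tissue_concentration,
            "exposure": _exposure(h, thresholds),
            "mass_balance_residual": h.mass_balance_residual(),
        }
    return ProtocolComparison(reports=reports)
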