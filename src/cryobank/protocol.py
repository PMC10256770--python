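"""Cryoprotectant loading/unloading protocols as piecewise concentration-time functions.

A perfusion protocol is an ordered list of segments, each prescribing how the
arterial CPA concentration evolves (flush, ramp, hold, step, or IONP
co-perfusion) together with the perfusion pressure and temperature setpoints.
Concentrations are stored in millimolar throughout ("5 M" is 5000 mM); an
optional adjunct solute (e.g. mannitol during unloading) rides on the same
timeline as a parallel piecewise function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Adjunct",
    "ProtocolSegment",
    "Protocol",
    "ProtocolError",
    "FlowQC",
    "build_protocol",
    "ramp_duration",
    "total_duration",
    "concentration_at",
    "flow_qc",
    "load_protocol",
    "save_protocol",
    "vmp_loading_protocol",
    "vmp_unloading_protocol",
]

SEGMENT_KINDS = ("flush", "ramp", "hold", "step", "ionp")


class ProtocolError(ValueError):
    """Raised when a protocol or segment fails validation."""


def ramp_duration(c_start: float, c_end: float, rate: float) -> float:
    """Duration in minutes of a linear concentration ramp.

    Parameters are in mM and mM/min; the sign of ``rate`` must match the
    direction of the ramp (negative for unloading ramps).
    """
    if rate == 0:
        raise ProtocolError("ramp rate must be nonzero")
    if (c_end - c_start) * rate < 0:
        raise ProtocolError(
            f"ramp rate sign ({rate:+g} mM/min) inconsistent with direction "
            f"{c_start:g} -> {c_end:g} mM"
        )
    d = abs(c_end - c_start) / abs(rate)
    if not np.isfinite(d) or d <= 0:
        raise ProtocolError("ramp duration must be finite and positive")
    return d


@dataclass(frozen=True)
class Adjunct:
    """Co-solute carried alongside the CPA (non-permeating in transport)."""

    name: str
    c_start: float  # mM
    c_end: float  # mM
    rate: float | None = None  # mM/min, ramps only


@dataclass(frozen=True)
class ProtocolSegment:
    kind: str
    c_start: float
    c_end: float
    rate: float | None = None  # mM/min, signed; ramp only
    duration: float | None = None  # min; derived for ramps
    pressure_setpoint: float = 40.0  # mmHg
    temperature: float = 4.0  # degC
    adjunct: Adjunct | None = None
    flow_setpoint: float | None = None  # mL/min, ionp only

    def validated(self, index: int | None = None) -> "ProtocolSegment":
        """Return a copy with derived fields populated, or raise ProtocolError."""
        where = f"segment {index}" if index is not None else "segment"
        if self.kind not in SEGMENT_KINDS:
            raise ProtocolError(f"{where}: unknown kind {self.kind!r}")
        if self.pressure_setpoint <= 0:
            raise ProtocolError(f"{where}: pressure_setpoint must be > 0 mmHg")
        if not -10.0 <= self.temperature <= 40.0:
            raise ProtocolError(f"{where}: temperature outside [-10, 40] degC")
        if self.c_start < 0 or self.c_end < 0:
            raise ProtocolError(f"{where}: concentrations must be >= 0")
        seg = self
        if self.kind == "ramp":
            if self.rate is None:
                raise ProtocolError(f"{where}: ramp requires a rate")
            try:
                d = ramp_duration(self.c_start, self.c_end, self.rate)
            except ProtocolError as e:
                raise ProtocolError(f"{where}: {e}") from None
            if self.duration is not None and not np.isclose(self.duration, d):
                raise ProtocolError(
                    f"{where}: stated duration {self.duration} min inconsistent "
                    f"with rate-derived {d} min"
                )
            seg = replace(seg, duration=d)
        else:
            if self.c_start != self.c_end:
                raise ProtocolError(f"{where}: non-ramp segment requires c_start == c_end")
            if self.duration is None or self.duration < 0:
                raise ProtocolError(f"{where}: {self.kind} requires duration >= 0 min")
        if self.kind == "ionp" and self.flow_setpoint is not None and self.flow_setpoint <= 0:
            raise ProtocolError(f"{where}: ionp flow_setpoint must be > 0 mL/min")
        adj = seg.adjunct
        if adj is not None and seg.kind == "ramp":
            # The adjunct shares the segment timeline; its rate, if stated, must agree.
            if adj.rate is not None and adj.c_start != adj.c_end:
                d_adj = ramp_duration(adj.c_start, adj.c_end, adj.rate)
                if not np.isclose(d_adj, seg.duration):
                    raise ProtocolError(
                        f"{where}: adjunct {adj.name!r} ramp duration {d_adj} min "
                        f"does not match segment duration {seg.duration} min"
                    )
        return seg

    def adjunct_value(self, frac: float) -> float:
        """Adjunct concentration at fractional position ``frac`` in [0, 1]."""
        if self.adjunct is None:
            return 0.0
        if self.kind == "ramp":
            return self.adjunct.c_start + frac * (self.adjunct.c_end - self.adjunct.c_start)
        return self.adjunct.c_start


@dataclass(frozen=True)
class Protocol:
    """A validated, ordered CPA perfusion schedule."""

    name: str
    segments: tuple[ProtocolSegment, ...]
    carrier: str = ""
    cpa: str = ""

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times in minutes (length = n segments + 1)."""
        durs = [s.duration for s in self.segments]
        return np.concatenate([[0.0], np.cumsum(durs)]) if durs else np.array([0.0])

    def total_duration(self) -> float:
        return float(self.boundaries[-1])

    def segment_at(self, t: float) -> tuple[int, float]:
        """Index of the segment containing time ``t`` and the local offset (min)."""
        total = self.total_duration()
        if t < 0 or t > total:
            raise ProtocolError(f"t = {t} min outside protocol span [0, {total}]")
        b = self.boundaries
        if t == total:
            return len(self.segments) - 1, t - b[-2]
        i = int(np.searchsorted(b, t, side="right") - 1)
        return i, t - b[i]

    def concentration_at(self, t: float, solute: str | None = None) -> float:
        """CPA (or named adjunct) concentration in mM at time ``t``.

        Step segments hold their value on the half-open interval
        [segment start, segment end); the protocol end evaluates to the final
        segment's end value.
        """
        if not self.segments:
            raise ProtocolError("empty protocol has no concentration timeline")
        i, dt = self.segment_at(t)
        seg = self.segments[i]
        frac = dt / seg.duration if seg.duration and seg.duration > 0 else 0.0
        if solute is not None:
            if seg.adjunct is not None and seg.adjunct.name == solute:
                return seg.adjunct_value(frac)
            return 0.0
        if seg.kind == "ramp":
            return seg.c_start + frac * (seg.c_end - seg.c_start)
        return seg.c_start

    def pressure_at(self, t: float) -> float:
        i, _ = self.segment_at(t)
        return self.segments[i].pressure_setpoint

    def temperature_at(self, t: float) -> float:
        i, _ = self.segment_at(t)
        return self.segments[i].temperature

    def adjunct_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for s in self.segments:
            if s.adjunct is not None and s.adjunct.name not in names:
                names.append(s.adjunct.name)
        return tuple(names)

    def to_dict(self) -> dict:
        segs = []
        for s in self.segments:
            d: dict = {"kind": s.kind, "c_start": s.c_start, "c_end": s.c_end}
            if s.kind == "ramp":
                d["rate"] = s.rate
            else:
                d["duration"] = s.duration
            d["pressure_setpoint"] = s.pressure_setpoint
            d["temperature"] = s.temperature
            if s.flow_setpoint is not None:
                d["flow_setpoint"] = s.flow_setpoint
            if s.adjunct is not None:
                a = {"name": s.adjunct.name, "c_start": s.adjunct.c_start,
                     "c_end": s.adjunct.c_end}
                if s.adjunct.rate is not None:
                    a["rate"] = s.adjunct.rate
                d["adjunct"] = a
            segs.append(d)
        return {"name": self.name, "cpa": self.cpa, "carrier": self.carrier,
                "segments": segs}


def build_protocol(
    spec: Iterable[dict | ProtocolSegment],
    name: str = "",
    carrier: str = "",
    cpa: str = "",
) -> Protocol:
    """Validate a structured segment list into a Protocol.

    Segments may be dicts (YAML-style) or ProtocolSegment instances. Ramp
    durations are derived from endpoints and rate. Concentration
    discontinuities between adjacent segments are rejected unless the later
    segment is an explicit ``step``.
    """
    segments: list[ProtocolSegment] = []
    for i, raw in enumerate(spec):
        if isinstance(raw, ProtocolSegment):
            seg = raw
        else:
            d = dict(raw)
            adj = d.pop("adjunct", None)
            if adj is not None:
                adj = Adjunct(**adj)
            seg = ProtocolSegment(adjunct=adj, **d)
        seg = seg.validated(index=i)
        if segments and seg.kind != "step":
            prev = segments[-1]
            if not np.isclose(prev.c_end, seg.c_start):
                raise ProtocolError(
                    f"segment {i}: concentration discontinuity "
                    f"({prev.c_end:g} -> {seg.c_start:g} mM) not marked as a step"
                )
        segments.append(seg)
    return Protocol(name=name, segments=tuple(segments), carrier=carrier, cpa=cpa)


def total_duration(p: Protocol) -> float:
    """Total protocol duration in minutes (derived ramp durations included)."""
    return p.total_duration()


def concentration_at(p: Protocol, t: float, solute: str | None = None) -> float:
    return p.concentration_at(t, solute=solute)


@dataclass(frozen=True)
class FlowQC:
    ratio: float
    passed: bool
    threshold: float = 0.45


def flow_qc(loading_flow: float, unloading_flow: float, threshold: float = 0.45) -> FlowQC:
    """IONP aggregation QC: unloading flow must exceed ``threshold`` of loading flow.

    The pass rule is a strict inequality (exactly 45% fails).
    """
    if loading_flow <= 0:
        raise ProtocolError("loading flow must be > 0 mL/min")
    ratio = unloading_flow / loading_flow
    return FlowQC(ratio=ratio, passed=ratio > threshold, threshold=threshold)


# ---------------------------------------------------------------------------
# Reference protocols (VMP loading/unloading schedules used throughout)

def vmp_loading_protocol(include_ionp: bool = False, ionp_duration: float = 4.5) -> Protocol:
    """VMP loading: 20-min carrier flush, 0->5 M ramp at 50 mM/min, 10-min
    hold, then a 25-min step at full strength (8.4 M); 155 min total.

    With ``include_ionp`` the final ``ionp_duration`` minutes of the
    full-strength step become an IONP co-perfusion segment at a constant
    0.5 mL/min flow (total unchanged).
    """
    segs: list[dict] = [
        {"kind": "flush", "c_start": 0, "c_end": 0, "duration": 20,
         "pressure_setpoint": 40, "temperature": 4},
        {"kind": "ramp", "c_start": 0, "c_end": 5000, "rate": 50,
         "pressure_setpoint": 40, "temperature": 4},
        {"kind": "hold", "c_start": 5000, "c_end": 5000, "duration": 10,
         "pressure_setpoint": 40, "temperature": 4},
    ]
    if include_ionp:
        segs += [
            {"kind": "step", "c_start": 8400, "c_end": 8400,
             "duration": 25 - ionp_duration, "pressure_setpoint": 60, "temperature": 4},
            {"kind": "ionp", "c_start": 8400, "c_end": 8400, "duration": ionp_duration,
             "pressure_setpoint": 60, "temperature": 4, "flow_setpoint": 0.5},
        ]
    else:
        segs.append({"kind": "step", "c_start": 8400, "c_end": 8400, "duration": 25,
                     "pressure_setpoint": 60, "temperature": 4})
    return build_protocol(segs, name="VMP loading", carrier="LM5-XZ", cpa="VMP")


def vmp_unloading_protocol() -> Protocol:
    """VMP unloading: 15-min hold at 4.2 M + 300 mM mannitol, ramp to 0 at
    -35 mM/min (mannitol at -2.5 mM/min), 30-min carrier flush; 165 min total.
    """
    mann_hold = {"name": "mannitol", "c_start": 300, "c_end": 300}
    mann_ramp = {"name": "mannitol", "c_start": 300, "c_end": 0, "rate": -2.5}
    segs = [
        {"kind": "hold", "c_start": 4200, "c_end": 4200, "duration": 15,
         "pressure_setpoint": 40, "temperature": 2, "adjunct": mann_hold},
        {"kind": "ramp", "c_start": 4200, "c_end": 0, "rate": -35,
         "pressure_setpoint": 40, "temperature": 2, "adjunct": mann_ramp},
        {"kind": "flush", "c_start": 0, "c_end": 0, "duration": 30,
         "pressure_setpoint": 40, "temperature": 2},
    ]
    return build_protocol(segs, name="VMP unloading", carrier="LM5-XZ", cpa="VMP")


# ---------------------------------------------------------------------------
# YAML round trip

def load_protocol(path) -> Protocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return build_protocol(
        doc.get("segments", []),
        name=doc.get("name", ""),
        carrier=doc.get("carrier", ""),
        cpa=doc.get("cpa", ""),
    )


def save_protocol(p: Protocol, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)
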