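"""Voltage-clamp protocols: piecewise waveforms of holds, ramps and sinusoids.

A protocol is an ordered, contiguous list of segments starting at t = 0,
each with a strictly positive duration (ms).  Segments are left-closed /
right-open, so at an internal boundary the *later* segment's voltage is
reported; the final boundary (t = total duration) belongs to the last
segment.  Protocols are model-independent: they only answer "what is the
command voltage at time t".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "Hold",
    "Ramp",
    "Sine",
    "VoltageProtocol",
    "default_fixture_protocol",
    "holding_protocol",
    "load_protocol",
    "dump_protocol",
]


@dataclass(frozen=True)
class Hold:
    """Constant command voltage ``v`` (mV) for ``duration`` ms."""

    duration: float
    v: float

    def voltage(self, t_local: float) -> float:
        return self.v

    def voltage_bounds(self) -> tuple[float, float]:
        return (self.v, self.v)

    def to_dict(self) -> dict:
        return {"kind": "hold", "duration": self.duration, "v": self.v}


@dataclass(frozen=True)
class Ramp:
    """Linear sweep from ``v_start`` to ``v_end`` (mV) over ``duration`` ms."""

    duration: float
    v_start: float
    v_end: float

    def voltage(self, t_local: float) -> float:
        return self.v_start + (self.v_end - self.v_start) * t_local / self.duration

    def voltage_bounds(self) -> tuple[float, float]:
        lo, hi = sorted((self.v_start, self.v_end))
        return (lo, hi)

    def to_dict(self) -> dict:
        return {
            "kind": "ramp",
            "duration": self.duration,
            "v_start": self.v_start,
            "v_end": self.v_end,
        }


@dataclass(frozen=True)
class Sine:
    """Sinusoid ``v_offset + amplitude*sin(2*pi*t/period + phase)`` (mV).

    ``t`` is local to the segment start; ``period`` in ms, ``phase`` in rad.
    """

    duration: float
    v_offset: float
    amplitude: float
    period: float
    phase: float = 0.0

    def voltage(self, t_local: float) -> float:
        return self.v_offset + self.amplitude * math.sin(
            2.0 * math.pi * t_local / self.period + self.phase
        )

    def voltage_bounds(self) -> tuple[float, float]:
        # Conservative: full swing, whether or not it is realised in-segment.
        return (self.v_offset - abs(self.amplitude), self.v_offset + abs(self.amplitude))

    def to_dict(self) -> dict:
        return {
            "kind": "sine",
            "duration": self.duration,
            "v_offset": self.v_offset,
            "amplitude": self.amplitude,
            "period": self.period,
            "phase": self.phase,
        }


Segment = Union[Hold, Ramp, Sine]

_SEGMENT_KINDS = {"hold": Hold, "ramp": Ramp, "sine": Sine}


class VoltageProtocol:
    """An ordered, contiguous sequence of clamp segments starting at t = 0."""

    def __init__(self, segments: Sequence[Segment]):
        segments = tuple(segments)
        if not segments:
            raise ValueError("protocol needs at least one segment")
        for seg in segments:
            if not (np.isfinite(seg.duration) and seg.duration > 0):
                raise ValueError(f"segment duration must be positive and finite: {seg}")
            if isinstance(seg, Sine) and not (np.isfinite(seg.period) and seg.period > 0):
                raise ValueError(f"sine period must be positive and finite: {seg}")
        self.segments: tuple[Segment, ...] = segments
        # boundaries[i] is the start time of segment i; last entry = total.
        self.boundaries = np.concatenate(
            [[0.0], np.cumsum([s.duration for s in segments])]
        )

    @property
    def total_duration(self) -> float:
        return float(self.boundaries[-1])

    def segment_index(self, t: float) -> int:
        """Index of the segment owning time ``t`` (left-closed/right-open;
        t = total duration belongs to the last segment)."""
        if not (0.0 <= t <= self.total_duration):
            raise ValueError(
                f"t={t} outside protocol duration [0, {self.total_duration}] ms"
            )
        i = int(np.searchsorted(self.boundaries, t, side="right")) - 1
        return min(i, len(self.segments) - 1)

    def voltage_at(self, t: float) -> float:
        """Command voltage (mV) at time ``t`` (ms)."""
        i = self.segment_index(t)
        return self.segments[i].voltage(t - self.boundaries[i])

    def voltages(self, times: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`voltage_at`."""
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < 0 or times.max() > self.total_duration):
            raise ValueError(
                f"times outside protocol duration [0, {self.total_duration}] ms"
            )
        idx = np.searchsorted(self.boundaries, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        out = np.empty(times.shape, dtype=float)
        for i, seg in enumerate(self.segments):
            mask = idx == i
            if not np.any(mask):
                continue
            t_local = times[mask] - self.boundaries[i]
            if isinstance(seg, Hold):
                out[mask] = seg.v
            elif isinstance(seg, Ramp):
                out[mask] = seg.v_start + (seg.v_end - seg.v_start) * t_local / seg.duration
            else:
                out[mask] = seg.v_offset + seg.amplitude * np.sin(
                    2.0 * np.pi * t_local / seg.period + seg.phase
                )
        return out

    def voltage_range(self) -> tuple[float, float]:
        """Conservative (min, max) command voltage over the protocol."""
        bounds = [s.voltage_bounds() for s in self.segments]
        return (min(b[0] for b in bounds), max(b[1] for b in bounds))

    def to_dicts(self) -> list[dict]:
        return [s.to_dict() for s in self.segments]

    @classmethod
    def from_dicts(cls, items: Sequence[dict]) -> "VoltageProtocol":
        segments = []
        for item in items:
            item = dict(item)
            kind = item.pop("kind", None)
            if kind not in _SEGMENT_KINDS:
                raise ValueError(f"unknown segment kind: {kind!r}")
            segments.append(_SEGMENT_KINDS[kind](**item))
        return cls(segments)

    def __eq__(self, other) -> bool:
        return isinstance(other, VoltageProtocol) and self.segments == other.segments

    def __repr__(self) -> str:
        return f"VoltageProtocol({len(self.segments)} segments, {self.total_duration} ms)"


def dump_protocol(protocol: VoltageProtocol) -> str:
    """Serialise a protocol to its JSON file form."""
    return json.dumps(protocol.to_dicts(), indent=2) + "\n"


def load_protocol(source: str) -> VoltageProtocol:
    """Parse a protocol from JSON text (a list of segment objects)."""
    items = json.loads(source)
    if not isinstance(items, list):
        raise ValueError("protocol file must contain a JSON list of segments")
    return VoltageProtocol.from_dicts(items)


def default_fixture_protocol() -> VoltageProtocol:
    """Deterministic information-rich clamp used for synthetic studies.

    2 s hold at -80 mV; a staircase of six 500 ms steps spanning
    -60..+40 mV, each followed by 500 ms at -40 mV (probing activation and
    deactivation across the physiological range); a 2 s sinusoid
    (offset -30 mV, amplitude 30 mV, period 200 ms) exciting fast
    inactivation/recovery kinetics; and a final 2 s hold at -80 mV.
    Total duration 12,000 ms.
    """
    segments: list[Segment] = [Hold(2000.0, -80.0)]
    for v in (-60.0, -40.0, -20.0, 0.0, 20.0, 40.0):
        segments.append(Hold(500.0, v))
        segments.append(Hold(500.0, -40.0))
    segments.append(Sine(2000.0, -30.0, 30.0, 200.0, 0.0))
    segments.append(Hold(2000.0, -80.0))
    return VoltageProtocol(segments)


def holding_protocol(duration: float = 12000.0, v: float = -80.0) -> VoltageProtocol:
    """A single constant hold — the deliberately uninformative protocol used
    for identifiability contrasts."""
    return VoltageProtocol([Hold(duration, v)])
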