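"""Piecewise-quadratic time profiles for coupling parameters.

A :class:`Schedule` represents a coupling strength that varies over the
simulation window as a sequence of contiguous quadratic segments,
``value(t) = a*t**2 + b*t + c`` on ``[t_start, t_end)``.  Negative
evaluations are clamped to zero: coupling strengths are non-negative by
definition, and the ramps used in the HeLa scenario are constructed to
pass through zero at the hand-off point, so clamping never introduces a
jump larger than the fitting residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = ["Segment", "Schedule", "CouplingValue", "evaluate_coupling"]


@dataclass(frozen=True)
class Segment:
    """One quadratic piece: value(t) = a*t**2 + b*t + c on [t_start, t_end)."""

    t_start: float
    t_end: float
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0

    def raw_value(self, t: float) -> float:
        return self.a * t * t + self.b * t + self.c


@dataclass(frozen=True)
class Schedule:
    """Contiguous, non-overlapping quadratic segments covering a window.

    The final segment is closed on the right so the last instant of the
    simulation window evaluates without error.
    """

    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("Schedule needs at least one segment")
        segs = sorted(self.segments, key=lambda s: s.t_start)
        object.__setattr__(self, "segments", tuple(segs))
        for prev, nxt in zip(segs, segs[1:]):
            if not np.isclose(prev.t_end, nxt.t_start):
                raise ValueError(
                    f"segments not contiguous: [{prev.t_start}, {prev.t_end}) "
                    f"then [{nxt.t_start}, {nxt.t_end})"
                )

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    @classmethod
    def constant(cls, value: float, t_start: float = 0.0, t_end: float = np.inf) -> "Schedule":
        return cls((Segment(t_start, t_end, 0.0, 0.0, value),))

    def _segment_at(self, t: float) -> Segment:
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg
        # closed right end of the final segment
        last = self.segments[-1]
        if np.isclose(t, last.t_end) or t >= last.t_end:
            return last
        if t < self.segments[0].t_start:
            return self.segments[0]
        raise ValueError(f"t={t} outside schedule window")  # pragma: no cover

    def raw_value(self, t: float) -> float:
        """Polynomial value before the non-negativity clamp."""
        return self._segment_at(t).raw_value(t)

    def value(self, t: float) -> float:
        """Evaluated coupling strength; negative values are clamped to 0."""
        v = self.raw_value(t)
        if v < 0.0:
            if v < -1e-2:  # clamping is expected only near hand-off points
                warnings.warn(
                    f"schedule value {v:.4g} at t={t:.4g} clamped to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
            return 0.0
        return v

    def values(self, times: Sequence[float]) -> np.ndarray:
        return np.array([self.value(float(t)) for t in np.asarray(times, float)])

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "a": s.a, "b": s.b, "c": s.c}
                for s in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Schedule":
        return cls(tuple(Segment(**seg) for seg in d["segments"]))


CouplingValue = Union[float, Schedule]


def evaluate_coupling(coupling: CouplingValue, t: float) -> float:
    """Evaluate a scalar-or-Schedule coupling at time t (clamped at 0)."""
    if isinstance(coupling, Schedule):
        return coupling.value(t)
    return max(float(coupling), 0.0)
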