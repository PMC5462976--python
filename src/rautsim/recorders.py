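"""Recording procedures: continuous recording and the three interval rules.

Discontinuous observational recording divides a session into ``n`` back-to-
back intervals of length ``tau`` and reduces the behavior stream to one
binary mark per interval:

* **MTS** (momentary time sampling) -- mark interval ``k`` iff the behavior
  is occurring at the interval's endpoint ``k * tau``.
* **PIR** (partial interval recording) -- mark iff the behavior occurs at
  any point within the interval (positive-measure overlap).
* **WIR** (whole interval recording) -- mark only if one event covers the
  entire closed interval.

For every stream the marks are ordered elementwise WIR <= MTS <= PIR.
Continuous recording keeps the exact occupied proportion and event count
and serves as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arp_core import BehaviorStream

__all__ = [
    "ContinuousSummary",
    "IntervalRecord",
    "PROCEDURES",
    "record_continuous",
    "record_mts",
    "record_pir",
    "record_wir",
    "record",
]

PROCEDURES = ("MTS", "PIR", "WIR")


@dataclass(frozen=True)
class ContinuousSummary:
    """Exact session measures from continuous recording."""

    prevalence: float  # occupied time / session length, in [0, 1]
    frequency: int  # number of events (a clipped final event counts)


@dataclass(frozen=True)
class IntervalRecord:
    """Binary per-interval marks from one discontinuous procedure."""

    procedure: str
    tau: float
    session_length: float
    marks: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.procedure not in PROCEDURES:
            raise ValueError(f"unknown procedure {self.procedure!r}")
        marks = np.asarray(self.marks, dtype=np.int8)
        if marks.ndim != 1 or marks.size < 1:
            raise ValueError("marks must be a non-empty 1-d vector")
        if not np.isin(marks, (0, 1)).all():
            raise ValueError("marks must be binary")
        object.__setattr__(self, "marks", marks)

    @property
    def n(self) -> int:
        return int(self.marks.size)


def _n_intervals(stream: BehaviorStream, tau: float) -> int:
    if not tau > 0:
        raise ValueError(f"interval length must be > 0, got {tau}")
    if tau > stream.session_length:
        raise ValueError(
            f"interval length {tau} exceeds session length {stream.session_length}"
        )
    # A final partial interval is discarded; leftover time never influences marks.
    return int(np.floor(stream.session_length / tau + 1e-9))


def record_continuous(stream: BehaviorStream) -> ContinuousSummary:
    """Exact prevalence and event count of a stream."""
    return ContinuousSummary(
        prevalence=stream.total_event_time() / stream.session_length,
        frequency=stream.n_events,
    )


def record_mts(stream: BehaviorStream, tau: float) -> IntervalRecord:
    """Momentary time sampling: sample occupancy at t = tau, 2*tau, ..., n*tau."""
    n = _n_intervals(stream, tau)
    samples = tau * np.arange(1, n + 1)
    marks = stream.occupied_at(samples)
    return IntervalRecord("MTS", tau, stream.session_length, marks.astype(np.int8))


def record_pir(stream: BehaviorStream, tau: float) -> IntervalRecord:
    """Partial interval recording: mark if any event overlaps the open interval."""
    n = _n_intervals(stream, tau)
    left = tau * np.arange(n)
    marks = np.zeros(n, dtype=np.int8)
    if stream.onsets.size:
        # First event ending strictly after the interval's left edge; it
        # overlaps with positive measure iff it starts before the right edge.
        j = np.searchsorted(stream.offsets, left, side="right")
        ok = j < stream.onsets.size
        marks[ok] = stream.onsets[j[ok]] < left[ok] + tau
    return IntervalRecord("PIR", tau, stream.session_length, marks)


def record_wir(stream: BehaviorStream, tau: float) -> IntervalRecord:
    """Whole interval recording: mark only if a single event spans [left, right].

    Events are separated by positive interims, so a single covering event is
    equivalent to the behavior occurring throughout the interval.
    """
    n = _n_intervals(stream, tau)
    left = tau * np.arange(n)
    marks = np.zeros(n, dtype=np.int8)
    if stream.onsets.size:
        j = np.searchsorted(stream.onsets, left, side="right") - 1
        ok = j >= 0
        marks[ok] = stream.offsets[j[ok]] >= left[ok] + tau
    return IntervalRecord("WIR", tau, stream.session_length, marks)


_RECORDERS = {"MTS": record_mts, "PIR": record_pir, "WIR": record_wir}


def record(stream: BehaviorStream, tau: float, procedure: str) -> IntervalRecord:
    """Apply one named discontinuous procedure."""
    try:
        fn = _RECORDERS[procedure.upper()]
    except KeyError:
        raise ValueError(f"unknown procedure {procedure!r}") from None
    return fn(stream, tau)
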