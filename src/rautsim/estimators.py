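"""Frequency and prevalence estimators from binary interval records.

From a mark vector the two primitive counts are the *pseudofrequency*
``PF = r + n01`` (first-interval mark plus the number of unmarked-to-marked
transitions, i.e. the number of marked runs) and the *modified frequency*
``theta`` (number of marked intervals).  Prevalence is estimated as
``theta/n``, with corrections ``(theta - PF)/n`` for PIR and
``(theta + PF)/n`` for WIR that offset the procedures' built-in over- and
under-counting.  For PIR a frequency estimate ``-n * ln(1 - theta/n)``
is also available; it is undefined (NaN) when every interval is marked.
Estimation error is summarized as relative bias ``(estimate - truth)/truth``
against either the generating prevalence or the continuous-recording
measure of the same session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .recorders import ContinuousSummary, IntervalRecord

__all__ = [
    "pseudofrequency",
    "modified_frequency",
    "estimate_prevalence",
    "estimate_frequency_pir",
    "relative_bias",
    "EstimateSet",
    "estimate_set",
]


def pseudofrequency(record: IntervalRecord) -> int:
    """PF = r + n01: first mark plus number of 0->1 transitions.

    Counts the marked runs in the record, the interval-record analogue of
    an event count.
    """
    m = record.marks
    r = int(m[0])
    n01 = int(np.sum((m[1:] == 1) & (m[:-1] == 0)))
    return r + n01


def modified_frequency(record: IntervalRecord) -> int:
    """theta: the number of marked intervals."""
    return int(record.marks.sum())


def estimate_prevalence(
    theta: int, pf: int, n: int, procedure: str, corrected: bool = False
) -> float:
    """Prevalence estimate theta/n, optionally corrected for PIR/WIR.

    PIR corrected: (theta - PF)/n; WIR corrected: (theta + PF)/n.  The WIR
    correction can exceed 1 for extreme records, so the result is clipped
    into [0, 1] (prevalence is a proportion).
    """
    procedure = procedure.upper()
    if n < 1:
        raise ValueError("record must contain at least one interval")
    if not 0 <= pf <= theta <= n:
        raise ValueError(f"require 0 <= pf <= theta <= n, got pf={pf}, theta={theta}, n={n}")
    if not corrected:
        return theta / n
    if procedure == "PIR":
        est = (theta - pf) / n
    elif procedure == "WIR":
        est = (theta + pf) / n
    else:
        raise ValueError("corrected estimates exist only for PIR and WIR")
    return min(1.0, max(0.0, est))


def estimate_frequency_pir(theta: int, n: int) -> float:
    """PIR frequency estimate -n * ln(1 - theta/n).

    Always >= theta, with equality iff theta == 0.  When theta == n the
    logarithm is singular and NaN is returned as the undefined flag; callers
    exclude flagged values from summaries rather than aborting.
    """
    if n < 1:
        raise ValueError("record must contain at least one interval")
    if not 0 <= theta <= n:
        raise ValueError(f"require 0 <= theta <= n, got theta={theta}, n={n}")
    if theta == n:
        return math.nan
    return -n * math.log1p(-theta / n)


def relative_bias(estimate: float, truth: float) -> float:
    """(estimate - truth)/truth; truth may be the generating prevalence or
    the continuous-recording measure of the same session."""
    if truth == 0:
        raise ValueError("relative bias is undefined for truth == 0")
    return (estimate - truth) / truth


@dataclass(frozen=True)
class EstimateSet:
    """All estimator outputs for one session under one procedure.

    ``prev_corrected`` is None for MTS; ``freq_formula`` is None except for
    PIR, where it is NaN when theta == n.  Both relative-bias baselines are
    carried side by side: the generating parameter pi and the session's own
    continuous-recording prevalence.
    """

    procedure: str
    n: int
    pf: int
    theta: int
    prev_raw: float
    prev_corrected: float | None
    freq_formula: float | None
    rel_bias_vs_param: float
    rel_bias_vs_continuous: float | None


def estimate_set(
    record: IntervalRecord,
    continuous: ContinuousSummary,
    pi: float,
) -> EstimateSet:
    """Compute every estimator for one interval record.

    The bias baseline against continuous recording is None when the session
    happened to contain no behavior at all (truth == 0).
    """
    pf = pseudofrequency(record)
    theta = modified_frequency(record)
    n = record.n
    proc = record.procedure
    prev_raw = estimate_prevalence(theta, pf, n, proc)
    prev_corr = (
        estimate_prevalence(theta, pf, n, proc, corrected=True)
        if proc in ("PIR", "WIR")
        else None
    )
    freq = estimate_frequency_pir(theta, n) if proc == "PIR" else None
    return EstimateSet(
        procedure=proc,
        n=n,
        pf=pf,
        theta=theta,
        prev_raw=prev_raw,
        prev_corrected=prev_corr,
        freq_formula=freq,
        rel_bias_vs_param=relative_bias(prev_raw, pi),
        rel_bias_vs_continuous=(
            relative_bias(prev_raw, continuous.prevalence)
            if continuous.prevalence > 0
            else None
        ),
    )
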