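"""Alternating renewal process (ARP) model of a behavior stream.

A behavior stream is the continuous alternation of occurrences of a target
behavior (events) and the gaps between them (interim times) over an
observation session.  The ARP models event durations and interim times as
independent random variables; here both are exponential, with mean event
duration ``mu`` (the "duration per occurrence", DPO) and mean interim time
``lam``.  Under this model the long-run proportion of time occupied by the
behavior -- its *prevalence* -- is ``pi = mu / (mu + lam)``, and the
*incidence* (events per unit time) is ``1 / (mu + lam)``.

The simulator draws streams in equilibrium: at time zero the behavior is
occurring with probability ``pi``, and because the exponential distribution
is memoryless the residual time in the initial state has the same
distribution as a full duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StreamParameters",
    "BehaviorStream",
    "derive_interim_time",
    "derive_incidence_per_minute",
    "prevalence_from_rates",
    "interval_ratio",
    "simulate_stream",
    "DURATION_FAMILIES",
]

#: Named extension point for duration/interim distributions.  Only the
#: exponential family is implemented; entries map a family name to a sampler
#: ``(rng, mean, size) -> ndarray``.
DURATION_FAMILIES = {
    "exponential": lambda rng, mean, size: rng.exponential(mean, size),
}


def derive_interim_time(mu: float, pi: float) -> float:
    """Mean interim time lam = mu*(1 - pi)/pi implied by mean duration and prevalence.

    Parameters
    ----------
    mu : float
        Mean event duration in seconds, > 0.
    pi : float
        Prevalence (long-run occupied proportion), in (0, 1).
    """
    if not mu > 0:
        raise ValueError(f"mean event duration must be > 0, got {mu}")
    if not 0 < pi < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {pi}")
    return mu * (1.0 - pi) / pi


def derive_incidence_per_minute(mu: float, lam: float) -> float:
    """Expected number of event onsets per minute, 60/(mu + lam)."""
    if not mu > 0:
        raise ValueError(f"mean event duration must be > 0, got {mu}")
    if lam < 0:
        raise ValueError(f"mean interim time must be >= 0, got {lam}")
    if mu + lam == 0:
        raise ValueError("mu + lam must be positive")
    return 60.0 / (mu + lam)


def prevalence_from_rates(mu: float, lam: float) -> float:
    """Prevalence pi = mu/(mu + lam) implied by the two mean durations."""
    if not mu > 0:
        raise ValueError(f"mean event duration must be > 0, got {mu}")
    if lam < 0:
        raise ValueError(f"mean interim time must be >= 0, got {lam}")
    return mu / (mu + lam)


def interval_ratio(tau: float, mu: float) -> float:
    """Interval length relative to mean event duration, tau/mu.

    Ratios above 1 mean the recording interval is longer than a typical
    occurrence, the regime in which interval recording distorts most.
    """
    if not tau > 0:
        raise ValueError(f"interval length must be > 0, got {tau}")
    if not mu > 0:
        raise ValueError(f"mean event duration must be > 0, got {mu}")
    return tau / mu


@dataclass(frozen=True)
class StreamParameters:
    """Generative settings of one ARP behavior stream.

    Attributes
    ----------
    mu : float
        Mean event duration (seconds), > 0.
    lam : float
        Mean interim time (seconds), >= 0.
    session_length : float
        Observation session length (seconds), > 0.
    """

    mu: float
    lam: float
    session_length: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mean event duration must be > 0, got {self.mu}")
        if self.lam < 0:
            raise ValueError(f"mean interim time must be >= 0, got {self.lam}")
        if not self.session_length > 0:
            raise ValueError(
                f"session length must be > 0, got {self.session_length}"
            )

    @classmethod
    def from_prevalence(
        cls, mu: float, pi: float, session_length: float
    ) -> "StreamParameters":
        """Build parameters from mean duration and target prevalence."""
        return cls(mu=mu, lam=derive_interim_time(mu, pi), session_length=session_length)

    @property
    def pi(self) -> float:
        """Prevalence mu/(mu + lam)."""
        return prevalence_from_rates(self.mu, self.lam)

    @property
    def incidence_per_minute(self) -> float:
        return derive_incidence_per_minute(self.mu, self.lam)


@dataclass(frozen=True)
class BehaviorStream:
    """One session's realized event intervals.

    Events are half-open intervals ``[onset, offset)`` in seconds, sorted,
    strictly non-overlapping and separated by positive gaps; an event still
    in progress at session end is clipped to ``session_length``.
    """

    session_length: float
    onsets: np.ndarray = field(repr=False)
    offsets: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        offsets = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "offsets", offsets)
        self.validate()

    def validate(self) -> None:
        on, off = self.onsets, self.offsets
        if on.shape != off.shape or on.ndim != 1:
            raise ValueError("onsets and offsets must be 1-d arrays of equal length")
        if on.size == 0:
            return
        if not (on >= 0).all():
            raise ValueError("event onsets must be >= 0")
        if not (off > on).all():
            raise ValueError("every event must have offset > onset")
        if not (off <= self.session_length).all():
            raise ValueError("events must end within the session")
        if on.size > 1 and not (on[1:] > off[:-1]).all():
            raise ValueError("events must be sorted and separated by positive gaps")

    @classmethod
    def from_events(
        cls, events, session_length: float
    ) -> "BehaviorStream":
        """Build from an iterable of (onset, offset) pairs."""
        events = list(events)
        if events:
            on, off = map(np.asarray, zip(*events))
        else:
            on = off = np.empty(0)
        return cls(session_length=float(session_length), onsets=on, offsets=off)

    @property
    def events(self) -> list[tuple[float, float]]:
        return list(zip(self.onsets.tolist(), self.offsets.tolist()))

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def total_event_time(self) -> float:
        return float(np.sum(self.offsets - self.onsets))

    def occupied_at(self, t: np.ndarray) -> np.ndarray:
        """Whether the behavior is occurring at each time in ``t``.

        Membership is half-open, ``onset <= t < offset``.  At the single
        boundary ``t == session_length`` an event clipped at session end
        (``offset == session_length``) counts as occurring: the behavior is
        genuinely in progress at the final instant, and this keeps momentary
        sampling consistent with whole-interval recording at the last
        interval.  Interior coincidences ``t == offset < session_length``
        have probability zero under the continuous model and score 0.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        occ = np.zeros(t.shape, dtype=bool)
        if self.onsets.size == 0:
            return occ
        idx = np.searchsorted(self.onsets, t, side="right") - 1
        valid = idx >= 0
        iv = idx[valid]
        tv = t[valid]
        inside = tv < self.offsets[iv]
        at_end = (tv == self.session_length) & (self.offsets[iv] == self.session_length)
        occ[valid] = inside | at_end
        return occ


def simulate_stream(
    params: StreamParameters, rng: np.random.Generator
) -> BehaviorStream:
    """Draw one equilibrium ARP behavior stream.

    The initial state is Bernoulli(pi); by memorylessness of the exponential
    the residual duration of that state is drawn from the full distribution.
    Alternating Exp(mu) event durations and Exp(lam) interim times are then
    generated until the session ends; a final in-progress event is clipped
    to the session length.  Deterministic for a given generator state.
    """
    mu, lam, L = params.mu, params.lam, params.session_length
    pi = params.pi

    if lam == 0.0:
        # Degenerate pi = 1: the behavior never ceases.
        return BehaviorStream(L, np.array([0.0]), np.array([L]))

    occupied = rng.random() < pi
    # Time of the first event onset.
    t = 0.0 if occupied else float(rng.exponential(lam))

    onsets_parts: list[np.ndarray] = []
    offsets_parts: list[np.ndarray] = []
    while t < L:
        # Enough full cycles to usually clear the session in one batch.
        m = int(math.ceil((L - t) / (mu + lam))) + 8
        durs = rng.exponential(mu, m)
        gaps = rng.exponential(lam, m)
        cycles = durs + gaps
        starts = t + np.concatenate(([0.0], np.cumsum(cycles[:-1])))
        keep = starts < L
        onsets_parts.append(starts[keep])
        offsets_parts.append(starts[keep] + durs[keep])
        t = float(starts[-1] + cycles[-1])

    onsets = np.concatenate(onsets_parts) if onsets_parts else np.empty(0)
    offsets = np.concatenate(offsets_parts) if offsets_parts else np.empty(0)
    np.minimum(offsets, L, out=offsets)
    return BehaviorStream(session_length=L, onsets=onsets, offsets=offsets)
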