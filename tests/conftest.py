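import numpy as np
import pytest

from rautsim import BehaviorStream, StreamParameters, simulate_stream


def random_grid_stream(rng: np.random.Generator, L_ms: int = 10_000) -> BehaviorStream:
    """Random stream whose onsets/offsets sit on a 1 ms grid.

    Interior onsets and offsets are odd milliseconds so they never coincide
    with interval edges at even-ms interval lengths; a final event may be
    clipped to the (even) session end, exercising the end-of-session rule.
    """
    events = []
    t = int(rng.integers(0, 1500))
    t += (t + 1) % 2  # make odd
    while t < L_ms:
        off = t + 2 * int(rng.integers(1, 1500))
        events.append((t / 1000, min(off, L_ms) / 1000))
        t = off + 2 * int(rng.integers(1, 1200))
    return BehaviorStream.from_events(events, L_ms / 1000)


def random_continuous_stream(rng: np.random.Generator) -> BehaviorStream:
    """Random equilibrium stream with irrational-scale float boundaries."""
    mu = float(rng.uniform(0.5, 5.0))
    pi = float(rng.uniform(0.05, 0.95))
    params = StreamParameters.from_prevalence(mu, pi, session_length=30.0)
    return simulate_stream(params, rng)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
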