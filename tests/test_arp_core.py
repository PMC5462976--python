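"""Parameter algebra of the alternating renewal process and stream simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rautsim import (
    BehaviorStream,
    StreamParameters,
    derive_incidence_per_minute,
    derive_interim_time,
    interval_ratio,
    prevalence_from_rates,
    simulate_stream,
)


class TestParameterAlgebra:
    @pytest.mark.parametrize(
        "mu, pi, lam",
        [(2, 0.3, 4.67), (18, 0.3, 42.0), (7, 0.5, 7.0)],
    )
    def test_interim_time_from_duration_and_prevalence(self, mu, pi, lam):
        assert derive_interim_time(mu, pi) == pytest.approx(lam, abs=5e-3)

    @pytest.mark.parametrize(
        "mu, lam, inc",
        [(2, 38, 1.5), (18, 0.947368, 3.2), (30, 30, 1.0)],
    )
    def test_incidence_per_minute(self, mu, lam, inc):
        assert derive_incidence_per_minute(mu, lam) == pytest.approx(inc, abs=5e-2)

    @pytest.mark.parametrize(
        "mu, lam, pi",
        [(2, 4.6667, 0.3), (5, 0, 1.0), (9, 9, 0.5)],
    )
    def test_prevalence_from_rates(self, mu, lam, pi):
        assert prevalence_from_rates(mu, lam) == pytest.approx(pi, abs=1e-4)

    @pytest.mark.parametrize(
        "tau, mu, ratio", [(2, 18, 0.11), (20, 2, 10.0), (6, 6, 1.0)]
    )
    def test_interval_ratio(self, tau, mu, ratio):
        assert interval_ratio(tau, mu) == pytest.approx(ratio, abs=5e-3)

    @pytest.mark.parametrize(
        "fn, args",
        [
            (derive_interim_time, (0, 0.5)),
            (derive_interim_time, (2, 0.0)),
            (derive_interim_time, (2, 1.0)),
            (derive_interim_time, (2, 1.5)),
            (derive_incidence_per_minute, (-1, 3)),
            (prevalence_from_rates, (2, -1)),
            (interval_ratio, (0, 5)),
            (interval_ratio, (5, -2)),
        ],
    )
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    @given(
        mu=st.floats(0.1, 200),
        pi=st.floats(0.01, 0.99),
    )
    @settings(derandomize=True, max_examples=200)
    def test_interim_time_round_trips_through_prevalence(self, mu, pi):
        assert prevalence_from_rates(mu, derive_interim_time(mu, pi)) == pytest.approx(
            pi, abs=1e-9
        )

    def test_interim_time_decreasing_in_prevalence(self):
        grid = np.linspace(0.05, 0.95, 50)
        lams = [derive_interim_time(8.0, p) for p in grid]
        assert all(a > b for a, b in zip(lams, lams[1:]))


class TestStreamParameters:
    def test_from_prevalence_sets_consistent_interim(self):
        p = StreamParameters.from_prevalence(mu=8, pi=0.3, session_length=1200)
        assert p.pi == pytest.approx(0.3, abs=1e-12)
        assert p.lam == pytest.approx(8 * 0.7 / 0.3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu=0, lam=1, session_length=10),
            dict(mu=1, lam=-1, session_length=10),
            dict(mu=1, lam=1, session_length=0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StreamParameters(**kwargs)


class TestBehaviorStream:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BehaviorStream.from_events([(0, 5), (4, 6)], 10)  # overlap
        with pytest.raises(ValueError):
            BehaviorStream.from_events([(3, 2)], 10)  # reversed
        with pytest.raises(ValueError):
            BehaviorStream.from_events([(0, 11)], 10)  # beyond session

    def test_occupancy_membership_is_half_open(self):
        s = BehaviorStream.from_events([(1.0, 3.0)], 10.0)
        assert s.occupied_at([1.0, 2.9, 3.0, 0.5]).tolist() == [True, True, False, False]

    def test_event_in_progress_at_session_end_counts_at_final_instant(self):
        s = BehaviorStream.from_events([(8.0, 10.0)], 10.0)
        assert s.occupied_at([10.0]).tolist() == [True]


class TestSimulateStream:
    def test_same_seed_identical_different_seed_differs(self):
        p = StreamParameters.from_prevalence(5, 0.4, 600)
        a = simulate_stream(p, np.random.default_rng(7))
        b = simulate_stream(p, np.random.default_rng(7))
        c = simulate_stream(p, np.random.default_rng(8))
        assert np.array_equal(a.onsets, b.onsets)
        assert np.array_equal(a.offsets, b.offsets)
        assert not np.array_equal(a.onsets, c.onsets)

    def test_streams_satisfy_invariants(self, rng):
        p = StreamParameters.from_prevalence(3, 0.6, 120)
        for _ in range(200):
            simulate_stream(p, rng).validate()

    def test_tiny_session_has_at_most_one_truncated_event(self, rng):
        p = StreamParameters.from_prevalence(5, 0.5, 1e-6)
        for _ in range(50):
            s = simulate_stream(p, rng)
            assert s.n_events <= 1
            if s.n_events:
                assert s.offsets[0] <= 1e-6

    def test_equilibrium_occupancy_matches_prevalence(self, rng):
        # Long-run fraction of occupied time across many sessions is pi.
        p = StreamParameters.from_prevalence(mu=4, pi=0.35, session_length=300)
        fracs = np.array(
            [simulate_stream(p, rng).total_event_time() / 300 for _ in range(1000)]
        )
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.35) <= 3 * se

    def test_event_count_matches_renewal_rate(self, rng):
        # Expected onsets per session = L/(mu+lam): 600/(2+38) = 15.
        p = StreamParameters.from_prevalence(mu=2, pi=0.05, session_length=600)
        counts = np.array([simulate_stream(p, rng).n_events for _ in range(1000)])
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 15.0) <= 3 * se

    def test_degenerate_full_prevalence_stream(self):
        p = StreamParameters(mu=5, lam=0.0, session_length=60)
        s = simulate_stream(p, np.random.default_rng(0))
        assert s.events == [(0.0, 60.0)]
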