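"""Agent-level dynamics: production, learning, forgetting, death."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iapsim import (
    ALREADY_KNOWN,
    EASY,
    HARD,
    LEARNED_NOW,
    NEW,
    STILL_PENDING,
    AgentState,
    Convention,
    ConventionRegistry,
    LearningThresholds,
    draw_production,
    forgetting_sweep,
    kill,
    production_distribution,
    receive,
    seat_token,
)


def agent_with(counts):
    a = AgentState()
    for cid, t in counts.items():
        for _ in range(t):
            seat_token(a, cid)
    return a


class TestProductionDistribution:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({}, {NEW: Fraction(1)}),
            (
                {1: 3, 2: 1},
                {1: Fraction(3, 5), 2: Fraction(1, 5), NEW: Fraction(1, 5)},
            ),
            ({7: 1}, {7: Fraction(1, 2), NEW: Fraction(1, 2)}),
        ],
    )
    def test_examples(self, counts, expected):
        assert production_distribution(agent_with(counts)) == expected

    @given(
        st.dictionaries(
            st.integers(0, 50), st.integers(1, 40), min_size=0, max_size=12
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_sums_to_one_exactly(self, counts):
        dist = production_distribution(agent_with(counts))
        assert sum(dist.values()) == 1
        assert all(p > 0 for p in dist.values())

    def test_empirical_draw_frequencies(self):
        """Draws match t_c/(M+1) and 1/(M+1) within 3 binomial s.e."""
        registry = ConventionRegistry.from_dict({"classes": [EASY, EASY]})
        agent = agent_with({0: 3, 1: 1})
        rng = np.random.default_rng(42)
        trials = 100_000
        hits = {0: 0, 1: 0, NEW: 0}
        for _ in range(trials):
            cid = draw_production(agent, registry, rng)
            hits[cid if cid < 2 else NEW] += 1
            # keep the repertoire fixed: inventions enlarge the registry only
        for key, p in [(0, 0.6), (1, 0.2), (NEW, 0.2)]:
            se = math.sqrt(p * (1 - p) / trials)
            assert abs(hits[key] / trials - p) < 3 * se

    def test_invention_class_split(self):
        registry = ConventionRegistry(class_prob=0.5)
        rng = np.random.default_rng(7)
        empty = AgentState()
        n = 100_000
        for _ in range(n):
            draw_production(empty, registry, rng)  # M=0 forces invention
        easy = sum(registry.class_of(i) == EASY for i in range(len(registry)))
        se = math.sqrt(0.25 / n)
        assert len(registry) == n
        assert abs(easy / n - 0.5) < 3 * se

    def test_empty_agent_always_invents(self):
        registry = ConventionRegistry()
        rng = np.random.default_rng(0)
        ids = {draw_production(AgentState(), registry, rng) for _ in range(20)}
        assert ids == set(range(20))  # fresh monotone ids every time


class TestSeatAndReceive:
    def test_seat_examples(self):
        a = AgentState()
        seat_token(a, 5)
        assert a.token_counts == {5: 1} and a.M == 1
        seat_token(a, 5)
        assert a.token_counts == {5: 2} and a.M == 2
        seat_token(a, 9)
        assert a.M == 3 and len(a.token_counts) == 2
        assert a.ever_known == {5, 9}

    def test_easy_single_exposure(self):
        a = AgentState()
        out = receive(a, Convention(0, EASY), LearningThresholds())
        assert out == LEARNED_NOW
        assert a.token_counts == {0: 1} and a.M == 1

    def test_hard_two_exposures_pool(self):
        a = AgentState()
        thr = LearningThresholds()
        assert receive(a, Convention(3, HARD), thr) == STILL_PENDING
        assert a.pending_exposures == {3: 1} and a.M == 0
        assert receive(a, Convention(3, HARD), thr) == LEARNED_NOW
        assert a.pending_exposures == {} and a.token_counts == {3: 1}
        assert receive(a, Convention(3, HARD), thr) == ALREADY_KNOWN
        assert a.token_counts == {3: 2}

    def test_pending_and_tables_stay_disjoint(self):
        a = AgentState()
        thr = LearningThresholds(easy_exposures=1, hard_exposures=3)
        for _ in range(2):
            receive(a, Convention(1, HARD), thr)
        assert a.pending_exposures == {1: 2}
        receive(a, Convention(1, HARD), thr)
        a.check_invariants()
        assert 1 in a.token_counts and 1 not in a.pending_exposures

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="easy_exposures"):
            LearningThresholds(easy_exposures=3, hard_exposures=2)


class TestForgetting:
    def test_p_zero_is_identity(self):
        a = agent_with({0: 4, 1: 2})
        forgetting_sweep(a, 0.0, np.random.default_rng(0))
        assert a.token_counts == {0: 4, 1: 2} and a.M == 6

    def test_p_one_clears_tokens_not_history(self):
        a = agent_with({0: 4, 1: 2})
        forgetting_sweep(a, 1.0, np.random.default_rng(0))
        assert a.token_counts == {} and a.M == 0
        assert a.ever_known == {0, 1}

    def test_mean_removed_is_M_times_p(self):
        """Over many sweeps of an M=500 store at p=1/500, ~1 token goes."""
        p = 1 / 500
        rng = np.random.default_rng(11)
        sweeps = 10_000
        removed = 0
        for _ in range(sweeps):
            a = AgentState(token_counts={0: 250, 1: 250}, M=500, ever_known={0, 1})
            forgetting_sweep(a, p, rng)
            removed += 500 - a.M
        expect = 500 * p  # = 1.0
        se = math.sqrt(500 * p * (1 - p) / sweeps)
        assert abs(removed / sweeps - expect) < 3 * se

    def test_emptied_table_needs_full_relearning(self):
        a = agent_with({0: 1})
        forgetting_sweep(a, 1.0, np.random.default_rng(0))
        out = receive(a, Convention(0, HARD), LearningThresholds())
        assert out == STILL_PENDING  # exposure count restarted from zero


class TestKill:
    def test_blank_slate(self):
        a = agent_with({0: 3, 1: 1})
        a.pending_exposures[9] = 1
        kill(a)
        assert a.M == 0
        assert not a.token_counts and not a.pending_exposures and not a.ever_known

    def test_killed_agent_restarts_hard_learning(self):
        a = agent_with({4: 2})
        receive(a, Convention(5, HARD), LearningThresholds())
        kill(a)
        assert receive(a, Convention(5, HARD), LearningThresholds()) == STILL_PENDING
        assert a.pending_exposures == {5: 1}

    def test_killed_agent_always_invents(self):
        a = agent_with({0: 10})
        kill(a)
        assert production_distribution(a) == {NEW: Fraction(1)}


_ops = st.lists(
    st.one_of(
        st.tuples(st.just("seat"), st.integers(0, 5)),
        st.tuples(st.just("easy"), st.integers(0, 5)),
        st.tuples(st.just("hard"), st.integers(0, 5)),
        st.tuples(st.just("sweep"), st.floats(0.0, 1.0, allow_nan=False)),
        st.tuples(st.just("kill"), st.integers(0, 0)),
    ),
    max_size=40,
)


@given(_ops, st.integers(0, 2**31 - 1))
@settings(derandomize=True, max_examples=150)
def test_invariants_hold_under_arbitrary_op_sequences(ops, seed):
    """M == sum(t_c), tables/pending disjoint, tables subset of history."""
    rng = np.random.default_rng(seed)
    a = AgentState()
    thr = LearningThresholds()
    for op, arg in ops:
        if op == "seat":
            seat_token(a, arg)
        elif op == "easy":
            receive(a, Convention(arg, EASY), thr)
        elif op == "hard":
            receive(a, Convention(arg, HARD), thr)
        elif op == "sweep":
            forgetting_sweep(a, arg, rng)
        else:
            kill(a)
        a.check_invariants()


def _crp_oracle_tables(t, rng):
    """Plain concentration-1 Chinese restaurant process, tables after t seats."""
    counts = []
    total = 0
    for _ in range(t):
        r = rng.random() * (total + 1)
        if r >= total:
            counts.append(1)
        else:
            acc = 0
            for i, c in enumerate(counts):
                acc += c
                if r < acc:
                    counts[i] += 1
                    break
        total += 1
    return len(counts)


def test_isolated_agent_matches_crp_table_growth():
    """Distinct conventions after t solo productions follow H_t = sum 1/(i+1)."""
    t, reps = 50, 500
    rng = np.random.default_rng(123)
    impl = np.empty(reps)
    oracle = np.empty(reps)
    for r in range(reps):
        registry = ConventionRegistry(class_prob=0.5)
        a = AgentState()
        for _ in range(t):
            seat_token(a, draw_production(a, registry, rng))
        impl[r] = len(a.token_counts)
        oracle[r] = _crp_oracle_tables(t, rng)
    harmonic = sum(1 / (i + 1) for i in range(t))
    var = sum((1 / (i + 1)) * (1 - 1 / (i + 1)) for i in range(t))
    se = math.sqrt(var / reps)
    assert abs(impl.mean() - harmonic) < 3 * se
    assert abs(impl.mean() - oracle.mean()) < 3 * math.sqrt(2) * se


def test_registry_rejects_bad_class_prob_and_ids():
    with pytest.raises(ValueError):
        ConventionRegistry(class_prob=1.5)
    with pytest.raises(ValueError):
        Convention(-1, EASY)
    with pytest.raises(ValueError):
        Convention(0, "Medium")
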