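import itertools

import numpy as np
import pytest

from _oracles import gellermann_brute_ok, max_matching_exhaustive
from vocalearn.session_design import (
    GellermannCriteria,
    PoolEntry,
    StimulusPool,
    build_session,
    check_gellermann,
    generate_gellermann_order,
    max_matching_size,
    sample_duration_matched_pairs,
)


def _entries(durations, vtype, prefix):
    return [PoolEntry(f"{prefix}{i}", vtype, d) for i, d in enumerate(durations)]


class TestDurationPairs:
    def test_identical_durations_any_pairs(self):
        e1 = _entries([0.5] * 6, 1, "a")
        e2 = _entries([0.5] * 6, 2, "b")
        pairs = sample_duration_matched_pairs(e1, e2, 6, seed=0)
        assert len(pairs) == 6
        assert len({a for a, _ in pairs}) == 6 and len({b for _, b in pairs}) == 6

    def test_infeasible_reports_zero_matching(self):
        e1 = _entries([0.52, 0.54], 1, "a")
        e2 = _entries([0.48, 0.49], 2, "b")  # all gaps >= 0.02 s
        with pytest.raises(ValueError, match="maximum feasible matching is 0"):
            sample_duration_matched_pairs(e1, e2, 1, tolerance=0.01, seed=0)

    def test_known_maximum_matching_three(self):
        # feasibility graph: a0-{b0}, a1-{b0,b1}, a2-{b1,b2}, a3-{b2}; max matching 3
        e1 = _entries([0.100, 0.109, 0.127, 0.136], 1, "a")
        e2 = _entries([0.105, 0.118, 0.132], 2, "b")
        adj = np.abs(
            np.array([e.duration for e in e1])[:, None]
            - np.array([e.duration for e in e2])[None, :]
        ) < 0.01
        assert max_matching_exhaustive(adj) == 3
        assert max_matching_size(adj) == 3
        pairs = sample_duration_matched_pairs(e1, e2, 3, seed=5)
        assert len(pairs) == 3
        with pytest.raises(ValueError, match="maximum feasible matching is 3"):
            sample_duration_matched_pairs(e1, e2, 4, seed=5)

    def test_pairs_respect_tolerance_and_disjointness(self, rng):
        e1 = _entries(rng.uniform(0.3, 0.7, 30), 1, "a")
        e2 = _entries(rng.uniform(0.3, 0.7, 30), 2, "b")
        d1 = {e.id: e.duration for e in e1}
        d2 = {e.id: e.duration for e in e2}
        pairs = sample_duration_matched_pairs(e1, e2, 10, seed=3)
        assert len({a for a, _ in pairs}) == 10
        assert len({b for _, b in pairs}) == 10
        for a, b in pairs:
            assert abs(d1[a] - d2[b]) < 0.01

    def test_matching_agrees_with_exhaustive_oracle(self, rng):
        for _ in range(10):
            adj = rng.random((4, 4)) < 0.4
            assert max_matching_size(adj) == max_matching_exhaustive(adj)


class TestGellermannCheck:
    def test_long_run_fails(self):
        ok, rules = check_gellermann([1, 1, 1, 1, 2, 2, 2, 2, 1, 2])
        assert not ok and "max_run" in rules

    def test_strict_alternation_fails(self):
        ok, rules = check_gellermann([1, 2] * 5)
        assert not ok and "alternation_range" in rules

    def test_unequal_counts_fail(self):
        ok, rules = check_gellermann([1, 1, 2, 1, 1, 2, 1, 2, 1, 1])
        assert not ok and "equal_counts" in rules

    def test_odd_length_error(self):
        with pytest.raises(ValueError, match="even"):
            check_gellermann([1, 2, 1])

    def test_exhaustive_equality_with_brute_force(self):
        accepted = set()
        for seq in itertools.product([1, 2], repeat=10):
            if check_gellermann(list(seq))[0]:
                accepted.add(seq)
        brute = {s for s in itertools.product([1, 2], repeat=10) if gellermann_brute_ok(s)}
        assert accepted == brute
        assert len(accepted) > 0

    def test_rules_individually_toggleable(self):
        # balanced, balanced halves, alternation 4/9, but one run of four
        seq = [2, 2, 1, 1, 1, 1, 2, 2, 1, 2]
        ok, rules = check_gellermann(seq)
        assert not ok and rules == ["max_run"]
        ok, _ = check_gellermann(seq, GellermannCriteria(max_run=None))
        assert ok


class TestGellermannGenerate:
    def test_postconditions(self):
        seq = generate_gellermann_order(10, seed=1)
        assert len(seq) == 10
        assert seq.count(1) == seq.count(2) == 5
        assert check_gellermann(seq)[0]

    def test_seed_determinism(self):
        assert generate_gellermann_order(20, seed=9) == generate_gellermann_order(20, seed=9)

    def test_uniform_over_passing_set(self):
        passing = sorted(
            s for s in itertools.product([1, 2], repeat=10) if gellermann_brute_ok(s)
        )
        index = {s: i for i, s in enumerate(passing)}
        rng = np.random.default_rng(77)
        counts = np.zeros(len(passing))
        n_draws = 6000
        for _ in range(n_draws):
            counts[index[tuple(generate_gellermann_order(10, seed=rng))]] += 1
        from scipy.stats import chisquare

        stat, p = chisquare(counts)
        assert p > 0.01

    def test_unsatisfiable_criteria_error(self):
        # a run bound of 1 forces strict alternation, which the alternation band forbids
        crit = GellermannCriteria(max_run=1, alternation_range=(0.4, 0.6))
        with pytest.raises(RuntimeError):
            generate_gellermann_order(10, crit, seed=0, max_attempts=2000)


def _pool(n_trained=10, n_novel2=20, n_novel3=40, seed=0):
    rng = np.random.default_rng(seed)
    entries = []
    for vtype in (1, 2):
        for origin, count in [("trained", n_trained), ("novel_exp2", n_novel2), ("novel_exp3", n_novel3)]:
            for i in range(count):
                entries.append(
                    PoolEntry(f"{origin}-{vtype}-{i}", vtype, float(rng.uniform(0.3, 0.8)), origin)
                )
    return StimulusPool(entries)


class TestBuildSession:
    def test_exp1_fixed_multiset(self):
        pool = _pool()
        trained_ids = {e.id for e in pool.entries if e.origin == "trained"}
        p1 = build_session(1, pool, seed=1)
        p2 = build_session(1, pool, seed=2)
        assert {sid for sid, _ in p1.trials} == trained_ids
        assert {sid for sid, _ in p2.trials} == trained_ids
        assert len(p1.trials) == 20

    def test_exp2_composition(self):
        pool = _pool()
        plan = build_session(2, pool, seed=3)
        assert len(plan.trials) == 30
        ids = [sid for sid, _ in plan.trials]
        assert len(set(ids)) == 30  # no repeats within session
        per_type = {t: [sid for sid, tt in plan.trials if tt == t] for t in (1, 2)}
        for vtype in (1, 2):
            trained = [s for s in per_type[vtype] if s.startswith("trained")]
            novel = [s for s in per_type[vtype] if s.startswith("novel_exp2")]
            assert len(trained) == 5 and len(novel) == 10

    def test_exp2_novel_can_recur_across_sessions(self):
        pool = _pool(n_novel2=10)  # exactly 10 per type: every session reuses them
        ids1 = {s for s, _ in build_session(2, pool, seed=1).trials if s.startswith("novel")}
        ids2 = {s for s, _ in build_session(2, pool, seed=2).trials if s.startswith("novel")}
        assert ids1 == ids2  # forced overlap across sessions -> with replacement

    def test_exp3_global_no_replacement_and_capacity(self):
        pool = _pool(n_novel3=40)
        used = set()
        for s in range(4):  # 40 per type / 10 per session -> exactly 4 sessions
            plan = build_session(3, pool, seed=s)
            ids = {sid for sid, _ in plan.trials}
            assert not (ids & used)
            used |= ids
        with pytest.raises(ValueError, match="exhausted"):
            build_session(3, pool, seed=99)

    @pytest.mark.parametrize("exp", [1, 2, 3])
    def test_every_plan_passes_gellermann(self, exp):
        pool = _pool()
        for seed in range(3):
            plan = build_session(exp, pool, seed=seed)
            assert check_gellermann(plan.type_sequence)[0]
            counts = {t: plan.type_sequence.count(t) for t in (1, 2)}
            assert counts[1] == counts[2]

    def test_exp3_pool_disjointness_enforced(self):
        entries = [
            PoolEntry("x", 1, 0.5, "trained"),
            PoolEntry("x", 1, 0.5, "novel_exp3"),
        ]
        with pytest.raises(ValueError):
            StimulusPool(entries)
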