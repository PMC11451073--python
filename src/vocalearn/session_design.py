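"""Session construction for the three playback experiments.

A session is an ordered list of (stimulus id, vocal type) trials.  Stimuli
enter sessions as duration-matched type pairs (paired durations differ by
less than 10 ms, removing duration as a cue), the pools follow each
experiment's sampling rules (trained set reused; trained + resampled novel;
entirely novel, consumed once), and the presentation order is a Gellermann
pseudorandom series: balanced counts, bounded runs, balanced halves and a
bounded alternation rate, so that neither position habits nor
win-stay/lose-shift strategies pay off.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

__all__ = [
    "PoolEntry",
    "StimulusPool",
    "GellermannCriteria",
    "SessionPlan",
    "sample_duration_matched_pairs",
    "check_gellermann",
    "generate_gellermann_order",
    "build_session",
    "TRIALS_PER_SESSION",
]

#: Trials per session in each experiment: 20 trained / 10 trained + 20 novel / 20 novel.
TRIALS_PER_SESSION = {1: 20, 2: 30, 3: 20}


@dataclass(frozen=True)
class PoolEntry:
    id: str
    type: int  # 1 or 2
    duration: float  # s
    origin: str = "trained"  # trained | novel_exp2 | novel_exp3


@dataclass
class StimulusPool:
    """Labelled stimuli with per-entry usage bookkeeping.

    The experiment-3 pool must be disjoint from every other origin: those
    stimuli may never have been heard before and are consumed on use.
    """

    entries: list[PoolEntry]
    used_count: dict[str, int] = field(default_factory=dict)
    consumed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate stimulus ids in pool")
        exp3 = {e.id for e in self.entries if e.origin == "novel_exp3"}
        other = {e.id for e in self.entries if e.origin != "novel_exp3"}
        if exp3 & other:
            raise ValueError("experiment-3 stimuli must be disjoint from all other origins")

    def by(self, origin: str, vtype: int, exclude_consumed: bool = False) -> list[PoolEntry]:
        return [
            e
            for e in self.entries
            if e.origin == origin
            and e.type == vtype
            and not (exclude_consumed and e.id in self.consumed)
        ]

    def mark_used(self, ids: list[str], consume: bool = False) -> None:
        for sid in ids:
            self.used_count[sid] = self.used_count.get(sid, 0) + 1
            if consume:
                self.consumed.add(sid)


@dataclass(frozen=True)
class GellermannCriteria:
    """Toggleable constraints on a binary presentation order."""

    equal_counts: bool = True
    max_run: int | None = 3
    balanced_halves: bool = True
    halves_tolerance: int = 1
    alternation_range: tuple[float, float] | None = (0.4, 0.6)


@dataclass
class SessionPlan:
    experiment: int
    trials: list[tuple[str, int]]  # (stimulus id, type), presentation order
    seed: int

    @property
    def type_sequence(self) -> list[int]:
        return [t for _, t in self.trials]


# --------------------------------------------------------------------------
# Duration-matched pairing
# --------------------------------------------------------------------------


def _feasible(d1: np.ndarray, d2: np.ndarray, tolerance: float) -> np.ndarray:
    return np.abs(d1[:, None] - d2[None, :]) < tolerance


def max_matching_size(adj: np.ndarray) -> int:
    """Size of a maximum bipartite matching of a boolean adjacency matrix."""
    if not adj.any():
        return 0
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int(np.count_nonzero(match >= 0))


def sample_duration_matched_pairs(
    pool_type1: list[PoolEntry],
    pool_type2: list[PoolEntry],
    n_pairs: int,
    tolerance: float = 0.01,
    seed: int | np.random.Generator = 0,
    max_restarts: int = 200,
) -> list[tuple[str, str]]:
    """Draw disjoint cross-type pairs whose durations differ by < tolerance.

    Sampling is random-order greedy with restarts, so on loosely constrained
    instances every feasible completion is reachable and roughly equally
    likely.  Infeasible requests raise, reporting the exact maximum matching
    size of the feasibility graph.
    """
    if not pool_type1 or not pool_type2:
        raise ValueError("both pools must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d1 = np.array([e.duration for e in pool_type1])
    d2 = np.array([e.duration for e in pool_type2])
    adj = _feasible(d1, d2, tolerance)
    best = min(max_matching_size(adj), min(len(pool_type1), len(pool_type2)))
    if n_pairs > best:
        raise ValueError(
            f"cannot form {n_pairs} duration-matched pairs at tolerance {tolerance} s: "
            f"maximum feasible matching is {best}"
        )
    for _ in range(max_restarts):
        order = rng.permutation(len(pool_type1))
        taken2: set[int] = set()
        pairs: list[tuple[str, str]] = []
        for i in order:
            cands = [j for j in np.flatnonzero(adj[i]) if j not in taken2]
            if not cands:
                continue
            j = int(rng.choice(cands))
            taken2.add(j)
            pairs.append((pool_type1[i].id, pool_type2[j].id))
            if len(pairs) == n_pairs:
                return pairs
    raise RuntimeError(
        f"failed to realize a feasible {n_pairs}-pair matching after {max_restarts} "
        "randomized attempts (the instance is tightly constrained)"
    )


# --------------------------------------------------------------------------
# Gellermann series
# --------------------------------------------------------------------------


def check_gellermann(
    seq: list[int] | np.ndarray, criteria: GellermannCriteria = GellermannCriteria()
) -> tuple[bool, list[str]]:
    """Check a binary type sequence against the Gellermann constraints.

    Returns (passed, violated rule names).  Rules, each toggleable:
    equal_counts; max_run (no run of one type longer than the bound);
    balanced_halves (per-type counts in each half differ by <= tolerance);
    alternation_range (fraction of adjacent unequal pairs within the band).
    """
    s = np.asarray(seq)
    if s.size % 2:
        raise ValueError("Gellermann sequences must have even length")
    labels = np.unique(s)
    if labels.size > 2:
        raise ValueError(f"binary sequence expected, found labels {labels.tolist()}")
    violated: list[str] = []
    a = labels[0]
    n_a = int(np.count_nonzero(s == a))
    if criteria.equal_counts and (labels.size != 2 or n_a != s.size - n_a):
        violated.append("equal_counts")
    if criteria.max_run is not None:
        runs = [len(list(g)) for _, g in itertools.groupby(s.tolist())]
        if max(runs) > criteria.max_run:
            violated.append("max_run")
    if criteria.balanced_halves:
        half = s.size // 2
        for part in (s[:half], s[half:]):
            ca = int(np.count_nonzero(part == a))
            if abs(ca - (part.size - ca)) > criteria.halves_tolerance:
                violated.append("balanced_halves")
                break
    if criteria.alternation_range is not None and s.size > 1:
        frac = float(np.count_nonzero(s[1:] != s[:-1])) / (s.size - 1)
        lo, hi = criteria.alternation_range
        if not (lo <= frac <= hi):
            violated.append("alternation_range")
    return (not violated, violated)


def generate_gellermann_order(
    n_trials: int,
    criteria: GellermannCriteria = GellermannCriteria(),
    seed: int | np.random.Generator = 0,
    types: tuple[int, int] = (1, 2),
    max_attempts: int = 100_000,
) -> list[int]:
    """Uniform draw from the Gellermann-passing sequences of a given length.

    Rejection sampling: uniformly random balanced permutations are drawn until
    one passes, which is uniform over the passing set.  Reproducible from the
    seed; raises if the attempt budget is exhausted (unsatisfiable criteria).
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = np.array([types[0]] * (n_trials // 2) + [types[1]] * (n_trials // 2))
    for _ in range(max_attempts):
        cand = rng.permutation(base)
        ok, _violated = check_gellermann(cand, criteria)
        if ok:
            return cand.tolist()
    raise RuntimeError(
        f"no Gellermann-valid order of length {n_trials} found in {max_attempts} attempts; "
        "criteria may be unsatisfiable for this length"
    )


# --------------------------------------------------------------------------
# Session building
# --------------------------------------------------------------------------


def _draw(rng: np.random.Generator, entries: list[PoolEntry], k: int, what: str) -> list[PoolEntry]:
    if len(entries) < k:
        raise ValueError(
            f"pool exhausted: need {k} {what} stimuli, only {len(entries)} remain"
        )
    idx = rng.choice(len(entries), size=k, replace=False)
    return [entries[int(i)] for i in idx]


def build_session(
    exp: int,
    pool: StimulusPool,
    seed: int,
    criteria: GellermannCriteria = GellermannCriteria(),
) -> SessionPlan:
    """Assemble one session plan for experiment 1, 2 or 3.

    Experiment 1: the fixed 20 trained stimuli (10 per type), each once.
    Experiment 2: 5+5 trained drawn without replacement within the session,
    plus 10+10 novel drawn without replacement within the session but with
    replacement across sessions (a novel stimulus may recur in a later
    session).  Experiment 3: 10+10 entirely novel stimuli, consumed globally
    — no stimulus is ever presented twice across the whole experiment.
    Presentation order is a fresh Gellermann series.
    """
    if exp not in TRIALS_PER_SESSION:
        raise ValueError(f"experiment must be 1, 2 or 3, got {exp}")
    rng = np.random.default_rng(seed)
    per_type = TRIALS_PER_SESSION[exp] // 2
    chosen: dict[int, list[PoolEntry]] = {}
    if exp == 1:
        for vtype in (1, 2):
            trained = pool.by("trained", vtype)
            if len(trained) != 10:
                raise ValueError(
                    f"experiment 1 requires exactly 10 trained type-{vtype} stimuli, "
                    f"found {len(trained)}"
                )
            chosen[vtype] = list(trained)
    elif exp == 2:
        for vtype in (1, 2):
            chosen[vtype] = _draw(rng, pool.by("trained", vtype), 5, f"trained type-{vtype}")
            chosen[vtype] += _draw(
                rng, pool.by("novel_exp2", vtype), 10, f"novel type-{vtype}"
            )
    else:
        for vtype in (1, 2):
            avail = pool.by("novel_exp3", vtype, exclude_consumed=True)
            chosen[vtype] = _draw(rng, avail, per_type, f"unconsumed novel type-{vtype}")
    order = generate_gellermann_order(TRIALS_PER_SESSION[exp], criteria, seed=rng)
    queues = {vtype: iter(rng.permutation(len(chosen[vtype]))) for vtype in (1, 2)}
    trials = [(chosen[t][int(next(queues[t]))].id, int(t)) for t in order]
    pool.mark_used([sid for sid, _ in trials], consume=(exp == 3))
    return SessionPlan(experiment=exp, trials=trials, seed=seed)
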