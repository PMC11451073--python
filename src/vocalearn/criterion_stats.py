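"""Learning-criterion detection and its exact chance-level statistics.

The learning criterion (LC) used throughout the experiments is a run rule:
the task counts as learned after `run_required` consecutive sessions each
with at least `threshold` correct responses (default: four sessions at 80%).
Under the null hypothesis of random guessing, each session is an i.i.d.
Bernoulli trial with success probability q = P(Bin(n, 1/2) >= ceil(0.8 n)),
and the p-value for "reached the LC within H sessions" is the first-passage
probability of a success run of the required length within H trials,
computed exactly by dynamic programming over run-length states.

Also here: the exact categorical tests used on the behavioural counts
(binomial, Fisher), with scipy providing the machinery behind the module
surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import stats

from .io_formats import ExperimentLog, SessionRecord

__all__ = [
    "CriterionSpec",
    "CriterionResult",
    "session_success_probability",
    "session_success_probability_exact",
    "lc_first_passage_probability",
    "session_proportions",
    "detect_learning_criterion",
    "exact_binomial_test",
    "fisher_exact_test",
]


@dataclass(frozen=True)
class CriterionSpec:
    """Run-based learning criterion and its chance model.

    Defaults encode the published rule: 20-trial sessions, 80% correct,
    four consecutive sessions, guessing probability one half.
    """

    n_trials: int = 20
    threshold: float = 0.8
    run_required: int = 4
    chance_p: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must be in [0, 1]")
        if self.run_required < 1:
            raise ValueError("run_required must be >= 1")
        if not (0 < self.chance_p < 1):
            raise ValueError("chance_p must be in (0, 1)")

    @property
    def min_correct(self) -> int:
        """Correct responses needed to pass one session: ceil(threshold * n)."""
        return math.ceil(self.threshold * self.n_trials - 1e-12)


@dataclass
class CriterionResult:
    lc_session: int | None  # 1-based index of the session completing the run
    proportions: list[float]  # per-session fraction correct (valid sessions)
    chance_probability: float | None  # exact P(chance responder reaches LC by lc_session)
    spec: CriterionSpec = field(default_factory=CriterionSpec)


# --------------------------------------------------------------------------
# Exact chance-level probabilities
# --------------------------------------------------------------------------


def session_success_probability_exact(spec: CriterionSpec) -> Fraction:
    """Exact rational binomial tail P(X >= min_correct), X ~ Bin(n, p).

    For the p = 1/2 null this is (sum of tail binomial coefficients) / 2^n,
    an exact integer ratio; for other rational p the computation stays in
    rational arithmetic.
    """
    p = Fraction(spec.chance_p).limit_denominator(10**9)
    q = 1 - p
    n, c = spec.n_trials, spec.min_correct
    if c <= 0:
        return Fraction(1)
    return sum(
        Fraction(math.comb(n, k)) * p**k * q ** (n - k) for k in range(c, n + 1)
    )


def session_success_probability(spec: CriterionSpec) -> float:
    """P(one session meets the per-session criterion under chance), as float."""
    return float(session_success_probability_exact(spec))


def lc_first_passage_probability(spec: CriterionSpec, horizon: int) -> float:
    """Exact P(a run of `run_required` criterion sessions occurs within `horizon`).

    Sessions are i.i.d. Bernoulli(q) under the chance model.  Dynamic
    programming over the current run length 0..run_required-1 with an
    absorbing "reached" state; this is the exact p-value for observing the
    LC within the given number of sessions when the responder guesses.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    r = spec.run_required
    if horizon < r:
        return 0.0
    q = session_success_probability(spec)
    state = np.zeros(r)  # state[k]: P(current success-run length == k, not absorbed)
    state[0] = 1.0
    absorbed = 0.0
    for _ in range(horizon):
        new = np.zeros(r)
        new[0] = state.sum() * (1.0 - q)
        new[1:] = state[:-1] * q
        absorbed += state[-1] * q
        state = new
    return float(absorbed)


# --------------------------------------------------------------------------
# Scoring behavioural logs
# --------------------------------------------------------------------------


def _session_proportion(session: SessionRecord, include_repeats: bool) -> float:
    trials = session.trials if include_repeats else [t for t in session.trials if not t.repeat_flag]
    if not trials:
        raise ValueError(
            f"session {session.session_id} has no valid (first-presentation) trials"
        )
    return sum(t.correct for t in trials) / len(trials)


def session_proportions(log: ExperimentLog, include_repeats: bool = False) -> list[float]:
    """Per-session fraction correct over non-terminated sessions.

    Repeated-after-failure trials are excluded by default: only first
    presentations count toward the criterion.
    """
    sessions = log.valid_sessions()
    if not sessions:
        raise ValueError("log contains no non-terminated sessions")
    return [_session_proportion(s, include_repeats) for s in sessions]


def detect_learning_criterion(
    log: ExperimentLog,
    spec: CriterionSpec = CriterionSpec(),
    include_repeats: bool = False,
) -> CriterionResult:
    """Find the first session completing the required run of criterion sessions.

    Returns per-session proportions, the 1-based LC session index (None if
    never attained) and, when attained, the exact probability that a chance
    responder would have reached the LC within that many sessions.
    """
    props = session_proportions(log, include_repeats)
    run = 0
    lc_session = None
    for i, prop in enumerate(props, start=1):
        run = run + 1 if prop >= spec.threshold - 1e-12 else 0
        if run >= spec.run_required:
            lc_session = i
            break
    chance = lc_first_passage_probability(spec, lc_session) if lc_session else None
    return CriterionResult(
        lc_session=lc_session,
        proportions=props,
        chance_probability=chance,
        spec=spec,
    )


# --------------------------------------------------------------------------
# Exact categorical tests
# --------------------------------------------------------------------------


def exact_binomial_test(k: int, n: int, p0: float = 0.5, sided: str = "two") -> float:
    """Exact binomial test p-value.

    Two-sided p-values use the small-probability method: the sum over all
    outcomes whose null probability does not exceed that of the observed k.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    return float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)


def fisher_exact_test(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table.

    Returns (sample odds ratio ad/bc, two-sided exact p-value).  A zero
    off-diagonal margin makes the odds ratio infinite (returned as inf); a
    zero row/column margin leaves it undefined (nan).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin: odds ratio undefined")
    (a, b), (c, d) = t
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = float(a * d / (b * c))
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return odds, float(p)
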