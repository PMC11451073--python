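"""Independent brute-force oracles used to validate the package's statistics.

Everything here is deliberately naive — enumeration, nested model fits,
quadrature — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

# --------------------------------------------------------------------------
# Run first-passage by exhaustive enumeration over outcome sequences
# --------------------------------------------------------------------------


def first_passage_enumeration(q: float, run: int, horizon: int) -> float:
    """P(success run >= `run` within `horizon` Bernoulli(q) trials), by brute force."""
    if horizon <= 0:
        return 0.0
    run_mask_hits = 0.0
    total = 0.0
    for mask in range(2**horizon):
        m = mask
        for _ in range(run - 1):
            m &= m >> 1
        prob = q ** bin(mask).count("1") * (1 - q) ** (horizon - bin(mask).count("1"))
        total += prob
        if m:
            run_mask_hits += prob
    assert abs(total - 1.0) < 1e-9
    return run_mask_hits


# --------------------------------------------------------------------------
# Gellermann rules, written straight from the classical description
# --------------------------------------------------------------------------


def gellermann_brute_ok(
    seq: tuple[int, ...],
    max_run: int = 3,
    halves_tol: int = 1,
    alt_lo: float = 0.4,
    alt_hi: float = 0.6,
) -> bool:
    n = len(seq)
    if seq.count(1) != seq.count(2):
        return False
    longest = 1
    cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        longest = max(longest, cur)
    if longest > max_run:
        return False
    for half in (seq[: n // 2], seq[n // 2 :]):
        if abs(half.count(1) - half.count(2)) > halves_tol:
            return False
    alts = sum(1 for a, b in zip(seq, seq[1:]) if a != b) / (n - 1)
    return alt_lo <= alts <= alt_hi


# --------------------------------------------------------------------------
# Exact tests by enumeration
# --------------------------------------------------------------------------


def binomial_two_sided_enumeration(k: int, n: int, p0: float) -> float:
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    cutoff = pmf[k] * (1 + 1e-12)
    return min(1.0, sum(p for p in pmf if p <= cutoff))


def fisher_two_sided_enumeration(table) -> float:
    (a, b), (c, d) = np.asarray(table, int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def hyper(x: int) -> Fraction:
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = hyper(a)
    total = sum(
        (p for x in range(min(r1, c1) + 1) if (p := hyper(x)) <= p_obs * Fraction(10**12 + 1, 10**12)),
        Fraction(0),
    )
    return float(min(total, 1))


def mannwhitney_u_stat(x, y) -> float:
    """U for sample x with midrank ties, by direct pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


def mannwhitney_two_sided_enumeration(x, y) -> float:
    """Exact two-sided p by enumerating all label assignments (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    m = n1 * len(y) / 2.0
    u_obs = mannwhitney_u_stat(x, y)
    us = [
        mannwhitney_u_stat([pooled[i] for i in comb], [pooled[i] for i in range(len(pooled)) if i not in set(comb)])
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    extreme = sum(1 for u in us if abs(u - m) >= abs(u_obs - m) - 1e-12)
    return extreme / len(us)


# --------------------------------------------------------------------------
# Two-way ANOVA sums of squares by nested-model residual comparison
# --------------------------------------------------------------------------


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_type2_ss(a_labels, b_labels, y) -> dict[str, float]:
    """Type-II SS for factors A and B (plus interaction and residual)."""
    y = np.asarray(y, float)
    a_labels = np.asarray(a_labels)
    b_labels = np.asarray(b_labels)
    ones = np.ones((y.size, 1))

    def dummies(labels):
        levels = sorted(set(labels.tolist()))[1:]  # drop first level
        return np.column_stack([(labels == lv).astype(float) for lv in levels]) if levels else np.empty((y.size, 0))

    A = dummies(a_labels)
    B = dummies(b_labels)
    AB = np.column_stack([A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]) if A.shape[1] and B.shape[1] else np.empty((y.size, 0))
    rss_b = _rss(np.hstack([ones, B]), y)
    rss_a = _rss(np.hstack([ones, A]), y)
    rss_ab = _rss(np.hstack([ones, A, B]), y)
    rss_full = _rss(np.hstack([ones, A, B, AB]), y)
    return {
        "type": rss_b - rss_ab,
        "stage": rss_a - rss_ab,
        "type:stage": rss_ab - rss_full,
        "residual": rss_full,
    }


# --------------------------------------------------------------------------
# Mutual information of a Gaussian mixture by quadrature
# --------------------------------------------------------------------------


def gaussian_mi_quadrature(mu0: float, mu1: float, sigma: float = 1.0) -> float:
    """I(X; Y) in bits for Y ~ Bernoulli(1/2), X | Y=y ~ N(mu_y, sigma^2)."""
    lo = min(mu0, mu1) - 8 * sigma
    hi = max(mu0, mu1) + 8 * sigma
    x = np.linspace(lo, hi, 20001)

    def pdf(mu):
        return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))

    f0, f1 = pdf(mu0), pdf(mu1)
    fbar = 0.5 * (f0 + f1)
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = 0.5 * f0 * np.log2(f0 / fbar) + 0.5 * f1 * np.log2(f1 / fbar)
    integrand = np.nan_to_num(integrand)
    return float(np.trapezoid(integrand, x))


# --------------------------------------------------------------------------
# Maximum bipartite matching by exhaustive search (tiny instances)
# --------------------------------------------------------------------------


def max_matching_exhaustive(adj: np.ndarray) -> int:
    n1, n2 = adj.shape
    best = 0
    for perm in itertools.permutations(range(n2), min(n1, n2)):
        size = sum(1 for i, j in zip(range(n1), perm) if adj[i, j])
        best = max(best, size)
    # permutations of rows too, since rows beyond min() are skipped
    for rows in itertools.permutations(range(n1), min(n1, n2)):
        for perm in itertools.permutations(range(n2), min(n1, n2)):
            size = sum(1 for i, j in zip(rows, perm) if adj[i, j])
            best = max(best, size)
    return best
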