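"""Independent brute-force oracles used to check the statistical kernels.

These deliberately avoid scipy and the package's own code paths: the
hypergeometric tail is computed by exhaustive enumeration of every possible
gene list, the Poisson tails by direct pmf summation, and ancestor closures
by a plain recursive DFS.
"""

from __future__ import annotations

import math
from itertools import combinations


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating all C(N, n) lists over a genome of N genes of
    which the first K carry the term."""
    total = 0
    at_least = 0
    for subset in combinations(range(N), n):
        total += 1
        hits = sum(1 for g in subset if g < K)
        if hits >= k:
            at_least += 1
    return at_least / total


def poisson_upper_tail_by_summation(k: int, lam: float) -> float:
    """P(X >= k) = 1 - sum_{i<k} e^-lam lam^i / i!, accumulated in log space
    term by term."""
    if k <= 0:
        return 1.0
    acc = 0.0
    log_term = -lam  # log pmf at i=0
    for i in range(k):
        if i > 0:
            log_term += math.log(lam) - math.log(i)
        acc += math.exp(log_term)
    return max(0.0, 1.0 - acc)


def poisson_lower_tail_by_summation(k: int, lam: float) -> float:
    """P(X <= k) by direct pmf summation."""
    if k < 0:
        return 0.0
    acc = 0.0
    log_term = -lam
    for i in range(k + 1):
        if i > 0:
            log_term += math.log(lam) - math.log(i)
        acc += math.exp(log_term)
    return min(1.0, acc)


def closure_by_dfs(parents: dict[str, set[str]], term: str) -> set[str]:
    """Reflexive transitive closure upward via recursive DFS."""
    out: set[str] = set()

    def visit(t: str) -> None:
        if t in out:
            return
        out.add(t)
        for p in parents.get(t, ()):
            visit(p)

    visit(term)
    return out
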