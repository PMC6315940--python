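"""Independent brute-force oracles used by the test-suite and acceptance checks.

Everything here is written as a direct, unoptimized transcription of the
defining formulas -- linear-space products, double loops, exhaustive
enumeration -- deliberately sharing no code path with the package's
optimized implementations.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# Segment fitness, literal transcriptions
# ---------------------------------------------------------------------------

def rnabound_fitness_literal(S: np.ndarray, k: int, l: int, f: int) -> float:
    """Product of the three geometric means in linear space, then logged.

    ``S`` is the dense symmetric score table (0-based); ``k``, ``l`` are
    1-based inclusive.
    """
    n = S.shape[0]
    length = l - k + 1
    ibp = 1.0
    for m in range(k, l + 1):
        inner = 0.0
        for q in range(k, l + 1):
            inner += S[m - 1, q - 1]
        ibp *= inner ** (1.0 / length)
    obp = 1.0
    for m in range(k, l + 1):
        outer = 0.0
        for q in range(1, n + 1):
            if q < k or q > l:
                outer += S[m - 1, q - 1]
        term = 1.0 - outer
        if term <= 0.0:
            return NEG_INF
        obp *= term ** (1.0 / length)
    sbp = 1.0
    for m in range(k - f, k):
        spanning = 0.0
        for q in range(l + 1, l + f + 1):
            spanning += S[m - 1, q - 1]
        term = 1.0 - spanning
        if term <= 0.0:
            return NEG_INF
        sbp *= term ** (1.0 / f)
    fitness = ibp * obp * sbp
    if fitness <= 0.0:
        return NEG_INF
    return math.log(fitness)


def dotu_fitness_literal(P: np.ndarray, i: int, j: int, w1: float, w2: float) -> float:
    """Double-loop transcription of the comparator fitness on probabilities."""
    n = P.shape[0]
    inside = 0.0
    for x in range(i, j + 1):
        for y in range(x + 1, j + 1):
            inside += P[x - 1, y - 1]
    cross = 0.0
    for x in range(i, j + 1):
        for y in range(1, n + 1):
            if y < i or y > j:
                cross += P[x - 1, y - 1]
    return (w1 * inside - w2 * cross) / (j - i + 1)


def best_segment_literal(grid_fn, n: int, lo: int, hi: int):
    """Exhaustive argmax with the smallest-k-then-smallest-l tie-break.

    ``grid_fn(k, l)`` evaluates one segment; admissible range is
    ``lo <= k < l <= hi``.  Returns (u, v, score) or (None, None, -inf).
    """
    best = (None, None, NEG_INF)
    for k in range(lo, hi):
        for l in range(k + 1, hi + 1):
            score = grid_fn(k, l)
            if score > best[2]:
                best = (k, l, score)
    return best


# ---------------------------------------------------------------------------
# Nested-structure enumeration for the toy folder
# ---------------------------------------------------------------------------

_CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}


def enumerate_structures(seq: str, min_loop: int = 3):
    """All nested canonical structures of ``seq`` as frozensets of (i, j) pairs."""
    n = len(seq)

    def can(i: int, j: int) -> bool:
        return j - i > min_loop and seq[i - 1] + seq[j - 1] in _CANONICAL

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def structures(i: int, j: int):
        if i >= j:
            return [frozenset()]
        out = [s for s in structures(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if can(i, k):
                for left in structures(i + 1, k - 1):
                    for right in structures(k + 1, j):
                        out.append(left | right | {(i, k)})
        return out

    return structures(1, n)


def pair_probs_enumerated(seq: str, pair_energy: float, kT: float) -> np.ndarray:
    """Exact pair probabilities by summing Boltzmann weights over all structures."""
    w = math.exp(-pair_energy / kT)
    n = len(seq)
    total = 0.0
    mass = np.zeros((n + 1, n + 1))
    for struct in enumerate_structures(seq):
        weight = w ** len(struct)
        total += weight
        for (i, j) in struct:
            mass[i, j] += weight
    return mass / total


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum exact enumeration
# ---------------------------------------------------------------------------

def _midranks(values):
    order = sorted(range(len(values)), key=lambda t: values[t])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = r
        i = j + 1
    return ranks


def ranksum_exact_enum(x, y):
    """Two-sided exact p-value: P(|U - mu| >= |u_obs - mu|) over all splits."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = _midranks(pooled)
    const = n1 * (n1 + 1) / 2.0
    u_obs = sum(ranks[:n1]) - const
    mu = n1 * n2 / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[t] for t in combo) - const
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total
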