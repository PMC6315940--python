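"""Synthetic probability matrices, toy alignments, and a minimal Boltzmann folder.

Every other module is testable without downloads or external folding
binaries through three generators:

* :func:`plant_structure` builds a window matrix with one planted
  self-contained structure (single hairpin, cloverleaf, or an adjacent
  double hairpin reminiscent of H/ACA-box snoRNAs).  Besides the helix
  pairs, every structurally unpaired position inside the planted region
  receives a weak alternative pairing ("ensemble breathing"): real
  Boltzmann ensembles never leave loop positions with zero pairing mass,
  and the geometric-mean fitness relies on that.  Background noise pairs
  can be sprinkled anywhere at probabilities up to a ceiling.

* :func:`toy_fold` computes exact base-pair probabilities for a single
  sequence over the Boltzmann ensemble of nested structures in which every
  canonical pair contributes a constant weight ``w = exp(-E/kT)``
  (a Nussinov-style energy model, deliberately simpler than
  nearest-neighbor thermodynamics).

* :func:`mutate_alignment` derives homolog rows from a reference sequence
  with i.i.d. substitutions and jointly-mutated (compensatory) base pairs,
  emulating the covariation signal consensus folders exploit.

All generators are bit-reproducible for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .alignment import AlignmentWindow
from .bp_matrix import BasePairMatrix
from .errors import GeometryError, ParameterError

CANONICAL_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")
MIN_HAIRPIN_LOOP = 3
_ROW_CAP = 0.99  # planted + breathing mass per position stays below unit


@dataclass(frozen=True)
class SyntheticCase:
    """A generated matrix with its planted ground truth."""

    matrix: BasePairMatrix
    truth: tuple[int, int]
    layout: str
    stem_prob: float
    noise_prob: float
    seed: int
    helix_pairs: tuple[tuple[int, int], ...]
    pairs: tuple[tuple[int, int, float], ...]  # all planted entries (i, j, p)


# ---------------------------------------------------------------------------
# Planted geometries
# ---------------------------------------------------------------------------

def _hairpin_pairs(s: int, e: int) -> list[tuple[int, int]]:
    """Helix pairs of a contiguous stem-loop on [s, e] (loop of 3-4 nt)."""
    L = e - s + 1
    if L < 9:
        raise GeometryError(f"hairpin needs >= 9 nt (stem 3 + loop 3), got {L}")
    stem = (L - MIN_HAIRPIN_LOOP) // 2
    return [(s + i, e - i) for i in range(stem)]


def _cloverleaf_pairs(s: int, e: int) -> list[tuple[int, int]]:
    """Acceptor-like closing stem plus three hairpin arms (tRNA-shaped)."""
    L = e - s + 1
    if L < 43:
        raise GeometryError(f"cloverleaf needs >= 43 nt, got {L}")
    acceptor = 7
    pairs = [(s + i, e - i) for i in range(acceptor)]
    lo, hi = s + acceptor, e - acceptor
    interior = hi - lo + 1
    arm_len = (interior - 2) // 3  # two 1-nt linkers between arms
    arm1 = (lo, lo + arm_len - 1)
    arm2 = (arm1[1] + 2, arm1[1] + 1 + arm_len)
    arm3 = (arm2[1] + 2, hi)
    for a, b in (arm1, arm2, arm3):
        pairs += _hairpin_pairs(a, b)
    return pairs


def _double_hairpin_pairs(s: int, e: int) -> list[tuple[int, int]]:
    """Two adjacent stem-loops separated by a short hinge (H/ACA-like)."""
    L = e - s + 1
    if L < 21:
        raise GeometryError(f"double hairpin needs >= 21 nt, got {L}")
    hinge = 3
    L1 = (L - hinge) // 2
    pairs = _hairpin_pairs(s, s + L1 - 1)
    pairs += _hairpin_pairs(s + L1 + hinge, e)
    return pairs


_LAYOUTS = {
    "hairpin": _hairpin_pairs,
    "cloverleaf": _cloverleaf_pairs,
    "double_hairpin": _double_hairpin_pairs,
}


def _breathing_pairs(
    s: int,
    e: int,
    helix_pairs: Sequence[tuple[int, int]],
    stem_prob: float,
    alt_prob: float,
) -> list[tuple[int, int, float]]:
    """Weak alternative pairings covering every structurally unpaired position.

    Partners are chosen inside [s, e]: preferentially another unpaired
    position as far away as possible (which links the arms of branched
    layouts, as consensus ensembles of adjacent stems do), otherwise a helix
    position with spare capacity.  Per-position mass stays below 1.
    """
    row_mass: dict[int, float] = {}
    for i, j in helix_pairs:
        row_mass[i] = row_mass.get(i, 0.0) + stem_prob
        row_mass[j] = row_mass.get(j, 0.0) + stem_prob
    paired = set(row_mass)
    unpaired = [u for u in range(s, e + 1) if u not in paired]
    extra: list[tuple[int, int, float]] = []
    for u in unpaired:
        if row_mass.get(u, 0.0) >= alt_prob * 0.999:
            continue  # already covered as someone's partner
        cands = [
            v
            for v in unpaired
            if v != u
            and abs(v - u) >= 4
            and row_mass.get(v, 0.0) + alt_prob <= _ROW_CAP
        ]
        if cands:
            v = max(cands, key=lambda t: (abs(t - u), -t))
            pr = min(alt_prob, _ROW_CAP - row_mass.get(u, 0.0))
        else:
            helix_cands = [v for v in sorted(paired) if abs(v - u) >= 4]
            if not helix_cands:
                continue
            v = min(helix_cands, key=lambda t: (row_mass.get(t, 0.0), abs(t - u)))
            pr = min(
                alt_prob,
                _ROW_CAP - row_mass.get(v, 0.0),
                _ROW_CAP - row_mass.get(u, 0.0),
            )
        if pr <= 0.0:
            continue
        a, b = (u, v) if u < v else (v, u)
        extra.append((a, b, pr))
        row_mass[u] = row_mass.get(u, 0.0) + pr
        row_mass[v] = row_mass.get(v, 0.0) + pr
    return extra


def plant_structure(
    n: int,
    layout: str,
    start: int,
    end: int,
    stem_prob: float = 0.95,
    noise_prob: float = 0.0,
    seed: int = 0,
    alt_prob: float = 0.05,
    noise_density: float = 0.5,
) -> SyntheticCase:
    """Generate a window matrix with one planted structure on [start, end].

    ``stem_prob`` is the probability assigned to every planted helix pair;
    ``alt_prob`` the probability of the breathing pairs that cover unpaired
    interior positions; ``noise_prob`` the ceiling for uniformly drawn
    background pairs (about ``noise_density * n`` of them, anywhere in the
    window at separation >= 4).  Deterministic for a fixed seed.
    """
    if not (1 <= start < end <= n):
        raise ParameterError(f"need 1 <= start < end <= n, got ({start}, {end}), n={n}")
    if not (0.0 < stem_prob <= 1.0):
        raise ParameterError("stem_prob must lie in (0, 1]")
    if noise_prob < 0.0 or noise_prob >= stem_prob:
        raise ParameterError("noise_prob must satisfy 0 <= noise_prob < stem_prob")
    if layout not in _LAYOUTS:
        raise ParameterError(f"unknown layout {layout!r}; expected one of {sorted(_LAYOUTS)}")
    helix = _LAYOUTS[layout](start, end)
    planted: list[tuple[int, int, float]] = [(i, j, stem_prob) for i, j in helix]
    planted += _breathing_pairs(start, end, helix, stem_prob, alt_prob)

    probs = {(i, j): p for i, j, p in planted}
    row_mass: dict[int, float] = {}
    for (i, j), p in probs.items():
        row_mass[i] = row_mass.get(i, 0.0) + p
        row_mass[j] = row_mass.get(j, 0.0) + p

    rng = np.random.default_rng(seed)
    if noise_prob > 0.0:
        for _ in range(int(round(noise_density * n))):
            i = int(rng.integers(1, n - 3))
            j = int(rng.integers(i + 4, n + 1))
            if (i, j) in probs:
                continue
            p = float(rng.uniform(0.0, noise_prob))
            if row_mass.get(i, 0.0) + p > _ROW_CAP or row_mass.get(j, 0.0) + p > _ROW_CAP:
                continue
            probs[(i, j)] = p
            row_mass[i] = row_mass.get(i, 0.0) + p
            row_mass[j] = row_mass.get(j, 0.0) + p

    matrix = BasePairMatrix(n, probs, source="synthetic")
    return SyntheticCase(
        matrix=matrix,
        truth=(start, end),
        layout=layout,
        stem_prob=stem_prob,
        noise_prob=noise_prob,
        seed=seed,
        helix_pairs=tuple(helix),
        pairs=tuple(sorted(planted)),
    )


# ---------------------------------------------------------------------------
# Toy Boltzmann folder
# ---------------------------------------------------------------------------

def _canonical_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    can = np.zeros((n + 2, n + 2), dtype=bool)
    for i in range(1, n + 1):
        for j in range(i + 4, n + 1):
            if seq[i - 1] + seq[j - 1] in CANONICAL_PAIRS:
                can[i, j] = True
    return can


def toy_fold(seq: str, pair_energy: float = -2.0, kT: float = 1.0) -> BasePairMatrix:
    """Exact pair probabilities over the Boltzmann ensemble of nested structures.

    Every canonical pair (Watson-Crick or GU wobble, hairpin loop >= 3)
    contributes a weight ``w = exp(-pair_energy / kT)``; a structure of k
    pairs has weight ``w**k``.  Probabilities come from the inside-outside
    recursions and satisfy ``sum_j p(i, j) <= 1`` exactly.  Intended for
    short windows (the outside pass is quartic in the length).
    """
    seq = seq.upper().replace("T", "U")
    if any(c not in "ACGU" for c in seq):
        bad = sorted(set(seq) - set("ACGU"))
        raise ParameterError(f"sequence contains non-ACGU characters: {bad}")
    n = len(seq)
    if n < 5:
        raise ParameterError(f"sequence must be at least 5 nt, got {n}")
    if kT <= 0:
        raise ParameterError("temperature scale kT must be positive")
    w = math.exp(-pair_energy / kT)
    can = _canonical_matrix(seq)

    # inside: Z[i, j] = partition function of subsequence [i..j]; empty = 1
    Z = np.ones((n + 2, n + 2))
    for d in range(4, n):
        for i in range(1, n - d + 1):
            j = i + d
            tot = Z[i + 1, j]
            ks = np.nonzero(can[i, i + 4 : j + 1])[0] + i + 4
            if ks.size:
                tot += w * float(np.dot(Z[i + 1, ks - 1], Z[ks + 1, j]))
            Z[i, j] = tot

    Ztot = Z[1, n]
    # outside: H[i, j] = PF of everything exterior to a forced pair (i, j),
    # decomposed by the innermost enclosing pair
    H = np.zeros((n + 2, n + 2))
    P = np.zeros((n + 2, n + 2))
    for d in range(n - 1, 3, -1):
        for i in range(1, n - d + 1):
            j = i + d
            if not can[i, j]:
                continue
            val = Z[1, i - 1] * Z[j + 1, n]
            if i > 1 and j < n:
                ps = np.arange(1, i)
                qs = np.arange(j + 1, n + 1)
                block = can[np.ix_(ps, qs)] * H[np.ix_(ps, qs)]
                if block.any():
                    zl = Z[ps + 1, i - 1]
                    zr = Z[j + 1, qs - 1]
                    val += w * float(zl @ block @ zr)
            H[i, j] = val
            P[i, j] = (w * Z[i + 1, j - 1]) * val / Ztot

    probs = {
        (i, j): float(P[i, j])
        for i in range(1, n + 1)
        for j in range(i + 4, n + 1)
        if P[i, j] > 0.0
    }
    return BasePairMatrix(n, probs, source="toyfold", labels=list(seq))


# ---------------------------------------------------------------------------
# Alignment generation
# ---------------------------------------------------------------------------

def mutate_alignment(
    seq: str,
    planted_pairs: Sequence[tuple[int, int]],
    rows: int,
    sub_rate: float = 0.1,
    compensatory_rate: float = 0.8,
    seed: int = 0,
    reference_id: str = "ref",
) -> AlignmentWindow:
    """Derive an alignment of ``rows`` sequences from a reference.

    The reference row is kept verbatim.  In every other row, each planted
    pair is jointly replaced by a different canonical pair with probability
    ``compensatory_rate`` (a compensatory change preserving the helix), and
    every position outside planted pairs is substituted i.i.d. with
    probability ``sub_rate``.  No gaps are introduced.
    """
    for name, rate in (("sub_rate", sub_rate), ("compensatory_rate", compensatory_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ParameterError(f"{name} must lie in [0, 1], got {rate}")
    if rows < 1:
        raise ParameterError("rows must be >= 1")
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    paired_pos = set()
    for a, b in planted_pairs:
        if not (1 <= a < b <= n):
            raise ParameterError(f"planted pair ({a}, {b}) outside sequence 1..{n}")
        paired_pos.update((a, b))
    rng = np.random.default_rng(seed)
    bases = "ACGU"
    out_rows = [(reference_id, seq)]
    for r in range(1, rows):
        chars = list(seq)
        for a, b in planted_pairs:
            if rng.random() < compensatory_rate:
                current = chars[a - 1] + chars[b - 1]
                options = [pq for pq in CANONICAL_PAIRS if pq != current]
                pick = options[int(rng.integers(len(options)))]
                chars[a - 1], chars[b - 1] = pick[0], pick[1]
        for pos in range(1, n + 1):
            if pos in paired_pos:
                continue
            if rng.random() < sub_rate:
                others = [c for c in bases if c != chars[pos - 1]]
                chars[pos - 1] = others[int(rng.integers(3))]
        out_rows.append((f"seq{r}", "".join(chars)))
    return AlignmentWindow(rows=out_rows, reference_id=reference_id)


def expected_pairwise_identity(sub_rate: float, rows: int) -> float:
    """Expected MPI of :func:`mutate_alignment` output without planted pairs.

    Reference-vs-mutant pairs match with probability ``1 - s``; two
    independently mutated rows with ``(1-s)^2 + s^2/3``.
    """
    if rows < 2:
        raise ParameterError("rows must be >= 2")
    s = sub_rate
    ref_pairs = rows - 1
    mut_pairs = (rows - 1) * (rows - 2) // 2
    m_ref = 1.0 - s
    m_mut = (1.0 - s) ** 2 + (s**2) / 3.0
    return (ref_pairs * m_ref + mut_pairs * m_mut) / (ref_pairs + mut_pairs)


def sub_rate_for_identity(target_mpi: float, rows: int) -> float:
    """Substitution rate whose expected MPI equals ``target_mpi``."""
    if not (0.3 < target_mpi < 1.0):
        raise ParameterError("target MPI must lie in (0.3, 1.0)")
    return float(
        brentq(lambda s: expected_pairwise_identity(s, rows) - target_mpi, 1e-9, 0.9)
    )


def hairpin_sequence(
    n: int, start: int, end: int, seed: int = 0
) -> tuple[str, list[tuple[int, int]]]:
    """A window sequence whose only structure is a hairpin on [start, end].

    The helix arms are exact reverse complements drawn from G/C, the loop is
    cytidine (so loop positions retain weak in-stem pairing alternatives),
    and everything else, including the flanks, is adenosine -- with no U in
    the window, no pairing mass can leave the planted region.  Returns the
    sequence and the planted helix pairs -- suitable input for
    :func:`toy_fold` followed by the boundary search.
    """
    if not (1 <= start < end <= n):
        raise ParameterError(f"need 1 <= start < end <= n, got ({start}, {end}), n={n}")
    pairs = _hairpin_pairs(start, end)
    rng = np.random.default_rng(seed)
    comp = {"G": "C", "C": "G"}
    chars = ["A"] * n
    for u in range(start - 1, end):
        chars[u] = "C"
    for i, j in pairs:
        left = "GC"[int(rng.integers(2))]
        chars[i - 1] = left
        chars[j - 1] = comp[left]
    return "".join(chars), pairs
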