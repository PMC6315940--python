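"""Segment fitness functions and the exhaustive boundary search.

Two fitness functions over candidate segments ``[k, l]`` of a window
``[1, n]`` are implemented:

* the RNAbound fitness -- the product of three geometric means computed from
  base-pair *scores*: the paired mass inside the segment (``Ibp``), the
  unpaired mass of inside positions towards the outside (``O_nbp``), and the
  unpaired mass between the two flanking margins of length ``f`` spanning the
  segment (``S_nbp``).  Arithmetic is carried out in log space; a vanishing
  inside term or a clamped penalty term yields ``-inf``, which simply
  disqualifies the segment.

* the Dotu et al. comparator -- a weighted difference of raw pairing
  probabilities inside the segment versus probabilities crossing its
  boundary, normalized by segment length.

The exhaustive scanners evaluate every admissible segment with incremental
row sums (O(n^3) for RNAbound, O(n^2) for the comparator) and report the
argmax with a fixed deterministic tie-break: smallest start, then smallest
end.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .bp_matrix import BasePairMatrix, ScoreParams, ScoreTable, score_matrix
from .errors import ContractError, ParameterError

NEG_INF = float("-inf")


@dataclass(frozen=True)
class DotuParams:
    """Weights of the comparator fitness (recommended: w1=2, w2=1)."""

    w1: float = 2.0
    w2: float = 1.0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ParameterError("comparator weights must be >= 0")


@dataclass(frozen=True)
class Segment:
    """A candidate boundary pair [k, l] (1-based inclusive) with its score."""

    k: int
    l: int
    score: float
    components: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.k >= self.l:
            raise ContractError(f"segment requires k < l, got [{self.k}, {self.l}]")


@dataclass(frozen=True)
class BoundaryPrediction:
    """Predicted boundaries [u, v] together with method metadata.

    ``status`` is ``"ok"`` for a regular prediction and ``"no_structure"``
    when every admissible segment was disqualified (RNAbound only), in which
    case ``u``/``v`` are None.  ``frame`` tags the coordinate system
    (alignment columns vs. ungapped reference positions) so that downstream
    evaluation can refuse to mix frames.
    """

    u: Optional[int]
    v: Optional[int]
    method: str
    params: Union[ScoreParams, DotuParams]
    score: float
    components: Optional[tuple[float, float, float]] = None
    status: str = "ok"
    frame: str = "window"


# ---------------------------------------------------------------------------
# Single-segment fitness evaluations
# ---------------------------------------------------------------------------

def _check_rnabound_range(n: int, k: int, l: int, f: int) -> None:
    if not (1 + f <= k < l <= n - f):
        raise ContractError(
            f"segment [{k}, {l}] outside admissible range 1+f <= k < l <= n-f "
            f"(n={n}, f={f})"
        )


def _mean_log(values: np.ndarray) -> float:
    """Mean of elementwise logs; -inf as soon as any value is <= 0."""
    if values.size == 0:
        return 0.0
    if np.any(values <= 0.0):
        return NEG_INF
    return float(np.log(values).mean())


def rnabound_fitness(
    scores: Union[ScoreTable, np.ndarray],
    k: int,
    l: int,
    params: ScoreParams,
    probs: Optional[Union[BasePairMatrix, np.ndarray]] = None,
    return_components: bool = False,
):
    """Log-fitness of segment ``[k, l]``: ``log Ibp + log O_nbp + log S_nbp``.

    ``scores`` is the score table of the window.  When
    ``params.transform_outside`` is False the two penalty terms are computed
    from raw probabilities, which must then be supplied via ``probs``.
    """
    S = scores.to_dense() if isinstance(scores, ScoreTable) else np.asarray(scores, float)
    n = S.shape[0]
    f = params.f
    _check_rnabound_range(n, k, l, f)
    if params.transform_outside:
        Q = S
    else:
        if probs is None:
            raise ParameterError(
                "transform_outside=False requires the raw probability matrix"
            )
        Q = probs.to_dense() if isinstance(probs, BasePairMatrix) else np.asarray(probs, float)

    a, b = k - 1, l - 1  # 0-based inclusive
    inside_rows = S[a : b + 1, a : b + 1].sum(axis=1)
    log_ibp = _mean_log(inside_rows)
    out_rows = Q[a : b + 1].sum(axis=1) - Q[a : b + 1, a : b + 1].sum(axis=1)
    log_obp = _mean_log(1.0 - out_rows)
    if f > 0:
        cross = Q[a - f : a, b + 1 : b + 1 + f].sum(axis=1)
        log_sbp = _mean_log(1.0 - cross)
    else:
        log_sbp = 0.0
    total = log_ibp + log_obp + log_sbp
    if return_components:
        return total, (log_ibp, log_obp, log_sbp)
    return total


def dotu_fitness(
    m: Union[BasePairMatrix, np.ndarray],
    i: int,
    j: int,
    params: DotuParams = DotuParams(),
) -> float:
    """Comparator fitness of segment ``[i, j]`` on raw probabilities.

    ``(w1 * sum_{i<=x<y<=j} p_xy - w2 * sum_{x in [i,j], y not in [i,j]} p_xy)
    / (j - i + 1)``.
    """
    P = m.to_dense() if isinstance(m, BasePairMatrix) else np.asarray(m, float)
    n = P.shape[0]
    if not (1 <= i < j <= n):
        raise ContractError(f"segment requires 1 <= i < j <= n, got [{i}, {j}] with n={n}")
    a, b = i - 1, j - 1
    block = P[a : b + 1, a : b + 1].sum()
    inside = block / 2.0
    cross = P[a : b + 1].sum() - block
    return float((params.w1 * inside - params.w2 * cross) / (j - i + 1))


# ---------------------------------------------------------------------------
# Exhaustive scanners
# ---------------------------------------------------------------------------

def _scan_rnabound(S: np.ndarray, f: int, Q: Optional[np.ndarray] = None) -> np.ndarray:
    """Score every admissible segment; returns F[a, b] (0-based, -inf default).

    ``Q`` carries the matrix used by the penalty terms (defaults to the score
    table itself).  Row cumulative sums make each segment O(n); positions
    with zero total score mass can never satisfy the inside term, which
    prunes the segment range sharply on sparse inputs.
    """
    n = S.shape[0]
    if Q is None:
        Q = S
    CS = np.zeros((n, n + 1))
    np.cumsum(S, axis=1, out=CS[:, 1:])
    CQ = CS if Q is S else np.zeros((n, n + 1))
    if Q is not S:
        np.cumsum(Q, axis=1, out=CQ[:, 1:])
    row_tot_s = CS[:, n]
    row_tot_q = CQ[:, n]

    # first position at or after a with zero total score mass: any segment
    # containing such a position has a vanishing inside term.
    nz = row_tot_s > 0.0
    next_zero = np.full(n + 1, n)
    for a in range(n - 1, -1, -1):
        next_zero[a] = a if not nz[a] else next_zero[a + 1]

    F = np.full((n, n), NEG_INF)
    b_cap = n - f - 1  # 0-based upper bound for l = n - f
    for a in range(f, b_cap):
        b_max = min(b_cap, next_zero[a] - 1)
        for b in range(a + 1, b_max + 1):
            in_rows = CS[a : b + 1, b + 1] - CS[a : b + 1, a]
            if np.any(in_rows <= 0.0):
                continue
            out_rows = row_tot_q[a : b + 1] - (CQ[a : b + 1, b + 1] - CQ[a : b + 1, a])
            t_out = 1.0 - out_rows
            if np.any(t_out <= 0.0):
                continue
            if f > 0:
                cross = CQ[a - f : a, b + 1 + f] - CQ[a - f : a, b + 1]
                t_span = 1.0 - cross
                if np.any(t_span <= 0.0):
                    continue
                log_sbp = np.log(t_span).mean()
            else:
                log_sbp = 0.0
            F[a, b] = np.log(in_rows).mean() + np.log(t_out).mean() + log_sbp
    return F


def _scan_dotu(P: np.ndarray, w1: float, w2: float) -> np.ndarray:
    """Comparator fitness of every segment via 2-D prefix sums; O(n^2)."""
    n = P.shape[0]
    SAT = np.zeros((n + 1, n + 1))
    SAT[1:, 1:] = P.cumsum(axis=0).cumsum(axis=1)
    rowcum = np.concatenate([[0.0], P.sum(axis=1).cumsum()])
    a = np.arange(n)[:, None]
    b = np.arange(n)[None, :]
    block = SAT[b + 1, b + 1] - SAT[a, b + 1] - SAT[b + 1, a] + SAT[a, a]
    inside = block / 2.0
    cross = (rowcum[b + 1] - rowcum[a]) - block
    with np.errstate(invalid="ignore"):
        F = (w1 * inside - w2 * cross) / (b - a + 1)
    F = np.where(a < b, F, NEG_INF)
    return F


def _argmax_first(F: np.ndarray) -> tuple[int, int, float]:
    """Row-major argmax = smallest k, then smallest l among ties."""
    idx = int(np.argmax(F))
    a, b = divmod(idx, F.shape[1])
    return a, b, float(F[a, b])


def _resolve_params(method: str, params):
    if method == "rnabound":
        if params is None:
            return ScoreParams()
        if not isinstance(params, ScoreParams):
            raise ParameterError("rnabound method requires ScoreParams")
        return params
    if method == "dotu":
        if params is None:
            return DotuParams()
        if not isinstance(params, DotuParams):
            raise ParameterError("dotu method requires DotuParams")
        return params
    raise ParameterError(f"unknown method {method!r}; expected 'rnabound' or 'dotu'")


def _score_grid(m: BasePairMatrix, method: str, params) -> np.ndarray:
    if method == "rnabound":
        if m.n < 2 * params.f + 2:
            raise ParameterError(
                f"window of {m.n} nt too short for flanking margin f={params.f}; "
                f"need n >= {2 * params.f + 2}"
            )
        S = score_matrix(m, params).to_dense()
        Q = None if params.transform_outside else m.to_dense()
        return _scan_rnabound(S, params.f, Q)
    if m.n < 2:
        raise ParameterError("comparator search requires n >= 2")
    return _scan_dotu(m.to_dense(), params.w1, params.w2)


def find_boundaries(
    m: BasePairMatrix,
    method: str = "rnabound",
    params: Optional[Union[ScoreParams, DotuParams]] = None,
    frame: str = "window",
) -> BoundaryPrediction:
    """Exact argmax of the chosen fitness over all admissible segments.

    Returns a :class:`BoundaryPrediction`; for the RNAbound fitness, if every
    segment is disqualified (all ``-inf``), the result carries status
    ``"no_structure"`` and no coordinates.
    """
    params = _resolve_params(method, params)
    F = _score_grid(m, method, params)
    a, b, best = _argmax_first(F)
    if best == NEG_INF:
        return BoundaryPrediction(
            u=None, v=None, method=method, params=params, score=NEG_INF,
            status="no_structure", frame=frame,
        )
    u, v = a + 1, b + 1
    components = None
    if method == "rnabound":
        st = score_matrix(m, params)
        _, components = rnabound_fitness(
            st, u, v, params, probs=m, return_components=True
        )
    return BoundaryPrediction(
        u=u, v=v, method=method, params=params, score=best,
        components=components, frame=frame,
    )


def suboptimal_segments(
    m: BasePairMatrix,
    method: str = "rnabound",
    params: Optional[Union[ScoreParams, DotuParams]] = None,
    min_gap: int = 1,
    max_segments: Optional[int] = None,
) -> list[Segment]:
    """Greedy extraction of non-overlapping high-fitness segments.

    Repeatedly takes the highest-scoring admissible segment that keeps a gap
    of at least ``min_gap - 1`` free positions to every already selected
    segment (``min_gap=1`` means strict non-overlap).  Stops when remaining
    candidates are disqualified (``-inf``, RNAbound) or non-positive
    (comparator).
    """
    if min_gap < 1:
        raise ParameterError("min_gap must be >= 1")
    params = _resolve_params(method, params)
    F = _score_grid(m, method, params)
    n = F.shape[0]
    aa, bb = np.nonzero(np.isfinite(F) if method == "rnabound" else (F > 0.0))
    if aa.size == 0:
        return []
    vals = F[aa, bb]
    order = np.lexsort((bb, aa, -vals))
    chosen: list[Segment] = []
    st = score_matrix(m, params) if method == "rnabound" else None
    pad = min_gap - 1
    for idx in order:
        if max_segments is not None and len(chosen) >= max_segments:
            break
        k, l = int(aa[idx]) + 1, int(bb[idx]) + 1
        if any(not (l + pad < seg.k or k - pad > seg.l) for seg in chosen):
            continue
        components = None
        if method == "rnabound":
            _, components = rnabound_fitness(
                st, k, l, params, probs=m, return_components=True
            )
        chosen.append(Segment(k=k, l=l, score=float(vals[idx]), components=components))
    return chosen
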