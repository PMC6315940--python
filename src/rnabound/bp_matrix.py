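"""Base-pairing probability matrices: container, I/O dialects, score transform.

A :class:`BasePairMatrix` holds the equilibrium probability ``p(m, n)`` that
positions ``m`` and ``n`` of a sequence (or alignment) window are paired in the
Boltzmann ensemble.  Storage is sparse: absent entries are zero.  All public
coordinates are 1-based inclusive.

Three text dialects are supported:

* RNAfold PostScript dot plots (``*_dp.ps``), whose ``ubox`` records store the
  *square root* of the pairing probability;
* plain whitespace-delimited ``n x n`` matrices (the shape consensus folders
  such as PETfold emit), optionally with ``#`` comment lines;
* a 3-column sparse text format ``i j p`` with an ``# n=<N>`` size pragma.

The score transform :func:`bp_score` converts a probability into a log-odds
score against a null model of random pairing (``p0``), normalized to ``[0, 1]``.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional, Union

import numpy as np

from .errors import ContractError, MatrixParseError, ParameterError

ROW_SUM_TOL = 1e-6
_VALUE_TOL = 1e-9

TextSource = Union[str, IO[str]]


def _read_text(stream: TextSource) -> str:
    if hasattr(stream, "read"):
        return stream.read()  # type: ignore[union-attr]
    return stream  # already a string


def _canon(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the base-pair score transform and the boundary search.

    Parameters
    ----------
    p0 : float
        Null-model probability of a random pairing.  Probabilities at or
        below ``p0`` score zero.
    f : int
        Flanking-margin length in nucleotides checked for spanning pairs
        up- and downstream of a candidate segment.
    transform_outside : bool
        If True (default) the score transform is applied in every term of
        the segment fitness, including the outside/spanning penalty terms.
        If False the penalty terms consume raw probabilities and only the
        inside term is score-transformed.  Both readings are defensible;
        the default keeps one consistent kernel.
    """

    p0: float = 0.0005
    f: int = 10
    transform_outside: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise ParameterError(f"p0 must lie strictly in (0, 1), got {self.p0}")
        if self.f < 0:
            raise ParameterError(f"flanking margin f must be >= 0, got {self.f}")


class BasePairMatrix:
    """Symmetric sparse matrix of base-pairing probabilities.

    Invariants enforced at construction: symmetry (stored upper-triangular),
    values in ``[0, 1]``, zero diagonal, and per-position pairing mass
    ``sum_n p(m, n) <= 1`` (violating rows are rescaled with a warning,
    tolerating slightly off third-party outputs).
    """

    __slots__ = ("n", "probs", "source", "labels")

    def __init__(
        self,
        n: int,
        probs: Optional[Mapping[tuple[int, int], float]] = None,
        source: str = "synthetic",
        labels: Optional[list[str]] = None,
    ) -> None:
        if n < 1:
            raise ParameterError(f"matrix size must be >= 1, got {n}")
        if labels is not None and len(labels) != n:
            raise ParameterError("labels must have one entry per position")
        store: dict[tuple[int, int], float] = {}
        for (i, j), p in (probs or {}).items():
            if not (1 <= i <= n and 1 <= j <= n):
                raise ParameterError(f"pair position out of range 1..{n}: ({i}, {j})")
            if i == j:
                if p != 0.0:
                    raise ParameterError(f"diagonal entry ({i},{i}) must be zero")
                continue
            if p < -_VALUE_TOL or p > 1.0 + _VALUE_TOL:
                raise ParameterError(f"probability outside [0, 1] at ({i},{j}): {p}")
            if p <= 0.0:
                continue
            key = _canon(i, j)
            prev = store.get(key)
            if prev is not None and abs(prev - p) > _VALUE_TOL:
                raise ParameterError(f"conflicting values for pair {key}")
            store[key] = min(float(p), 1.0)
        self.n = int(n)
        self.probs = store
        self.source = source
        self.labels = list(labels) if labels is not None else None
        self._clamp_row_sums()

    def _clamp_row_sums(self) -> None:
        rs = np.zeros(self.n + 1)
        for (i, j), p in self.probs.items():
            rs[i] += p
            rs[j] += p
        bad = rs > 1.0 + ROW_SUM_TOL
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} position(s) carry pairing mass > 1; "
                "rescaling the offending rows",
                RuntimeWarning,
                stacklevel=3,
            )
            factor = np.ones(self.n + 1)
            factor[bad] = 1.0 / rs[bad]
            for key in self.probs:
                i, j = key
                self.probs[key] *= min(factor[i], factor[j])

    # -- accessors ---------------------------------------------------------
    def p(self, i: int, j: int) -> float:
        """Pairing probability of positions ``i`` and ``j`` (1-based)."""
        if i == j:
            return 0.0
        return self.probs.get(_canon(i, j), 0.0)

    def items(self) -> Iterator[tuple[tuple[int, int], float]]:
        return iter(self.probs.items())

    @property
    def nnz(self) -> int:
        return len(self.probs)

    def row_sums(self) -> np.ndarray:
        """Total pairing mass per position, 0-based array of length ``n``."""
        rs = np.zeros(self.n)
        for (i, j), p in self.probs.items():
            rs[i - 1] += p
            rs[j - 1] += p
        return rs

    def to_dense(self) -> np.ndarray:
        """Full symmetric ``(n, n)`` array, 0-based indexing."""
        arr = np.zeros((self.n, self.n))
        for (i, j), p in self.probs.items():
            arr[i - 1, j - 1] = p
            arr[j - 1, i - 1] = p
        return arr

    @classmethod
    def from_dense(
        cls,
        arr: np.ndarray,
        source: str = "synthetic",
        labels: Optional[list[str]] = None,
    ) -> "BasePairMatrix":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ParameterError(f"expected a square matrix, got shape {arr.shape}")
        n = arr.shape[0]
        iu, ju = np.nonzero(np.triu(arr, k=1))
        probs = {(int(i) + 1, int(j) + 1): float(arr[i, j]) for i, j in zip(iu, ju)}
        return cls(n, probs, source=source, labels=labels)

    def allclose(self, other: "BasePairMatrix", tol: float = 1e-9) -> bool:
        if self.n != other.n:
            return False
        keys = set(self.probs) | set(other.probs)
        return all(abs(self.probs.get(k, 0.0) - other.probs.get(k, 0.0)) <= tol for k in keys)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BasePairMatrix(n={self.n}, nnz={self.nnz}, source={self.source!r})"


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

_UBOX_RE = re.compile(r"^\s*(\S+)\s+(\S+)\s+(\S+)\s+ubox\s*$")


def parse_dotplot_ps(stream: TextSource) -> BasePairMatrix:
    """Parse an RNAfold PostScript dot plot (``*_dp.ps``).

    Only the ``ubox`` record grammar and the ``/sequence`` block are
    interpreted; ``lbox`` (MFE structure) records and all other PostScript
    are ignored.  Each ``i j v ubox`` line stores ``v = sqrt(p_ij)``, so
    probabilities are recovered by squaring.
    """
    text = _read_text(stream)
    probs: dict[tuple[int, int], float] = {}
    seq_parts: list[str] = []
    in_seq = False
    max_idx = 0
    for ln, line in enumerate(text.splitlines(), start=1):
        if in_seq:
            s = line.strip()
            if s.startswith(")"):
                in_seq = False
            else:
                seq_parts.append(s.rstrip("\\"))
            continue
        stripped = line.lstrip()
        if stripped.startswith("/sequence"):
            in_seq = True
            if "(" in stripped:
                tail = stripped.split("(", 1)[1].strip()
                if tail.startswith(")"):
                    in_seq = False
                else:
                    seq_parts.append(tail.rstrip("\\"))
            continue
        m = _UBOX_RE.match(line)
        if m is None:
            continue
        try:
            i, j, v = int(m.group(1)), int(m.group(2)), float(m.group(3))
        except ValueError as exc:
            raise MatrixParseError(
                f"line {ln}: malformed ubox record {line.strip()!r}"
            ) from exc
        if i >= j:
            raise MatrixParseError(f"line {ln}: ubox record requires i < j, got ({i}, {j})")
        if v < 0.0 or v > 1.0 + _VALUE_TOL:
            raise MatrixParseError(f"line {ln}: sqrt-probability {v} outside [0, 1]")
        probs[(i, j)] = min(v, 1.0) ** 2
        max_idx = max(max_idx, j)
    sequence = "".join(seq_parts)
    n = len(sequence) if sequence else max_idx
    if n == 0:
        raise MatrixParseError("no ubox records and no /sequence block found")
    if max_idx > n:
        raise MatrixParseError(
            f"ubox index {max_idx} exceeds sequence length {n} from /sequence block"
        )
    labels = list(sequence) if sequence else None
    return BasePairMatrix(n, probs, source="dotplot-ps", labels=labels)


def parse_tabular(stream: TextSource) -> BasePairMatrix:
    """Parse a whitespace-delimited ``n x n`` probability matrix.

    Lines starting with ``#`` or ``%`` are comments.  Asymmetric input
    (beyond 1e-6) is symmetrized by the elementwise maximum with a warning;
    the diagonal is forced to zero.
    """
    text = _read_text(stream)
    rows: list[tuple[int, list[float]]] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#") or s.startswith("%"):
            continue
        try:
            vals = [float(t) for t in s.split()]
        except ValueError as exc:
            raise MatrixParseError(f"line {ln}: non-numeric matrix entry") from exc
        rows.append((ln, vals))
    if not rows:
        raise MatrixParseError("no numeric rows found")
    n = len(rows)
    for ln, vals in rows:
        if len(vals) != n:
            raise MatrixParseError(
                f"line {ln}: expected {n} columns for a {n}x{n} matrix, got {len(vals)}"
            )
    arr = np.array([vals for _, vals in rows], dtype=float)
    if arr.min() < -ROW_SUM_TOL or arr.max() > 1.0 + ROW_SUM_TOL:
        raise MatrixParseError(
            f"matrix values outside [0, 1]: min={arr.min():g}, max={arr.max():g}"
        )
    arr = np.clip(arr, 0.0, 1.0)
    if np.abs(arr - arr.T).max() > 1e-6:
        warnings.warn(
            "asymmetric probability matrix; symmetrizing by elementwise maximum",
            RuntimeWarning,
            stacklevel=2,
        )
    arr = np.maximum(arr, arr.T)
    np.fill_diagonal(arr, 0.0)
    return BasePairMatrix.from_dense(arr, source="tabular")


_SPARSE_N_RE = re.compile(r"^#\s*n\s*=\s*(\d+)\s*$")


def parse_sparse(stream: TextSource) -> BasePairMatrix:
    """Parse 3-column sparse text: one ``i j p`` record per line.

    An ``# n=<N>`` pragma fixes the matrix size; otherwise the largest index
    seen is used.
    """
    text = _read_text(stream)
    n_pragma: Optional[int] = None
    probs: dict[tuple[int, int], float] = {}
    max_idx = 0
    for ln, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            m = _SPARSE_N_RE.match(s)
            if m:
                n_pragma = int(m.group(1))
            continue
        parts = s.split()
        if len(parts) != 3:
            raise MatrixParseError(f"line {ln}: expected 'i j p', got {s!r}")
        try:
            i, j, p = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise MatrixParseError(f"line {ln}: non-numeric sparse record") from exc
        if i == j:
            raise MatrixParseError(f"line {ln}: diagonal entry ({i},{j}) not allowed")
        if p < 0.0 or p > 1.0 + _VALUE_TOL:
            raise MatrixParseError(f"line {ln}: probability {p} outside [0, 1]")
        probs[_canon(i, j)] = p
        max_idx = max(max_idx, i, j)
    n = n_pragma if n_pragma is not None else max_idx
    if n == 0:
        raise MatrixParseError("empty sparse matrix with no size pragma")
    return BasePairMatrix(n, probs, source="sparse")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_sparse(m: BasePairMatrix, stream: Optional[IO[str]] = None) -> str:
    lines = [f"# n={m.n}"]
    for (i, j) in sorted(m.probs):
        lines.append(f"{i} {j} {m.probs[(i, j)]:.12g}")
    out = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(out)
    return out


def write_tabular(m: BasePairMatrix, stream: Optional[IO[str]] = None) -> str:
    arr = m.to_dense()
    lines = [f"# {m.n}x{m.n} base-pair probability matrix"]
    for row in arr:
        lines.append(" ".join(f"{v:.12g}" for v in row))
    out = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(out)
    return out


def write_dotplot_ps(
    m: BasePairMatrix,
    stream: Optional[IO[str]] = None,
    sequence: Optional[str] = None,
) -> str:
    """Write a minimal RNAfold-style dot plot (ubox records, sqrt dialect)."""
    if sequence is None:
        if m.labels is not None and all(len(c) == 1 for c in m.labels):
            sequence = "".join(m.labels)
        else:
            sequence = "N" * m.n
    if len(sequence) != m.n:
        raise ParameterError("sequence length must match matrix size")
    lines = [
        "%!PS-Adobe-3.0 EPSF-3.0",
        "%%Title: RNA Dot Plot",
        "/sequence { (\\",
        sequence + "\\",
        ") } def",
        "%start of base pair probability data",
    ]
    for (i, j) in sorted(m.probs):
        lines.append(f"{i} {j} {math.sqrt(m.probs[(i, j)]):.12g} ubox")
    lines.append("showpage")
    out = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(out)
    return out


# ---------------------------------------------------------------------------
# Score transform
# ---------------------------------------------------------------------------

def bp_score(p, params: ScoreParams):
    """Log-odds base-pair score against the random-pairing null model.

    ``score = max(0, log(p / p0) / log(1 / p0))`` -- zero at or below the
    null probability ``p0``, one at ``p = 1``, monotone nondecreasing in
    between.  Accepts scalars or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0 + _VALUE_TOL):
        raise ContractError("probabilities must lie in [0, 1]")
    denom = math.log(1.0 / params.p0)
    with np.errstate(divide="ignore"):
        s = np.log(np.clip(arr, 0.0, 1.0) / params.p0) / denom
    s = np.where(arr <= params.p0, 0.0, np.minimum(s, 1.0))
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(s)
    return s


@dataclass
class ScoreTable:
    """Sparse symmetric table of base-pair scores (same shape as its matrix)."""

    n: int
    scores: dict[tuple[int, int], float] = field(default_factory=dict)

    def s(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        return self.scores.get(_canon(i, j), 0.0)

    @property
    def nnz(self) -> int:
        return len(self.scores)

    def to_dense(self) -> np.ndarray:
        arr = np.zeros((self.n, self.n))
        for (i, j), v in self.scores.items():
            arr[i - 1, j - 1] = v
            arr[j - 1, i - 1] = v
        return arr


def score_matrix(m: BasePairMatrix, params: ScoreParams) -> ScoreTable:
    """Elementwise :func:`bp_score`; entries at or below ``p0`` are dropped."""
    scores = {
        key: bp_score(p, params) for key, p in m.items() if p > params.p0
    }
    return ScoreTable(n=m.n, scores=scores)
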