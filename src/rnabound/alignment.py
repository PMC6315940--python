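"""Alignment windows: quality filters, pairwise identity, coordinate maps.

The quality gates mirror a common benchmark protocol for consensus folding:
rows that are mostly gaps are dropped, at least three sequences must remain,
and the mean pairwise sequence identity (MPI) must fall in a band where
sequence-based alignments are both informative (>= 60%) and non-redundant
(< 95%).

Identity convention: gap-vs-base counts as a mismatch, gap-vs-gap is
excluded from the denominator.  The alternative (excluding gap-vs-base as
well) is available through a switch.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Optional, Union

import numpy as np
from Bio import AlignIO

from .errors import ContractError, ParameterError

GAP = "-"
_ALPHABET = set("ACGUN-")


def _normalize(seq: str) -> str:
    """Uppercase, DNA thymine to uracil, dot gaps to dashes."""
    return seq.upper().replace(".", GAP).replace("T", "U")


@dataclass
class AlignmentWindow:
    """A slice of a multiple sequence alignment with a designated reference row.

    ``rows`` are ``(sequence id, gapped sequence)`` pairs over a shared column
    count; boundary coordinates found on alignment columns are reported in the
    ungapped coordinates of the reference row.
    """

    rows: list[tuple[str, str]]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ParameterError("alignment must contain at least one row")
        self.rows = [(rid, _normalize(seq)) for rid, seq in self.rows]
        ncols = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != ncols:
                raise ParameterError(f"row {rid!r} length {len(seq)} != {ncols}")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ParameterError(f"row {rid!r} contains invalid characters {bad}")
        if self.reference_id not in {rid for rid, _ in self.rows}:
            raise ParameterError(f"reference row {self.reference_id!r} not present")

    @property
    def columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def reference(self) -> str:
        return next(seq for rid, seq in self.rows if rid == self.reference_id)

    def gap_fraction(self, row_id: str) -> float:
        seq = next(seq for rid, seq in self.rows if rid == row_id)
        return seq.count(GAP) / self.columns

    @classmethod
    def from_file(
        cls,
        source: Union[str, IO[str]],
        fmt: str = "fasta",
        reference_id: Optional[str] = None,
    ) -> "AlignmentWindow":
        """Read an aligned FASTA or Clustal file; first row is the default reference."""
        if isinstance(source, str):
            with open(source) as handle:
                aln = AlignIO.read(handle, fmt)
        else:
            aln = AlignIO.read(source, fmt)
        rows = [(rec.id, str(rec.seq)) for rec in aln]
        return cls(rows=rows, reference_id=reference_id or rows[0][0])

    def to_fasta(self) -> str:
        return "".join(f">{rid}\n{seq}\n" for rid, seq in self.rows)


@dataclass(frozen=True)
class FilterResult:
    """Outcome of :func:`filter_alignment` with the filter that fired on rejection."""

    passed: bool
    alignment: Optional[AlignmentWindow]
    reason: Optional[str] = None
    removed_ids: tuple[str, ...] = ()
    mpi: Optional[float] = None


def filter_alignment(
    a: AlignmentWindow,
    max_gap_frac: float = 0.75,
    min_rows: int = 3,
    mpi_min: float = 0.60,
    mpi_max: float = 0.95,
) -> FilterResult:
    """Apply the alignment quality gates in order.

    1. rows with a gap fraction above ``max_gap_frac`` are removed (the
       reference row triggers outright rejection instead);
    2. at least ``min_rows`` rows must remain;
    3. the mean pairwise identity must satisfy ``mpi_min <= MPI < mpi_max``.
    """
    if a.gap_fraction(a.reference_id) > max_gap_frac:
        return FilterResult(False, None, reason="reference_gap_fraction")
    kept, removed = [], []
    for rid, seq in a.rows:
        if rid != a.reference_id and seq.count(GAP) / a.columns > max_gap_frac:
            removed.append(rid)
        else:
            kept.append((rid, seq))
    filtered = AlignmentWindow(rows=kept, reference_id=a.reference_id)
    if filtered.n_rows < min_rows:
        return FilterResult(
            False, None, reason="min_rows", removed_ids=tuple(removed)
        )
    mpi = mean_pairwise_identity(filtered)
    if mpi < mpi_min:
        return FilterResult(False, None, reason="mpi_low", removed_ids=tuple(removed), mpi=mpi)
    if mpi >= mpi_max:
        return FilterResult(False, None, reason="mpi_high", removed_ids=tuple(removed), mpi=mpi)
    return FilterResult(True, filtered, removed_ids=tuple(removed), mpi=mpi)


def _encoded(a: AlignmentWindow) -> np.ndarray:
    return np.array([list(seq) for _, seq in a.rows])


def mean_pairwise_identity(
    a: AlignmentWindow,
    per_column: bool = False,
    count_gap_base: bool = True,
    max_col_gap_frac: float = 0.25,
):
    """Mean pairwise sequence identity, as a scalar or a per-column profile.

    For each row pair, identity = matching positions / compared positions;
    gap-vs-gap positions are never compared, gap-vs-base counts as a mismatch
    unless ``count_gap_base`` is False (then it is excluded from the
    denominator as well).

    In per-column mode, columns where more than ``max_col_gap_frac`` of the
    rows are gaps, and columns where the reference row has a gap, are ignored
    (returned as NaN); each retained column reports the fraction of matching
    row pairs among the pairs compared in that column.
    """
    if a.n_rows < 2:
        raise ContractError("pairwise identity requires at least two rows")
    X = _encoded(a)
    gaps = X == GAP
    n_rows, n_cols = X.shape

    if not per_column:
        idents = []
        for r in range(n_rows):
            for s in range(r + 1, n_rows):
                both_gap = gaps[r] & gaps[s]
                if count_gap_base:
                    compared = ~both_gap
                else:
                    compared = ~(gaps[r] | gaps[s])
                denom = int(compared.sum())
                if denom == 0:
                    continue
                matches = int(((X[r] == X[s]) & ~gaps[r] & ~gaps[s] & compared).sum())
                idents.append(matches / denom)
        if not idents:
            raise ContractError("no comparable positions in any row pair")
        return float(np.mean(idents))

    ref_gaps = np.array(list(a.reference)) == GAP
    col_gap_frac = gaps.mean(axis=0)
    keep = (col_gap_frac <= max_col_gap_frac) & ~ref_gaps
    match_count = np.zeros(n_cols)
    valid_count = np.zeros(n_cols)
    for r in range(n_rows):
        for s in range(r + 1, n_rows):
            both_gap = gaps[r] & gaps[s]
            if count_gap_base:
                compared = ~both_gap
            else:
                compared = ~(gaps[r] | gaps[s])
            match_count += ((X[r] == X[s]) & ~gaps[r] & ~gaps[s] & compared)
            valid_count += compared
    profile = np.full(n_cols, np.nan)
    ok = keep & (valid_count > 0)
    profile[ok] = match_count[ok] / valid_count[ok]
    return profile


# ---------------------------------------------------------------------------
# Column <-> reference coordinate maps
# ---------------------------------------------------------------------------

def columns_to_reference(
    a: AlignmentWindow, u: int, v: int
) -> Optional[tuple[int, int]]:
    """Map alignment columns ``[u, v]`` to ungapped reference positions.

    If column ``u`` is a reference gap the start snaps to the next reference
    base; symmetrically the end snaps to the previous one.  Returns None when
    no reference base lies inside ``[u, v]``.
    """
    ref = a.reference
    if not (1 <= u <= v <= a.columns):
        raise ContractError(
            f"columns [{u}, {v}] out of range 1..{a.columns}"
        )
    nongap = np.array([c != GAP for c in ref])
    cum = np.concatenate([[0], np.cumsum(nongap)])  # cum[c] = bases in cols 1..c
    start = int(cum[u]) if nongap[u - 1] else int(cum[u]) + 1
    end = int(cum[v])
    total = int(cum[-1])
    if start > end or start > total or end < 1:
        return None
    return start, end


def reference_to_columns(a: AlignmentWindow, start: int, end: int) -> tuple[int, int]:
    """Inverse map: ungapped reference positions to their alignment columns."""
    ref = a.reference
    positions = [c + 1 for c, ch in enumerate(ref) if ch != GAP]
    total = len(positions)
    if not (1 <= start <= end <= total):
        raise ContractError(
            f"reference positions [{start}, {end}] out of range 1..{total}"
        )
    return positions[start - 1], positions[end - 1]
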