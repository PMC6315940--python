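"""Boundary-difference metric, per-family summaries, method comparison.

The signed boundary differences are ``left = actual_start - predicted_start``
and ``right = predicted_end - actual_end``: positive means the predicted
boundary lies outside the annotation (excess), negative inside (short), zero
exact.  Left and right are always reported separately -- summing or taking
absolute values would lose which side failed and in which direction.

Two prediction sets are compared side-wise with the two-sided Wilcoxon
rank-sum (Mann-Whitney) test: exact enumeration of the permutation
distribution for small samples, tie-corrected normal approximation for
large ones.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .boundary import BoundaryPrediction
from .errors import ContractError, ParameterError

_EXACT_MAX_COMBINATIONS = 200_000
COORD_PRAGMA = "# coords=1-based-inclusive"


@dataclass(frozen=True)
class AnnotatedRegion:
    """Annotated (actual) boundaries of a structured region, 1-based inclusive."""

    id: str
    actual_start: int
    actual_end: int
    family: str = "unknown"
    shape_group: str = "single_hairpin"
    frame: str = "window"

    def __post_init__(self) -> None:
        if self.actual_start >= self.actual_end:
            raise ParameterError(
                f"{self.id}: actual_start must be < actual_end, "
                f"got ({self.actual_start}, {self.actual_end})"
            )


@dataclass(frozen=True)
class BoundaryDiff:
    """Signed left/right offsets between predicted and annotated boundaries."""

    left: int
    right: int


def boundary_difference(
    actual: AnnotatedRegion,
    predicted: Union[BoundaryPrediction, tuple[int, int]],
) -> BoundaryDiff:
    """Exact integer boundary differences between a prediction and its annotation.

    Both coordinates must live in the same frame (alignment columns or
    ungapped reference positions); a mismatch of the frame tags is refused.
    """
    if isinstance(predicted, BoundaryPrediction):
        if predicted.status != "ok":
            raise ContractError(
                f"prediction for {actual.id} has status {predicted.status!r}"
            )
        if predicted.frame != actual.frame:
            raise ContractError(
                f"coordinate frame mismatch: annotation in {actual.frame!r}, "
                f"prediction in {predicted.frame!r}"
            )
        u, v = predicted.u, predicted.v
    else:
        u, v = predicted
    return BoundaryDiff(left=actual.actual_start - u, right=v - actual.actual_end)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(
    records: Union[pd.DataFrame, Iterable[dict]],
    by: Sequence[str] = ("family",),
    small_n: int = 5,
) -> pd.DataFrame:
    """Median/IQR table of left and right differences per group.

    ``records`` carries one row per evaluated region with at least ``left``
    and ``right`` columns plus the grouping keys.  Groups with
    ``n <= small_n`` are flagged (medians over a handful of entries are
    fragile).
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty:
        raise ContractError("summarize requires at least one record")
    for col in ("left", "right", *by):
        if col not in df.columns:
            raise ParameterError(f"records lack required column {col!r}")

    def _iqr(x: pd.Series) -> float:
        return float(np.percentile(x, 75) - np.percentile(x, 25))

    grouped = df.groupby(list(by), sort=True)
    out = grouped.agg(
        n=("left", "size"),
        median_left=("left", "median"),
        median_right=("right", "median"),
        iqr_left=("left", _iqr),
        iqr_right=("right", _iqr),
    ).reset_index()
    out["small_group"] = out["n"] <= small_n
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum outcome.

    ``u`` is the Mann-Whitney U of the first sample; ``z`` is reported only
    on the normal-approximation path; ``method`` is ``"exact"``,
    ``"asymptotic"`` or ``"degenerate"``.
    """

    u: float
    p: float
    z: Optional[float] = None
    method: str = "exact"
    degenerate: bool = False


def _extract(values, side: Optional[str]) -> np.ndarray:
    vals = list(values)
    if vals and isinstance(vals[0], BoundaryDiff):
        if side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right' for BoundaryDiff input")
        vals = [getattr(d, side) for d in vals]
    return np.asarray(vals, dtype=float)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Complete enumeration of the permutation distribution of U (handles ties)."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    const = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - const)
    mu = n1 * n2 / 2.0
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n1 + n2), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    u_all = ranks[combos].sum(axis=1) - const
    p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-9))
    return u_obs, p


def compare_methods(
    diffs_a: Iterable,
    diffs_b: Iterable,
    side: Optional[str] = None,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test between two sets of boundary differences.

    Accepts raw numbers or :class:`BoundaryDiff` lists (then ``side`` selects
    the boundary).  Small samples are tested by exact enumeration of the
    permutation distribution of U; larger ones by the tie-corrected normal
    approximation (no continuity correction), for which the z statistic is
    also returned.
    """
    x = _extract(diffs_a, side)
    y = _extract(diffs_b, side)
    if len(x) == 0 or len(y) == 0:
        raise ContractError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankSumResult(
            u=n1 * n2 / 2.0, p=1.0, z=0.0, method="degenerate", degenerate=True
        )
    if math.comb(n1 + n2, n1) <= _EXACT_MAX_COMBINATIONS:
        u_obs, p = _exact_ranksum_p(x, y)
        return RankSumResult(u=u_obs, p=p, method="exact")
    u_obs = _u_statistic(x, y)
    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    z = (u_obs - n1 * n2 / 2.0) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(u=u_obs, p=min(p, 1.0), z=z, method="asymptotic")


# ---------------------------------------------------------------------------
# Annotation I/O (TSV with an explicit coordinate pragma)
# ---------------------------------------------------------------------------

def write_annotations(
    regions: Iterable[AnnotatedRegion], stream: Optional[IO[str]] = None
) -> str:
    lines = [COORD_PRAGMA, "id\tstart\tend\tfamily\tshape_group"]
    for r in regions:
        lines.append(
            f"{r.id}\t{r.actual_start}\t{r.actual_end}\t{r.family}\t{r.shape_group}"
        )
    out = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(out)
    return out


def read_annotations(source: Union[str, IO[str]]) -> list[AnnotatedRegion]:
    """Read BED-like annotation TSV declared 1-based inclusive by its pragma."""
    text = source.read() if hasattr(source, "read") else open(source).read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ContractError("empty annotation file")
    if lines[0].replace(" ", "") != COORD_PRAGMA.replace(" ", ""):
        warnings.warn(
            "annotation file lacks the coordinate pragma; assuming 1-based inclusive",
            RuntimeWarning,
            stacklevel=2,
        )
    regions = []
    for ln in lines:
        if ln.startswith("#") or ln.startswith("id\t"):
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ContractError(f"malformed annotation line: {ln!r}")
        regions.append(
            AnnotatedRegion(
                id=parts[0],
                actual_start=int(parts[1]),
                actual_end=int(parts[2]),
                family=parts[3] if len(parts) > 3 else "unknown",
                shape_group=parts[4] if len(parts) > 4 else "single_hairpin",
            )
        )
    return regions
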