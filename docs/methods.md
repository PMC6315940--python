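# Methods

This note documents the models, conventions and numerical choices behind the
package, the way the synthetic generators emulate real data, and the known
limitations.

## Segment fitness and the score transform

The core quantity is a fitness `F(k,l)` over candidate segments `[k,l]` of a
window `[1,n]`, built from three geometric means of base-pair scores: paired
mass inside the segment (`Ibp`), unpaired mass of inside positions towards
the outside (`O¬bp`), and unpaired mass between the two flanking margins of
length `f` spanning the segment (`S¬bp`). The geometric mean normalizes for
segment length without letting a few near-certain pairs dominate the
average, which matters because ensemble pair probabilities are roughly
exponentially distributed.

The score transform `s = max(0, log(p/p0)/log(1/p0))` maps probabilities to
`[0,1]` log-odds scores against a null probability `p0` of random pairing.
Probabilities at or below `p0` score zero and are dropped from the sparse
score table. Anchors: `s(p0)=0`, `s(√p0)=1/2`, `s(1)=1`; the transform is
monotone, so raising `p0` can only empty the score table, never populate it.

**Scope of the substitution.** The fitness is stated in terms of pair
scores, but the two penalty terms are written as `1 − Σ`, a form natural for
probabilities. We substitute scores in *all three* terms for internal
consistency (one kernel throughout). Since score row-sums may exceed 1, the
penalty terms are clamped at zero and `log 0` is an explicit `−∞` sentinel —
a segment with overwhelming boundary-crossing mass is simply disqualified.
No epsilon smoothing is applied inside the formula: smoothing would silently
reorder segments near the clamp. The alternative reading — scores inside
`Ibp`, raw probabilities in the penalties — is defensible too, so it is kept
behind a single switch (`ScoreParams.transform_outside=False`), where the
penalty terms are then automatically bounded in `[0,1]` by the unit row-mass
invariant.

Arithmetic is in log space (sums of logs), with `−∞` propagating through.
One consequence worth stating: `log F ≤ 0` always, with equality exactly
when every inside row carries unit score mass and nothing crosses the
boundary — a perfectly self-contained segment.

**Search.** The scanner evaluates every admissible segment
(`1+f ≤ k < l ≤ n−f`) using per-row cumulative sums, O(n) per segment and
O(n³) overall; positions with zero total score mass prune the segment range
sharply on sparse inputs. The comparator scanner uses 2-D prefix sums and is
O(n²). Ties are broken deterministically: smallest `k`, then smallest `l`
(the choice is arbitrary but fixed). Naive literal transcriptions of both
formulas — linear-space products, double loops — live in the test suite as
oracles and must agree with the scanners exactly on every segment.

**Comparator.** The Dotu et al. fitness consumes raw probabilities, not
scores: it is a distinct fitness function being compared against, not a
variant of the same kernel. Its printed denominator is read as the segment
length `j−i+1` (the obvious typo `j−1+1` would make the normalization
constant). Default weights `w1=2, w2=1` are the ones recommended by its
authors (tuned on single-hairpin miRNA structures); no weight optimization
is provided.

**Sub-optimal segments.** Windows can contain clusters of self-contained
structures (tRNA or miRNA clusters). Extraction is greedy: repeatedly accept
the best-scoring segment that keeps at least `min_gap − 1` free positions to
every accepted segment (`min_gap=1` = strict non-overlap, the default),
stopping at `−∞` (RNAbound) or non-positive scores (comparator). Greedy
selection by score is not globally optimal interval scheduling; it matches
the intended "highest-scoring non-overlapping regions" semantics.

## Matrix I/O conventions

Coordinates are 1-based inclusive in all public I/O. The RNAfold PostScript
dialect stores `sqrt(p)` in its `ubox` records, so values are squared on
ingestion; `lbox` (MFE) records are ignored, and the window length comes
from the `/sequence` block when present, else the largest index seen.
Tabular input is symmetrized by the elementwise maximum (with a warning
beyond 1e-6 asymmetry) and the diagonal forced to zero. Rows whose total
pairing mass exceeds `1 + 1e-6` — seen in third-party outputs — are rescaled
rather than rejected, with a warning; the rescale factor `min(r_i, r_j)` per
entry keeps the matrix symmetric and every row at or below unit mass.
Storage is sparse with implicit zeros throughout.

## Alignment handling

Mean pairwise identity counts gap-vs-base as mismatch and skips gap-vs-gap;
the literature rarely states its convention, so the denominator choice is
exposed as an option (`count_gap_base`). Per-column profiles ignore columns
with more than 25% gap characters and columns where the reference row is
gapped — positions with no reference coordinate have no meaningful profile
entry. `N` is treated as an ordinary character; ambiguity handling is out of
scope. Filters run in a fixed order (gap fraction → row count → MPI band)
and are idempotent; the reference row is never silently dropped — a
too-gappy reference rejects the whole window with a distinct reason.

Column→reference mapping snaps gap columns inward (start to the next
reference base, end to the previous one) and reports an empty interval when
no reference base is covered, so that boundaries found on alignment columns
— which can exceed the nominal window size once gaps are inserted — are
always reportable against genomic annotations. Predictions and annotations
carry a coordinate-frame tag, and the evaluation refuses to mix frames.

## Evaluation

Boundary differences are exact integer arithmetic:
`left = actual_start − u`, `right = v − actual_end`; positive = excess,
negative = short. Left and right are never summed or folded into an absolute
value — that would lose which boundary failed and in which direction.
Summaries report median and IQR per group (midpoint convention for even
counts) and flag groups of five or fewer entries, where medians are fragile.

The two-sided Wilcoxon rank-sum comparison uses complete enumeration of the
permutation distribution of U whenever the number of splits is at most
2×10⁵ (which covers all pairs of sample sizes up to 10 vs 10, ties
included); larger samples use the tie-corrected normal approximation without
continuity correction, reporting U, z and p. SciPy's exact method serves as
an independent cross-check in the tests on untied data; the in-package
enumeration exists because the exact path must also handle ties, which the
library's exact method does not correct for. Degenerate input (all pooled
values identical) returns `p = 1` with an explicit flag.

## Synthetic data

`plant_structure` emulates a consensus-folder matrix for a window containing
one self-contained structure, in three layouts: a contiguous stem-loop
(`hairpin`, loop 3–4 nt), a cloverleaf (7-bp closing stem plus three
hairpin arms, tRNA-shaped, ≥ 43 nt), and two adjacent stem-loops separated
by a 3-nt hinge (`double_hairpin`, H/ACA-like). Helix pairs carry
`stem_prob` (default 0.95).

Two features are deliberate emulations of real ensembles rather than
decoration:

* **Breathing pairs.** Every structurally unpaired position inside the
  planted region receives a weak alternative pairing (default 0.05),
  preferentially to a distant unpaired position — which links the arms of
  branched layouts, as consensus ensembles of adjacent stems do — else to a
  helix position with spare capacity. Real Boltzmann ensembles never leave
  loop positions at exactly zero pairing mass, and the geometric-mean
  fitness depends on that: a segment containing a zero-mass position is
  disqualified outright. Per-position mass is capped at 0.99 so that no
  row-sum rescaling fires and noise injection cannot perturb planted
  entries.

* **Background noise** is sampled anywhere in the window (separation ≥ 4 to
  respect the minimum hairpin loop) with values drawn uniformly below a
  ceiling `noise_prob`. At or below the null probability `p0` the score
  transform removes it entirely — the planted-recovery property
  (`find_boundaries` returns the planted interval exactly when
  `noise_prob ≤ p0` and margins are at least `f`) is therefore a sharp
  statement about the fitness, not about luck with noise.

What the generator does **not** emulate: nearest-neighbor energetics,
pseudoknots, alignment gaps in matrices, position-dependent conservation, or
the diffuse multi-register ensembles of low-complexity sequences. Passing
the planted-recovery suite therefore demonstrates correctness of the search
under clean, well-separated structure signal; it does not predict accuracy
on genome-scale screens, which depends on folding quality and alignment
quality outside this package's control.

`toy_fold` is a minimal exact folder: nested canonical structures
(Watson–Crick + GU, hairpin loop ≥ 3), each pair contributing a constant
Boltzmann weight `w = exp(−E/kT)` (defaults `E = −2`, `kT = 1`). Inside and
outside recursions give exact pair probabilities whose row sums are bounded
by 1 by construction; the test suite checks them against exhaustive
enumeration of all structures for short sequences. It exists to create
realistic-shaped ensembles for tests and examples — it is a Nussinov-style
model by design, not a replacement for thermodynamic folders, and its
outside pass is quartic in the length (intended for windows up to roughly
150 nt). `hairpin_sequence` designs windows for it with G/C helix arms, a
cytidine loop and adenosine flanks, so all ensemble mass stays inside the
planted region.

`mutate_alignment` derives homolog rows by i.i.d. substitution outside
planted pairs and joint (compensatory) canonical replacement of planted
pairs, the covariation signal consensus folders exploit. Expected pairwise
identity as a function of the substitution rate has a closed form
(`expected_pairwise_identity`), inverted numerically to hit a target MPI.
No gaps or indels are generated.

## Problem sizes and defaults

Defaults follow the intended operating point of the method: `p0 = 0.0005`,
`f = 10`, comparator weights `(2, 1)`, windows of 100–200 nt. The validation
suite uses 150 planted cases (50 per layout) for recovery, 20 random
matrices up to n = 40 for scanner/oracle equivalence, 100 sequences up to
14 nt for folder exactness, and 2000 null replicates at n = 50 for the
type-I error of the rank-sum test — sizes at which every check is exact or
tightly bounded while the whole suite runs in seconds.

## Known limitations

* The exhaustive O(n³) scan is meant for windows of a few hundred
  nucleotides, not chromosomes; windowing is the caller's job.
* With very high `stem_prob` (> ~0.94) and a short plain hairpin, breathing
  capacity on stem rows shrinks; at `stem_prob = 1` loop positions cannot be
  covered at all and the planted region is (correctly) disqualified.
* The comparator's known preference for single dense stems on two-hairpin
  layouts is reproduced, not corrected; only its recommended weights are
  shipped.
* Wilcoxon exact enumeration is complete, not network-algorithm based; its
  2×10⁵-split ceiling is a pragmatic bound, beyond which the tie-corrected
  normal approximation is used.
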