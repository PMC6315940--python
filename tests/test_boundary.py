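"""Fitness functions and the exhaustive boundary search against literal oracles."""
import numpy as np
import pytest

from rnabound import (
    BasePairMatrix,
    ContractError,
    DotuParams,
    ParameterError,
    ScoreParams,
    dotu_fitness,
    find_boundaries,
    rnabound_fitness,
    score_matrix,
    suboptimal_segments,
)
from rnabound.boundary import NEG_INF, _scan_dotu, _scan_rnabound
from rnabound.synthetic import plant_structure

from .conftest import random_sparse_matrix
from .oracles import (
    best_segment_literal,
    dotu_fitness_literal,
    rnabound_fitness_literal,
)


# ---------------------------------------------------------------------------
# RNAbound fitness
# ---------------------------------------------------------------------------

class TestRnaboundFitness:
    def test_all_zero_scores_give_minus_inf(self):
        params = ScoreParams(f=3)
        S = np.zeros((20, 20))
        assert rnabound_fitness(S, 5, 12, params) == NEG_INF

    def test_perfect_self_containment_scores_zero(self):
        # every row inside [k, l] carries unit score mass inside, nothing
        # crosses the boundary: all three log components vanish
        params = ScoreParams(f=3)
        n, k, l = 20, 6, 15
        S = np.zeros((n, n))
        for m, q in [(6, 15), (7, 14), (8, 13), (9, 12), (10, 11)]:
            S[m - 1, q - 1] = S[q - 1, m - 1] = 1.0
        total, comps = rnabound_fitness(S, k, l, params, return_components=True)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert comps == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_linear_space_literal_evaluation(self, seed):
        params = ScoreParams(f=4)
        m = random_sparse_matrix(30, 0.15, seed=seed)
        S = score_matrix(m, params).to_dense()
        rng = np.random.default_rng(seed + 100)
        for _ in range(10):
            k = int(rng.integers(1 + params.f, 30 - params.f))
            l = int(rng.integers(k + 1, 30 - params.f + 1))
            got = rnabound_fitness(S, k, l, params)
            expect = rnabound_fitness_literal(S, k, l, params.f)
            if expect == NEG_INF:
                assert got == NEG_INF
            else:
                assert got == pytest.approx(expect, abs=1e-9)

    def test_out_of_range_segment_rejected(self):
        params = ScoreParams(f=5)
        S = np.zeros((20, 20))
        with pytest.raises(ContractError):
            rnabound_fitness(S, 2, 10, params)
        with pytest.raises(ContractError):
            rnabound_fitness(S, 6, 16, params)

    def test_score_never_positive(self):
        params = ScoreParams(f=3)
        for seed in range(5):
            m = random_sparse_matrix(25, 0.25, seed=seed)
            S = score_matrix(m, params).to_dense()
            F = _scan_rnabound(S, params.f)
            assert np.all(F[np.isfinite(F)] <= 1e-12)


# ---------------------------------------------------------------------------
# Comparator fitness
# ---------------------------------------------------------------------------

class TestDotuFitness:
    def setup_method(self):
        self.single = BasePairMatrix(10, {(3, 8): 0.8})

    def test_all_zero_matrix_scores_zero(self):
        m = BasePairMatrix(10)
        assert dotu_fitness(m, 1, 10) == 0.0
        assert dotu_fitness(m, 4, 7) == 0.0

    def test_pair_inside_segment(self):
        assert dotu_fitness(self.single, 1, 10) == pytest.approx(0.16)

    def test_pair_straddling_boundary(self):
        assert dotu_fitness(self.single, 1, 5) == pytest.approx(-0.16)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ContractError):
            dotu_fitness(self.single, 5, 5)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_matches_double_loop_literal_evaluation(self, seed):
        m = random_sparse_matrix(25, 0.2, seed=seed)
        P = m.to_dense()
        params = DotuParams()
        F = _scan_dotu(P, params.w1, params.w2)
        for i in range(1, 26):
            for j in range(i + 1, 26):
                assert F[i - 1, j - 1] == pytest.approx(
                    dotu_fitness_literal(P, i, j, params.w1, params.w2), abs=1e-9
                )


# ---------------------------------------------------------------------------
# Boundary search
# ---------------------------------------------------------------------------

class TestFindBoundaries:
    def test_planted_hairpin_recovered_by_both_methods(self):
        case = plant_structure(150, "hairpin", 41, 90, stem_prob=0.95, seed=1)
        for method in ("rnabound", "dotu"):
            pred = find_boundaries(case.matrix, method)
            assert (pred.u, pred.v) == (41, 90), method

    def test_all_zero_dotu_tie_break(self):
        pred = find_boundaries(BasePairMatrix(30), "dotu")
        assert (pred.u, pred.v) == (1, 2)
        assert pred.score == 0.0

    def test_all_zero_rnabound_reports_no_structure(self):
        pred = find_boundaries(BasePairMatrix(30), "rnabound", ScoreParams(f=3))
        assert pred.status == "no_structure"
        assert pred.u is None and pred.v is None

    def test_window_too_short_for_flank(self):
        with pytest.raises(ParameterError):
            find_boundaries(BasePairMatrix(15), "rnabound", ScoreParams(f=10))

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            find_boundaries(BasePairMatrix(15), "centroid")

    @pytest.mark.parametrize("seed", range(5))
    def test_scanner_equals_exhaustive_literal_argmax(self, seed):
        """Optimized scanners reproduce naive re-evaluation at every (k, l)."""
        n = 24
        m = random_sparse_matrix(n, 0.2, seed=seed)
        params = ScoreParams(f=4)
        S = score_matrix(m, params).to_dense()
        u, v, score = best_segment_literal(
            lambda k, l: rnabound_fitness_literal(S, k, l, params.f),
            n, 1 + params.f, n - params.f,
        )
        pred = find_boundaries(m, "rnabound", params)
        if u is None:
            assert pred.status == "no_structure"
        else:
            assert (pred.u, pred.v) == (u, v)
            assert pred.score == pytest.approx(score, abs=1e-9)

        P = m.to_dense()
        du, dv, dscore = best_segment_literal(
            lambda i, j: dotu_fitness_literal(P, i, j, 2.0, 1.0), n, 1, n
        )
        dpred = find_boundaries(m, "dotu")
        assert (dpred.u, dpred.v) == (du, dv)
        assert dpred.score == pytest.approx(dscore, abs=1e-9)

    def test_translation_equivariance(self):
        """Shifting the planted structure shifts the prediction identically."""
        base = plant_structure(160, "hairpin", 31, 80, seed=4)
        for d in (5, 23, 60):
            shifted = plant_structure(160, "hairpin", 31 + d, 80 + d, seed=4)
            p0 = find_boundaries(base.matrix, "rnabound")
            p1 = find_boundaries(shifted.matrix, "rnabound")
            assert (p1.u - p0.u, p1.v - p0.v) == (d, d)

    def test_double_hairpin_covered_by_rnabound(self):
        """Both adjacent stems fall inside the RNAbound prediction (H/ACA-like)."""
        case = plant_structure(200, "double_hairpin", 61, 140, seed=2)
        pred = find_boundaries(case.matrix, "rnabound")
        first_stem_start = min(i for i, _ in case.helix_pairs)
        second_stem_end = max(j for _, j in case.helix_pairs)
        assert pred.u <= first_stem_start
        assert pred.v >= second_stem_end

    def test_outside_transform_switch_still_recovers_planted(self):
        case = plant_structure(150, "hairpin", 41, 90, seed=6)
        params = ScoreParams(transform_outside=False)
        pred = find_boundaries(case.matrix, "rnabound", params)
        assert (pred.u, pred.v) == (41, 90)

    def test_components_sum_to_score(self):
        case = plant_structure(150, "hairpin", 41, 90, seed=1)
        pred = find_boundaries(case.matrix, "rnabound")
        assert sum(pred.components) == pytest.approx(pred.score, abs=1e-12)


# ---------------------------------------------------------------------------
# Sub-optimal segments
# ---------------------------------------------------------------------------

def _two_hairpin_matrix():
    a = plant_structure(160, "hairpin", 21, 60, seed=1)
    b = plant_structure(160, "hairpin", 101, 140, seed=2)
    merged = dict(a.matrix.probs)
    merged.update(b.matrix.probs)
    return BasePairMatrix(160, merged), a, b


class TestSuboptimalSegments:
    def test_two_planted_structures_both_returned(self):
        m, a, b = _two_hairpin_matrix()
        segs = suboptimal_segments(m, "rnabound")
        assert len(segs) == 2
        assert {(s.k, s.l) for s in segs} == {a.truth, b.truth}
        assert segs[0].score >= segs[1].score

    def test_single_structure_matches_argmax(self):
        case = plant_structure(150, "hairpin", 41, 90, seed=1)
        segs = suboptimal_segments(case.matrix, "rnabound")
        pred = find_boundaries(case.matrix, "rnabound")
        assert segs[0].k == pred.u and segs[0].l == pred.v
        assert segs[0].score == pytest.approx(pred.score)
        # nothing admissible remains outside the structure
        assert all(not (s.k <= pred.u <= s.l) for s in segs[1:])

    def test_all_zero_matrix_yields_empty_list(self):
        assert suboptimal_segments(BasePairMatrix(40), "rnabound") == []

    def test_selected_segments_never_overlap(self):
        m, _, _ = _two_hairpin_matrix()
        segs = suboptimal_segments(m, "dotu", min_gap=5)
        for x in segs:
            for y in segs:
                if x is not y:
                    assert x.l + 4 < y.k or x.k - 4 > y.l
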