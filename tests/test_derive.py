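import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import eig

from mcda_weights import (
    BWSDesign,
    BWSResponse,
    CriteriaHierarchy,
    PairwiseJudgment,
    PairwiseResponse,
    PointAllocationResponse,
    RankingResponse,
    RatingResponse,
    equal_weights,
    weights_from_bws,
    weights_from_pairwise,
    weights_from_points,
    weights_from_ranking,
    weights_from_ratings,
)
from mcda_weights.derive import (
    eigenvector_weights,
    geometric_mean_weights,
    propagate_hierarchy,
    rank_shares,
)
from mcda_weights.hierarchy import Criterion


def _uniform_within(evidem, budget=100.0):
    sizes = evidem.category_sizes()
    return {
        cat: {code: budget / sizes[cat] for code in evidem.category_codes(cat)}
        for cat in evidem.categories
    }


class TestRatings:
    def test_equal_ratings_give_equal_weights(self, evidem):
        w = weights_from_ratings(RatingResponse("R1", {c: 3 for c in evidem.codes}), evidem)
        assert np.allclose(w.values, 1 / 14)
        # the no-prioritization baseline rounds to 0.07 per criterion
        assert round(w.values[0], 2) == 0.07
        assert np.allclose(w.values, equal_weights(evidem).values)

    def test_two_criteria_direct_normalization(self, two_leaf):
        w = weights_from_ratings(RatingResponse("R1", {"A1": 5, "A2": 1}), two_leaf)
        assert w.as_dict() == pytest.approx({"A1": 5 / 6, "A2": 1 / 6})

    def test_hierarchical_equal_ratings(self, evidem):
        # equal shares per block propagate to 1/(6*size), not 1/14
        r = RatingResponse(
            "R1",
            {c: 4 for c in evidem.codes},
            category_ratings={c: 2 for c in evidem.categories},
        )
        w = weights_from_ratings(r, evidem)
        sizes = evidem.category_sizes()
        for crit in evidem.criteria:
            assert w[crit.code] == pytest.approx(1 / 6 / sizes[crit.category])

    def test_invalid_rating_rejected(self, evidem):
        ratings = {c: 3 for c in evidem.codes}
        ratings["D1"] = 0
        with pytest.raises(ValueError):
            weights_from_ratings(RatingResponse("R1", ratings), evidem)


class TestPoints:
    def test_single_category_takes_all(self, evidem):
        cats = evidem.categories
        resp = PointAllocationResponse(
            "R1",
            category_points={c: (100.0 if c == cats[0] else 0.0) for c in cats},
            within_points=_uniform_within(evidem),
        )
        w = weights_from_points(resp, evidem)
        inside = sum(w[c] for c in evidem.category_codes(cats[0]))
        assert inside == pytest.approx(1.0)

    def test_uniform_blocks_give_hierarchical_uniform(self, evidem):
        resp = PointAllocationResponse(
            "R1",
            category_points={c: 100.0 / 6 for c in evidem.categories},
            within_points=_uniform_within(evidem),
        )
        w = weights_from_points(resp, evidem)
        sizes = evidem.category_sizes()
        for crit in evidem.criteria:
            assert w[crit.code] == pytest.approx(1 / 6 / sizes[crit.category])

    def test_hand_multiplied_shares(self, evidem):
        # 50 points on the first category, split 60/40 inside -> 0.30, 0.20
        cats = evidem.categories
        pts = {c: 10.0 for c in cats}
        pts[cats[0]] = 50.0
        within = _uniform_within(evidem)
        d1, d2 = evidem.category_codes(cats[0])
        within[cats[0]] = {d1: 60.0, d2: 40.0}
        w = weights_from_points(
            PointAllocationResponse("R1", pts, within), evidem
        )
        assert w[d1] == pytest.approx(0.30)
        assert w[d2] == pytest.approx(0.20)

    def test_zero_block_rejected(self, evidem):
        resp = PointAllocationResponse(
            "R1",
            category_points={c: 100.0 / 6 for c in evidem.categories},
            within_points=_uniform_within(evidem),
        )
        resp.within_points[evidem.categories[0]] = {
            c: 0.0 for c in evidem.category_codes(evidem.categories[0])
        }
        with pytest.raises(ValueError):
            weights_from_points(resp, evidem)


class TestRanking:
    def test_rank_sum_block_of_two(self):
        assert rank_shares(2, "rank_sum") == pytest.approx([2 / 3, 1 / 3])

    def test_centroid_block_of_three(self):
        # (1/3)(1 + 1/2 + 1/3), (1/3)(1/2 + 1/3), (1/3)(1/3)
        assert rank_shares(3, "centroid") == pytest.approx([11 / 18, 5 / 18, 2 / 18])

    def test_singleton_block_gets_full_share(self):
        for scheme in ("rank_sum", "centroid"):
            assert rank_shares(1, scheme) == pytest.approx([1.0])

    def test_incomplete_permutation_rejected(self, evidem):
        resp = RankingResponse(
            "R1",
            category_ranks={c: 1 for c in evidem.categories},
            within_ranks={
                cat: {c: i + 1 for i, c in enumerate(evidem.category_codes(cat))}
                for cat in evidem.categories
            },
        )
        with pytest.raises(ValueError, match="permutation"):
            weights_from_ranking(resp, evidem)

    def test_full_derivation_sums_to_one(self, evidem, rng):
        cat_ranks = dict(zip(evidem.categories, rng.permutation(6) + 1))
        within = {
            cat: dict(
                zip(
                    evidem.category_codes(cat),
                    rng.permutation(len(evidem.category_codes(cat))) + 1,
                )
            )
            for cat in evidem.categories
        }
        for scheme in ("rank_sum", "centroid"):
            w = weights_from_ranking(
                RankingResponse("R1", cat_ranks, within), evidem, scheme=scheme
            )
            assert w.values.sum() == pytest.approx(1.0)
            assert (w.values >= 0).all()


def _consistent_matrix(shares: np.ndarray) -> np.ndarray:
    return np.outer(shares, 1.0 / shares)


class TestPairwise:
    def test_two_by_two_closed_form(self):
        m = np.array([[1.0, 3.0], [1 / 3, 1.0]])
        assert geometric_mean_weights(m) == pytest.approx([0.75, 0.25])
        assert eigenvector_weights(m) == pytest.approx([0.75, 0.25])

    def test_consistent_matrix_recovers_shares(self):
        shares = np.array([0.5, 0.3, 0.2])
        m = _consistent_matrix(shares)
        assert geometric_mean_weights(m) == pytest.approx(shares, abs=1e-9)
        assert eigenvector_weights(m) == pytest.approx(shares, abs=1e-9)

    def test_geometric_mean_matches_eigen_oracle(self, rng):
        # random reciprocal 3x3: geometric mean equals the principal
        # eigenvector exactly at n=3, checked against a dense eig solve
        for _ in range(50):
            a, b, c = rng.choice([1 / 5, 1 / 3, 1 / 2, 1, 2, 3, 5], size=3)
            m = np.array([[1, a, b], [1 / a, 1, c], [1 / b, 1 / c, 1]])
            vals, vecs = eig(m)
            principal = np.real(vecs[:, np.argmax(np.real(vals))])
            principal = np.abs(principal) / np.abs(principal).sum()
            assert geometric_mean_weights(m) == pytest.approx(principal, abs=1e-6)

    def test_full_hierarchical_derivation(self, evidem):
        judgments = []
        for block in ("TOP", *evidem.categories):
            items = evidem.block_items(block)
            for a, b in itertools.combinations(items, 2):
                judgments.append(PairwiseJudgment(block, a, b, 1.0))
        w = weights_from_pairwise(
            PairwiseResponse("R1", judgments), evidem, method="eigenvector"
        )
        sizes = evidem.category_sizes()
        for crit in evidem.criteria:
            assert w[crit.code] == pytest.approx(1 / 6 / sizes[crit.category])

    def test_nonpositive_judgment_rejected(self, evidem):
        judgments = [
            PairwiseJudgment("TOP", evidem.categories[0], evidem.categories[1], -2.0)
        ]
        with pytest.raises(ValueError):
            PairwiseResponse("R1", judgments).matrix("TOP", evidem.categories[:2])


class TestBWS:
    def _toy(self):
        h = CriteriaHierarchy(
            tuple(Criterion(c, c.lower(), "G") for c in ("A", "B", "C", "D"))
        )
        design = BWSDesign((("A", "B", "C", "D"),) * 3)
        return h, design

    def test_always_best_scores_one(self):
        h, design = self._toy()
        from mcda_weights.derive import bws_counts

        resp = BWSResponse("R1", [("A", "D")] * 3)
        best, worst, appear = bws_counts(resp, design)
        score_a = (best["A"] - worst.get("A", 0) + appear["A"]) / (2 * appear["A"])
        score_d = (best.get("D", 0) - worst["D"] + appear["D"]) / (2 * appear["D"])
        assert score_a == 1.0
        assert score_d == 0.0

    def test_weights_match_hand_tally(self):
        h, design = self._toy()
        resp = BWSResponse("R1", [("A", "D"), ("B", "D"), ("A", "C")])
        # B = {A:2, B:1}, W = {D:2, C:1}, r = 3 for all
        scores = {
            "A": (2 - 0 + 3) / 6,
            "B": (1 - 0 + 3) / 6,
            "C": (0 - 1 + 3) / 6,
            "D": (0 - 2 + 3) / 6,
        }
        total = sum(scores.values())
        w = weights_from_bws(resp, design, h)
        for code in "ABCD":
            assert w[code] == pytest.approx(scores[code] / total)

    def test_never_shown_criterion_rejected(self):
        h, design = self._toy()
        h5 = CriteriaHierarchy(h.criteria + (Criterion("E", "e", "G"),))
        resp = BWSResponse("R1", [("A", "D")] * 3)
        with pytest.raises(ValueError, match="never shown"):
            weights_from_bws(resp, design, h5)

    def test_sqrt_ratio_transform(self):
        h, design = self._toy()
        resp = BWSResponse("R1", [("A", "D")] * 3)
        w = weights_from_bws(resp, design, h, transform="sqrt_ratio")
        raw = {
            "A": np.sqrt(3.5 / 0.5),
            "B": np.sqrt(0.5 / 0.5),
            "C": np.sqrt(0.5 / 0.5),
            "D": np.sqrt(0.5 / 3.5),
        }
        total = sum(raw.values())
        assert w["A"] == pytest.approx(raw["A"] / total)


class TestPropagation:
    def test_blocks_must_sum_to_one(self, evidem):
        shares = {"TOP": {c: 1 / 6 for c in evidem.categories}}
        for cat in evidem.categories:
            codes = evidem.category_codes(cat)
            shares[cat] = {c: 1 / len(codes) for c in codes}
        shares["TOP"][evidem.categories[0]] = 0.5  # breaks the sum
        with pytest.raises(ValueError, match="sum"):
            propagate_hierarchy(shares, evidem)

    def test_conservation(self, evidem, rng):
        shares = {}
        top = rng.dirichlet(np.ones(6))
        shares["TOP"] = dict(zip(evidem.categories, top))
        for cat in evidem.categories:
            codes = evidem.category_codes(cat)
            shares[cat] = dict(zip(codes, rng.dirichlet(np.ones(len(codes)))))
        leaf = propagate_hierarchy(shares, evidem)
        assert leaf.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

rating_values = st.lists(st.integers(1, 5), min_size=14, max_size=14)


@given(rating_values)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_rating_weights_sum_to_one_and_nonnegative(values):
    evidem = CriteriaHierarchy.default()
    w = weights_from_ratings(
        RatingResponse("R", dict(zip(evidem.codes, values))), evidem
    )
    assert w.values.sum() == pytest.approx(1.0, abs=1e-9)
    assert (w.values >= 0).all()


@given(rating_values, st.randoms(use_true_random=False))
@settings(derandomize=True, max_examples=25, deadline=None)
def test_rating_weights_equivariant_under_relabeling(values, pyrandom):
    """Permuting which criterion got which rating permutes the weights."""
    evidem = CriteriaHierarchy.default()
    w = weights_from_ratings(
        RatingResponse("R", dict(zip(evidem.codes, values))), evidem
    )
    perm = list(range(14))
    pyrandom.shuffle(perm)
    permuted = [values[p] for p in perm]
    w2 = weights_from_ratings(
        RatingResponse("R", dict(zip(evidem.codes, permuted))), evidem
    )
    assert w2.values == pytest.approx([w.values[p] for p in perm])


@given(st.lists(st.floats(0.05, 1.0), min_size=3, max_size=6))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_ahp_methods_agree_on_consistent_matrices(shares):
    s = np.asarray(shares) / np.sum(shares)
    m = _consistent_matrix(s)
    gm = geometric_mean_weights(m)
    ev = eigenvector_weights(m)
    assert np.max(np.abs(gm - ev)) <= 1e-9


@given(st.floats(0.1, 10.0))
@settings(derandomize=True, max_examples=25, deadline=None)
def test_point_weights_scale_invariant(factor):
    """Multiplying every block's points by a constant leaves weights alone."""
    evidem = CriteriaHierarchy.default()
    # raw within-block allocations before budget normalization
    rng = np.random.default_rng(0)
    base_top = rng.dirichlet(np.ones(6)) * 100
    resp = PointAllocationResponse(
        "R",
        dict(zip(evidem.categories, base_top)),
        {
            cat: dict(
                zip(
                    evidem.category_codes(cat),
                    rng.dirichlet(np.ones(len(evidem.category_codes(cat)))) * 100,
                )
            )
            for cat in evidem.categories
        },
    )
    w1 = weights_from_points(resp, evidem)
    # the derivation normalizes by the block total, so a rescaled budget
    # (e.g. per-mille instead of percent) must give identical weights
    scaled = PointAllocationResponse(
        "R",
        {k: v * factor for k, v in resp.category_points.items()},
        {
            cat: {k: v * factor for k, v in block.items()}
            for cat, block in resp.within_points.items()
        },
    )
    w2 = weights_from_points(scaled, evidem)
    assert w2.values == pytest.approx(w1.values, abs=1e-12)


class TestFlatPairwiseMode:
    def test_flat_mode_single_block_over_all_criteria(self, evidem, rng):
        from mcda_weights.derive import FLAT_BLOCK

        shares = rng.dirichlet(np.full(14, 5.0))
        judgments = [
            PairwiseJudgment(FLAT_BLOCK, a, b,
                             shares[i] / shares[j])
            for (i, a), (j, b) in itertools.combinations(enumerate(evidem.codes), 2)
        ]
        w = weights_from_pairwise(
            PairwiseResponse("R1", judgments), evidem, mode="flat"
        )
        # a consistent flat matrix recovers the shares without any
        # hierarchical propagation
        assert w.values == pytest.approx(shares, abs=1e-9)
        assert len(judgments) == 91

    def test_unknown_mode_rejected(self, evidem):
        with pytest.raises(ValueError, match="mode"):
            weights_from_pairwise(PairwiseResponse("R1", []), evidem, mode="bogus")


def test_weights_frame_times_hundred(evidem):
    w = weights_from_ratings(RatingResponse("R", {c: 3 for c in evidem.codes}), evidem)
    from mcda_weights import weights_to_frame

    frame = weights_to_frame([w], scale=100.0)
    assert frame["weight"].sum() == pytest.approx(100.0)
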