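"""Turn raw elicitation responses into normalized criterion weights.

Every derivation ends in a :class:`WeightVector`: nonnegative weights over
the hierarchy's leaves summing to one.  Hierarchical instruments first
yield *local shares* per judgment block (the category block plus one block
per category); :func:`propagate_hierarchy` multiplies category share by
within-category share to obtain leaf weights.

Conversion conventions (each a configurable choice, since stated-preference
instruments do not define a unique numeric mapping):

* ratings — direct sum-normalization of the 1-5 ratings (the EVIDEM
  framework's own convention);
* ranks — rank-sum shares ``(n-j+1)/sum`` by default, rank-order-centroid
  shares as an alternative;
* point allocations — points divided by the 100-point budget;
* pairwise matrices — row geometric means by default, the principal right
  eigenvector (classical AHP) as an alternative;
* best-worst choices — the shifted best-minus-worst count score
  ``(B-W+r)/(2r)`` by default, the square-root choice-ratio score
  ``sqrt((B+.5)/(W+.5))`` as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import TOP_BLOCK, CriteriaHierarchy
from .instruments import (
    BWSDesign,
    BWSResponse,
    PairwiseJudgment,
    PairwiseResponse,
    PointAllocationResponse,
    RankingResponse,
    RatingResponse,
)

__all__ = [
    "WeightVector",
    "weights_from_ratings",
    "weights_from_points",
    "weights_from_ranking",
    "weights_from_pairwise",
    "weights_from_bws",
    "propagate_hierarchy",
    "derive_weights",
    "rank_shares",
    "geometric_mean_weights",
    "eigenvector_weights",
    "consistency_ratio",
    "equal_weights",
    "weights_to_frame",
]

WEIGHT_SUM_TOL = 1e-9

GROUP_MEAN = "GROUP_MEAN"


@dataclass(frozen=True)
class WeightVector:
    """Normalized criterion weights for one respondent and technique.

    ``values`` follow the hierarchy's canonical leaf order.  Constructing
    a vector whose entries are negative or do not sum to one (within
    1e-9) raises ``ValueError``.
    """

    codes: tuple[str, ...]
    values: np.ndarray
    technique: str = ""
    respondent_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.codes),):
            raise ValueError("weights and codes differ in length")
        if (v < -WEIGHT_SUM_TOL).any():
            raise ValueError("negative weight")
        if abs(v.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"weights sum to {v.sum()!r}, not 1")

    def __getitem__(self, code: str) -> float:
        return float(self.values[self.codes.index(code)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.codes), name="weight")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.codes, map(float, self.values)))


def equal_weights(h: CriteriaHierarchy) -> WeightVector:
    """The no-prioritization baseline: 1/n for each of the n criteria.

    For the 14-criterion EVIDEM hierarchy each weight is 1/14 ~= 0.07.
    """
    n = h.n_criteria
    return WeightVector(h.codes, np.full(n, 1.0 / n), technique="EQUAL")


def _normalize(values: np.ndarray) -> np.ndarray:
    total = float(values.sum())
    if total <= 0:
        raise ValueError("cannot normalize a block with non-positive total")
    return values / total


# ---------------------------------------------------------------------------
# hierarchical propagation
# ---------------------------------------------------------------------------


def propagate_hierarchy(
    local_shares: Mapping[str, Mapping[str, float]], h: CriteriaHierarchy
) -> np.ndarray:
    """Multiply block-local shares down the two-level tree.

    ``local_shares`` maps block label (``TOP`` plus one label per
    category) to that block's share map.  Each block must be a
    probability vector over its items; the leaf weight is category share
    times within-category share, so the result sums to one by
    construction.  Note hierarchical-uniform is not flat-uniform: equal
    shares in every block give leaves 1/(6*2) or 1/(6*3), not 1/14.
    """
    blocks = [TOP_BLOCK, *h.categories]
    for block in blocks:
        if block not in local_shares:
            raise ValueError(f"missing block {block!r}")
        items = h.block_items(block)
        shares = local_shares[block]
        if set(shares) != set(items):
            raise ValueError(f"block {block!r}: items do not match hierarchy")
        vals = np.array([shares[i] for i in items], dtype=float)
        if (vals < 0).any():
            raise ValueError(f"block {block!r}: negative share")
        if abs(vals.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"block {block!r}: shares sum to {vals.sum()}, not 1")
    out = np.empty(h.n_criteria)
    for i, crit in enumerate(h.criteria):
        out[i] = (
            local_shares[TOP_BLOCK][crit.category]
            * local_shares[crit.category][crit.code]
        )
    # guard against accumulated rounding
    return out / out.sum()


# ---------------------------------------------------------------------------
# direct techniques: ratings, points, ranks
# ---------------------------------------------------------------------------


def weights_from_ratings(r: RatingResponse, h: CriteriaHierarchy) -> WeightVector:
    """Five-point ratings to weights by sum-normalization.

    Flat mode: ``w_i = rating_i / sum(ratings)``.  Hierarchical mode:
    category ratings and within-category ratings are normalized per block
    and propagated.
    """
    _check_ratings(r.ratings, h.codes)
    if not r.hierarchical:
        vals = np.array([r.ratings[c] for c in h.codes], dtype=float)
        return WeightVector(
            h.codes, _normalize(vals), technique="RS_nH", respondent_id=r.respondent_id
        )
    assert r.category_ratings is not None
    _check_ratings(r.category_ratings, h.categories)
    shares: dict[str, dict[str, float]] = {
        TOP_BLOCK: _share_map(r.category_ratings, h.categories)
    }
    for cat in h.categories:
        shares[cat] = _share_map(r.ratings, h.category_codes(cat))
    return WeightVector(
        h.codes,
        propagate_hierarchy(shares, h),
        technique="RS_H",
        respondent_id=r.respondent_id,
    )


def _check_ratings(ratings: Mapping[str, int], items: Sequence[str]) -> None:
    for code in items:
        v = ratings.get(code)
        if v is None:
            raise ValueError(f"missing rating for {code}")
        if not (1 <= int(v) <= 5) or int(v) != v:
            raise ValueError(f"rating {v!r} for {code} not an integer in 1..5")


def _share_map(values: Mapping[str, float], items: Sequence[str]) -> dict[str, float]:
    vals = np.array([float(values[i]) for i in items])
    return dict(zip(items, _normalize(vals)))


def weights_from_points(
    p: PointAllocationResponse, h: CriteriaHierarchy
) -> WeightVector:
    """100-point budgets to weights: points/100 per block, propagated."""
    shares: dict[str, dict[str, float]] = {
        TOP_BLOCK: _share_map(p.category_points, h.categories)
    }
    for cat in h.categories:
        block = p.within_points.get(cat)
        if block is None:
            raise ValueError(f"missing point block for category {cat!r}")
        shares[cat] = _share_map(block, h.category_codes(cat))
    return WeightVector(
        h.codes,
        propagate_hierarchy(shares, h),
        technique="PA",
        respondent_id=p.respondent_id,
    )


def rank_shares(n: int, scheme: str = "rank_sum") -> np.ndarray:
    """Local share for ranks 1..n (index 0 = rank 1 = most important).

    ``rank_sum``: share_j = (n-j+1) / (n(n+1)/2).
    ``centroid``: rank-order-centroid share_j = (1/n) * sum_{t>=j} 1/t.
    """
    if n < 1:
        raise ValueError("empty rank block")
    j = np.arange(1, n + 1)
    if scheme == "rank_sum":
        return (n - j + 1) / (n * (n + 1) / 2)
    if scheme == "centroid":
        inv = 1.0 / j
        return np.array([inv[k - 1 :].sum() for k in j]) / n
    raise ValueError(f"unknown ranking scheme {scheme!r}")


def weights_from_ranking(
    k: RankingResponse, h: CriteriaHierarchy, scheme: str = "rank_sum"
) -> WeightVector:
    """Complete rankings to weights via surrogate rank shares, propagated."""
    shares: dict[str, dict[str, float]] = {
        TOP_BLOCK: _rank_block(k.category_ranks, h.categories, scheme)
    }
    for cat in h.categories:
        block = k.within_ranks.get(cat)
        if block is None:
            raise ValueError(f"missing rank block for category {cat!r}")
        shares[cat] = _rank_block(block, h.category_codes(cat), scheme)
    return WeightVector(
        h.codes,
        propagate_hierarchy(shares, h),
        technique="RA",
        respondent_id=k.respondent_id,
    )


def _rank_block(
    ranks: Mapping[str, int], items: Sequence[str], scheme: str
) -> dict[str, float]:
    n = len(items)
    if set(ranks) != set(items) or sorted(ranks.values()) != list(range(1, n + 1)):
        raise ValueError(f"ranks {dict(ranks)} are not a complete permutation of 1..{n}")
    table = rank_shares(n, scheme)
    return {code: float(table[ranks[code] - 1]) for code in items}


# ---------------------------------------------------------------------------
# pairwise comparison (AHP)
# ---------------------------------------------------------------------------

# Saaty's random consistency indices for matrix sizes 1..10.
_RANDOM_INDEX = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}


def geometric_mean_weights(m: np.ndarray) -> np.ndarray:
    """Local priorities as normalized row geometric means."""
    _check_reciprocal(m)
    gm = np.exp(np.log(m).mean(axis=1))
    return gm / gm.sum()


def eigenvector_weights(m: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Local priorities as the principal right eigenvector (power iteration)."""
    _check_reciprocal(m)
    n = m.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = m @ w
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            return nxt
        w = nxt
    return w  # pragma: no cover - convergence is immediate for small n


def _check_reciprocal(m: np.ndarray) -> None:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("comparison matrix must be square")
    if (m <= 0).any():
        raise ValueError("comparison matrix entries must be positive")
    if not np.allclose(m * m.T, 1.0, atol=1e-12, rtol=1e-9):
        raise ValueError("comparison matrix is not reciprocal")


def consistency_ratio(m: np.ndarray) -> float:
    """Saaty consistency ratio CI/RI; 0 for a perfectly consistent matrix.

    Reported as a diagnostic only — inconsistent responses are never
    rejected on its account.
    """
    _check_reciprocal(m)
    n = m.shape[0]
    if n <= 2:
        return 0.0
    w = eigenvector_weights(m)
    lam = float(np.mean((m @ w) / w))
    ci = (lam - n) / (n - 1)
    return ci / _RANDOM_INDEX[min(n, 10)]


#: Block label for the non-hierarchical all-criteria comparison mode.
FLAT_BLOCK = "FLAT"


def weights_from_pairwise(
    j: PairwiseResponse | Iterable[PairwiseJudgment],
    h: CriteriaHierarchy,
    method: str = "geometric_mean",
    mode: str = "hierarchical",
) -> WeightVector:
    """Pairwise judgments to weights.

    The default ``hierarchical`` mode reduces each block's reciprocal
    matrix (categories, then criteria within each category) to local
    priorities and propagates the shares down the tree; this is the
    survey-practical administration, since a flat comparison of all 14
    criteria needs 91 judgments.  ``flat`` mode expects one complete
    block labelled ``FLAT`` over all leaves.  Both priority methods
    coincide exactly on consistent matrices.
    """
    if method not in ("geometric_mean", "eigenvector"):
        raise ValueError(f"unknown AHP method {method!r}")
    local = geometric_mean_weights if method == "geometric_mean" else eigenvector_weights
    if not isinstance(j, PairwiseResponse):
        j = PairwiseResponse(respondent_id="", judgments=list(j))
    if mode == "flat":
        m = j.matrix(FLAT_BLOCK, h.codes)
        return WeightVector(
            h.codes, local(m), technique="PC", respondent_id=j.respondent_id
        )
    if mode != "hierarchical":
        raise ValueError(f"unknown pairwise mode {mode!r}")
    shares: dict[str, dict[str, float]] = {}
    for block in (TOP_BLOCK, *h.categories):
        items = h.block_items(block)
        m = j.matrix(block, items)
        shares[block] = dict(zip(items, local(m)))
    return WeightVector(
        h.codes,
        propagate_hierarchy(shares, h),
        technique="PC",
        respondent_id=j.respondent_id,
    )


def pairwise_consistency(j: PairwiseResponse, h: CriteriaHierarchy) -> dict[str, float]:
    """Consistency ratio per judgment block (diagnostic)."""
    return {
        block: consistency_ratio(j.matrix(block, h.block_items(block)))
        for block in (TOP_BLOCK, *h.categories)
    }


# ---------------------------------------------------------------------------
# best-worst scaling (case 1, counting analysis)
# ---------------------------------------------------------------------------


def bws_counts(
    b: BWSResponse, d: BWSDesign
) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    """Tally best choices ``B_i``, worst choices ``W_i`` and appearances ``r_i``."""
    if len(b.choices) != d.n_sets:
        raise ValueError(
            f"{len(b.choices)} choice pairs for a design of {d.n_sets} sets"
        )
    best: dict[str, int] = {}
    worst: dict[str, int] = {}
    appear: dict[str, int] = {}
    for (bb, ww), members in zip(b.choices, d.sets):
        if bb not in members or ww not in members or bb == ww:
            raise ValueError(f"invalid choice ({bb},{ww}) for set {members}")
        best[bb] = best.get(bb, 0) + 1
        worst[ww] = worst.get(ww, 0) + 1
        for code in members:
            appear[code] = appear.get(code, 0) + 1
    return best, worst, appear


def weights_from_bws(
    b: BWSResponse,
    d: BWSDesign,
    h: CriteriaHierarchy | None = None,
    transform: str = "shifted_bw",
) -> WeightVector:
    """Best-worst counts to weights.

    ``shifted_bw``: score_i = (B_i - W_i + r_i) / (2 r_i), a count score
    rescaled to [0, 1] (0 = always worst, 1 = always best), then
    normalized.  ``sqrt_ratio``: score_i = sqrt((B_i+0.5)/(W_i+0.5)),
    the usual choice-ratio analysis with a half count to keep zero counts
    finite, then normalized.
    """
    best, worst, appear = bws_counts(b, d)
    codes = h.codes if h is not None else tuple(sorted(appear))
    missing = [c for c in codes if appear.get(c, 0) == 0]
    if missing:
        raise ValueError(f"criteria never shown in the design: {missing}")
    if transform == "shifted_bw":
        scores = np.array(
            [
                (best.get(c, 0) - worst.get(c, 0) + appear[c]) / (2.0 * appear[c])
                for c in codes
            ]
        )
    elif transform == "sqrt_ratio":
        scores = np.array(
            [
                np.sqrt((best.get(c, 0) + 0.5) / (worst.get(c, 0) + 0.5))
                for c in codes
            ]
        )
    else:
        raise ValueError(f"unknown BWS transform {transform!r}")
    return WeightVector(
        tuple(codes),
        _normalize(scores),
        technique="BWS",
        respondent_id=b.respondent_id,
    )


# ---------------------------------------------------------------------------
# dispatch and tabulation
# ---------------------------------------------------------------------------


def derive_weights(
    response: object,
    h: CriteriaHierarchy,
    design: BWSDesign | None = None,
    *,
    ranking_scheme: str = "rank_sum",
    ahp_method: str = "geometric_mean",
    bws_transform: str = "shifted_bw",
) -> WeightVector:
    """Route a response object to its technique's derivation."""
    if isinstance(response, RatingResponse):
        return weights_from_ratings(response, h)
    if isinstance(response, PointAllocationResponse):
        return weights_from_points(response, h)
    if isinstance(response, RankingResponse):
        return weights_from_ranking(response, h, scheme=ranking_scheme)
    if isinstance(response, PairwiseResponse):
        return weights_from_pairwise(response, h, method=ahp_method)
    if isinstance(response, BWSResponse):
        if design is None:
            raise ValueError("BWS derivation needs the choice-set design")
        return weights_from_bws(response, design, h, transform=bws_transform)
    raise TypeError(f"cannot derive weights from {type(response).__name__}")


def weights_to_frame(
    weight_vectors: Iterable[WeightVector], scale: float = 1.0
) -> pd.DataFrame:
    """Tidy table: respondent_id, technique, criterion, weight.

    ``scale=100`` exports weights as points out of 100, a presentation
    that makes small differences between criteria easier to read without
    changing any downstream analysis.
    """
    rows = [
        dict(
            respondent_id=w.respondent_id,
            technique=w.technique,
            criterion=code,
            weight=float(val) * scale,
        )
        for w in weight_vectors
        for code, val in zip(w.codes, w.values)
    ]
    return pd.DataFrame(rows, columns=["respondent_id", "technique", "criterion", "weight"])
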