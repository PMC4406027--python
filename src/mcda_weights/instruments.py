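"""Elicitation instruments: response containers, validation, and designs.

Five techniques are modelled, using the labels of the underlying study
design:

``RS_nH``
    Five-point rating of all criteria in one flat list.
``RS_H``
    Five-point rating of categories and of criteria within each category.
``RA``
    Ranking of categories and of criteria within each category.
``PA``
    Allocation of a 100-point budget over categories and, separately,
    over the criteria within each category.
``PC``
    Pairwise comparison on the reciprocal 1-9 scale of the analytic
    hierarchy process, administered hierarchically: one block comparing
    the categories, plus one block per category comparing its members.
``BWS``
    Best-worst scaling (object case): repeated choice of the most and
    least important criterion from small subsets.

Responses are plain dataclasses; validation never raises on bad content
but returns a report listing every violation, so a whole survey file can
be triaged in one pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import TOP_BLOCK, CriteriaHierarchy

__all__ = [
    "TECHNIQUES",
    "RATING_MIN",
    "RATING_MAX",
    "ADMISSIBLE_JUDGMENTS",
    "RatingResponse",
    "RankingResponse",
    "PointAllocationResponse",
    "PairwiseJudgment",
    "PairwiseResponse",
    "BWSDesign",
    "BWSResponse",
    "Violation",
    "ValidationReport",
    "make_bws_design",
    "pc_num_comparisons",
    "validate_responses",
    "responses_to_frame",
    "frame_to_responses",
]

TECHNIQUES = ("RS_nH", "RS_H", "RA", "PA", "PC", "BWS")

RATING_MIN, RATING_MAX = 1, 5
POINT_BUDGET = 100.0
POINT_TOL = 1e-9

#: The admissible pairwise judgment values: 1/9 .. 1/2, 1, 2 .. 9.
ADMISSIBLE_JUDGMENTS = tuple(1.0 / k for k in range(9, 1, -1)) + tuple(
    float(k) for k in range(1, 10)
)


# ---------------------------------------------------------------------------
# response containers
# ---------------------------------------------------------------------------


@dataclass
class RatingResponse:
    """Five-point importance ratings, flat or hierarchical."""

    respondent_id: str
    ratings: dict[str, int]
    category_ratings: dict[str, int] | None = None

    @property
    def technique(self) -> str:
        return "RS_H" if self.category_ratings is not None else "RS_nH"

    @property
    def hierarchical(self) -> bool:
        return self.category_ratings is not None


@dataclass
class RankingResponse:
    """Complete rankings (1 = most important) of categories and members."""

    respondent_id: str
    category_ranks: dict[str, int]
    within_ranks: dict[str, dict[str, int]]
    technique: str = "RA"


@dataclass
class PointAllocationResponse:
    """100-point budgets over categories and within each category."""

    respondent_id: str
    category_points: dict[str, float]
    within_points: dict[str, dict[str, float]]
    technique: str = "PA"


@dataclass(frozen=True)
class PairwiseJudgment:
    """One pairwise comparison inside a judgment block.

    ``value`` > 1 favours ``a``; < 1 favours ``b``; 1 means indifference.
    The reciprocal judgment for ``(b, a)`` is implied as ``1/value`` and
    never stored separately.
    """

    block: str
    a: str
    b: str
    value: float


@dataclass
class PairwiseResponse:
    """All pairwise judgments of one respondent (hierarchical blocks)."""

    respondent_id: str
    judgments: list[PairwiseJudgment]
    technique: str = "PC"

    def matrix(self, block: str, items: Sequence[str]) -> np.ndarray:
        """Reciprocal comparison matrix of a block in the given item order."""
        n = len(items)
        pos = {code: i for i, code in enumerate(items)}
        m = np.full((n, n), np.nan)
        np.fill_diagonal(m, 1.0)
        for j in self.judgments:
            if j.block != block:
                continue
            if j.a not in pos or j.b not in pos:
                raise KeyError(f"judgment {j.a}/{j.b} not in block {block!r}")
            if j.value <= 0:
                raise ValueError(f"non-positive judgment {j.value} for {j.a}/{j.b}")
            m[pos[j.a], pos[j.b]] = j.value
            m[pos[j.b], pos[j.a]] = 1.0 / j.value
        if np.isnan(m).any():
            missing = [
                (items[r], items[c])
                for r, c in zip(*np.nonzero(np.isnan(m)))
                if r < c
            ]
            raise ValueError(f"block {block!r}: missing pairs {missing}")
        return m


@dataclass(frozen=True)
class BWSDesign:
    """A best-worst scaling design: ordered choice sets of criterion codes."""

    sets: tuple[tuple[str, ...], ...]

    @property
    def set_size(self) -> int:
        return len(self.sets[0])

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def appearance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sets:
            for code in s:
                counts[code] = counts.get(code, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"set_index": i, **{f"member_{k + 1}": code for k, code in enumerate(s)}}
            for i, s in enumerate(self.sets)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BWSDesign":
        member_cols = sorted(
            (c for c in frame.columns if c.startswith("member_")),
            key=lambda c: int(c.split("_")[1]),
        )
        frame = frame.sort_values("set_index")
        return cls(
            tuple(tuple(row[c] for c in member_cols) for _, row in frame.iterrows())
        )


@dataclass
class BWSResponse:
    """Best/worst choices, one pair per choice set of the design."""

    respondent_id: str
    choices: list[tuple[str, str]]  # (best, worst) per set, in design order
    technique: str = "BWS"


# ---------------------------------------------------------------------------
# designs and counts
# ---------------------------------------------------------------------------


def pc_num_comparisons(n_items: int) -> int:
    """Number of pairwise judgments needed for ``n_items``: n(n-1)/2.

    For the 14 EVIDEM criteria compared in one flat block this is 91 —
    the workload that motivates hierarchical administration.
    """
    if n_items < 2:
        raise ValueError("need at least 2 items to compare")
    return n_items * (n_items - 1) // 2


def make_bws_design(
    h: CriteriaHierarchy,
    n_sets: int = 12,
    set_size: int = 4,
    seed: int | np.random.Generator = 0,
) -> BWSDesign:
    """Build a balanced best-worst choice-set design.

    Greedy construction: each set takes the least-shown criteria first
    (ties broken by co-appearance pressure, then randomly), so appearance
    counts differ by at most one across criteria.  With the default 12
    sets of 4 over 14 criteria the 48 slots yield counts of 3 or 4 —
    exact balance is arithmetically impossible there.  Reproducible from
    the seed.
    """
    codes = list(h.codes)
    n = len(codes)
    if set_size >= n:
        raise ValueError(f"set_size {set_size} must be smaller than {n} criteria")
    if n_sets * set_size < n:
        raise ValueError("design too small: every criterion must appear at least once")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = {c: 0 for c in codes}
    co = pd.DataFrame(0, index=codes, columns=codes)
    sets: list[tuple[str, ...]] = []
    for _ in range(n_sets):
        chosen: list[str] = []
        for _ in range(set_size):
            pool = [c for c in codes if c not in chosen]
            # least shown first; among those, least co-shown with current set
            pressure = {
                c: (counts[c], sum(int(co.at[c, d]) for d in chosen)) for c in pool
            }
            best = min(pressure.values())
            tied = [c for c in pool if pressure[c] == best]
            chosen.append(tied[int(rng.integers(len(tied)))])
        for a, b in itertools.combinations(chosen, 2):
            co.at[a, b] += 1
            co.at[b, a] += 1
        for c in chosen:
            counts[c] += 1
        sets.append(tuple(chosen))
    return BWSDesign(tuple(sets))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    respondent_id: str
    technique: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, respondent_id: str, technique: str, message: str) -> None:
        self.violations.append(Violation(respondent_id, technique, message))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(v) for v in self.violations],
            columns=["respondent_id", "technique", "message"],
        )

    def __len__(self) -> int:
        return len(self.violations)


def _check_rating_block(
    report: ValidationReport,
    rid: str,
    tech: str,
    block: str,
    given: Mapping[str, int],
    expected: Sequence[str],
) -> None:
    for code in expected:
        if code not in given:
            report.add(rid, tech, f"{block}: missing rating for {code}")
        else:
            v = given[code]
            if not (isinstance(v, (int, np.integer)) and RATING_MIN <= v <= RATING_MAX):
                report.add(rid, tech, f"{block}: rating {v!r} for {code} not in 1..5")
    for code in given:
        if code not in expected:
            report.add(rid, tech, f"{block}: unexpected item {code}")


def _check_rank_block(
    report: ValidationReport,
    rid: str,
    tech: str,
    block: str,
    ranks: Mapping[str, int],
    expected: Sequence[str],
) -> None:
    if set(ranks) != set(expected):
        report.add(rid, tech, f"{block}: items {sorted(ranks)} != {sorted(expected)}")
        return
    if sorted(ranks.values()) != list(range(1, len(expected) + 1)):
        report.add(
            rid, tech, f"{block}: ranks {sorted(ranks.values())} not a permutation"
        )


def _check_point_block(
    report: ValidationReport,
    rid: str,
    tech: str,
    block: str,
    points: Mapping[str, float],
    expected: Sequence[str],
) -> None:
    if set(points) != set(expected):
        report.add(rid, tech, f"{block}: items {sorted(points)} != {sorted(expected)}")
        return
    if any(p < 0 for p in points.values()):
        report.add(rid, tech, f"{block}: negative points")
    total = float(sum(points.values()))
    if abs(total - POINT_BUDGET) > POINT_TOL:
        report.add(rid, tech, f"{block}: points sum to {total}, expected 100")


def validate_responses(
    responses: Iterable[object],
    h: CriteriaHierarchy,
    design: BWSDesign | None = None,
) -> ValidationReport:
    """Check every response against the instrument invariants.

    Violations are collected, not raised; a clean survey yields an empty
    report.  BWS responses need the ``design`` they were answered against.
    """
    report = ValidationReport()
    for resp in responses:
        rid = getattr(resp, "respondent_id", "?")
        if isinstance(resp, RatingResponse):
            tech = resp.technique
            _check_rating_block(report, rid, tech, "leaves", resp.ratings, h.codes)
            if resp.category_ratings is not None:
                _check_rating_block(
                    report, rid, tech, TOP_BLOCK, resp.category_ratings, h.categories
                )
        elif isinstance(resp, RankingResponse):
            _check_rank_block(
                report, rid, "RA", TOP_BLOCK, resp.category_ranks, h.categories
            )
            for cat in h.categories:
                block = resp.within_ranks.get(cat)
                if block is None:
                    report.add(rid, "RA", f"{cat}: missing within-category ranks")
                else:
                    _check_rank_block(
                        report, rid, "RA", cat, block, h.category_codes(cat)
                    )
        elif isinstance(resp, PointAllocationResponse):
            _check_point_block(
                report, rid, "PA", TOP_BLOCK, resp.category_points, h.categories
            )
            for cat in h.categories:
                block = resp.within_points.get(cat)
                if block is None:
                    report.add(rid, "PA", f"{cat}: missing within-category points")
                else:
                    _check_point_block(
                        report, rid, "PA", cat, block, h.category_codes(cat)
                    )
        elif isinstance(resp, PairwiseResponse):
            _validate_pairwise(report, resp, h)
        elif isinstance(resp, BWSResponse):
            if design is None:
                report.add(rid, "BWS", "no design supplied for BWS validation")
                continue
            if len(resp.choices) != design.n_sets:
                report.add(
                    rid,
                    "BWS",
                    f"{len(resp.choices)} choice pairs for {design.n_sets} sets",
                )
                continue
            for i, ((best, worst), members) in enumerate(
                zip(resp.choices, design.sets)
            ):
                if best == worst:
                    report.add(rid, "BWS", f"set {i}: best equals worst ({best})")
                if best not in members:
                    report.add(rid, "BWS", f"set {i}: best {best} not in set")
                if worst not in members:
                    report.add(rid, "BWS", f"set {i}: worst {worst} not in set")
        else:
            report.add(rid, type(resp).__name__, "unknown response type")
    return report


def _validate_pairwise(
    report: ValidationReport, resp: PairwiseResponse, h: CriteriaHierarchy
) -> None:
    rid = resp.respondent_id
    blocks = {TOP_BLOCK: h.categories, **{c: h.category_codes(c) for c in h.categories}}
    seen: dict[str, set[frozenset]] = {b: set() for b in blocks}
    for j in resp.judgments:
        if j.block not in blocks:
            report.add(rid, "PC", f"unknown block {j.block!r}")
            continue
        items = blocks[j.block]
        if j.a not in items or j.b not in items:
            report.add(rid, "PC", f"{j.block}: pair ({j.a},{j.b}) not in block")
            continue
        if not any(np.isclose(j.value, g, rtol=1e-9) for g in ADMISSIBLE_JUDGMENTS):
            report.add(
                rid, "PC", f"{j.block}: judgment {j.value} not on the 1/9..9 scale"
            )
        key = frozenset((j.a, j.b))
        if key in seen[j.block]:
            report.add(rid, "PC", f"{j.block}: duplicate judgment for ({j.a},{j.b})")
        seen[j.block].add(key)
    for block, items in blocks.items():
        expected = {frozenset(p) for p in itertools.combinations(items, 2)}
        missing = expected - seen[block]
        for pair in sorted(missing, key=sorted):
            report.add(rid, "PC", f"{block}: missing judgment for {tuple(sorted(pair))}")


# ---------------------------------------------------------------------------
# tabular (CSV) interchange
# ---------------------------------------------------------------------------

RESPONSE_COLUMNS = ["respondent_id", "technique", "block", "item", "value"]
BWS_COLUMNS = ["respondent_id", "set_index", "best", "worst"]


def responses_to_frame(responses: Iterable[object]) -> pd.DataFrame:
    """Flatten non-BWS responses to the long tabular dialect.

    One row per (respondent, technique, block, item, value).  Pairwise
    rows store the pair as ``item = "A|B"``.  BWS responses have their
    own dialect (see :data:`BWS_COLUMNS`) and are rejected here.
    """
    rows: list[dict] = []
    for resp in responses:
        rid = resp.respondent_id
        if isinstance(resp, RatingResponse):
            tech = resp.technique
            if resp.category_ratings is not None:
                for code, v in resp.category_ratings.items():
                    rows.append(
                        dict(
                            respondent_id=rid,
                            technique=tech,
                            block=TOP_BLOCK,
                            item=code,
                            value=v,
                        )
                    )
            for code, v in resp.ratings.items():
                rows.append(
                    dict(
                        respondent_id=rid,
                        technique=tech,
                        block="LEAF",
                        item=code,
                        value=v,
                    )
                )
        elif isinstance(resp, RankingResponse):
            for code, v in resp.category_ranks.items():
                rows.append(
                    dict(
                        respondent_id=rid,
                        technique="RA",
                        block=TOP_BLOCK,
                        item=code,
                        value=v,
                    )
                )
            for cat, block in resp.within_ranks.items():
                for code, v in block.items():
                    rows.append(
                        dict(
                            respondent_id=rid,
                            technique="RA",
                            block=cat,
                            item=code,
                            value=v,
                        )
                    )
        elif isinstance(resp, PointAllocationResponse):
            for code, v in resp.category_points.items():
                rows.append(
                    dict(
                        respondent_id=rid,
                        technique="PA",
                        block=TOP_BLOCK,
                        item=code,
                        value=v,
                    )
                )
            for cat, block in resp.within_points.items():
                for code, v in block.items():
                    rows.append(
                        dict(
                            respondent_id=rid,
                            technique="PA",
                            block=cat,
                            item=code,
                            value=v,
                        )
                    )
        elif isinstance(resp, PairwiseResponse):
            for j in resp.judgments:
                rows.append(
                    dict(
                        respondent_id=rid,
                        technique="PC",
                        block=j.block,
                        item=f"{j.a}|{j.b}",
                        value=j.value,
                    )
                )
        elif isinstance(resp, BWSResponse):
            raise TypeError("BWS responses use bws_responses_to_frame")
        else:
            raise TypeError(f"unknown response type {type(resp).__name__}")
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def bws_responses_to_frame(responses: Iterable[BWSResponse]) -> pd.DataFrame:
    rows = [
        dict(respondent_id=r.respondent_id, set_index=i, best=b, worst=w)
        for r in responses
        for i, (b, w) in enumerate(r.choices)
    ]
    return pd.DataFrame(rows, columns=BWS_COLUMNS)


def frame_to_responses(frame: pd.DataFrame) -> list[object]:
    """Rebuild response objects from the long tabular dialect."""
    out: list[object] = []
    for (rid, tech), grp in frame.groupby(["respondent_id", "technique"], sort=False):
        rid = str(rid)
        if tech in ("RS_nH", "RS_H"):
            leaves = grp[grp["block"] == "LEAF"]
            cats = grp[grp["block"] == TOP_BLOCK]
            out.append(
                RatingResponse(
                    respondent_id=rid,
                    ratings={r.item: int(r.value) for r in leaves.itertuples()},
                    category_ratings=(
                        {r.item: int(r.value) for r in cats.itertuples()}
                        if tech == "RS_H"
                        else None
                    ),
                )
            )
        elif tech == "RA":
            top = grp[grp["block"] == TOP_BLOCK]
            out.append(
                RankingResponse(
                    respondent_id=rid,
                    category_ranks={r.item: int(r.value) for r in top.itertuples()},
                    within_ranks={
                        str(cat): {r.item: int(r.value) for r in sub.itertuples()}
                        for cat, sub in grp[grp["block"] != TOP_BLOCK].groupby(
                            "block", sort=False
                        )
                    },
                )
            )
        elif tech == "PA":
            top = grp[grp["block"] == TOP_BLOCK]
            out.append(
                PointAllocationResponse(
                    respondent_id=rid,
                    category_points={r.item: float(r.value) for r in top.itertuples()},
                    within_points={
                        str(cat): {r.item: float(r.value) for r in sub.itertuples()}
                        for cat, sub in grp[grp["block"] != TOP_BLOCK].groupby(
                            "block", sort=False
                        )
                    },
                )
            )
        elif tech == "PC":
            judgments = [
                PairwiseJudgment(
                    block=str(r.block),
                    a=r.item.split("|")[0],
                    b=r.item.split("|")[1],
                    value=float(r.value),
                )
                for r in grp.itertuples()
            ]
            out.append(PairwiseResponse(respondent_id=rid, judgments=judgments))
        else:
            raise ValueError(f"unknown technique {tech!r} in response table")
    return out


def frame_to_bws_responses(frame: pd.DataFrame) -> list[BWSResponse]:
    out = []
    for rid, grp in frame.groupby("respondent_id", sort=False):
        grp = grp.sort_values("set_index")
        out.append(
            BWSResponse(
                respondent_id=str(rid),
                choices=[(r.best, r.worst) for r in grp.itertuples()],
            )
        )
    return out


def read_response_csv(path: str | Path) -> list[object]:
    return frame_to_responses(pd.read_csv(path))


def read_bws_csv(path: str | Path) -> list[BWSResponse]:
    return frame_to_bws_responses(pd.read_csv(path))
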