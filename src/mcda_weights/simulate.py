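"""Synthetic respondent cohorts with the weighting study's design.

The generator emulates a two-technique survey: every respondent answers
the flat five-point rating scale plus the technique of their arm
(ranking + point allocation, pairwise comparison, best-worst scaling, or
hierarchical rating; 15 respondents per arm, 60 in total by default), in
randomized order.

Statistical structure:

* each respondent carries a latent importance vector on the 14-criterion
  simplex, drawn from a symmetric Dirichlet.  The default concentration
  (4 per component) reproduces the magnitude of individual departure
  from equal weights seen in real elicitation data of this kind (mean
  |w_i - 1/14| around 0.027);
* a consistency parameter ``kappa`` scales multiplicative response
  noise: shares are perturbed by lognormal noise with sigma = 1/kappa
  before each instrument discretizes them.  ``kappa = inf`` is the
  noiseless limit;
* each instrument then discretizes the (perturbed) latent the way its
  response format forces: ratings are anchored to the block's most
  important item (rating = round(5 * share / max share), clipped to
  1..5); rankings sort the perturbed shares; point budgets are
  multinomial draws of 100 points; pairwise judgments snap the share
  ratio to the admissible 1/9..9 grid; best/worst picks are the
  arg-max/arg-min within each choice set;
* an optional anchoring (order) effect: at second position the latent is
  shrunk toward uniform by a factor ``alpha``, reproducing the observed
  tendency to discriminate less the second time.

All randomness flows from one master seed through named substreams
(latents, design, order, noise, scores) so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import TOP_BLOCK, CriteriaHierarchy
from .instruments import (
    ADMISSIBLE_JUDGMENTS,
    BWSDesign,
    BWSResponse,
    PairwiseJudgment,
    PairwiseResponse,
    PointAllocationResponse,
    RankingResponse,
    RatingResponse,
    bws_responses_to_frame,
    make_bws_design,
    responses_to_frame,
)
from .value import ScoreVector

__all__ = [
    "LatentPreference",
    "StudyDesign",
    "SimulatedCohort",
    "draw_latents",
    "respond",
    "simulate_cohort",
    "draw_scores",
]

#: Population mean importance profile for the 14 EVIDEM criteria, in
#: canonical leaf order.  Taken from observed group-mean weights of a
#: flat five-point rating of these criteria by a student cohort, so the
#: simulated population prefers disease impact and intervention-outcome
#: criteria over contextual ones the way real respondents do.
DEFAULT_POPULATION_MEAN = np.array(
    [0.089, 0.100, 0.080, 0.065, 0.085, 0.069, 0.076,
     0.052, 0.072, 0.075, 0.057, 0.061, 0.066, 0.057]
)
DEFAULT_POPULATION_MEAN = DEFAULT_POPULATION_MEAN / DEFAULT_POPULATION_MEAN.sum()

#: Total Dirichlet concentration (sum of the parameter vector).  56 over
#: 14 criteria (i.e. 4 per criterion) reproduces the observed magnitude
#: of individual departure from equal weights, mean |w_i - 1/14| ~ 0.027.
DEFAULT_TOTAL_CONCENTRATION = 56.0

DEFAULT_KAPPA = 8.0

# kept for backward-compatible symmetric draws on non-default hierarchies
DEFAULT_CONCENTRATION = 4.0


def default_concentration(n_criteria: int = 14) -> np.ndarray:
    """Default Dirichlet parameters: asymmetric for the 14-criterion
    hierarchy (population-mean profile times total concentration),
    symmetric 4-per-component otherwise."""
    if n_criteria == DEFAULT_POPULATION_MEAN.size:
        return DEFAULT_TOTAL_CONCENTRATION * DEFAULT_POPULATION_MEAN
    return np.full(n_criteria, DEFAULT_CONCENTRATION)

_SUBSTREAMS = ("latents", "design", "order", "noise", "scores")


@dataclass(frozen=True)
class LatentPreference:
    """A respondent's true importance vector and consistency."""

    respondent_id: str
    weights: np.ndarray  # on the simplex, canonical leaf order
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("latent weights must lie on the simplex")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: arm sizes, order randomization, anchoring strength."""

    cohort_size: int = 60
    arms: Mapping[str, int] = field(
        default_factory=lambda: {"RA+PA": 15, "PC": 15, "BWS": 15, "RS_H": 15}
    )
    randomize_order: bool = True
    anchoring: float = 0.3  # shrinkage toward uniform at second position
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.arms.values()) != self.cohort_size:
            raise ValueError(
                f"arm sizes {dict(self.arms)} do not sum to cohort {self.cohort_size}"
            )
        if self.anchoring < 0:
            raise ValueError("anchoring strength must be >= 0")

    def arm_techniques(self, arm: str) -> tuple[str, ...]:
        return tuple(arm.split("+"))


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def draw_latents(
    n: int,
    concentration: float | Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
    n_criteria: int = 14,
    kappa: float = DEFAULT_KAPPA,
) -> list[LatentPreference]:
    """Draw ``n`` independent Dirichlet importance vectors.

    ``concentration`` may be a scalar (symmetric Dirichlet), a full
    parameter vector, or ``None`` for the default asymmetric population
    profile.
    """
    if concentration is None:
        concentration = default_concentration(n_criteria)
    conc = np.asarray(
        np.broadcast_to(np.asarray(concentration, dtype=float), n_criteria)
    )
    if (conc <= 0).any():
        raise ValueError("Dirichlet concentration must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.dirichlet(conc, size=n)
    return [
        LatentPreference(respondent_id=f"R{i + 1:03d}", weights=draws[i], kappa=kappa)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# response models
# ---------------------------------------------------------------------------


def _perturb(shares: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal noise with sigma = 1/kappa, renormalized."""
    if np.isinf(kappa):
        return shares
    noisy = shares * rng.lognormal(0.0, 1.0 / kappa, size=shares.shape)
    return noisy / noisy.sum()


def _anchored(w: np.ndarray, position: int, alpha: float) -> np.ndarray:
    if position == 2 and alpha > 0:
        return (1.0 - alpha) * w + alpha / w.size
    return w


def _rating_block(shares: np.ndarray) -> np.ndarray:
    """Ratings anchored to the block's most important item."""
    r = np.clip(np.round(5.0 * shares / shares.max()), 1, 5)
    return r.astype(int)


def _rank_block(shares: np.ndarray) -> np.ndarray:
    """Ranks 1..n, 1 = largest share; deterministic tie-break by index."""
    order = np.lexsort((np.arange(shares.size), -shares))
    ranks = np.empty(shares.size, dtype=int)
    ranks[order] = np.arange(1, shares.size + 1)
    return ranks


def _point_block(
    shares: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """100-point budget: exact at kappa=inf, multinomial otherwise."""
    if np.isinf(kappa):
        return 100.0 * shares
    return rng.multinomial(100, shares).astype(float)


_LOG_GRID = np.log(np.asarray(ADMISSIBLE_JUDGMENTS))


def _snap_judgment(ratio: float) -> float:
    """Nearest admissible 1/9..9 value in log space."""
    return float(ADMISSIBLE_JUDGMENTS[int(np.argmin(np.abs(_LOG_GRID - np.log(ratio))))])


def _category_shares(w: np.ndarray, h: CriteriaHierarchy) -> np.ndarray:
    codes = list(h.codes)
    return np.array(
        [sum(w[codes.index(c)] for c in h.category_codes(cat)) for cat in h.categories]
    )


def respond(
    latent: LatentPreference,
    technique: str,
    h: CriteriaHierarchy,
    rng: np.random.Generator,
    position: int = 1,
    alpha: float = 0.0,
    design: BWSDesign | None = None,
) -> object:
    """Generate one technique-specific response from a latent preference."""
    w = _anchored(latent.weights, position, alpha)
    kappa = latent.kappa
    codes = list(h.codes)

    if technique == "RS_nH":
        p = _perturb(w, kappa, rng)
        return RatingResponse(
            respondent_id=latent.respondent_id,
            ratings=dict(zip(codes, map(int, _rating_block(p)))),
        )

    if technique == "RS_H":
        cat_p = _perturb(_category_shares(w, h), kappa, rng)
        ratings: dict[str, int] = {}
        for cat in h.categories:
            members = h.category_codes(cat)
            local = np.array([w[codes.index(c)] for c in members])
            local = _perturb(local / local.sum(), kappa, rng)
            for c, r in zip(members, _rating_block(local)):
                ratings[c] = int(r)
        return RatingResponse(
            respondent_id=latent.respondent_id,
            ratings=ratings,
            category_ratings=dict(zip(h.categories, map(int, _rating_block(cat_p)))),
        )

    if technique == "RA":
        cat_p = _perturb(_category_shares(w, h), kappa, rng)
        within = {}
        for cat in h.categories:
            members = h.category_codes(cat)
            local = np.array([w[codes.index(c)] for c in members])
            local = _perturb(local / local.sum(), kappa, rng)
            within[cat] = dict(zip(members, map(int, _rank_block(local))))
        return RankingResponse(
            respondent_id=latent.respondent_id,
            category_ranks=dict(zip(h.categories, map(int, _rank_block(cat_p)))),
            within_ranks=within,
        )

    if technique == "PA":
        cat_p = _perturb(_category_shares(w, h), kappa, rng)
        within = {}
        for cat in h.categories:
            members = h.category_codes(cat)
            local = np.array([w[codes.index(c)] for c in members])
            local = _perturb(local / local.sum(), kappa, rng)
            within[cat] = dict(
                zip(members, map(float, _point_block(local, kappa, rng)))
            )
        return PointAllocationResponse(
            respondent_id=latent.respondent_id,
            category_points=dict(
                zip(h.categories, map(float, _point_block(cat_p, kappa, rng)))
            ),
            within_points=within,
        )

    if technique == "PC":
        judgments: list[PairwiseJudgment] = []
        for block in (TOP_BLOCK, *h.categories):
            items = h.block_items(block)
            if block == TOP_BLOCK:
                shares = _category_shares(w, h)
            else:
                shares = np.array([w[codes.index(c)] for c in items])
                shares = shares / shares.sum()
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    ratio = shares[i] / shares[j]
                    if not np.isinf(kappa):
                        ratio *= rng.lognormal(0.0, 1.0 / kappa)
                    judgments.append(
                        PairwiseJudgment(
                            block=block,
                            a=items[i],
                            b=items[j],
                            value=_snap_judgment(ratio),
                        )
                    )
        return PairwiseResponse(respondent_id=latent.respondent_id, judgments=judgments)

    if technique == "BWS":
        if design is None:
            raise ValueError("BWS responses need a choice-set design")
        choices: list[tuple[str, str]] = []
        for members in design.sets:
            local = np.array([w[codes.index(c)] for c in members])
            local = _perturb(local / local.sum(), kappa, rng)
            best_i = int(np.argmax(local))
            # stable ascending sort; skip the best item so a flat block
            # still yields best != worst
            order = np.argsort(local, kind="stable")
            worst_i = int(order[0]) if int(order[0]) != best_i else int(order[1])
            choices.append((members[best_i], members[worst_i]))
        return BWSResponse(respondent_id=latent.respondent_id, choices=choices)

    raise ValueError(f"unknown technique {technique!r}")


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """Everything one simulated survey run produced."""

    hierarchy: CriteriaHierarchy
    design: StudyDesign
    bws_design: BWSDesign
    responses: list[object]
    bws_responses: list[BWSResponse]
    orders: pd.DataFrame  # respondent_id, technique, position
    ground_truth: pd.DataFrame  # respondent_id, criterion, latent_weight, kappa, arm, rs_position
    latents: list[LatentPreference]

    def all_responses(self) -> list[object]:
        return [*self.responses, *self.bws_responses]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the CSV file set; byte-identical for identical seeds."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "responses": out / "responses.csv",
            "bws_responses": out / "bws_responses.csv",
            "bws_design": out / "bws_design.csv",
            "orders": out / "orders.csv",
            "ground_truth": out / "ground_truth.csv",
        }
        responses_to_frame(self.responses).to_csv(paths["responses"], index=False)
        bws_responses_to_frame(self.bws_responses).to_csv(
            paths["bws_responses"], index=False
        )
        self.bws_design.to_frame().to_csv(paths["bws_design"], index=False)
        self.orders.to_csv(paths["orders"], index=False)
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


def simulate_cohort(
    design: StudyDesign,
    h: CriteriaHierarchy | None = None,
    concentration: float | Sequence[float] | None = None,
    kappa: float = DEFAULT_KAPPA,
) -> SimulatedCohort:
    """Simulate a full two-technique survey cohort.

    Every respondent answers the flat rating scale plus their arm's
    technique(s); presentation order is randomized per respondent when
    the design says so (otherwise the rating scale comes first).
    """
    if h is None:
        h = CriteriaHierarchy.default()
    rngs = _substreams(design.seed)
    latents = draw_latents(
        design.cohort_size,
        concentration,
        seed=rngs["latents"],
        n_criteria=h.n_criteria,
        kappa=kappa,
    )
    bws_design = make_bws_design(h, seed=rngs["design"])

    arm_of: list[str] = []
    for arm, size in design.arms.items():
        arm_of.extend([arm] * size)

    responses: list[object] = []
    bws_responses: list[BWSResponse] = []
    order_rows: list[dict] = []
    truth_rows: list[dict] = []
    noise = rngs["noise"]
    for latent, arm in zip(latents, arm_of):
        rs_position = (
            1 + int(rngs["order"].integers(2)) if design.randomize_order else 1
        )
        arm_position = 2 if rs_position == 1 else 1
        plan = [("RS_nH", rs_position)] + [
            (t, arm_position) for t in design.arm_techniques(arm)
        ]
        for tech, position in plan:
            resp = respond(
                latent,
                tech,
                h,
                noise,
                position=position,
                alpha=design.anchoring,
                design=bws_design,
            )
            if tech == "BWS":
                bws_responses.append(resp)  # type: ignore[arg-type]
            else:
                responses.append(resp)
            order_rows.append(
                dict(
                    respondent_id=latent.respondent_id,
                    technique=tech,
                    position=position,
                )
            )
        for code, wv in zip(h.codes, latent.weights):
            truth_rows.append(
                dict(
                    respondent_id=latent.respondent_id,
                    criterion=code,
                    latent_weight=float(wv),
                    kappa=kappa if np.isfinite(kappa) else np.inf,
                    arm=arm,
                    rs_position=rs_position,
                )
            )
    return SimulatedCohort(
        hierarchy=h,
        design=design,
        bws_design=bws_design,
        responses=responses,
        bws_responses=bws_responses,
        orders=pd.DataFrame(order_rows, columns=["respondent_id", "technique", "position"]),
        ground_truth=pd.DataFrame(
            truth_rows,
            columns=[
                "respondent_id",
                "criterion",
                "latent_weight",
                "kappa",
                "arm",
                "rs_position",
            ],
        ),
        latents=latents,
    )


def draw_scores(
    h: CriteriaHierarchy,
    s_max: float = 3.0,
    seed: int | np.random.Generator = 0,
    kind: str = "uniform",
) -> ScoreVector:
    """Performance scores for a hypothetical intervention.

    ``uniform`` draws each criterion's score independently on
    [0, s_max]; ``mid`` sets every score to s_max/2; ``max`` to s_max.
    """
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = h.n_criteria
    if kind == "uniform":
        vals = rng.uniform(0.0, s_max, size=n)
    elif kind == "mid":
        vals = np.full(n, s_max / 2.0)
    elif kind == "max":
        vals = np.full(n, float(s_max))
    else:
        raise ValueError(f"unknown score kind {kind!r}")
    return ScoreVector(h.codes, vals, s_max=s_max)
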