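"""Model/results interface for a weight-elicitation comparison study.

:class:`ElicitationStudy` holds the raw material of one study — a
criteria hierarchy, the respondents' instrument responses (real or
simulated), optionally performance scores for a hypothetical
intervention and the per-respondent technique order.  :meth:`fit`
derives every respondent's weight vector and returns a
:class:`StudyResults` carrying the estimates (group mean weights and
value estimates with their dispersion), the diagnostics (discriminative
power, rank stability, agreement and Bland-Altman statistics against
the flat rating-scale reference) and a ``summary()`` table.

>>> from mcda_weights import ElicitationStudy, StudyDesign
>>> study = ElicitationStudy.from_simulation(StudyDesign(seed=7))
>>> res = study.fit()
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from . import agreement as agr
from .derive import derive_weights, weights_to_frame
from .hierarchy import CriteriaHierarchy
from .instruments import BWSDesign, BWSResponse, validate_responses
from .simulate import SimulatedCohort, StudyDesign, draw_scores, simulate_cohort, _substreams
from .value import ScoreVector

__all__ = ["ElicitationStudy", "StudyResults"]

REFERENCE_TECHNIQUE = "RS_nH"


@dataclass
class ElicitationStudy:
    """A weight-elicitation study ready to be fitted.

    Parameters
    ----------
    responses
        Response objects for the direct and pairwise instruments.
    hierarchy
        The criteria tree; defaults to the bundled 14-criterion EVIDEM
        hierarchy.
    bws_responses, bws_design
        Best-worst responses and the choice-set design they answered.
    scores
        Performance scores of the intervention being valued; optional —
        without them the value analysis is skipped.
    orders
        Frame (respondent_id, technique, position) recording at which
        position each respondent met each technique; enables the
        order-effect analysis.
    ranking_scheme, ahp_method, bws_transform, corr_method
        Conversion conventions, surfaced so reports can name them.
    """

    responses: list[object]
    hierarchy: CriteriaHierarchy = field(default_factory=CriteriaHierarchy.default)
    bws_responses: list[BWSResponse] = field(default_factory=list)
    bws_design: BWSDesign | None = None
    scores: ScoreVector | None = None
    orders: pd.DataFrame | None = None
    reference: str = REFERENCE_TECHNIQUE
    ranking_scheme: str = "rank_sum"
    ahp_method: str = "geometric_mean"
    bws_transform: str = "shifted_bw"
    corr_method: str = "pearson"
    ground_truth: pd.DataFrame | None = None

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_simulation(
        cls,
        design: StudyDesign,
        hierarchy: CriteriaHierarchy | None = None,
        concentration=None,
        kappa: float = 8.0,
        s_max: float = 3.0,
        **options,
    ) -> "ElicitationStudy":
        """Simulate a cohort and wrap it as a ready-to-fit study.

        Performance scores are drawn uniformly on [0, s_max] from the
        master seed's ``scores`` substream.
        """
        cohort = simulate_cohort(design, hierarchy, concentration, kappa)
        scores = draw_scores(
            cohort.hierarchy, s_max=s_max, seed=_substreams(design.seed)["scores"]
        )
        return cls.from_cohort(cohort, scores=scores, **options)

    @classmethod
    def from_cohort(
        cls, cohort: SimulatedCohort, scores: ScoreVector | None = None, **options
    ) -> "ElicitationStudy":
        return cls(
            responses=list(cohort.responses),
            hierarchy=cohort.hierarchy,
            bws_responses=list(cohort.bws_responses),
            bws_design=cohort.bws_design,
            scores=scores,
            orders=cohort.orders,
            ground_truth=cohort.ground_truth,
            **options,
        )

    # -- fitting ---------------------------------------------------------

    def validate(self):
        return validate_responses(
            [*self.responses, *self.bws_responses], self.hierarchy, self.bws_design
        )

    def fit(self) -> "StudyResults":
        """Derive all weight vectors and compute every comparison statistic."""
        vectors = [
            derive_weights(
                r,
                self.hierarchy,
                design=self.bws_design,
                ranking_scheme=self.ranking_scheme,
                ahp_method=self.ahp_method,
                bws_transform=self.bws_transform,
            )
            for r in [*self.responses, *self.bws_responses]
        ]
        weights = weights_to_frame(vectors)
        return StudyResults(model=self, weights=weights)


class StudyResults:
    """Fitted results of an :class:`ElicitationStudy`.

    Attributes
    ----------
    weights : pandas.DataFrame
        Tidy per-respondent weights (respondent_id, technique,
        criterion, weight).
    """

    def __init__(self, model: ElicitationStudy, weights: pd.DataFrame):
        self.model = model
        self.weights = weights
        self.hierarchy = model.hierarchy
        self.techniques = tuple(weights["technique"].unique())

    # -- estimates -------------------------------------------------------

    def group_weights(self) -> pd.DataFrame:
        """Mean and sd of each criterion's weight, per technique."""
        g = (
            self.weights.groupby(["technique", "criterion"], sort=False)["weight"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"mean": "weight_mean", "std": "weight_sd", "count": "n"})
        )
        order = {c: i for i, c in enumerate(self.hierarchy.codes)}
        return g.sort_values(
            ["technique", "criterion"],
            key=lambda s: s.map(order) if s.name == "criterion" else s,
            kind="stable",
        ).reset_index(drop=True)

    def technique_weights(self, technique: str) -> pd.DataFrame:
        sub = self.weights[self.weights["technique"] == technique]
        if sub.empty:
            raise KeyError(f"no responses for technique {technique!r}")
        return sub

    # -- discriminative power -------------------------------------------

    def discrimination(self) -> pd.DataFrame:
        """Per-respondent (d13, dml, deq) for every technique."""
        return agr.discrimination_table(self.weights)

    def discrimination_summary(self) -> pd.DataFrame:
        """Group mean/sd of the three measures plus t-tests against zero."""
        disc = self.discrimination()
        rows = []
        for tech, grp in disc.groupby("technique", sort=False):
            row: dict = {"technique": tech, "n": len(grp)}
            for m in ("d13", "dml", "deq"):
                row[f"{m}_mean"] = grp[m].mean()
                row[f"{m}_sd"] = grp[m].std(ddof=1) if len(grp) > 1 else 0.0
            for m in ("d13", "dml"):
                if len(grp) >= 2:
                    t, p = agr.test_nonzero(grp[m].to_numpy())
                    row[f"{m}_t"], row[f"{m}_p"] = t, p
            rows.append(row)
        return pd.DataFrame(rows)

    # -- rank stability --------------------------------------------------

    def rank_orders(self) -> pd.DataFrame:
        """Group-level criterion rank order per technique (1 = heaviest)."""
        rows = []
        for tech, grp in self.weights.groupby("technique", sort=False):
            means = grp.groupby("criterion", sort=False)["weight"].mean()
            ro = agr.rank_order(means)
            for code in self.hierarchy.codes:
                rows.append(
                    dict(
                        technique=tech,
                        criterion=code,
                        rank=ro.ranks[code],
                        mean_weight=float(means[code]),
                        tied=code in ro.tied,
                    )
                )
        return pd.DataFrame(rows)

    def rank_differences(self) -> pd.DataFrame:
        """Group- and individual-level rank reversal vs the reference."""
        ref = self.model.reference
        ranks = self.rank_orders()
        ref_ranks = {
            r.criterion: r.rank for r in ranks[ranks["technique"] == ref].itertuples()
        }
        rows = []
        ref_w = self.technique_weights(ref)
        for tech in self.techniques:
            if tech == ref:
                continue
            tech_ranks = {
                r.criterion: r.rank
                for r in ranks[ranks["technique"] == tech].itertuples()
            }
            gmean, gsd = agr.rank_difference(ref_ranks, tech_ranks)
            try:
                imean, isd = agr.individual_rank_difference(
                    ref_w, self.technique_weights(tech)
                )
            except ValueError:
                imean = isd = np.nan
            rows.append(
                dict(
                    technique=tech,
                    group_mean=gmean,
                    group_sd=gsd,
                    individual_mean=imean,
                    individual_sd=isd,
                )
            )
        return pd.DataFrame(rows)

    # -- agreement -------------------------------------------------------

    def correlations(self) -> pd.DataFrame:
        """Across-respondent and mean within-respondent r vs the reference."""
        ref = self.model.reference
        ref_w = self.technique_weights(ref)
        rows = []
        for tech in self.techniques:
            if tech == ref:
                continue
            across, within = agr.agreement_correlations(
                ref_w, self.technique_weights(tech), method=self.model.corr_method
            )
            rows.append(
                dict(
                    technique=tech,
                    across_respondents_r=across,
                    mean_within_respondent_r=within,
                    method=self.model.corr_method,
                )
            )
        return pd.DataFrame(rows)

    def group_bland_altman(self) -> dict[str, agr.BlandAltman]:
        """Group-level Bland-Altman of each technique vs the reference."""
        ref_w = self.technique_weights(self.model.reference)
        return {
            tech: agr.group_bland_altman(ref_w, self.technique_weights(tech))
            for tech in self.techniques
            if tech != self.model.reference
        }

    def individual_bland_altman(self) -> dict[str, agr.BlandAltman]:
        ref_w = self.technique_weights(self.model.reference)
        return {
            tech: agr.individual_bland_altman(ref_w, self.technique_weights(tech))
            for tech in self.techniques
            if tech != self.model.reference
        }

    def order_effect(self) -> dict[str, agr.BlandAltman]:
        """First- vs second-position group weights per technique."""
        if self.model.orders is None:
            raise ValueError("no technique-order information recorded")
        return agr.order_effect_analysis(self.weights, self.model.orders)

    # -- value model -----------------------------------------------------

    def value_estimates(self) -> pd.DataFrame:
        """Per-respondent overall value V and % of maximum, per technique."""
        scores = self.model.scores
        if scores is None:
            raise ValueError("no performance scores attached to the study")
        svec = scores.as_series().reindex(list(self.hierarchy.codes)).to_numpy()
        rows = []
        for (tech, rid), grp in self.weights.groupby(
            ["technique", "respondent_id"], sort=False
        ):
            w = (
                grp.set_index("criterion")["weight"]
                .reindex(list(self.hierarchy.codes))
                .to_numpy()
            )
            V = float(np.dot(w, svec))
            rows.append(
                dict(
                    technique=tech,
                    respondent_id=rid,
                    V=V,
                    pct_of_max=100.0 * V / scores.s_max,
                )
            )
        return pd.DataFrame(rows)

    def value_table(self) -> pd.DataFrame:
        """Group value summary: N, mean V (se; sd), % of maximum, min-max.

        One row per technique, mirroring the usual presentation of
        overall value estimates across elicitation methods.
        """
        est = self.value_estimates()
        rows = []
        for tech, grp in est.groupby("technique", sort=False):
            v = grp["V"].to_numpy()
            rows.append(
                dict(
                    technique=tech,
                    N=len(v),
                    V_mean=v.mean(),
                    V_se=v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
                    V_sd=v.std(ddof=1) if len(v) > 1 else 0.0,
                    pct_of_max=grp["pct_of_max"].mean(),
                    pct_min=grp["pct_of_max"].min(),
                    pct_max=grp["pct_of_max"].max(),
                )
            )
        return pd.DataFrame(rows)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        """Human-readable study summary."""
        lines = [
            "Weight-elicitation study summary",
            "=" * 34,
            f"criteria: {self.hierarchy.n_criteria} in {len(self.hierarchy.categories)} categories",
            f"techniques: {', '.join(self.techniques)}",
            f"reference technique: {self.model.reference}",
            (
                "options: ranking={0}, ahp={1}, bws={2}, correlation={3}".format(
                    self.model.ranking_scheme,
                    self.model.ahp_method,
                    self.model.bws_transform,
                    self.model.corr_method,
                )
            ),
            "",
            "Group rank order (rank 1 = heaviest mean weight)",
            self._rank_table_text(),
            "",
            "Discriminative power (group mean (sd))",
            self.discrimination_summary()
            .round(4)
            .to_string(index=False),
        ]
        rd = self.rank_differences()
        if not rd.empty:
            lines += ["", "Rank differences vs reference", rd.round(3).to_string(index=False)]
        corr = self.correlations()
        if not corr.empty:
            lines += ["", "Agreement vs reference", corr.round(3).to_string(index=False)]
        if self.model.scores is not None:
            lines += [
                "",
                "Overall value estimates",
                self.value_table().round(3).to_string(index=False),
            ]
        return "\n".join(lines)

    def _rank_table_text(self) -> str:
        ranks = self.rank_orders()
        pivot = ranks.pivot(index="criterion", columns="technique", values="rank")
        pivot = pivot.loc[list(self.hierarchy.codes)]
        return pivot.to_string()
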