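"""Statistics for comparing weight-elicitation techniques.

Three families of comparison:

* discriminative power — how far a technique spreads its weights:
  the gap between the 1st- and 3rd-ranked weight (``d13``), between the
  most and least important (``dml``), and the mean absolute distance
  from the equal weight 1/n (``deq``);
* rank stability — criterion rank orders per technique and the mean
  absolute rank difference against a reference technique, at the group
  level (on mean weights) and the individual level (per respondent,
  then averaged);
* agreement — the correlation of across-respondent mean weights, the
  mean within-respondent correlation, and Bland-Altman bias / 95%
  limits of agreement, including the order-effect variant that compares
  a technique administered first versus second in the survey.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "discrimination_measures",
    "discrimination_table",
    "test_nonzero",
    "rank_order",
    "rank_difference",
    "individual_rank_difference",
    "agreement_correlations",
    "bland_altman",
    "order_effect_analysis",
    "BlandAltman",
    "RankOrder",
]


# ---------------------------------------------------------------------------
# discriminative power
# ---------------------------------------------------------------------------


def discrimination_measures(weights: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """(d13, dml, deq) for one weight vector.

    d13 = w_(1) - w_(3) (first minus third largest), dml = w_(1) - w_(n),
    deq = mean |w_i - 1/n|.  All zero iff the vector is uniform; always
    dml >= d13 >= 0.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 3:
        raise ValueError("need at least 3 criteria")
    s = np.sort(w)[::-1]
    d13 = float(s[0] - s[2])
    dml = float(s[0] - s[-1])
    deq = float(np.mean(np.abs(w - 1.0 / w.size)))
    return d13, dml, deq


def discrimination_table(weights: pd.DataFrame) -> pd.DataFrame:
    """Per-respondent measures plus group mean/sd, per technique.

    ``weights`` is the tidy table (respondent_id, technique, criterion,
    weight).  Returns one row per (technique, respondent) with columns
    d13, dml, deq.
    """
    rows = []
    for (tech, rid), grp in weights.groupby(["technique", "respondent_id"], sort=False):
        d13, dml, deq = discrimination_measures(grp["weight"].to_numpy())
        rows.append(dict(technique=tech, respondent_id=rid, d13=d13, dml=dml, deq=deq))
    return pd.DataFrame(rows)


def test_nonzero(differences: Sequence[float]) -> tuple[float, float]:
    """One-sample two-sided t-test of mean zero.

    Used on per-respondent weight gaps (d13, dml) to ask whether a
    technique discriminates at all.  Degenerate zero-variance samples
    get the conventional limits: p=1 when the mean is also zero, p=0
    (t=inf) otherwise.
    """
    x = np.asarray(differences, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0.0:
        return (0.0, 1.0) if x[0] == 0.0 else (np.inf, 0.0)
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# rank orders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankOrder:
    """Criterion ranks (1 = heaviest weight) with a tie flag."""

    ranks: dict[str, int]
    tied: tuple[str, ...] = ()

    @property
    def has_ties(self) -> bool:
        return bool(self.tied)


def rank_order(weights: Mapping[str, float] | pd.Series) -> RankOrder:
    """Rank criteria by descending weight.

    Ties are broken by the input (canonical) order and every tied
    criterion is flagged, because silently tied ranks corrupt
    rank-difference statistics downstream.
    """
    series = pd.Series(weights, dtype=float)
    order = sorted(range(len(series)), key=lambda i: (-series.iloc[i], i))
    ranks = {str(series.index[i]): pos + 1 for pos, i in enumerate(order)}
    counts = series.round(15).value_counts()
    tied_values = set(counts[counts > 1].index)
    tied = tuple(
        str(ix) for ix in series.index if round(float(series[ix]), 15) in tied_values
    )
    return RankOrder(ranks=ranks, tied=tied)


def rank_difference(
    ranks_a: Mapping[str, int], ranks_b: Mapping[str, int]
) -> tuple[float, float]:
    """Mean and sd of per-criterion absolute rank differences.

    Symmetric in its arguments; (0, 0) for identical rankings.  The sd
    is the population sd over criteria, matching a plain descriptive
    mean-and-spread presentation.
    """
    if set(ranks_a) != set(ranks_b):
        raise ValueError("rankings cover different criteria")
    diffs = np.array([abs(ranks_a[c] - ranks_b[c]) for c in ranks_a], dtype=float)
    return float(diffs.mean()), float(diffs.std(ddof=0))


def individual_rank_difference(
    weights_a: pd.DataFrame, weights_b: pd.DataFrame
) -> tuple[float, float]:
    """Individual-level rank reversal between two techniques.

    For each respondent present in both tables, rank their criteria per
    technique and take the mean absolute rank difference; the per-
    respondent means are then averaged (mean, sd over respondents).
    """
    a = weights_a.pivot(index="respondent_id", columns="criterion", values="weight")
    b = weights_b.pivot(index="respondent_id", columns="criterion", values="weight")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared respondents")
    per_resp = []
    for rid in shared:
        ra = rank_order(a.loc[rid]).ranks
        rb = rank_order(b.loc[rid]).ranks
        per_resp.append(rank_difference(ra, rb)[0])
    arr = np.asarray(per_resp)
    return float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def agreement_correlations(
    weights_a: pd.DataFrame,
    weights_b: pd.DataFrame,
    method: str = "pearson",
) -> tuple[float, float]:
    """(across-respondent r, mean within-respondent r) for two techniques.

    The across-respondent correlation relates the two techniques'
    per-criterion mean weights; the within-respondent correlation is
    computed per shared respondent and averaged.  Respondents with
    zero-variance weights under either technique cannot be correlated
    and are excluded.
    """
    a = weights_a.pivot(index="respondent_id", columns="criterion", values="weight")
    b = weights_b.pivot(index="respondent_id", columns="criterion", values="weight")
    b = b[a.columns]
    across = _corr(
        a.mean(axis=0).to_numpy(), b.mean(axis=0).to_numpy(), method
    )
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared respondents")
    within = []
    for rid in shared:
        xa, xb = a.loc[rid].to_numpy(), b.loc[rid].to_numpy()
        if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
            continue  # uniform weights carry no correlation information
        within.append(_corr(xa, xb, method))
    if not within:
        raise ValueError("all shared respondents have zero-variance weights")
    return across, float(np.mean(within))


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman summary of paired measurements.

    ``bias`` is the mean difference (a - b); the limits of agreement are
    ``bias +- 1.96 * sd`` of the differences, i.e. the 95% band under
    normality.  ``labels`` carries the identity of each pair so outliers
    are reportable; ``t``/``p`` test the bias against zero (paired t).
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    diffs: np.ndarray
    labels: tuple[str, ...]
    t: float
    p: float

    @property
    def outliers(self) -> tuple[str, ...]:
        out = (self.diffs < self.loa_lower) | (self.diffs > self.loa_upper)
        return tuple(lab for lab, o in zip(self.labels, out) if o)

    def to_frame(self) -> pd.DataFrame:
        """Tidy coordinates of the plot, one row per pair."""
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "mean": self.means,
                "difference": self.diffs,
                "bias": self.bias,
                "loa_lower": self.loa_lower,
                "loa_upper": self.loa_upper,
            }
        )


LOA_MULTIPLIER = 1.96  # 95% limits of agreement


def bland_altman(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: Sequence[str] | None = None,
) -> BlandAltman:
    """Bland-Altman fragment for paired measurements of the same objects."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1-d arrays")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    means = (a + b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if np.ptp(diffs) == 0.0:
        t, p = (0.0, 1.0) if bias == 0.0 else (np.inf, 0.0)
    else:
        tt = stats.ttest_rel(a, b)
        t, p = float(tt.statistic), float(tt.pvalue)
    labs = tuple(map(str, labels)) if labels is not None else tuple(
        str(i) for i in range(a.size)
    )
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        means=means,
        diffs=diffs,
        labels=labs,
        t=t,
        p=p,
    )


def group_bland_altman(
    weights_a: pd.DataFrame, weights_b: pd.DataFrame
) -> BlandAltman:
    """Group-level agreement: per-criterion mean weights of two techniques."""
    a = weights_a.groupby("criterion", sort=False)["weight"].mean()
    b = weights_b.groupby("criterion", sort=False)["weight"].mean().reindex(a.index)
    return bland_altman(a.to_numpy(), b.to_numpy(), labels=list(a.index))


def individual_bland_altman(
    weights_a: pd.DataFrame, weights_b: pd.DataFrame
) -> BlandAltman:
    """Individual-level agreement: per respondent-criterion weight pairs."""
    a = weights_a.set_index(["respondent_id", "criterion"])["weight"]
    b = weights_b.set_index(["respondent_id", "criterion"])["weight"]
    shared = a.index.intersection(b.index)
    labels = [f"{rid}:{crit}" for rid, crit in shared]
    return bland_altman(a.loc[shared].to_numpy(), b.loc[shared].to_numpy(), labels)


def order_effect_analysis(
    weights: pd.DataFrame, orders: Mapping[tuple[str, str], int] | pd.DataFrame
) -> dict[str, BlandAltman]:
    """Per-technique Bland-Altman of first- versus second-position weights.

    ``orders`` maps (respondent_id, technique) to the position (1 or 2)
    at which that respondent met that technique, or is a frame with
    columns respondent_id, technique, position.  For each technique,
    respondents are split by position, group mean weights are computed
    per split, and the two mean-weight profiles are compared.  A
    stable-preference cohort shows bias ~ 0 and differences scattered
    about zero; an anchoring effect shows second-position weights pulled
    toward uniform.
    """
    if isinstance(orders, pd.DataFrame):
        orders = {
            (str(r.respondent_id), str(r.technique)): int(r.position)
            for r in orders.itertuples()
        }
    out: dict[str, BlandAltman] = {}
    for tech, grp in weights.groupby("technique", sort=False):
        pos = grp.apply(
            lambda row: orders.get((str(row["respondent_id"]), str(tech))), axis=1
        )
        grp = grp.assign(position=pos).dropna(subset=["position"])
        first = grp[grp["position"] == 1]
        second = grp[grp["position"] == 2]
        if first.empty or second.empty:
            raise ValueError(f"technique {tech!r}: a position split is empty")
        a = first.groupby("criterion", sort=False)["weight"].mean()
        b = second.groupby("criterion", sort=False)["weight"].mean().reindex(a.index)
        out[str(tech)] = bland_altman(a.to_numpy(), b.to_numpy(), labels=list(a.index))
    return out
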