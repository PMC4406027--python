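"""Configured, logged pipeline runs: simulate -> derive -> value -> compare.

A :class:`RunConfig` (built in code or read from YAML) drives
:func:`run_pipeline`, which writes a CSV-first report bundle: per-
respondent weights, group weights, the value-estimate table, rank
orders and discrimination measures, agreement statistics, Bland-Altman
coordinate tables (with optional rendered plots) and a run log naming
every convention in effect.  CSV-first so that every reported number is
testable without reading a figure.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hierarchy import CriteriaHierarchy, load_hierarchy
from .simulate import DEFAULT_KAPPA, StudyDesign
from .study import ElicitationStudy, StudyResults

__all__ = ["RunConfig", "run_pipeline", "compare_report"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    seed: int
    out_dir: str = "mcda_run"
    hierarchy_file: str | None = None  # bundled default when None
    cohort_size: int = 60
    arms: Mapping[str, int] = field(
        default_factory=lambda: {"RA+PA": 15, "PC": 15, "BWS": 15, "RS_H": 15}
    )
    randomize_order: bool = True
    anchoring: float = 0.3
    concentration: float | None = None  # None = default asymmetric population profile
    kappa: float = DEFAULT_KAPPA
    s_max: float = 3.0
    ranking_scheme: str = "rank_sum"
    ahp_method: str = "geometric_mean"
    bws_transform: str = "shifted_bw"
    corr_method: str = "pearson"
    reference: str = "RS_nH"
    max_violations: int = 0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def design(self) -> StudyDesign:
        return StudyDesign(
            cohort_size=self.cohort_size,
            arms=dict(self.arms),
            randomize_order=self.randomize_order,
            anchoring=self.anchoring,
            seed=self.seed,
        )

    def hierarchy(self) -> CriteriaHierarchy:
        if self.hierarchy_file:
            return load_hierarchy(self.hierarchy_file)
        return CriteriaHierarchy.default()


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> StudyResults:
    """Run a full simulated study and write the report bundle.

    Returns the fitted :class:`StudyResults`; the bundle lands in
    ``config.out_dir``.  Aborts (after writing the validation report)
    when the simulated responses violate instrument invariants more
    than ``config.max_violations`` times — which for the bundled
    generator means never.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    study = ElicitationStudy.from_simulation(
        config.design(),
        hierarchy=config.hierarchy(),
        concentration=config.concentration,
        kappa=config.kappa,
        s_max=config.s_max,
        reference=config.reference,
        ranking_scheme=config.ranking_scheme,
        ahp_method=config.ahp_method,
        bws_transform=config.bws_transform,
        corr_method=config.corr_method,
    )

    report = study.validate()
    report.to_frame().to_csv(out / "validation.csv", index=False)
    if len(report) > config.max_violations:
        raise PipelineError(
            f"{len(report)} response violations exceed the configured "
            f"maximum of {config.max_violations}; see validation.csv"
        )

    results = study.fit()

    results.weights.to_csv(out / "weights.csv", index=False)
    results.group_weights().to_csv(out / "group_weights.csv", index=False)
    results.rank_orders().to_csv(out / "rank_orders.csv", index=False)
    results.rank_differences().to_csv(out / "rank_differences.csv", index=False)
    results.discrimination().to_csv(out / "discrimination.csv", index=False)
    results.discrimination_summary().to_csv(
        out / "discrimination_summary.csv", index=False
    )
    results.correlations().to_csv(out / "correlations.csv", index=False)

    # AHP consistency ratios: reported as a diagnostic, never a filter
    from .derive import pairwise_consistency
    from .instruments import PairwiseResponse

    cr_rows = [
        dict(respondent_id=resp.respondent_id, block=block, consistency_ratio=cr)
        for resp in study.responses
        if isinstance(resp, PairwiseResponse)
        for block, cr in pairwise_consistency(resp, study.hierarchy).items()
    ]
    if cr_rows:
        pd.DataFrame(cr_rows).to_csv(out / "consistency_ratios.csv", index=False)
    results.value_estimates().to_csv(out / "value_estimates.csv", index=False)
    results.value_table().to_csv(out / "value_table.csv", index=False)

    for tech, ba in results.group_bland_altman().items():
        ba.to_frame().to_csv(out / f"bland_altman_group_{tech}.csv", index=False)
        if config.plots:
            _plot_bland_altman(
                ba, out / f"bland_altman_group_{tech}.png", f"{config.reference} vs {tech}"
            )
    for tech, ba in results.individual_bland_altman().items():
        ba.to_frame().to_csv(out / f"bland_altman_individual_{tech}.csv", index=False)
    try:
        for tech, ba in results.order_effect().items():
            ba.to_frame().to_csv(out / f"bland_altman_order_{tech}.csv", index=False)
            if config.plots:
                _plot_bland_altman(
                    ba, out / f"bland_altman_order_{tech}.png", f"{tech}: first vs second"
                )
    except ValueError:
        pass  # single-order designs have no order contrast to report

    compare_report(results).to_csv(out / "compare_report.csv", index=False)
    if study.ground_truth is not None:
        study.ground_truth.to_csv(out / "ground_truth.csv", index=False)

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    return results


def compare_report(results: StudyResults) -> pd.DataFrame:
    """One-row-per-technique cross-technique comparison table.

    Columns: group mean value (% of maximum), discriminative-power
    means, rank differences against the reference technique, and the two
    agreement correlations.  The reference technique's own row carries
    zeros/ones in the comparison columns by construction.
    """
    if len(results.techniques) < 2:
        raise ValueError("need at least two techniques to compare")
    ref = results.model.reference
    if ref not in results.techniques:
        raise ValueError(f"reference technique {ref!r} missing from the bundle")
    disc = results.discrimination_summary().set_index("technique")
    rd = results.rank_differences().set_index("technique")
    corr = results.correlations().set_index("technique")
    value = (
        results.value_table().set_index("technique")
        if results.model.scores is not None
        else None
    )
    rows = []
    for tech in results.techniques:
        row: dict = {
            "technique": tech,
            "n": int(disc.loc[tech, "n"]),
            "d13_mean": disc.loc[tech, "d13_mean"],
            "dml_mean": disc.loc[tech, "dml_mean"],
            "deq_mean": disc.loc[tech, "deq_mean"],
        }
        if value is not None:
            row["value_pct_of_max"] = value.loc[tech, "pct_of_max"]
        if tech == ref:
            row.update(
                group_rank_diff=0.0,
                individual_rank_diff=0.0,
                across_respondents_r=1.0,
                mean_within_respondent_r=1.0,
            )
        else:
            row.update(
                group_rank_diff=rd.loc[tech, "group_mean"],
                individual_rank_diff=rd.loc[tech, "individual_mean"],
                across_respondents_r=corr.loc[tech, "across_respondents_r"],
                mean_within_respondent_r=corr.loc[tech, "mean_within_respondent_r"],
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _plot_bland_altman(ba, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18)
    ax.axhline(ba.bias, color="k", lw=1, label=f"bias {ba.bias:.4f}")
    for y in (ba.loa_lower, ba.loa_upper):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean weight")
    ax.set_ylabel("difference")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
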