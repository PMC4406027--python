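# mcda-weights

Weight elicitation for multi-criteria decision analysis (MCDA) in health
technology assessment, built around the 14-criterion / 6-category EVIDEM
framework.

When a committee values a new drug or device with MCDA, the overall value
of an intervention is the additive model

```
V = Σᵢ wᵢ · vᵢ,          Σᵢ wᵢ = 1,  wᵢ ≥ 0,
```

where *wᵢ* is the normalized importance weight of criterion *i* (disease
severity, budget impact, quality of evidence, …) and *vᵢ* its performance
score on a declared scale `[0, s_max]`; `100·V/s_max` expresses the
estimate as a percentage of the maximum attainable value.  The weights,
however, have to be *elicited*, and the elicitation technique is a design
choice.  This package implements five standard techniques and the
statistics needed to compare them:

* **five-point rating scale** (flat `RS_nH`, or hierarchical `RS_H` over
  categories and criteria within categories),
* **ranking** (`RA`) with rank-sum or rank-order-centroid surrogate
  weights,
* **point allocation** (`PA`) of a 100-point budget per judgment block,
* **pairwise comparison** (`PC`) on the reciprocal 1/9…9 scale of the
  analytic hierarchy process (row geometric means by default, principal
  eigenvector optional, consistency ratios reported),
* **best-worst scaling case 1** (`BWS`): repeated best/worst choices
  from balanced subsets of four criteria, analysed by counting
  (`score = (B − W + r) / 2r`).

Hierarchical instruments produce block-local shares; leaf weights are the
product of category share and within-category share.  Comparison
statistics cover discriminative power (weight gap between the 1st- and
3rd-ranked criterion *d₁₃*, most-vs-least gap *d_ml*, mean distance from
the equal weight 1/n *d_eq*, with one-sample t-tests against zero), rank
orders and rank reversals against the flat rating-scale reference,
Nickerson-style agreement (correlation of across-respondent means and
mean within-respondent correlation), and Bland-Altman bias / 95% limits
of agreement at the group, individual and presentation-order levels.

Because survey data of this kind are rarely shareable, the package ships
a synthetic-respondent generator with the study design such comparisons
use: 60 respondents, four arms of 15 (each arm pairing the flat rating
scale with one other technique), randomized technique order, latent
Dirichlet importance vectors, technique-specific response discretization
with a consistency parameter κ, and an optional anchoring effect that
shrinks discrimination at second position.

It is aimed at health-preference and HTA methods researchers who want to
stress-test weighting protocols before fielding them, and at anyone who
needs a tested reference implementation of these elicitation analyses.

## Worked example

```python
from mcda_weights import ElicitationStudy, StudyDesign

study = ElicitationStudy.from_simulation(StudyDesign(seed=7))
results = study.fit()
print(results.value_table().round(3).to_string(index=False))
```

```
technique  N  V_mean  V_se  V_sd  pct_of_max  pct_min  pct_max
    RS_nH 60   1.614 0.014 0.106      53.787   46.023   63.569
       RA 15   1.607 0.028 0.110      53.552   44.268   58.191
       PA 15   1.601 0.029 0.111      53.366   46.327   59.361
       PC 15   1.638 0.032 0.123      54.588   44.757   60.590
     RS_H 15   1.616 0.029 0.112      53.868   48.861   60.538
      BWS 15   1.670 0.024 0.092      55.672   49.856   61.287
```

Every technique's *group* mean value lands within ~2 points of 54% of
maximum, while *individual* estimates range from 44% to 64% — technique
choice matters little for group decisions and a lot for individual ones.
The agreement statistics sharpen that:

```python
print(results.correlations().round(2).to_string(index=False))
```

```
technique  across_respondents_r  mean_within_respondent_r  method
       RA                  0.54                      0.66 pearson
       PA                  0.84                      0.76 pearson
       PC                  0.91                      0.89 pearson
     RS_H                  0.85                      0.84 pearson
      BWS                  0.77                      0.79 pearson
```

Ranking agrees least with the rating-scale reference (its rank-sum
surrogate weights discard magnitude information); pairwise comparison
agrees most and, per `results.discrimination_summary()`, discriminates
most strongly between criteria.  `results.summary()` prints the full
report; `results.order_effect()` returns per-technique Bland-Altman
fragments contrasting first- versus second-position administration.

The same pipeline runs from the shell:

```bash
mcda-weights run-all --seed 7 --out-dir run7 --plots
mcda-weights simulate --seed 7 --out-dir sim7        # response CSVs only
```

`run-all` writes CSV-first reports (per-respondent and group weights,
value table, rank orders and reversals, discrimination, correlations,
Bland-Altman coordinates, consistency ratios, validation and a run log);
plots are optional renderings of the same coordinate tables.

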