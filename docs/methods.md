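# Methods

This note documents the models, conversion conventions, simulator design
and numerical choices behind `mcda_weights`, and what the test suite does
and does not establish about real elicitation data.

## The additive value model

An intervention's overall value is `V = Σᵢ wᵢ·vᵢ` with normalized,
nonnegative weights over the 14 leaves of the criteria hierarchy and
performance scores `vᵢ ∈ [0, s_max]`.  Since the weights sum to one,
`V_max = s_max` and the percentage of maximum is `100·V/s_max`.
`s_max` defaults to 3 (a 0–3 performance scale is the convention in the
EVIDEM line of work, and a mean V of 1.370 on that scale corresponds to
the familiar ~45.7% value level); it is a parameter everywhere, never a
hard-coded constant.

## The hierarchy

Two levels only: 6 categories over 14 criteria (sizes 2, 3, 2, 2, 2, 3).
Deeper trees are rejected by the loader's format.  The canonical leaf
order — D1, D2 | I1, I2, I3 | Q1, Q2 | C1, C2 | T1, T2 | E1, E2, E3 —
keys every weight and score vector, which prevents silent misalignment
between derivation, valuation and comparison.  Custom hierarchies load
from YAML; the only structural requirements are unique codes, named
categories and contiguous category blocks.

## From responses to weights

None of the five instruments defines a unique numeric conversion, so the
conventions below are explicit options, named in every report:

* **Ratings** (1–5): sum-normalization, `wᵢ = rᵢ/Σr` — the original
  EVIDEM convention.  Hierarchical mode normalizes per block and
  propagates.
* **Ranks**: rank-sum shares `(n−j+1)/(n(n+1)/2)` by default; the
  rank-order-centroid `(1/n)Σ_{t≥j}1/t` as an option.  Note the
  surrogate profile is fixed given the block size: ranks cannot carry
  magnitude information, which matters below.
* **Points**: block points divided by the block total (the budget is
  100, so this is points/100 for valid responses); propagated.
* **Pairwise**: per-block reciprocal matrices on the admissible grid
  {1/9 … 1/2, 1, 2 … 9}; local priorities from row geometric means
  (deterministic, rank-order invariant) or the principal right
  eigenvector via power iteration (tolerance 1e-10).  The two coincide
  exactly on consistent matrices and at n ≤ 3.  Saaty consistency
  ratios are computed per block and *reported only* — no response is
  discarded for inconsistency, since the comparison of techniques must
  see respondents as they are.  Hierarchical administration is the
  default (the category block plus one block per category, 25 judgments
  instead of the 91 a flat comparison of 14 criteria needs); a flat
  91-judgment mode exists.
* **Best-worst choices**: counting analysis.  With Bᵢ best choices, Wᵢ
  worst choices and rᵢ appearances, the default shifted score
  `(Bᵢ−Wᵢ+rᵢ)/(2rᵢ) ∈ [0,1]` is normalized to weights; the
  `sqrt((Bᵢ+0.5)/(Wᵢ+0.5))` choice-ratio score is the alternative.

Hierarchical propagation multiplies category share by within-category
share; results are renormalized to absorb floating-point drift, and
every constructed `WeightVector` enforces nonnegativity and a unit sum
within 1e-9.  A caution worth repeating: *hierarchically uniform* is not
flat-uniform — equal shares in every block give leaf weights 1/12 or
1/18, not 1/14.

The best-worst choice-set design is built greedily: each of the 12 sets
of 4 takes the least-shown criteria first, with co-appearance pressure
breaking ties.  48 slots over 14 criteria cannot be exactly balanced;
the design guarantees appearance counts of 3 or 4 and is reproducible
from its seed.

## Comparison statistics

* **Discriminative power** per respondent: `d₁₃ = w₍₁₎−w₍₃₎`,
  `d_ml = w₍₁₎−w₍ₙ₎`, `d_eq = mean|wᵢ−1/n|`; group means and standard
  deviations per technique, plus one-sample t-tests of d₁₃ and d_ml
  against zero (all-equal weights).  Degenerate zero-variance samples
  use the conventional limits (t=0, p=1 at mean zero; p→0 otherwise).
* **Rank stability**: rank 1 = heaviest mean weight; ties broken by
  canonical order and always flagged, because silent ties corrupt
  downstream rank differences.  Rank reversal is the mean absolute
  per-criterion rank difference versus the flat rating scale, at the
  group level (on mean weights) and the individual level
  (within-respondent first, then averaged over respondents — the
  alternative pooling over all respondent-criterion pairs is not used,
  a documented choice).
* **Agreement**: correlation of the two techniques' per-criterion
  across-respondent means, and the mean of per-respondent correlations
  (Pearson by default, Spearman by flag).  Respondents with
  zero-variance weight vectors carry no correlation information and are
  excluded from the within-respondent mean.
* **Bland-Altman**: bias = mean difference, limits of agreement =
  bias ± 1.96·sd(differences), outliers = points outside the limits,
  paired t-test of the bias.  Implemented at the group level
  (per-criterion mean weights), the individual level (respondent ×
  criterion pairs) and the order-effect level (a technique's
  first-position versus second-position group means).  Plots are
  renderings of tidy coordinate CSVs, so every agreement number is
  testable without reading a figure.  No regression-based trend
  correction is applied.

## The synthetic cohort

The generator emulates a two-technique survey: every respondent answers
the flat rating scale plus their arm's technique(s) — ranking + point
allocation, pairwise comparison, best-worst scaling, or hierarchical
rating; 15 per arm, 60 in total by default — in randomized order.

**Latent preferences.** Each respondent carries a vector on the
14-simplex drawn from an *asymmetric* Dirichlet.  The default mean
profile is a published group-mean weight profile for these criteria
(disease impact and intervention outcomes heaviest, clinical guidelines
lightest); the total concentration of 56 (4 per criterion) reproduces a
realistic individual departure from equal weights, `E|wᵢ−1/14| ≈ 0.027`.
The asymmetry matters: with a symmetric (uniform-mean) population,
per-criterion group means are pure sampling noise and across-respondent
correlations between techniques collapse, which no real cohort shows.
Both the profile and the concentration are constructor arguments.

**Response models.** A consistency parameter κ (default 8) scales
multiplicative lognormal noise (σ = 1/κ) applied to the relevant shares
before each instrument discretizes them; κ = ∞ is the noiseless limit.

* ratings: anchored to the block's most important item,
  `rating = clip(round(5·s/s_max-in-block), 1, 5)`.  A rank-quantile
  mapping was rejected because it discards magnitudes and caps the
  noiseless weight-recovery correlation near 0.92; the ratio-anchored
  map (how respondents use an intensity scale relative to their top
  criterion) recovers ≈ 0.97;
* ranks: order of the perturbed shares, per block;
* points: multinomial allocation of the 100-point budget over the
  perturbed shares (exact continuous allocation at κ = ∞);
* pairwise: the share ratio, lognormally perturbed, snapped to the
  nearest admissible grid value in log space (reciprocity by
  construction).  The snap is deliberate instrument realism: even
  noiseless responses are quantized;
* best-worst: arg-max/arg-min of the perturbed shares within each set,
  with a stable tie-break that keeps best ≠ worst.

**Anchoring.** At second position the latent is shrunk toward uniform,
`w ← (1−α)w + α/14` (α default 0.3), modelling the observed tendency to
discriminate less after a first elicitation.  α = 0 disables the
effect.

**Reproducibility.** One master seed feeds named substreams (latents,
design, order, noise, scores); identical seeds give byte-identical
response files.

**Performance scores** for the valued intervention are drawn uniformly
on [0, s_max] per criterion (constant-score variants available).  Real
studies score a concrete intervention through evidence review; the
uniform draw only fixes a realistic spread, so simulated value *levels*
(~50% of maximum) are not comparable to any particular published value
estimate, though the group-versus-individual spread contrast is.

## What the simulation shows — and its limits

With the defaults, the pipeline reproduces the qualitative structure of
real technique-comparison studies: group mean value estimates within a
few points of each other with individual estimates spreading several
times wider; pairwise comparison the most discriminating technique;
ranking the weakest correlate of the rating-scale reference.

Two structural facts are worth stating plainly, because the test suite
documents them rather than hiding them:

* **Rank-based instruments cannot round-trip magnitudes.**  Noiseless
  ranking responses recover the latent *order* perfectly (block by
  block), but rank-sum surrogate weights are a fixed profile per block —
  the category-level profile (6…1)/21 is far steeper than true category
  shares — capping the within-respondent Pearson correlation with the
  latent vector near 0.86 (centroid is worse).  Best-worst counting
  from 12 sets yields a coarse, approximately rank-like score and caps
  near 0.92.  The magnitude-preserving instruments (ratings, points,
  pairwise) all exceed 0.97, and point allocation is exact in the
  noiseless limit.  The acceptance suite asserts the uniform 0.95
  recovery bar for *every* technique, so the ranking and best-worst
  cases fail it by design of the instruments, not of the code.
* **Group rank-order round-trips are bounded by instrument
  resolution.**  Five rating levels, the 1/9…9 judgment grid and 12
  choice sets cannot resolve 14 criteria arbitrarily finely, so exact
  noiseless group-rank equality is asserted only for the
  magnitude-preserving instruments; order-only instruments are held to
  exact block-level order plus high rank correlation.

The simulator also deliberately omits features of real cohorts:
demographics, dropout, cross-country differences, within-survey
learning other than the single anchoring shrinkage, and any positional
effects inside best-worst choice sets.  Passing tests therefore
establish internal consistency and correct analysis code — not that any
particular human population behaves like the generator.

## Numerical and design choices

* Weight sums validated to 1e-9; reciprocal matrices to 1e-12; power
  iteration tolerance 1e-10.
* The 1.96 multiplier for limits of agreement is fixed (95% band).
* Rank-order ties: canonical-order tie-break, always flagged.
* Out-of-grid pairwise judgments are validation errors, not clamped.
* Missing response items are violations, never imputed.
* The reference technique for all comparisons is the flat five-point
  rating scale, the one instrument every respondent answers.
* Monte-Carlo problem sizes used by the tests and the acceptance
  script: 200-respondent cohorts for recovery, 200 cohorts of 16 for
  the anchoring direction, 1000 consistent matrices and 500 toy
  best-worst designs for the solver-equivalence checks.  These sizes
  give stable statistics at interactive runtimes.
* Group-level value convergence is asserted as a direction ("a few
  points, and several-fold tighter than individual spread") rather than
  a fixed 2-point band: the residual spread is partly systematic — the
  rank-based techniques' weight distortion interacts with the drawn
  score vector — and varies with the score draw.

## Known limitations

* Group-consensus AHP (aggregating matrices across respondents) and
  incomplete-matrix completion are out of scope.
* The contextual-criteria extension of the framework (and its value
  adjustment) is not modelled; only the 14 quantitative criteria.
* The anchoring strength α is a free simulation parameter; no published
  estimate of its magnitude exists to calibrate against.
* The CLI `compare` subcommand assumes weight tables over the bundled
  hierarchy unless a hierarchy file is supplied through the library
  API.
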