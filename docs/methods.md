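# Methods

## The decision problem

Deciding whether a condition belongs in a publicly funded newborn-screening
(NBS) panel involves trading off heterogeneous evidence: how common and how
severe the disease is, how well the screening test performs, whether early
intervention demonstrably helps, whether the follow-up system can absorb the
patients, and whether the programme is economically justified.  `nbsahp`
implements a quantitative scoring model for this decision, built with the
analytic hierarchy process (AHP): stakeholder judgments about the *relative
importance* of the evaluation items are turned into numeric weights, the
weights into an integer point allocation, and candidate conditions are then
rated against the allocation from objective evidence.

## The hierarchy

The assessment instrument is a three-level tree:

* **5 categories** — disease/condition, screening test, intervention,
  follow-up setting, economic evaluation;
* **16 subcategories** — the evaluation items (e.g. incidence, test
  performance, scientific evidence for the benefits of early intervention);
* **50 criterion options** — the ordinal levels at which a candidate
  condition can be rated (e.g. incidence ≥1/20,000 … <1/200,000).

The canonical instance ships as `nbsahp/data/hierarchy.yaml`.  The economic
evaluation category has a single subcategory; single-child nodes carry local
weight 1 and generate no comparison questions.

Full pairwise enumeration of this tree yields 10 category-level, 25
subcategory-level and 57 criterion-level questions.  The fielded survey asked
10/22/56; the reduced design behind the three missing comparisons was never
published, so the questionnaire generator emits the full pairwise sets and the
discrepancy is asserted in the tests rather than silently reconciled.

## From verbal judgments to weights

Respondents answer each pairwise question on a four-level verbal scale —
*equal*, *moderate*, *strong*, *very strong* importance.  The numeric values
of the verbal levels were not published; the package defaults to the odd
Saaty values 1/3/5/7 (the fifth Saaty level, "extreme" = 9, has no verbal
counterpart here).  The mapping is a config object (`JudgmentScale`), so
alternative scales such as 1/2/3/4 are directly testable.

For one respondent and one node with *n* children, the judgments form a
positive reciprocal matrix *A* with `a_ij` the judged importance of child *i*
over child *j* (`a_ji = 1/a_ij`).  Priorities are row geometric means,

    w_i ∝ ( Π_j a_ij )^(1/n),  normalised to Σ w_i = 1,

which is exact for consistent matrices (`a_ij = w_i/w_j`).

**Group aggregation.** "Geometric mean" aggregation is ambiguous between
aggregating judgments (AIJ: element-wise geometric mean of respondent
matrices, one solve) and aggregating priorities (AIP: solve per respondent,
geometric-mean the weight vectors).  The package defaults to AIJ — it
preserves reciprocity exactly and yields the single per-item consistency
index the study reported — with AIP available as a policy option.  The two
coincide whenever all respondents are consistent with a common truth.

**Consistency.** Each aggregated matrix is summarised by
`CI = (λmax − n)/(n − 1)`, with λmax estimated as the mean Rayleigh ratio
`(A·w)_i / w_i` against the geometric-mean weights (this coincides with the
principal eigenvalue in the consistent case, and for any matrix of order
≤ 3 the geometric-mean vector *is* the principal eigenvector).  CI = 0 marks
perfect consistency; CI > 0.15 flags the node as inconsistent — a
conventional relaxation of Saaty's 0.1 rule for coarse verbal scales.
Complete reciprocal 2×2 matrices are always consistent (CI = 0 by
construction).  A power-iteration principal-eigenvector solver
(`eigenvector_weights`, tolerance 1e−10, cap 10,000 iterations) is kept as an
independent cross-check; for near-consistent matrices of order ≤ 6 the two
methods agree within L1 0.05 (property-tested).

**Missing data.** Respondents could skip the 56 technical criterion-level
questions as a block.  A respondent absent from a node is simply excluded
from that node's aggregation; a *partially* answered node matrix is rejected
as a schema violation (no Harker-style completion is attempted).  Individual
respondents are never excluded on consistency grounds by default; per-node
CI is reported for the aggregated matrices.

## From weights to points

Global option weights are the product of local weights along the
root→category→subcategory→option path; they telescope to Σ = 1 for any
hierarchy shape.  Points are `round(1000 × weight)` under half-up rounding
(the conventional Japanese 四捨五入; banker's rounding is available as an
option).  With 50 options the grand total is guaranteed within 1000 ± 50;
the published table totals 1001.

The published allocation ships as an immutable fixture
(`nbsahp/data/table3_allocation.csv`, provenance `published_table3`);
recomputation from survey data never overwrites it.  Inverting the published
points back to local weights (points proportional within each subcategory,
subcategory sums within each category) and re-running the ×1000 half-up
allocation reproduces every published integer — a round-trip the tests pin.

## Scoring candidate conditions

A disease profile selects exactly one criterion option per subcategory.  Its
scorecard awards the selected option's points per item and reports them
against the "full marks" (per-item maxima), with category subtotals and a
total.  With the published allocation the achievable range is 114–620.  The
three bundled validation profiles reproduce the published results:
phenylketonuria 609, MCAD deficiency 605, congenital hypothyroidism 540 —
CH loses 68 points on economic evaluation and 12 on the number of conditions
testable at once.  The model deliberately sets no inclusion threshold;
`deduction_report` surfaces where a candidate loses points instead.

## The synthetic panel generator

Because the raw survey is unavailable, the estimation chain is validated by
parameter recovery.  `simulate_panel` draws, for each respondent, node and
pair, the true ratio `w_i/w_j` perturbed by multiplicative log-normal noise
`exp(N(0, σ))` — the standard heterogeneity model for ratio judgments, and
one that preserves reciprocity — then snaps it to the nearest verbal-scale
value in log space (ties toward the weaker judgment, so a true ratio of 1 is
always "equal").  Criterion-block skipping is whole-block Bernoulli, matching
the survey's skip rule.  Defaults mirror the study: 143 respondents, skip
probability 48/143 (so ≈ 95 complete respondents), noise σ = 0.3.  The
default ground truth is the one implied by the published allocation.

What the generator does **not** emulate: respondent covariates and
stratified views (occupation, NBS experience), any within-respondent
correlation structure beyond i.i.d. pair noise, and the fielded survey's
reduced question design.  Passing recovery tests therefore show that the
pipeline inverts its own generative model at the study's scale — not that
the published weights are correct for the real panel.

### Discretisation bias and the recovery experiment

The four-level verbal scale is coarse and bounded, which has two measurable
consequences the experiments are designed around:

* **Snapping bias.** A truth whose ratios are off the scale lattice
  {1/7 … 7} is recovered only up to snapping: an error-free panel recovers
  `snapped_weights(truth)`, not truth (tested explicitly with the published
  category weights, whose ratios are off-lattice).  Recovery is exact in the
  noiseless, no-skip limit when the truth's ratios lie on the lattice.
* **Scale saturation.** The expected log of the snapped ratio is a
  non-monotone function of the noise σ: around σ ≈ 0.3 upward flips (3→5)
  dominate, while by σ ≈ 0.5 flips toward "equal" offset them, so recovery
  RMSE against an on-lattice truth *plateaus and can fall* beyond σ ≈ 0.3.
  Noise response is therefore only cleanly monotone below saturation.

`recovery_experiment` consequently sweeps panel size n ∈ {10, 30, 100}
against sub-saturation noise σ ∈ {0.1, 0.2, 0.3} (bracketing the study's
σ = 0.3 from below), 20 replicates per cell, using an on-lattice truth so
noise response is not confounded with snapping bias, and asserts the main
effects on the grid margins: mean RMSE falls with n and rises with σ.  Within
bias-floor cells (σ ≥ 0.2) the per-cell n-effect is of order 3×10⁻⁴ and is
not individually resolvable at 20 replicates — a power limit, not a defect.
Error metrics pool the 5 category weights and the 16 subcategory local
weights; criterion-level weights are noisier simply because only ≈ 70% of
respondents contribute there, exactly as in the study.

At the study's own conditions (100 respondents, σ = 0.3, 30% skipping) the
recovered category weights sit within L∞ ≈ 0.006 of the generating truth —
comfortably inside the ±0.05 band the tests require.

## Numerical choices

* Priority vectors normalised to Σ = 1 within 1e−12; AIJ aggregation
  symmetrises mean-logs so reciprocity holds exactly despite floating point.
* Power iteration: tolerance 1e−10 on the L∞ change, 10,000-iteration cap.
* CI values below 1e−12 are clipped to exactly 0 (consistent case).
* Rounding: half-up implemented as `floor(x + 0.5)` (positive domain).
* Seeds: panel generation uses `numpy.random.default_rng(seed)`;
  `recovery_experiment` derives per-replicate seeds (< 2³¹) from a base seed.

## Known limitations

* The verbal→numeric mapping (1/3/5/7) is a convention, not a published
  fact; results that depend on the exact mapping should be checked under
  alternative scales via `JudgmentScale`.
* Whether the original analysis screened out high-CI respondents is unknown;
  the package reports per-node CI of the aggregate and leaves respondent
  exclusion to the caller.
* The published category weights (Figure-level, 3 decimals) are not exactly
  recomputable from any deposited data; the package treats the published
  point allocation as the reference artefact and checks internal consistency
  (category point sums within ±3 of 1000× the published weights) instead.
* No incomplete-matrix completion, fuzzy AHP, consistency repair, or
  alternative MCDA weighting schemes (ANP, best–worst, swing weighting).
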