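# nbsahp

Quantitative scoring model for selecting newborn-screening (NBS) conditions,
built on the analytic hierarchy process (AHP).

Public NBS programmes must decide, transparently, which conditions to screen
for.  This package implements a published Japanese assessment model for that
decision: a three-level hierarchy of evaluation items (5 categories, 16
subcategories, 50 criterion options), stakeholder pairwise-comparison
judgments turned into priority weights, weights turned into an integer point
allocation, and candidate conditions scored against the allocation from
objective evidence.  It is aimed at health-policy analysts and NBS
researchers who want to reproduce, stress-test, or re-derive such scoring
models from their own survey data.

## The model

For each internal node of the hierarchy, respondents compare the node's
children pairwise on a four-level verbal scale (equal / moderate / strong /
very strong importance, mapped by default to 1/3/5/7).  Each respondent's
judgments form a positive reciprocal matrix A = (a_ij); group judgments are
aggregated by element-wise geometric mean (AIJ) and solved by row geometric
means:

    w_i ∝ ( Π_j a_ij )^(1/n),   Σ_i w_i = 1.

Consistency per node is CI = (λmax − n)/(n − 1), with λmax the mean Rayleigh
ratio (A·w)_i/w_i; CI = 0 is perfectly consistent and CI > 0.15 is treated as
inconsistent.  Global option weights are products of local weights along each
root→option path, and points = round(1000 · weight), half-up.  A disease
profile (one selected criterion option per evaluation item) is scored by
summing the selected options' points.

The published allocation, hierarchy, and the three validation disease
profiles — phenylketonuria (PKU), medium-chain acyl-CoA dehydrogenase (MCAD)
deficiency, and congenital hypothyroidism (CH) — ship as bundled fixtures.
Because the underlying survey was never deposited, a synthetic-panel
generator with known ground truth supports parameter-recovery validation of
the whole chain.

## Worked example

Score the bundled congenital-hypothyroidism profile against the published
allocation:

```sh
$ nbsahp score --profile ch --format csv | tail -7
criterion,Follow-up setting,Post-screening follow-up system,Well established,66,66
criterion,Follow-up setting,Availability of post-screening consultation,Available,60,60
subtotal,Follow-up setting,,,126,126
criterion,Economic evaluation,Economic evaluation,Some scientific evidence is available,46,114
subtotal,Economic evaluation,,,46,114
total,,,,540,620
540/620
```

CH scores 540 of the model's 620 achievable points (the model's range over
all syntactically valid profiles is 114–620).  The final column pair is
rating vs full marks: CH concedes 68 points on economic evaluation (only
some scientific evidence is available in the national context) and 12 on the
number of conditions testable at once (its test is run separately).  The
same profiles give PKU 609 and MCAD deficiency 605 — `nbsahp score --profile
pku` / `mcad`.

The same workflow from raw survey data:

```sh
nbsahp simulate --truth table3-implied --n 143 --noise 0.3 --out panel.csv
nbsahp weights --responses panel.csv --out weights.yaml   # per-node weights + CI table
nbsahp allocate --weights weights.yaml --out allocation.csv
nbsahp score --profile my_condition.yaml --allocation allocation.csv
```

or in Python:

```python
import nbsahp as nb

h = nb.canonical_hierarchy()
alloc = nb.published_allocation()
card = nb.score_disease(nb.bundled_profile("pku"), alloc, h)
print(card.total, card.full_marks_total)      # 609 620
print(nb.deduction_report(nb.bundled_profile("ch"), alloc, h))
# [('economic_evaluation', 68), ('multiplex_capacity', 12)]
```

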