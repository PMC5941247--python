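# clinrank

Quantitative aggregation of ClinVar-style clinical assertions, for curators
and researchers prioritizing variant **reclassification**. Public archives
accumulate per-submitter significance calls of varying age and rigor; a
variant's overall label can lag far behind its criteria-based evidence.
`clinrank` condenses a variation report's assertions into a handful of
metrics that flag records whose evidence and label disagree — it does **not**
determine clinical significance, which requires primary-evidence review
under the ACMG/AMP guidelines.

## The metrics

For a record with clinical assertions *i* (only *valid* assertions count:
submitter published assertion criteria, five-tier significance present,
last-evaluated date present):

```
CTRS = Σ_i  x_i · d_i · s_i
```

* `x_i` — significance weight: B = −6, LB = −3, US = −0.3, LP = +3, P = +6
* `d_i` — age decay over the whole years `n` since last evaluation:
  1 for n < 2, (11 − n)/10 for 2 ≤ n ≤ 6, 0.5 for n > 6
* `s_i` — submitter tier: practice guideline 1.25, expert panel 1.10,
  criteria-provided 1.00 (anything else is excluded)

**CTAA** is the mean whole-year age of valid assertions and **CVNA** their
count. **CTPS**, the predicted significance, locates the CTRS within seven
calibrated score ranges (B, BLB, LB, US, LP, PLP, P) built from
non-parametric prediction intervals of two-star control distributions, with
zero-side endpoints fixed analytically at `2·x·0.7` (±4.2, ±8.4); the
B∩LB and LP∩P overlaps form the combined BLB and PLP bands. **CTRR** ranks
reclassification priority 0–3: one point per step between the database's
significance and the CTPS on the seven-position scale (conflicting
interpretations score as uncertain), plus one point per
benign/uncertain/pathogenic zone crossing, capped at 3.

## Worked example

```python
import datetime, clinrank as cr

ctx = cr.EvaluationContext(evaluation_date=datetime.date(2018, 6, 1))
ranges = cr.default_ranges()
rec = cr.three_star_us_records()[0]            # VID 38183, six valid assertions
m = cr.annotate_record(rec, ranges, ctx)
print(m.vid, m.cvcs.value, round(m.ctrs, 3), m.ctps.value, m.ctrr)
```

prints

```
38183 US 24.903 P 3
```

Six criteria-based assertions (five P/LP from clinical labs, one aging
expert-panel US) sum to a raw score of 24.903 — far above the pathogenic
range floor of 14.7 — so the predicted significance is P while the archived
label is US: a high-priority (rank 3) reclassification candidate. The
`examples/` scripts walk through scoring, recalibration from synthetic
control records, VCF annotation, and batch table runs; each prints the
numbers it computes.

## VCF annotation

`annotate_vcf` matches VCF sites to records **by rsID and alternate allele
only** and appends twelve `CT_*` INFO fields (one value per alternate
allele, `.` where unmatched); `strip_annotations` removes them,
byte-identically restoring the input.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the packaged worked-example records from their published assertion
sets, recomputes their raw scores and mean assertion ages at the pinned
evaluation date (2018-06-01), recomputes the analytic range-boundary
constants, and writes the results as JSON.
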