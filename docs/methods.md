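# Methods

## Model

A variation record carries a list of clinical assertions — per-submitter
five-tier significance calls (B, LB, US, LP, P) with a last-evaluated date
and a submitter review category. The package treats each assertion as an
additive, independently weighted piece of evidence:

    CTRS = Σ_i x_i · d_i · s_i        over valid assertions i

An assertion is *valid* iff its submitter category carries published
assertion criteria (practice guideline, expert panel, or criteria-provided
clinical testing), its significance is on the five-tier Mendelian scale,
and its date is present. Literature-only submissions are evidence citations
rather than clinical assertions and contribute nothing; so do assertions
with incomplete data, since their reliability is unknowable.

The additive form is deliberate: means or medians of assertion values
discard the volume of concordant evidence, whereas an aggregate lets many
"likely" calls accumulate toward the full class. A consequence embraced by
the model is that several concordant LP assertions can predict P.

### Parameters

| parameter | value | units | role |
|---|---|---|---|
| x (B, LB, US, LP, P) | −6, −3, −0.3, +3, +6 | score | significance weight; full classes 2× their "likely" neighbour, US an order of magnitude below LB |
| age grace | 2 | years | no decay for fresh assertions |
| age decay | 10%/year, years 2–6 | — | d = (11−n)/10 |
| age floor | 0.5 | — | a decayed P (±6 → ±3) is effectively its "likely" neighbour |
| s (guideline, expert, criteria) | 1.25, 1.10, 1.00 | — | submitter tier; others 0 |

Assertion age is `floor(days / 365.25)` whole years. Continuous ages
cannot reproduce the published worked-example scores; floored integer
years reproduce all twenty-six of them exactly, so that convention is
fixed. Future-dated assertions clamp to age 0 with a warning. The mean
assertion age (CTAA) is reported even for a single valid assertion; the
raw score is reported for any record, including those too thin to predict
from.

## Calibration of the predicted-significance ranges

Controls are two-star records of unambiguous Mendelian significance with at
least two valid assertions (combined P/LP and B/LB labels and conflicting
records are excluded — they cannot anchor a single class). Per class, a
distribution-free prediction interval is taken at the order statistics
c = trunc(α/2·(n+1)) and r = n−c+1.

The interval endpoint nearer zero is not estimated: it is fixed at
`2·x·0.7·1.0`, the minimum score of a two-star variant whose two
assertions are at most five years old — +4.2/+8.4 for LP/P, mirrored for
LB/B. Per class the highest confidence on a grid
{0.90, 0.95, 0.96, 0.98, 0.99, 0.995, 0.998, 0.999} whose zero-side PI
endpoint does not cross the fixed bound toward zero is selected, and the
endpoint is then clamped onto the bound. Clamping only widens the
interval, so nominal coverage is preserved. The uncertain class has no
fixed bound; its band is simply the open interval between the LB and LP
bounds, (−4.2, 4.2), and its recorded confidence is the highest computable
grid level.

The seven ranges partition the real line: B below the LB PI; the B∩LB
overlap as BLB (closed); LB up to −4.2 (inclusive); US open between the
fixed bounds; LP from +4.2 (inclusive) to the P PI; the LP∩P overlap as
PLP (closed); P above the LP PI. Scores beyond the extreme PI endpoints
still classify as B or P — only upper bounds are vulnerable to outliers
and the label cannot change past them. Boundary inclusivity follows the
published worked examples (a score of exactly 8.4 is PLP); the benign side
is mirrored by symmetry, there being no printed benign boundary case.

Shipped defaults live in `src/clinrank/data/calibration_default.tsv`
(per-class n, median, PI, confidence). The analytic zero-side endpoints
are reproduced by construction; the data-dependent far endpoints are
shipped constants, since recomputing them requires the full archive
snapshot they summarize. `calibrate()` rebuilds everything from any record
set and `save_calibration_stats()` writes the same resource format.

## Reclassification rank

Overall significances occupy seven ordinal positions
(B=1, BLB=2, LB=3, US=4=CI, LP=5, PLP=6, P=7). The rank is the ordinal
distance between the archived significance and the prediction, plus one
point per zone boundary crossed (benign | uncertain | pathogenic), capped
at 3. The bonus is counted per boundary crossed; for every reachable pair
the capped result equals a single-bonus reading, so the choice is one of
definiteness. A prediction requires ≥2 valid assertions; otherwise rank
and prediction are missing (`.`). Non-Mendelian significances ("drug
response", "risk factor") pass through as opaque text: scored, never
ranked, never fatal in batch runs.

## Synthetic records

The generator emulates only the coarse census structure of the archive:
class mix, assertions per record (rounded normal, mean 3.3, sd 1.9,
clipped to ≥2 so every record is scoreable), assertion age (gamma, mean
1.5 y, sd 0.9 y), submitter mix (predominantly criteria-provided), and a
one-step label-noise probability (default 0.1). Stars follow assertion
concordance (2 for concordant criteria-based records, 1 for conflicted,
0 with no valid assertion) and the overall label follows the valid
assertions (concordant label; same-zone mixes become the combined
category; cross-zone mixes become conflicting). Everything is determined
by the seed; dates are laid out relative to a fixed reference date
(2018-06-01) so generation is reproducible across days.

It does not emulate submitter ecology, per-gene or per-condition
structure, somatic assertions, or haplotype records. A green calibration
recovery test therefore establishes that the PI machinery is internally
calibrated on a stated world with the reported moments — not that the
shipped default ranges are optimal for any particular archive snapshot.

## Numerical choices

* Ages floored whole years (see above); ties at range boundaries resolved
  by the stated inclusivity; table numbers rendered via `round(x, 9)` then
  compact formatting, matching the published precision.
* PI selection requires c ≥ 1; grid levels not computable at the sample
  size are skipped, and a class with no aligning level is an error rather
  than a silently widened range.
* VCF I/O is line-based text editing: body lines are preserved verbatim
  except for appended INFO keys, making annotate → strip a byte-identical
  round trip; values are sanitised of `; , = whitespace`. Matching is by
  rsID + alternate allele only, by design.

## Limitations

* The submitter and significance weights are expert-chosen constants, not
  fitted quantities; alternative weightings are configurable but no search
  is provided.
* The XML reader targets a variation-report-style subset and is best
  effort; the JSON-lines fixture format is the canonical input.
* Assertions are not split by condition/phenotype; conditions are carried
  as free text only.
* The predicted significance rates evidence strength for prioritization.
  It is not a clinical classifier and must not be used as one.
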