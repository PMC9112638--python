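# Methods

This note documents the models, conventions and numerical choices behind
`polypsurv`, in the order a reader meets them: the rule engine, the interview
flow, the exact tests, the audit layer, and the synthetic data. It states no
empirical result the test suite and `scripts/acceptance.py` do not themselves
compute.

## The rule engine

### Units and intervals

All intervals are closed ranges in **months**. Guideline categories mix
scales ("6 months" after piecemeal resection of a large lesion, "5–10 years"
for small sessile serrated polyps); months are the coarsest unit that
represents both exactly. The display layer renders years where the range is a
multiple of 12. Every emitted range satisfies 6 ≤ min ≤ max ≤ 120 on the
default rule set; this is asserted as a property test.

### Combination operator

When several index rules match one exam, the result is the **elementwise
minimum** of the matched ranges ("most conservative wins"). Guidelines do not
state a combination operator because their categories are written as if
mutually exclusive; real exams mix categories (e.g. one 12 mm adenoma plus
two small ones). Shortest-interval dominance is the clinically safe reading:
no combination can ever be later than any of its matched categories. All
matching rule ids are reported in rule-table order, so a reviewer can see
which row was binding.

### Aggregation conventions

Count predicates aggregate across histology groups: adenoma counts over
tubular + tubulovillous/villous + high-grade-dysplasia groups, sessile
serrated counts over SSP + SSP-with-dysplasia (traditional serrated adenomas
are category-triggering on presence, not count). Guideline count bands
("3–4 adenomas") refer to total adenomas, not per-histology totals.

### The default rule table

`data/default_rules.yaml` is a hand transcription of the CAG recommendations
with USMSTF filling the uncovered scenarios. Two cells deserve comment:

- **Hyperplastic polyps.** Rectosigmoid HPs < 10 mm carry baseline risk and
  map to the no-polyp interval (10 y); HPs ≥ 10 mm get 3–5 y. Proximal (or
  unknown-location) HPs < 10 mm are not a printed guideline row; they are
  assigned 5–10 y — the same band as 1–2 small SSPs — because small proximal
  serrated-appearing lesions are frequently under-called SSPs, and because
  treating unknown location as proximal keeps the engine conservative. This
  is the one row added beyond the 17 directly transcribed categories, and it
  makes the coverage check total.
- **Piecemeal resection.** Any lesion ≥ 20 mm removed piecemeal fires a
  6-month rule that dominates everything through the min-combination.

- **Second-surveillance grid.** Only part of the grid is commonly printed;
  the bundled 3×3 table is completed from the USMSTF second-surveillance
  recommendations and kept monotone non-increasing in the current exam's risk
  class for every prior row, which is what makes the engine's conservatism
  property (adding a polyp group never lengthens the recommendation) hold
  globally:

  | prior \ current | NORMAL | LOW_RISK | HIGH_RISK |
  |---|---|---|---|
  | NORMAL | 120 | 84–120 | 36 |
  | LOW_RISK | 120 | 60 | 36 |
  | HIGH_RISK | 60 | 60 | 36 |

- **Risk classifier.** HIGH_RISK = any adenoma ≥ 10 mm, villous component or
  HGD, ≥ 5 adenomas, SSP ≥ 10 mm or with dysplasia, or TSA. The thresholds
  sit in the rule file's `options` block so an alternative transcription can
  move them; they are pinned so tests are deterministic.

### Gates

Eligibility: the tool addresses screening-age patients without hereditary CRC
syndromes or IBD. The age gate is **≥ 75 exactly** (the source material says
both "< 75" and "over 75"; the inclusive-75 reading was chosen and is
documented here). Quality: an exam without cecal intubation or adequate
preparation yields CASE_BY_CASE ("repeat/complete high-quality examination"),
not an interval, since guideline intervals assume a complete, well-prepared
colonoscopy.

### Family-history modifier

Applied last, as an elementwise cap: 60 months for high-risk history (≥ 2
FDRs with CRC, or any FDR with CRC or advanced adenoma diagnosed < 60),
120 months for a single FDR diagnosed ≥ 60. A cap is idempotent and can only
tighten; when it binds, a rationale line and a `family_history_cap` rule id
are appended.

## The interview flow

The flow asks one eligibility screener, one pathway question (first exam /
surveillance / post-CRC), the findings block, and one family-history
question. Numeric answers are bucketed at the rule boundaries (counts 1–2 /
3–4 / 5–10 / > 10, adenoma sizes < 10 / 10–19 / ≥ 20 mm), which makes the
answer alphabet finite: the default flow has exactly 78,225 enumerable
completed assessments, all terminating, with path lengths between **4**
(index exam, no polyps) and **13** (surveillance exam with adenomatous and
serrated findings, a ≥ 20 mm lesion and the piecemeal question). Reaching
the 4-question minimum requires the eligibility screener and the
pathway/history question each to be a single combined question; splitting
either pushes the minimum to 5, so the combined form is the design. Patients
screened out as ineligible terminate after 1 question; these short-circuits
are reported separately by `enumerate_paths` and are not counted in the 4–13
assessment bounds.

`finalize` hands the assembled inputs to the batch engine, so interview/batch
equivalence holds by construction; the acceptance suite still executes the
comparison on every enumerated path. Bucketed answers are materialised as
band-edge representatives (e.g. "3–4 adenomas, < 10 mm" becomes one group of
3 at 5 mm); since rule bounds are closed at exactly the bucket boundaries,
any representative of a band yields the same recommendation. The interview
does not ask about exam quality (it assumes a complete, prepared exam, as the
in-room user knows whether to bother asking for an interval at all); quality
flags are available on the batch path.

## Exact tests

Table probabilities under fixed margins are multivariate hypergeometric
masses computed with `fractions.Fraction`; floats appear only at the return
boundary. This matters for the two-sided / Freeman–Halton sum "mass of all
tables no more probable than the observed", where a float comparison could
misclassify ties; ties are accepted with relative tolerance 10⁻¹² in exact
arithmetic.

Sidedness: the published 2×2 comparisons are reproduced exactly by the
**one-sided min-tail** convention (the smaller of the lower and upper tail of
the top-left cell, inclusive), not by the two-sided convention — the
7-scenario gender table gives 0.630 one-sided and 1.0 two-sided. One-sided
min-tail is therefore the default for 2×2 audit reports, with two-sided
available by flag. Tables with more than two informative rows use the
Freeman–Halton test by complete enumeration; rows with zero total (a group
not given a battery) are dropped first. Enumeration beyond a configurable cap
(2 × 10⁶ tables) raises an explicit error rather than approximating; there is
deliberately no chi-square or Monte-Carlo fallback and no mid-p variant.

## The audit layer

Concordance against an interval range is inclusive at both bounds — a
"5 years" answer agrees with "3–5 years" — because a range is itself the
recommendation, not a confidence statement. A skipped scenario counts as
incorrect with no direction. A clinician at exactly 50% correct is a "low
scorer" (the published threshold is ≤ 50%). Display percentages round
half-up to integers; all comparisons in tests use the underlying fractions.

Two source-data quirks are preserved rather than repaired:

- In the published 7-scenario battery the gender margins (6/13 + 3/6 = 9 low
  scorers) are inconsistent with the printed total (10/19) while the
  clinician-type margins are consistent. The fixtures store both count tables
  exactly as printed; the synthetic per-clinician scorecards reproduce the
  clinician-type margins and the 10/19 total, and gender analyses run off the
  printed gender tables directly.
- The published issue rate "12 of 58 (20%)" rounds to 21% under the half-up
  convention used everywhere else in the same table; the package reports the
  exact fraction 12/58 and lets display rounding be what it is.

Pilot records with tool-use issues (stated agreement contradicted by chart
review; age-driven "no follow-up" calls; hereditary syndrome / anal cancer
cases the tool does not cover) are excluded from the headline agreement rate,
mirroring the published 46-colonoscopy denominator. The 16 countable
discordances split 11 shorter / 5 longer — the unique integer split of 16
whose shorter share rounds to the published ~70%; the split is reconstructed,
not printed.

## Synthetic data

`simulate.generate_cohort` draws a mixed practice: 50% index, 30%
surveillance, 20% post-CRC pathways; 5% of records trip the eligibility gate;
findings mix adenoma count bands (30/30/15/15/10% over 0, 1–2, 3–4, 5–10,
> 10), size bands (55/25/20% over < 10, 10–19, ≥ 20 mm), serrated and
hyperplastic arms, a 50% piecemeal rate for ≥ 20 mm lesions, and a 70/15/15%
family-history mix. The weights are deliberately enriched for rare categories
(> 10 adenomas, large piecemeal resections) so that a 500–1,000-record cohort
exercises every index rule; they are test scaffolding and model no real
polyp-prevalence epidemiology. Everything is driven by one
`numpy.random.default_rng(seed)`, so cohorts are bit-reproducible. Passing
tests on these cohorts therefore demonstrates the engine's logical
properties (determinism, totality, conservatism, oracle agreement) across the
whole rule space — not calibration against any real screening population.

## Problem sizes and verification

The acceptance script and test suite use: all 78,225 interview paths (with
full interview-vs-batch comparison), a 1,000-case cohort for
engine-vs-brute-force agreement, 40–60 random r×2 tables with grand total
≤ 30 for the enumeration-oracle check at 10⁻¹², and the bundled fixtures
(19- and 10-clinician batteries, 58 pilot records) for the published-table
reproductions. The brute-force recommendation oracle shares no combination
code with the engine; the exact-test oracles use an independent
factorial-form mass and an independent table enumerator, plus
`scipy.stats.fisher_exact` for the 2×2 two-sided cross-check.

## Known limitations

- The bundled rule table is a guideline transcription, not the authors'
  unpublished appendix; wording and a few boundary choices (proximal small
  HPs, the completed surveillance grid) are this package's own, documented
  above.
- The CSV record format cannot attribute a piecemeal resection to a specific
  histology group (it re-attaches it to the largest group on read) or carry
  per-group locations except for hyperplastic polyps; JSON is the canonical
  lossless format.
- Two published scenario answer keys ("5 years" for two unpublished
  scenarios) cannot seed engine tests because their inputs were never
  printed; engine correctness is instead anchored to the transcribed
  guideline lookups and the oracle properties.
- No hereditary-syndrome, IBD, or European-guideline pathways; the
  endoscopist opinion survey is stored in the pilot fixture layout only.
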