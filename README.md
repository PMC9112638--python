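# polypsurv

A guideline rule engine and concordance-audit toolkit for **colonoscopy
polyp-surveillance intervals**.

After a colonoscopy with polypectomy, the recommended time to the next
colonoscopy depends on many interacting factors — personal history of
colorectal cancer (CRC), the number, size and histology of polyps on the
current and any prior exam, and family history of CRC or advanced adenoma in
first-degree relatives (FDRs). North American guidelines (Canadian
Association of Gastroenterology, with the US Multi-Society Task Force filling
scenarios CAG does not address, e.g. follow-up after CRC resection) encode
these as dozens of categories that clinicians demonstrably misapply: audits
find roughly half of clinicians agreeing with the guidelines in at most half
of standard scenarios. `polypsurv` is for clinical-decision-support
developers, guideline auditors and biostatisticians who need:

- a **deterministic, declarative rule engine** mapping a patient + findings to
  the guideline interval (a closed range in months), with every fired rule
  cited and the most conservative (elementwise-minimum) interval winning when
  several rules match;
- a **conditional interview flow** (4–13 questions, bucketed at rule
  boundaries) that assembles exactly the inputs the dispatched pathway needs
  and provably agrees with the batch engine on every enumerable path;
- **exact small-sample inference**: Fisher's exact test (one-sided min-tail
  and two-sided) and the Freeman–Halton extension to r×2 tables, by complete
  enumeration in exact rational arithmetic;
- **concordance audits** reproducing a published evaluation of such a tool —
  scenario scorecards, low-scorer contingency tables, pilot-study agreement
  summaries — from bundled fixtures of the printed tables;
- a seeded **synthetic cohort generator** spanning every rule category.

## The core logic

For an index (first) colonoscopy the engine evaluates every rule row whose
predicate matches the findings signature (aggregate adenoma count over
tubular/tubulovillous/HGD groups, aggregate sessile-serrated count, maximum
sizes, advanced histologies, hyperplastic-polyp location, piecemeal
resections) and combines matches by elementwise minimum:

```
interval(findings) = ( min_r min_months(r),  min_r max_months(r) )   over matching rules r
```

Surveillance exams are keyed by a 3×3 grid over (prior risk, current risk)
with risk ∈ {NORMAL, LOW_RISK, HIGH_RISK}; post-CRC-resection follow-up is a
sequence (12, 36, 60 months) keyed by the number of colonoscopies since
resection; both tighten by the index rules when the current exam is abnormal.
A family-history modifier caps the result at 60 months (≥ 2 FDRs with CRC, or
any FDR diagnosed < 60) or 120 months (single FDR diagnosed ≥ 60). Patients
aged ≥ 75 or with hereditary CRC syndromes or IBD are out of scope by design.

Concordance between a clinician's answer `a` (months) and an engine interval
`[lo, hi]` is inclusive: concordant iff `lo ≤ a ≤ hi`, discordant-shorter iff
`a < lo`, discordant-longer iff `a > hi`.

## Worked example

```python
import polypsurv as ps

profile = ps.PatientProfile(age_years=55)
exam = ps.ColonoscopyFindings(polyp_groups=(
    ps.PolypGroup(histology=ps.Histology.TUBULAR_ADENOMA, count=1, max_size_mm=12),
    ps.PolypGroup(histology=ps.Histology.TUBULAR_ADENOMA, count=2, max_size_mm=5,
                  location=ps.Location.RECTOSIGMOID),
))
rec = ps.recommend(profile, None, exam)
print(rec.interval, rec.fired_rule_ids)
```

prints

```
min_months=36 max_months=36 ('adenoma_ge10mm',)
```

— three tubular adenomas, one ≥ 10 mm, so the ≥ 10 mm rule (3 years) is the
binding category. The same result through the command line, plus the bundled
audits:

```
$ polypsurv stats --table "6,7;3,3"
{"rows": [["row0", 6, 7], ["row1", 3, 3]],
 "fisher_p": 0.6300309597523219, "alternative": "ONE_SIDED_MIN_TAIL",
 "freeman_halton_p": 1.0}

$ polypsurv evaluate --fixture table3
{"n_total": 58, "n_agree": 30, "n_disagree": 16, ...
 "agreement_all_pct": 52, "agreement_excluding_issues_pct": 65,
 "discordance_excluding_issues_pct": 35, "issue_rate_pct": 21, ...}
```

The first is the gender comparison of the 7-scenario knowledge battery
(6/13 vs 3/6 low scorers; exact one-sided p = 0.63); the second summarises the
58-colonoscopy pilot: 65% agreement between endoscopist and tool once the 12
records with tool-use issues are excluded. Other subcommands: `recommend`
(batch JSON/CSV records), `interview` (interactive or `--answers` replay),
`simulate` (seeded cohorts), `fixtures` (emit the bundled tables as CSV).

## Layout

- `src/polypsurv/model.py` — validated domain types (patients, findings,
  intervals, recommendations)
- `src/polypsurv/rules.py`, `data/default_rules.yaml` — declarative rule sets
  with coverage validation; the bundled CAG/USMSTF transcription
- `src/polypsurv/engine.py` — pathways, dispatcher, family-history cap, and an
  independent brute-force evaluator used as a test oracle
- `src/polypsurv/interview.py` — the conditional question flow and exhaustive
  path enumeration
- `src/polypsurv/exact.py` — exact Fisher / Freeman–Halton machinery
- `src/polypsurv/evaluation.py` — scoring, scorecards, audit summaries
- `src/polypsurv/fixtures.py`, `simulate.py` — published-table fixtures and
  the synthetic cohort generator
- `src/polypsurv/io.py`, `cli.py` — JSON/CSV record formats and the CLI

See `docs/methods.md` for the modelling choices and their rationale.
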