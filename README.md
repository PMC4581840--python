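# kg7screen

Development and validation toolkit for the **KG-7**, a seven-item
geriatric screening score for older patients in high-volume oncology
clinics. Full comprehensive geriatric assessment (CGA) is
resource-intensive; a two-step workflow first screens everyone with a
short questionnaire and reserves full assessment for screen-positive
patients. `kg7screen` implements the whole derivation-and-validation
pipeline of such a score, for biostatisticians and clinical researchers
who want to reproduce, stress-test or adapt it:

- **GA domain categorization** — Barthel ADL, Lawton–Brody IADL,
  MMSE-KC, SGDS, MNA and Timed Get Up and Go, each graded
  intact / mild / severe, with *abnormal GA* defined as deficits in ≥2
  of the 6 domains and a severe-impairment (≥1 domain) alternative.
- **Item screening & selection** — every candidate instrument item is
  scored for sensitivity (SE), specificity (SP), PPV and NPV against its
  domain's impairment (category-vs-rest for mild/severe domains); per
  domain, items with mean SE >90% (widening to >80% when needed, after
  configurable feasibility exclusions) are ranked by balanced accuracy
  (SE+SP)/2 and the top two selected.
- **Instruments** — the KG-7 (0–7 points, one per favorable answer,
  screen-positive at ≤5) scored directly or derived from GA records, and
  the G-8 comparator (MNA components + age, 0–17, positive at ≤14).
- **Diagnostics** — score-by-reference cross-tables, confusion tables,
  metrics with Wald 95% CIs, the Mann–Whitney AUC
  (= P(case scores below control), ties ½) with Hanley–McNeil interval,
  and cut-off selection maximizing Youden's J subject to a sensitivity
  floor.
- **Survival** — Kaplan–Meier and log-rank (via `lifelines`) and an
  in-package Cox partial-likelihood fit (Newton, Breslow ties) for
  hazard ratios across score groups.
- **Synthetic cohorts** — a latent-frailty generator reproducing the
  development registry's marginal distributions with realistic
  cross-domain correlation and score-dependent exponential survival, so
  every stage runs without access to patient data.

The development cohort's KG-7 score-by-GA-status cross-table
(N = 1069) ships as a packaged fixture; all published internal-validation
numbers are recomputed from it at run time.

## Worked example

The packaged development cross-table through the full diagnostics stack:

```bash
$ kg7 table3-check
n=1069  abnormal prevalence 71.4%
cut-off <= 5:
  SENSITIVITY   95.0% (95% CI 93.5-96.6)
  SPECIFICITY   59.2% (95% CI 53.6-64.7)
  PPV           85.3% (95% CI 82.9-87.7)
  NPV           82.6% (95% CI 77.6-87.7)
  screen-normal 20.5%
  AUC 0.93 (95% CI 0.92-0.94)
  cut-off selected at SE>=90%: <= 5
```

Reading: 71.4% of assessable patients had abnormal GA; at the ≤5 cut-off
the KG-7 catches 95.0% of them while 20.5% of all patients screen normal
and could forgo full assessment; the score's overall discrimination is
AUC 0.93; and the constrained Youden rule (maximize SE+SP−1 subject to
SE ≥ 90%) re-derives the published cut-off of ≤5.

The same pipeline end-to-end on a synthetic cohort — simulate, score,
classify, validate:

```bash
$ kg7 simulate --n 300 --seed 7 --out demo.csv --truth truth.json
wrote 300 patients to demo.csv
$ kg7 validate --cohort demo.csv
n=288  abnormal prevalence 74.0%
cut-off <= 5:
  SENSITIVITY   98.1% (95% CI 96.3-99.9)
  SPECIFICITY   54.7% (95% CI 43.4-65.9)
  ...
  AUC 0.95 (95% CI 0.93-0.97)
```

(12 of 300 synthetic patients drop out as complete-case exclusions —
missing instruments make either the score or the reference
indeterminate, mirroring the registry's 1284 → 1069 attrition.)

Other subcommands: `kg7 develop` (runs the item-selection algorithm on a
cohort), `kg7 score --instrument kg7|g8`, `kg7 survival --grouping
score|category|binary`. The same operations are importable:

```python
from kg7screen import development_crosstable, confusion_at_cutoff, \
    diagnostic_metrics, empirical_auc

table = development_crosstable()
m = diagnostic_metrics(confusion_at_cutoff(table, 5))
print(round(100 * m.sensitivity.value, 1))   # 95.0
print(round(empirical_auc(table).auc, 2))    # 0.93
```

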