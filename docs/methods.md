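# Methods

`kg7screen` implements the full development-and-validation workflow of the
KG-7, a seven-item geriatric screening score built to triage older
patients for comprehensive geriatric assessment (CGA). This note records
the models, rules and numerical conventions the package uses, the design
decisions taken where the published description is silent, and what the
synthetic cohorts can and cannot show.

## Reference standard

Six GA domains form the reference: Barthel ADL (0–100), Lawton–Brody IADL
(5 items for men, 8 for women), MMSE-KC cognition (0–30), SGDS depression
(0–15), MNA nutrition (0–30, 0.5 steps) and the Timed Get Up and Go
(seconds). Charlson comorbidity is categorized (0 / 1–2 / 3–4 / ≥5
points) but is descriptive only. Categorization:

| domain | severe | mild (deficit) | intact |
|---|---|---|---|
| ADL | total ≤ 75 | any item dependency | total 100 |
| IADL | independent items ≤3 (M) / ≤6 (F) | ≥1 dependent item | all independent |
| MMSE | ≤ 16 | 17–24 | 25–30 |
| SGDS | ≥ 10 | 5–9 | < 5 |
| MNA | < 17 | 17–23.5 | ≥ 24 |
| TGUG | ≥ 25 s | > 20 s | ≤ 20 s |

Because severe-IADL is defined on the independent-item count, the two
definitions interlock: "mild" IADL is exactly one dependent item.

*Abnormal GA* = deficit (mild or worse) in ≥ 2 of the 6 domains;
*severe-any* = severe impairment in ≥ 1 domain. Two conventions matter:

- **Not capable vs missing.** A "not capable" (NC) response is an
  observed inability and is categorized *severe* in every domain; a
  missing instrument is *unassessed* and yields a missing category. When
  the KG-7 is derived from GA records, an NC source instrument produces
  the unfavorable answer while a missing source makes the score missing.
- **Indeterminacy.** With missing domains the binary flags are reported
  only when every completion of the missing domains agrees (e.g. one
  observed deficit plus one missing domain leaves abnormal-GA open). The
  implementation is a counting rule; the test suite proves it equal to
  exhaustive enumeration over all 4^6 status patterns. Indeterminate
  patients are dropped from cross-tables (complete-case), which is how a
  registry of 1284 assessments yields a usable cross-table of 1069.

## Item screening and selection

Each candidate item is dichotomized (impaired response vs not — any lost
point for scored items, non-independence for IADL) and evaluated against
its own domain. For domains with mild and severe bands the 2×2 metrics
are computed *category-vs-rest* — the non-case group differs between the
mild and severe analyses, which is why one item can carry two different
specificities — and sensitivity/specificity are averaged over bands.
Selection within a domain: items with mean SE > 90% form the pool; if,
after feasibility exclusions, fewer than two remain, the pool widens to
mean SE > 80%; the two highest balanced-accuracy ((SE+SP)/2) items win.
Feasibility exclusions are configuration data (expert judgment, e.g.
attention-and-calculation, recall and complex commands in an outpatient
oncology clinic), never computed. Ties break by higher mean SE, then
item id — the package's own rule; real data produced no ties.

## Scoring and diagnostics

KG-7: one point per favorable answer, range 0–7, higher is better;
screen-positive at ≤ 5. No pro-rating: a missing item makes the score
missing (imputing items would silently change the operating
characteristics). G-8 is scored from its seven MNA components plus an
age band (0–17, positive at ≤ 14) with the weights of its original
publication, shipped as JSON config.

All accuracy analysis flows from the score-by-reference cross-table.
Positive screen = score ≤ cutoff. SE/SP/PPV/NPV carry Wald 95% intervals
p ± 1.96·√(p(1−p)/n) truncated to [0,1] — the interval family that
reproduces the published CIs (the published SP lower bound prints 53.7
where the Wald value is 53.6; one printed digit of rounding path). The
AUC is the Mann–Whitney estimator — the probability a random case scores
below a random control, ties counted ½ — with a Hanley–McNeil interval;
it equals the trapezoidal area under the empirical ROC exactly. The AUC
interval method is a package choice (the published one is unstated).

**Cut-off selection.** "Maximal AUC" is not by itself an operational
cut-off rule (the AUC is threshold-free). The package reconstructs the
choice as: among cut-offs with SE ≥ a floor (default 90%, the screening
priority), maximize Youden's J. On the development cross-table the
unconstrained Youden maximizer is 4; the constrained rule returns the
published ≤ 5. Ties go to the lower cut-off.

## Survival

Overall survival runs from GA date to death or last follow-up.
Kaplan–Meier curves (Greenwood variance, events-first at ties) and the
k-group log-rank test are computed via `lifelines`. The Cox
proportional-hazards fit is implemented in-package: Newton maximization
of the Breslow partial likelihood with step-halving, Wald CI on the log
scale. Breslow ties were chosen for simplicity on day-scale,
mostly-untied data; with no ties it coincides with Efron, which the
tests exploit by cross-checking against `lifelines` on continuous times.
Monotone likelihoods (complete separation) are flagged
(`converged=False`) rather than raised: the estimate drifts past
|log HR| > 20 or an absurd standard error. Score groupings mirror the
published panels: per-score, four categories (bounds 0–1 / 2–3 / 4–5 /
6–7 by default; the published bounds are not printed, so they are
config), and binary normal(>5)/abnormal(≤5).

## Synthetic cohorts

No patient-level data are published, so every stage is exercised on
generated cohorts built to the registry's documented margins:

- **Latent frailty.** One standard-normal trait per patient, shifted
  0.03 per year of age from the median (77 y). Each domain's latent
  score is `loading × frailty + noise`; category thresholds are set by
  quantiles of a 200 000-draw seeded calibration sample, so configured
  marginal rates (the registry's Table of baseline characteristics:
  ADL independent 50.8%, IADL dependent 61.1%, MMSE mild 33.3% / severe
  29.4%, SGDS 25.5%/16.0% plus 13.4% not-capable, MNA 34.6%/36.4%, TGUG
  impaired 43.5%, Charlson medium 46.4%, polypharmacy ≥5 drugs 60.4%)
  are matched by construction. Default loadings of 2.0 (0.8× for SGDS,
  0.9× for TGUG) were fixed once so that the generated regime matches
  the documented one — abnormal-GA prevalence ≈ 71% (observed 0.714 at
  n = 3000) with KG-7 AUC ≈ 0.95.
- **Item fills.** Raw items are generated *conditionally on the drawn
  category* and always land on the correct side of every categorization
  threshold (a tested closure invariant). Impairment propensities were
  derived analytically from the published item operating
  characteristics: bathing carries dependencies with probability
  0.90 (mild) / 0.98 (severe) giving ≈ 94% sensitivity, stairs
  0.70/0.95 ≈ 85%, shopping 0.87-equivalent ≈ 91% with specificity 1 by
  construction. The IADL severe share among dependents (0.87) is forced
  by arithmetic: shopping (91.1%) and food preparation (89.8%) can only
  both be that sensitive if nearly all dependent patients have ≥ 2
  dependencies. MMSE/SGDS/MNA totals are drawn inside the band and
  decomposed over components by weighted capped-multinomial allocation,
  with weights that reproduce the published sensitivity ordering
  (attention ≻ recall ≻ orientation; the SGDS activity/energy/spirits
  trio above 90%; the MNA health-comparison item above the self-view,
  protein and drug items). The >3-prescription-drugs MNA item is pinned
  to the generated drug count.
- **Survival.** Exponential event times with log-hazard linear in the
  number of unfavorable KG-7 answers (slope log(5.1)/7 per point, i.e.
  extreme-group HR 5.1), baseline median six years at score 7,
  independent exponential censoring (2.5 × 10⁻⁴/day) plus a ten-year
  administrative cut — about 70% events. Exponential, not Weibull, so
  recovery checks have closed-form truth.
- **Missingness.** Independent per-instrument masking at the registry's
  documented missing rates (TGUG 4.6%, drug count 4.9%, others ≤ 1.5%),
  applied after the ground-truth sidecar is frozen.

What the synthetic cohorts do **not** emulate: multi-factor impairment
structure (one latent trait only), informative missingness, measurement
error in the reference standard, calendar-time effects, and the joint
distribution beyond printed margins. Passing tests therefore show the
pipeline is correct and well-calibrated under the stated generative
model — not that the instrument's real-world operating characteristics
are reproduced beyond the packaged development cross-table.

## Problem sizes and tolerances

The test suite and acceptance script use: the packaged 1069-patient
cross-table (exact assertions at the printed rounding); n = 5000 default
cohorts for regime checks (prevalence within [60%, 80%], AUC > 0.85);
n = 20 000 at zero loading for marginal calibration (±1.5 percentage
points); 100 two-arm cohorts of 400 patients at true HR 5.1 for Cox
recovery (mean log-HR within 5%, CI coverage within [90%, 99%]); and
100 random small cross-tables against brute-force pairwise oracles
(agreement to 10⁻¹²). Newton convergence uses |step| < 10⁻⁹.

## Known limitations

- External (cancer-cohort) validation and the real-data G-8 comparison
  cannot be re-run: no patient-level data exist. The G-8 scorer is
  exercised on synthetic cohorts only.
- The four-level survival grouping bounds and the exact complete-case
  rule of the original analysis are unpublished; both are configurable
  reconstructions.
- Wald intervals are known to undercover for proportions near 0/1; they
  are used deliberately to match the published intervals.
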