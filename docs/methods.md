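# Methods

This note documents the models, rules, parameters and design choices behind
`vaxcheck`, and what the shipped tests do and do not demonstrate.

## The recommendation model

A patient profile is mapped to a set of per-vaccine recommendations in two
stages.

**Stage 1 — rule matching.** The knowledge base holds declarative indication
rules, each with a single trigger: membership of an age-band set, presence of
a condition token, or a therapy predicate.  Every rule whose trigger matches
fires; matched vaccines are unioned and their reasons merged and
de-duplicated.  Vaccines may therefore be indicated for three reasons — age,
comorbidity, or the treatment regimen — and a single vaccine row can carry
several.  An empty match is legal output: the report then contains only the
input echo, the "other vaccines" notice and the disclaimer.

**Stage 2 — safety overlay.** Platform and therapy class determine status:

- live attenuated vaccines (MMR, varicella in the default KB) are
  `contraindicated_during_current_therapy` when the patient is
  immunosuppressed.  With the KB setting `therapy_timing: upcoming` the
  status becomes `recommended_pre_therapy_only` with a configurable lead
  time (default 4 weeks) instead — the checker's single "current or
  upcoming therapy" question cannot distinguish the two situations, so the
  conservative "current" interpretation is the default;
- pregnancy forces live vaccines to contraindicated regardless of therapy;
- non-live vaccines remain recommended during any systemic therapy but carry
  a timing note (default lead time 2 weeks before treatment initiation);
- seasonal vaccines (influenza, COVID-19) are `seasonal_recommended` with a
  seasonality note; the dTpa row carries its 10-year booster note.

Reports are deterministic: vaccines render in the KB's fixed catalogue
order, and with an injected timestamp two runs are byte-identical.

## Immunosuppression classification

Therapy is classed `none` (no chronic therapy, or topical treatment),
`non_suppressive_systemic`, or `suppressive`.  Biologics (TNF, IL-17,
IL-23, IL-12/23, IL-4/13 antagonists) and JAK inhibitors default to always
suppressive; acitretin, apremilast and dimethyl fumarate default to
non-suppressive systemic.  The three dose-driven drugs use thresholds:

| drug | absolute cutoff | per-kg cutoff |
|---|---|---|
| prednisone | 20 mg/day | — |
| methotrexate | 15 mg/week | 0.4 mg/kg/week |
| ciclosporin | — | 2.5 mg/kg/day |

A patient is suppressive as soon as the reported dose reaches **any**
applicable cutoff (per-kg cutoffs scale by the captured body weight).  The
any-breach rule was chosen over a most-lenient (max-threshold) rule because
the classification feeds a live-vaccine safety decision, where the
conservative reading is the defensible default; it also keeps the
classification monotone in dose.  All cutoffs are provisional, clearly
editable config in `default_kb.yaml`, not code.

HIV infection and congenital/acquired immunodeficiency carry the same
live-vaccine safety semantics as drug-induced suppression: they escalate the
overlay (stage 2) without changing the drug classification used by therapy
triggers (stage 1).  The set is a KB setting.

Hand involvement is captured and echoed but has no effect in the default
rule set; no published rule consequence exists for it, so inventing one was
avoided.  KB authors can target it once a rule is defined.

## The default rule catalogue

The bundled KB transcribes the national adult immunization plan's age- and
risk-group structure: dTpa for all adults (10-year booster), influenza and
COVID-19 from age 60, pneumococcal (conjugate then 23-valent polysaccharide,
linked by a sequencing note) and recombinant zoster from 65; per-condition
risk-group rules (e.g. asplenia → pneumococcal, Hib, meningococcal ACWY and
B; chronic liver disease → hepatitis A and B; MSM → hepatitis A/B, HPV,
mpox); and therapy-driven rules that indicate influenza, COVID-19,
pneumococcal, zoster, hepatitis B and — pre-therapy — varicella and MMR for
immunosuppressed patients.  Zoster is the recombinant (non-live) formulation
by default, with the live formulation available as a commented alternate
entry; the mpox vaccine is a non-replicating viral vector and does not
trigger the live-vaccine overlay.  Every vaccine must be reachable by at
least one rule, and loading fails on any dangling reference, duplicate
identifier, or a drug catalogue that deviates from the checker's 25
medication options.

## Synthetic cohorts and verification

The generator emulates the mock-patient exercise used to verify checkers of
this kind: default 50 patients split 25/25 between psoriasis and atopic
dermatitis, uniform age bands, therapy probability 0.7 with the medication
drawn uniformly from the full 25-drug catalogue, doses uniform over
clinically plausible ranges (ciclosporin 100–400 mg/day, methotrexate
7.5–25 mg/week, prednisone 5–50 mg/day, rounded to 0.1 mg), weight uniform
on 50–110 kg, and each comorbidity drawn independently at 0.1 (an msm +
pregnancy draw is resolved by dropping one at random, since the two answers
are mutually exclusive).  Generation is bit-stable for a fixed seed and
every record passes profile validation by construction.

The verification harness recomputes each profile's report and audits it
against (a) structural invariants — unique vaccine rows, non-empty merged
reasons, disclaimer present, no live vaccine unconditionally recommended
under suppression or pregnancy — and (b) exact agreement with an
independent brute-force evaluator that re-derives classification, trigger
matching and status with plain loops and none of the engine's machinery.
Failures are returned as data (an audit record), never raised.

What this does **not** show: the synthetic cohort exercises the rule logic,
not clinical reality — attribute distributions are uniform/independent
rather than epidemiological, no immunization history exists, and a clean
audit certifies internal consistency of engine and KB, not the clinical
validity of any rule.

## Readability scoring

The Gulpease index is computed from letter, word and sentence counts as
`89 + (300·S − 10·L)/W`, clamped to [0, 100]; texts under the target
(default 40) are flagged as difficult for readers with a high-school
education.  Tokenization is fixed for determinism: letters are Unicode
alphabetic characters (accented Italian letters counted, digits and
punctuation never); apostrophe elisions split into two words while
hyphenated compounds count as one; a run of `.`, `!`, `?` or `…` closes one
sentence and a trailing unterminated segment still counts.  Corpus
aggregation reports both the unweighted mean over texts and the
word-count-weighted mean, since a corpus-level figure can be defined either
way.  The formula is arithmetic on any text, but its calibration is
Italian-specific; scores for other languages are not meaningful.

## Survey statistics

uMARS scoring follows the instrument: per rater, each objective subscale
score is the mean of that rater's item scores with not-applicable items
dropped (a subscale with all items NA is undefined and propagates NaN), and
the total is the unweighted mean of the four subscale scores.  Cohort
means/SDs (SD with n−1) and medians/IQRs (linear-interpolation quantiles)
aggregate the per-rater values.  `aggregate_item_means` applies the same
identities one level up, re-aggregating a published item-mean table; note
that aggregating *rounded* item means can differ in the second decimal from
aggregating raw data (the information subscale is the documented example).
Display rounding is half-up: 2 dp for scores, 0 dp for percentages; raw
precision is kept internally.

Group comparison is a two-tailed independent t test.  Welch is the default
(robust to unequal group sizes and variances, the typical
dermatologist-vs-public-health setting); the pooled-variance variant is
available, and both accept (mean, SD, n) summary input.  The t and df
formulas are implemented directly and cross-checked in the tests against
`scipy.stats.ttest_ind` / `ttest_ind_from_stats` as an independent
reference.  Sample sizing inverts the normal-approximation confidence
half-width for a mean: the smallest integer n with `z·σ/√n ≤ d`, with an
exact-minimality guard at integer boundaries.  Agreement proportions count
scores of 4 or 5 on the 5-point scale.

## Numerical and interface choices

- Distances use the haversine formula on a 6371-km sphere; ties at equal
  distance are broken by center name; only the 5- and 10-km radii offered
  by the finder are accepted.
- Doses are plain milligrams (daily for ciclosporin/prednisone, weekly for
  methotrexate); per-kg conversion happens in the classifier, never in the
  profile model.  Age is captured as the checker's three bands — the rules
  never need finer granularity.
- Profile field names are fixed snake-case English tokens regardless of UI
  locale; all patient-facing strings are KB templates, so an Italian
  template set is a KB edit, not a code change.
- Report JSON is schema-versioned and round-trips losslessly; the Markdown
  rendering is derived from the same report object.

## Problem sizes

The shipped suite verifies the 50-patient cohort exactly as specified,
extends the same audit to a ~900-profile deterministic branch-coverage
cohort (every age band × medication × condition combination) and a
1,000-profile sampled cohort for the monotonicity property, and runs the
property-based checks with fixed (derandomised) hypothesis profiles of
50–100 examples per property.  These sizes keep the whole suite in the
seconds range on one CPU while covering every rule branch at least once.

## Known limitations

Dose thresholds and washout windows for the original clinical rule set are
not published; the defaults here are documented, provisional, and marked as
config.  The rule catalogue covers internal consistency, not guideline
completeness (no travel or occupational vaccines, no immunization-history
reconciliation, no pediatric rules, single-drug regimens only).  The
readability module scores text it is given; it cannot reproduce any
particular app's corpus average without that corpus.
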