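# Methods

## Problem and approach

`hffree` labels study participants as *HF-free* or *suspected HF* at
baseline using only their medication inventory plus two derived
comorbidities, and quantifies the quality of the resulting HF-free cohort
against claims-based referent definitions. The package has five analysis
stages — eligibility cascade, medication-rule assembly, claims phenotyping,
validation metrics, event rates — plus a synthetic-data generator that
stands in for the restricted cohort/claims linkage.

## The exclusion cascade

Eligibility removes, in order: anomalous records (an input flag, not a
computed rule — no public definition of "anomalous" exists, so inventing
one would be arbitrary), participants with no follow-up, missing
self-reported AF, missing medication data, and adjudicated HF
hospitalizations in the half-open window `[interview, in-home visit)`.
Each step is counted among survivors of the previous steps; the final set
is order-independent (the filters are independent predicates) but the
per-step attribution is not, which the tests document explicitly.

Two deliberate readings of ambiguous definitions, both switchable:

* **Hypertension threshold** is strict (`> 140 / > 90` mmHg), matching the
  wording "greater than"; `strict=False` gives the conventional ≥140/≥90.
* The interview-to-visit HF window is half-open: an admission on the visit
  day belongs to follow-up.

Missing medication data is an explicit per-participant flag, distinct from
an empty inventory: an empty inventory is informative (no HF medications),
a missing one is not.

## Medication rules

Drug names are normalized against an offline registry (generic rosters of
ACE inhibitors, ARBs and beta-blockers current to the mid-2000s US market,
with brand synonyms and combination products; shipped as a versioned CSV,
user-replaceable). Matching is exact on normalized tokens — determinism is
worth more here than typo tolerance, which is a pre-processing concern.
Unrecognized names yield empty ingredient sets, never errors.

Rule details worth noting: carvedilol excludes unconditionally *and*
counts as the beta-blocker of rule 2; the loop-diuretic roster is
furosemide/bumetanide/torsemide; eplerenone is present in the registry but
deliberately carries no trigger class (its use in the study era was rare) —
adding it is a one-line registry edit; the nitrate class is isosorbide
dinitrate/mononitrate and nitroglycerin.

## Claims referents

ICD-9-CM codes are handled as dotted text (undotted CMS exports can be
converted with `normalize_icd9`). The HF code set is the nine listed
402/404 sub-codes plus the whole 428 family by prefix. Lookback is every
claim strictly before the index date (no upper cap); a claim dated on the
index date is excluded. The two qualifying outpatient claims must fall on
distinct service dates by default — same-day duplicates are commonly
billing artifacts — with a switch to count raw claims. The three
definitions nest (a ⇒ b ⇒ c) by construction, and a property test checks
the implementation preserves that on arbitrary claim streams.

## Validation metrics

"Test positive" is *excluded from the HF-free cohort*; this orientation is
fixed in the 2×2 type itself to eliminate transposition bugs. All four
metrics are Wald proportions with z = 1.96 on the metric's own
denominator, truncated to [0, 100]%; Clopper–Pearson intervals are
available behind `interval="exact"` but are not the default because the
validation tables use the normal approximation. Zero denominators produce
explicitly undefined estimates, never silent zeros. No multiplicity
adjustment is applied anywhere. Age strata are [65, 75) and [75, ∞), the
boundary participant going to the older stratum.

Rate CIs use `rate ± 1.96·rate/√events`, which exactly reproduces the
published rate intervals this package is tested against; a Poisson-exact
(chi-square) option exists. Person-time runs from the in-home visit to the
first adjudicated HF admission or censoring; a year is 365.25 days (the
difference from calendar years is far below reporting precision).

## Synthetic generator

The generator emulates the *structure* the analysis needs, not the real
population. Defaults (the fixed study conditions of the test suite):

| parameter | default | basis |
| --- | --- | --- |
| latent HF prevalence | 0.113 | the any-diagnosis claims prevalence in the published validation cohort |
| HF-hospitalization rate, latent HF / not | 26.6 / 4.29 per 1000 PY | published group rates |
| AF (HF / not) | 0.225 / 0.093 | published baseline table, validation cohort |
| hypertension (HF / not) | 0.762 / 0.643 | published baseline table |
| orthopnea, PND (HF / not) | 0.35/0.08, 0.22/0.04 | chosen so the symptom variant moves ≈13% of the HF-free cohort, as published |
| age | truncated normal(64.9, 9.4²) on [45, ∞) | published mean (SD), entry age ≥45 |
| female, Black | 0.55, 0.409 | published marginals |
| missing AF / meds, anomalous, no follow-up | 0.023, 0.0045, 0.002, 0.015 | published attrition fractions |
| follow-up | Uniform(5, 10) years | implies ≈7.5 y mean, matching published person-years per participant |
| claims coverage | Uniform(6, 60) months | validation cohort requires ≥6 months |

Medication-class conditionals (e.g. loop diuretic 0.55 given HF, 0.075
given not) are free parameters — no joint distribution of medications and
comorbidities is published — chosen to yield an excluded fraction (≈18%)
and NPV (≈95–97%) in the published range. Use is drawn per *drug class*,
with a concrete generic or brand name sampled from the registry, so rule
conjunctions and name normalization are genuinely exercised; carvedilol is
its own class and is excluded from the generic beta-blocker pool so the
two rules stay statistically independent. Claims counts are Poisson per
setting over the coverage window, each claim independently carrying an HF
code in principal or secondary position with status-specific
probabilities; defaults put the any-diagnosis referent prevalence at
≈11.3% for the default latent prevalence. Hospitalizations are
exponential waiting times at the status-specific rate, censored at the
drawn follow-up; a small planted fraction of admissions between interview
and visit exercises that eligibility filter.

What the generator does **not** model: correlation among comorbidities
beyond the shared latent status, dose/indication structure, seasonal or
secular claim patterns, geographic sampling, differential coverage by age.
Passing tests therefore demonstrate correctness of the *pipeline
machinery* under the stated conditional structure, not performance of the
phenotype on real data.

`force_inpatient_principal_if_hf` plus zero false-positive code
probabilities makes the claims referent coincide with latent status
exactly; under those conditions the cascade's NPV has a closed form by
Bayes' rule over the configured conditionals, which the test suite uses
for parameter-recovery checks (100 replicates of n = 10,000; the analytic
NPV must fall in the estimate's own 95% CI in ≥93 of them). Simulation
sizes throughout the suite (3,000–30,000 participants; 25 pooled
replicates for rate recovery) were chosen to keep Monte-Carlo tolerances —
4·√(p(1−p)/n) for proportions, 4·rate/√events for rates — meaningfully
tight.

## Numerical and degenerate-input choices

* Dates are integer days from a fixed epoch; only order and duration matter.
* An empty cohort (n = 0) flows through every stage and yields zero counts
  and undefined metrics, not errors.
* Reports carry full-precision values alongside one-decimal renderings;
  tests compare at full precision except where a published table fixes the
  precision.
* Determinism: one `numpy` Generator seeded from the config drives every
  draw in a fixed order; identical (config, seed) pairs produce
  byte-identical CSV output, and the pipeline report embeds the seed and a
  config hash sufficient to re-run bit-identically.

## Known limitations

* The registry is a curated snapshot, not an RxNorm/ATC service; rare
  brands or misspellings normalize to nothing (and therefore never
  trigger exclusion).
* Study-scale absolute counts (e.g. a 25,759-participant HF-free cohort)
  depend on the restricted source data; the package reproduces their
  arithmetic and their proportion structure on synthetic analogues only.
* The Wald intervals are anti-conservative for denominators below ~30 or
  proportions near 0/1; use the exact option there.
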