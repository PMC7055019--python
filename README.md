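# hffree

Tools for assembling a **heart-failure-free cohort** from a baseline
medication inventory and validating that assembly against claims-based
referent definitions of heart failure (HF).

Longitudinal cohort studies of *incident* HF need a baseline denominator
free of *prevalent* HF. When echocardiography or clinical adjudication of
every participant is infeasible, a practical alternative is a computable
phenotype: exclude anyone whose baseline medications indicate possible HF
treatment, then quantify how clean the remaining cohort is using linked
fee-for-service Medicare claims as the referent standard. `hffree`
implements that workflow end to end, together with a synthetic
Medicare-linked cohort generator, so the whole pipeline is testable without
access to restricted participant-level data.

## The method

**Exclusion cascade.** After removing participants with anomalous data, no
follow-up, missing atrial-fibrillation (AF) or medication data, or an
adjudicated HF hospitalization between the baseline interview and the
in-home visit, a participant is flagged *suspected HF* if their inventory
contains any of:

1. digoxin in the absence of AF;
2. an ACE inhibitor or ARB **plus** a beta-blocker, in the absence of
   hypertension;
3. carvedilol;
4. spironolactone;
5. a loop diuretic (furosemide, bumetanide, torsemide);
6. hydralazine combined with a nitrate.

AF is self-report OR AF on the baseline ECG; hypertension is self-reported
BP-medication use OR measured SBP > 140 mmHg OR DBP > 90 mmHg.

**Claims referents.** Three nested ICD-9-CM definitions (codes 402.01,
402.11, 402.91, 404.01, 404.03, 404.11, 404.13, 404.91, 404.93, 428.xx),
from all claims prior to the in-home visit: (a) ≥1 inpatient claim with a
principal HF diagnosis; (b) definition (a) or ≥2 outpatient claims with
principal HF diagnoses; (c) ≥1 inpatient or ≥2 outpatient claims with HF in
any position.

**Validation metrics.** With "test positive" = excluded, the package
reports NPV = tn/(tn+fn) (the headline metric: the proportion of the
HF-free cohort without claims evidence of HF), PPV, sensitivity and
specificity, each with a 95% normal-approximation CI
p ± 1.96·√(p(1−p)/m), overall, within a-priori subgroups (age 65–74 vs
≥75, sex, race), and under two variants that additionally exclude
symptomatic participants (orthopnea/PND) or early adjudicated HF events.
First-event HF-hospitalization rates per 1000 person-years are estimated
with CIs rate ± 1.96·rate/√events.

## Worked example

```bash
hffree run --seed 7 --out-dir out/
```

simulates 10,000 participants under the default study conditions, runs the
full cascade and validation, and prints (abridged):

```
| quantity        | n    |
| n_eligible      | 9572 |
| n_hf_free       | 7749 |
| n_suspected_hf  | 1823 |

| group        | events | person-years | rate | ci low | ci high |
| full_sample  | 426    | 70110.4      | 6.1  | 5.5    | 6.7     |
| hf_free      | 282    | 56910.5      | 5.0  | 4.4    | 5.5     |
| suspected_hf | 144    | 13199.9      | 10.9 | 9.1    | 12.7    |

| referent                   | tp  | fp   | fn  | tn   | NPV %| PPV % | Sens % | Spec % |
| Hospitalization for HF     | 443 | 1380 | 175 | 7574 | 97.7  | 24.3  | 71.7   | 84.6   |
| Principal diagnosis of HF  | 726 | 1097 | 283 | 7466 | 96.3  | 39.8  | 72.0   | 87.2   |
| Any diagnosis of HF        | 782 | 1041 | 320 | 7429 | 95.9  | 42.9  | 71.0   | 87.7   |
```

428 of 10,000 simulated participants fall out of the eligibility cascade;
81% of the survivors take no HF-specific medication and form the HF-free
cohort. Its NPV is 96–98% depending on the referent: the medication screen
keeps claims-evident HF in the retained cohort rare, at the cost of
excluding many referent-negative participants (modest PPV) — the intended
trade-off when the goal is a clean denominator. Suspected-HF participants
are hospitalized for HF at roughly twice the rate of the HF-free cohort
here; the gap is attenuated relative to the latent-status rates because
rule-positive inventories only partially overlap latent HF.

The stage commands `hffree simulate | assemble | phenotype | validate |
rates` expose the same steps over CSV files; `--help` documents each.
Library entry points: `hffree.generate_cohort`, `hffree.apply_eligibility`,
`hffree.assemble_hf_free`, `hffree.label_cohort`, `hffree.build_two_by_two`,
`hffree.diagnostic_metrics`, `hffree.rate_estimate`,
`hffree.run_full_pipeline`.

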