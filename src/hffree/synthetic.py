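"""Synthetic Medicare-linked cohort generator.

The real study population (a national cohort of Black and White US adults
aged >=45, linked to fee-for-service Medicare claims) is not publicly
available, so this module generates tables with the same layout and the
statistical structure the downstream analysis assumes:

* a latent baseline heart-failure status per participant;
* HF-medication use drawn per drug class conditional on latent status (the
  exclusion rules are *not* baked in — rule conjunctions such as ACEi+BB
  are genuinely exercised);
* atrial fibrillation, hypertension and symptom indicators (orthopnea, PND)
  conditional on latent status, decomposed into the raw components the
  assembly stage derives them from;
* inpatient/outpatient claims with principal- or secondary-position HF
  codes at configurable conditional probabilities;
* adjudicated HF hospitalizations as exponential waiting times at
  status-specific rates per 1000 person-years, censored at a drawn
  follow-up duration;
* missingness and anomaly flags so every eligibility filter is exercised.

Dates are integer days on a simple calendar (day 0 = study start; the
enrollment window mimics 2003-2007 but only orderings and durations matter).
Identical (config, seed) pairs produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from . import claims as claims_mod
from .medications import CLASS_TAGS, DrugClassRegistry

# representative dotted ICD-9-CM codes drawn for HF-coded claim positions
HF_CODE_POOL = (
    "428.0",
    "428.1",
    "428.20",
    "428.22",
    "428.30",
    "428.33",
    "428.40",
    "402.01",
    "402.11",
    "402.91",
    "404.01",
    "404.13",
    "404.91",
)

# common non-HF codes for the remaining positions
OTHER_CODE_POOL = (
    "250.00",
    "401.9",
    "414.01",
    "496",
    "715.90",
    "272.4",
    "486",
    "599.0",
    "427.31",
    "780.79",
)

# free-text names with no rule-relevant class, to exercise normalization
NOISE_MED_POOL = (
    "aspirin",
    "atorvastatin",
    "simvastatin",
    "metformin",
    "omeprazole",
    "levothyroxine",
    "amlodipine",
    "hydrochlorothiazide",
    "vitamin d",
    "fish oil",
)


class CondProb(BaseModel):
    """A probability conditional on latent HF status."""

    hf: float = Field(ge=0.0, le=1.0)
    no_hf: float = Field(ge=0.0, le=1.0)

    def by_status(self, latent_hf: np.ndarray) -> np.ndarray:
        return np.where(latent_hf, self.hf, self.no_hf)


class Distribution(BaseModel):
    """A simple one-dimensional sampling distribution (uniform or constant)."""

    kind: Literal["uniform", "constant"] = "uniform"
    low: float = 0.0
    high: float = 1.0
    value: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "uniform" and self.high < self.low:
            raise ValueError("uniform distribution needs high >= low")
        return self

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.value)
        return rng.uniform(self.low, self.high, n)


class SettingClaims(BaseModel):
    """Claim-count and HF-coding parameters for one care setting.

    ``mean_*`` are mean total claim counts over the pre-visit lookback;
    ``p_principal_*`` / ``p_secondary_*`` are per-claim probabilities that
    the claim carries an HF code in that position.
    """

    mean_hf: float = Field(ge=0.0)
    mean_no_hf: float = Field(ge=0.0)
    p_principal_hf: float = Field(ge=0.0, le=1.0)
    p_principal_no_hf: float = Field(ge=0.0, le=1.0)
    p_secondary_hf: float = Field(ge=0.0, le=1.0)
    p_secondary_no_hf: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self):
        if self.p_principal_hf + self.p_secondary_hf > 1:
            raise ValueError("p_principal_hf + p_secondary_hf must not exceed 1")
        if self.p_principal_no_hf + self.p_secondary_no_hf > 1:
            raise ValueError("p_principal_no_hf + p_secondary_no_hf must not exceed 1")
        return self


class ClaimsParams(BaseModel):
    inpatient: SettingClaims = SettingClaims(
        mean_hf=1.5,
        mean_no_hf=0.35,
        p_principal_hf=0.55,
        p_principal_no_hf=0.003,
        p_secondary_hf=0.25,
        p_secondary_no_hf=0.006,
    )
    outpatient: SettingClaims = SettingClaims(
        mean_hf=7.0,
        mean_no_hf=4.0,
        p_principal_hf=0.45,
        p_principal_no_hf=0.003,
        p_secondary_hf=0.15,
        p_secondary_no_hf=0.006,
    )
    #: every latent-HF participant receives one inpatient claim with a
    #: principal HF code (used to force referent == latent truth in tests)
    force_inpatient_principal_if_hf: bool = False


def _default_med_use() -> dict[str, CondProb]:
    return {
        "digoxin": CondProb(hf=0.20, no_hf=0.02),
        "ace_inhibitor": CondProb(hf=0.45, no_hf=0.20),
        "arb": CondProb(hf=0.12, no_hf=0.08),
        "beta_blocker": CondProb(hf=0.45, no_hf=0.15),
        "carvedilol": CondProb(hf=0.15, no_hf=0.004),
        "spironolactone": CondProb(hf=0.10, no_hf=0.008),
        "loop_diuretic": CondProb(hf=0.55, no_hf=0.075),
        "hydralazine": CondProb(hf=0.06, no_hf=0.006),
        "nitrate": CondProb(hf=0.25, no_hf=0.02),
    }


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic cohort, with study-calibrated defaults.

    Defaults emulate the source study's marginals: latent HF prevalence 11.3%
    (the "any diagnosis" claims prevalence in the validation cohort),
    HF-hospitalization rates 26.6 vs 4.29 per 1000 person-years by latent
    status, and comorbidity/symptom conditionals consistent with the printed
    baseline tables.  The medication and claims conditionals are free
    parameters of the generator (no joint distribution is published) —
    see docs/methods.md.
    """

    n_participants: int = Field(default=10_000, ge=0)
    seed: int = 0

    hf_prevalence: float = Field(default=0.113, ge=0.0, le=1.0)

    med_use: dict[str, CondProb] = Field(default_factory=_default_med_use)
    p_brand_name: float = Field(default=0.3, ge=0.0, le=1.0)
    noise_meds_mean: float = Field(default=1.5, ge=0.0)

    p_af: CondProb = CondProb(hf=0.225, no_hf=0.093)
    p_htn: CondProb = CondProb(hf=0.762, no_hf=0.643)
    p_orthopnea: CondProb = CondProb(hf=0.35, no_hf=0.08)
    p_pnd: CondProb = CondProb(hf=0.22, no_hf=0.04)

    claims_params: ClaimsParams = ClaimsParams()
    coverage_months_distribution: Distribution = Distribution(
        kind="uniform", low=6.0, high=60.0
    )
    followup_years_distribution: Distribution = Distribution(
        kind="uniform", low=5.0, high=10.0
    )

    #: HF-hospitalization rates per 1000 person-years by latent status
    hosp_rate_hf: float = Field(default=26.6, ge=0.0)
    hosp_rate_no_hf: float = Field(default=4.29, ge=0.0)
    #: non-HF hospitalizations (adjudicated hf=False rows), per 1000 PY
    hosp_rate_non_hf_cause: float = Field(default=15.0, ge=0.0)

    p_anomalous: float = Field(default=0.002, ge=0.0, le=1.0)
    p_no_followup: float = Field(default=0.015, ge=0.0, le=1.0)
    p_missing_af: float = Field(default=0.023, ge=0.0, le=1.0)
    p_missing_meds: float = Field(default=0.0045, ge=0.0, le=1.0)
    #: adjudicated HF admission planted between interview and in-home visit
    p_hf_between_interview_and_visit: float = Field(default=0.0004, ge=0.0, le=1.0)

    age_mean: float = 64.9
    age_sd: float = Field(default=9.4, gt=0.0)
    age_min: float = 45.0
    p_female: float = Field(default=0.55, ge=0.0, le=1.0)
    p_black: float = Field(default=0.409, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_med_classes(self):
        unknown = set(self.med_use) - set(CLASS_TAGS)
        if unknown:
            raise ValueError(f"unknown medication class(es) in med_use: {sorted(unknown)}")
        return self


@dataclass
class SyntheticCohort:
    """The five analysis tables plus the latent ground truth."""

    participants: pd.DataFrame
    medications: pd.DataFrame
    claims: pd.DataFrame
    adjudicated: pd.DataFrame
    followup: pd.DataFrame
    truth: pd.DataFrame

    TABLES = ("participants", "medications", "claims", "adjudicated", "followup", "truth")

    def write(self, out_dir) -> None:
        """Write each table as CSV; diagnosis codes stay quoted text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import csv as _csv

        for name in self.TABLES:
            df: pd.DataFrame = getattr(self, name)
            df.to_csv(out / f"{name}.csv", index=False, quoting=_csv.QUOTE_NONNUMERIC)

    @classmethod
    def read(cls, in_dir) -> "SyntheticCohort":
        in_dir = Path(in_dir)
        kwargs = {}
        for name in cls.TABLES:
            kwargs[name] = pd.read_csv(
                in_dir / f"{name}.csv", dtype={"dx_codes": str} if name == "claims" else None
            )
        return cls(**kwargs)


# ---------------------------------------------------------------------------


def _med_name_pools(registry: DrugClassRegistry) -> dict[str, list[tuple[str, ...]]]:
    """Per class: list of (generic, brand...) name groups to draw from.

    The beta-blocker pool excludes carvedilol, which is drawn through its own
    class so the two rules stay independent.
    """
    pools: dict[str, list[tuple[str, ...]]] = {}
    for tag in CLASS_TAGS:
        members = sorted(registry.members(tag))
        if tag == "beta_blocker":
            members = [m for m in members if "carvedilol" not in registry.classes_of(m)]
        pools[tag] = [(m, *registry.brands_of(m)) for m in members]
    return pools


def _empty_cohort() -> SyntheticCohort:
    return SyntheticCohort(
        participants=pd.DataFrame(
            columns=[
                "participant_id", "age", "sex", "race", "interview_date",
                "inhome_visit_date", "self_report_af", "ecg_af", "bp_med",
                "sbp", "dbp", "orthopnea", "pnd", "anomalous_flag",
                "meds_missing_flag", "has_followup", "coverage_months_pre_visit",
            ]
        ),
        medications=pd.DataFrame(columns=["participant_id", "raw_name"]),
        claims=pd.DataFrame(
            columns=["participant_id", "service_date", "setting", "dx_codes"]
        ),
        adjudicated=pd.DataFrame(columns=["participant_id", "admission_date", "hf"]),
        followup=pd.DataFrame(columns=["participant_id", "censor_date"]),
        truth=pd.DataFrame(columns=["participant_id", "latent_hf"]),
    )


def generate_cohort(
    config: GeneratorConfig,
    seed: Optional[int] = None,
    registry: Optional[DrugClassRegistry] = None,
) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic under fixed (config, seed)."""
    n = config.n_participants
    if n == 0:
        return _empty_cohort()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    registry = registry or DrugClassRegistry.default()

    ids = np.arange(1, n + 1)
    latent_hf = rng.random(n) < config.hf_prevalence

    # demographics
    a = (config.age_min - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    ).round(1)
    sex = np.where(rng.random(n) < config.p_female, "F", "M")
    race = np.where(rng.random(n) < config.p_black, "black", "white")

    # calendar: telephone interview, then in-home visit 2-8 weeks later
    interview = rng.integers(0, 1400, n)
    visit = interview + rng.integers(14, 61, n)

    # comorbidities, decomposed into the raw components assembly derives from
    af = rng.random(n) < config.p_af.by_status(latent_hf)
    self_report_af = af & (rng.random(n) < 0.85)
    ecg_af = af & (~self_report_af | (rng.random(n) < 0.2))

    htn = rng.random(n) < config.p_htn.by_status(latent_hf)
    bp_med = htn & (rng.random(n) < 0.75)
    # pressures: elevated only for hypertensives without BP medication
    sbp = np.round(100 + 40 * rng.random(n), 0)
    dbp = np.round(60 + 30 * rng.random(n), 0)
    need_high = htn & ~bp_med
    sbp = np.where(need_high, np.round(141 + 40 * rng.random(n), 0), sbp)

    orthopnea = rng.random(n) < config.p_orthopnea.by_status(latent_hf)
    pnd = rng.random(n) < config.p_pnd.by_status(latent_hf)

    anomalous = rng.random(n) < config.p_anomalous
    no_followup = rng.random(n) < config.p_no_followup
    missing_af = rng.random(n) < config.p_missing_af
    missing_meds = rng.random(n) < config.p_missing_meds
    coverage = np.round(config.coverage_months_distribution.sample(rng, n), 1)

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "age": age,
            "sex": sex,
            "race": race,
            "interview_date": interview,
            "inhome_visit_date": visit,
            "self_report_af": pd.array(self_report_af, dtype="boolean"),
            "ecg_af": ecg_af,
            "bp_med": bp_med,
            "sbp": sbp,
            "dbp": dbp,
            "orthopnea": orthopnea,
            "pnd": pnd,
            "anomalous_flag": anomalous,
            "meds_missing_flag": missing_meds,
            "has_followup": ~no_followup,
            "coverage_months_pre_visit": coverage,
        }
    )
    participants.loc[missing_af, "self_report_af"] = pd.NA

    # medications: one bernoulli draw per rule-relevant class, plus noise meds
    pools = _med_name_pools(registry)
    med_pid: list[np.ndarray] = []
    med_names: list[np.ndarray] = []
    for tag in CLASS_TAGS:
        prob = config.med_use.get(tag)
        if prob is None:
            continue
        takers = rng.random(n) < prob.by_status(latent_hf)
        take_ids = ids[takers]
        if not len(take_ids):
            continue
        groups = pools[tag]
        gi = rng.integers(0, len(groups), len(take_ids))
        use_brand = rng.random(len(take_ids)) < config.p_brand_name
        names = np.array(
            [
                groups[g][1 + int(rng.integers(0, len(groups[g]) - 1))]
                if (b and len(groups[g]) > 1)
                else groups[g][0]
                for g, b in zip(gi, use_brand)
            ]
        )
        med_pid.append(take_ids)
        med_names.append(names)
    n_noise = rng.poisson(config.noise_meds_mean, n)
    noise_ids = np.repeat(ids, n_noise)
    if len(noise_ids):
        med_pid.append(noise_ids)
        med_names.append(
            np.array(NOISE_MED_POOL)[rng.integers(0, len(NOISE_MED_POOL), len(noise_ids))]
        )
    if med_pid:
        medications = pd.DataFrame(
            {"participant_id": np.concatenate(med_pid), "raw_name": np.concatenate(med_names)}
        ).sort_values(["participant_id", "raw_name"], kind="stable")
    else:
        medications = pd.DataFrame(columns=["participant_id", "raw_name"])
    # explicit missing-marker semantics: flagged participants have no inventory rows
    medications = medications[
        ~medications["participant_id"].isin(ids[missing_meds])
    ].reset_index(drop=True)

    # claims over the pre-visit coverage window
    cov_days = np.maximum((coverage * 30.44).astype(int), 0)
    claim_frames = []
    cp = config.claims_params
    for setting in ("inpatient", "outpatient"):
        sp: SettingClaims = getattr(cp, setting)
        mean = np.where(latent_hf, sp.mean_hf, sp.mean_no_hf)
        counts = rng.poisson(mean)
        counts = np.where(cov_days > 0, counts, 0)
        total = int(counts.sum())
        if total == 0:
            continue
        pid = np.repeat(ids, counts)
        window = np.repeat(cov_days, counts)
        vis = np.repeat(visit, counts)
        dates = vis - 1 - (rng.random(total) * (window - 1).clip(min=0)).astype(int)
        p1 = np.repeat(np.where(latent_hf, sp.p_principal_hf, sp.p_principal_no_hf), counts)
        p2 = np.repeat(np.where(latent_hf, sp.p_secondary_hf, sp.p_secondary_no_hf), counts)
        u = rng.random(total)
        principal_hf = u < p1
        secondary_hf = ~principal_hf & (u < p1 + p2)
        hf_codes = np.array(HF_CODE_POOL)[rng.integers(0, len(HF_CODE_POOL), total)]
        other1 = np.array(OTHER_CODE_POOL)[rng.integers(0, len(OTHER_CODE_POOL), total)]
        other2 = np.array(OTHER_CODE_POOL)[rng.integers(0, len(OTHER_CODE_POOL), total)]
        dx = np.where(
            principal_hf,
            np.char.add(np.char.add(hf_codes, "|"), other1),
            np.where(
                secondary_hf,
                np.char.add(np.char.add(other1, "|"), hf_codes),
                np.char.add(np.char.add(other1, "|"), other2),
            ),
        )
        claim_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "service_date": dates,
                    "setting": setting,
                    "dx_codes": dx,
                }
            )
        )
    if cp.force_inpatient_principal_if_hf and latent_hf.any():
        fid = ids[latent_hf]
        m = len(fid)
        claim_frames.append(
            pd.DataFrame(
                {
                    "participant_id": fid,
                    "service_date": visit[latent_hf]
                    - 1
                    - (rng.random(m) * 120).astype(int),
                    "setting": "inpatient",
                    "dx_codes": np.array(HF_CODE_POOL)[
                        rng.integers(0, len(HF_CODE_POOL), m)
                    ],
                }
            )
        )
    if claim_frames:
        claims = (
            pd.concat(claim_frames, ignore_index=True)
            .sort_values(["participant_id", "service_date", "setting"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        claims = pd.DataFrame(columns=["participant_id", "service_date", "setting", "dx_codes"])

    # follow-up and adjudicated hospitalizations
    followup_years = config.followup_years_distribution.sample(rng, n)
    censor = visit + np.round(followup_years * 365.25).astype(int)
    followup = pd.DataFrame(
        {"participant_id": ids[~no_followup], "censor_date": censor[~no_followup]}
    )

    adj_frames = []
    hf_rate = np.where(latent_hf, config.hosp_rate_hf, config.hosp_rate_no_hf) / 1000.0
    with np.errstate(divide="ignore"):
        wait_years = rng.exponential(np.where(hf_rate > 0, 1.0 / hf_rate, np.inf))
    has_event = (wait_years < followup_years) & ~no_followup
    if has_event.any():
        adm = visit[has_event] + np.maximum(
            np.round(wait_years[has_event] * 365.25).astype(int), 1
        )
        adm = np.minimum(adm, censor[has_event])
        adj_frames.append(
            pd.DataFrame(
                {"participant_id": ids[has_event], "admission_date": adm, "hf": True}
            )
        )
    # planted admissions between interview and visit (exercises eligibility)
    between = rng.random(n) < config.p_hf_between_interview_and_visit
    if between.any():
        gap = visit[between] - interview[between]
        adm = interview[between] + (rng.random(int(between.sum())) * gap).astype(int)
        adj_frames.append(
            pd.DataFrame(
                {"participant_id": ids[between], "admission_date": adm, "hf": True}
            )
        )
    # non-HF hospitalizations: consumed as hf=False rows downstream
    nh_rate = config.hosp_rate_non_hf_cause / 1000.0
    if nh_rate > 0:
        nh_wait = rng.exponential(1.0 / nh_rate, n)
        nh = (nh_wait < followup_years) & ~no_followup
        if nh.any():
            adj_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": ids[nh],
                        "admission_date": visit[nh]
                        + np.maximum(np.round(nh_wait[nh] * 365.25).astype(int), 1),
                        "hf": False,
                    }
                )
            )
    if adj_frames:
        adjudicated = (
            pd.concat(adj_frames, ignore_index=True)
            .sort_values(["participant_id", "admission_date"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        adjudicated = pd.DataFrame(columns=["participant_id", "admission_date", "hf"])

    truth = pd.DataFrame({"participant_id": ids, "latent_hf": latent_hf})
    return SyntheticCohort(
        participants=participants,
        medications=medications,
        claims=claims,
        adjudicated=adjudicated,
        followup=followup,
        truth=truth,
    )


def truth_referent_alignment(
    cohort: SyntheticCohort,
    codeset: claims_mod.HFCodeSet = claims_mod.DEFAULT_CODESET,
) -> pd.DataFrame:
    """Join latent truth to the three claims-referent labels (calibration harness)."""
    if not len(cohort.participants):
        return pd.DataFrame(
            columns=["participant_id", "latent_hf", "def_a_hosp", "def_b_principal", "def_c_any"]
        )
    labels = claims_mod.label_cohort(cohort.claims, cohort.participants, codeset)
    return cohort.truth.merge(labels, on="participant_id", how="left")
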