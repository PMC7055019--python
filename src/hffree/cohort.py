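"""Eligibility cascade and assembly of the heart-failure-free cohort.

Two cascades are implemented:

* the main eligibility cascade — drop participants with anomalous data, no
  follow-up, missing self-reported atrial-fibrillation data, missing baseline
  medication data, or an adjudicated HF hospitalization between the baseline
  telephone interview and the in-home visit, in that order, each step counted
  among survivors of the previous steps;
* the validation-cohort cascade — restrict to participants with at least six
  months of fee-for-service claims coverage at the in-home visit, then apply
  the missing-AF / missing-meds / interview-to-visit-HF exclusions.

Survivors of the eligibility cascade are then labelled ``hf_free`` or
``suspected_hf`` by the medication rules (:mod:`hffree.medications`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .medications import (
    CLASS_TAGS,
    DrugClassRegistry,
    ExclusionFlags,
    normalize_medication,
)

logger = logging.getLogger(__name__)

#: eligibility steps in cascade order
ELIGIBILITY_STEPS = (
    "anomalous",
    "no_followup",
    "missing_af",
    "missing_meds",
    "hf_between_interview_and_visit",
)


@dataclass(frozen=True)
class EligibilityTally:
    """Attrition bookkeeping: participants removed at each cascade step.

    ``n_start - (sum of step counts) == n_eligible`` on every input; for the
    validation cascade ``insufficient_coverage`` precedes the shared steps.
    """

    n_start: int
    anomalous: int = 0
    no_followup: int = 0
    missing_af: int = 0
    missing_meds: int = 0
    hf_between_interview_and_visit: int = 0
    insufficient_coverage: int = 0
    n_eligible: int = 0

    def __post_init__(self):
        removed = (
            self.anomalous
            + self.no_followup
            + self.missing_af
            + self.missing_meds
            + self.hf_between_interview_and_visit
            + self.insufficient_coverage
        )
        if self.n_eligible != self.n_start - removed:
            raise ValueError(
                f"tally does not conserve: {self.n_start} - {removed} != {self.n_eligible}"
            )
        if min(asdict(self).values()) < 0:
            raise ValueError("tally counts must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def _require_unique_ids(participants: pd.DataFrame) -> None:
    if participants["participant_id"].duplicated().any():
        dup = participants.loc[
            participants["participant_id"].duplicated(), "participant_id"
        ].head()
        raise ValueError(f"duplicate participant ids, e.g. {list(dup)}")


def _to_boolean(series: pd.Series) -> pd.Series:
    """Coerce a possibly CSV-round-tripped column to nullable boolean."""
    if series.dtype == object:
        series = series.map(
            {
                True: True, False: False,
                "True": True, "False": False,
                "true": True, "false": False,
                1: True, 0: False, 1.0: True, 0.0: False,
            }
        )
    return series.astype("boolean")


def resolve_covariates(participants: pd.DataFrame, strict_htn: bool = True) -> pd.DataFrame:
    """Derive the af and htn columns from their components where absent.

    af = self-reported AF OR AF on ECG, missing when self-report is missing;
    htn = self-reported BP-medication use OR SBP > 140 OR DBP > 90 (never
    missing: absent pressures do not contribute).
    """
    p = participants.copy()
    if "af" not in p.columns:
        sr = _to_boolean(p["self_report_af"])
        ecg = _to_boolean(p["ecg_af"]).fillna(False).astype(bool)
        af = sr | ecg
        af[sr.isna()] = pd.NA
        p["af"] = af
    if "htn" not in p.columns:
        sbp = pd.to_numeric(p["sbp"], errors="coerce")
        dbp = pd.to_numeric(p["dbp"], errors="coerce")
        if (sbp.dropna() < 0).any() or (dbp.dropna() < 0).any():
            raise ValueError("blood pressures must be non-negative")
        if strict_htn:
            high = (sbp > 140) | (dbp > 90)
        else:
            high = (sbp >= 140) | (dbp >= 90)
        p["htn"] = (
            _to_boolean(p["bp_med"]).fillna(False).astype(bool) | high.fillna(False)
        )
    return p


def _hf_between(participants: pd.DataFrame, adjudicated: pd.DataFrame) -> pd.Series:
    """Ids with an adjudicated HF admission in [interview_date, inhome_visit_date).

    A same-day-as-visit event belongs to follow-up, hence the half-open window.
    """
    if adjudicated is None or not len(adjudicated):
        return pd.Series(False, index=participants["participant_id"])
    adj = adjudicated
    if "hf" in adj.columns:
        adj = adj[adj["hf"].astype(bool)]
    merged = adj.merge(
        participants[["participant_id", "interview_date", "inhome_visit_date"]].reset_index(
            drop=True
        ),
        on="participant_id",
    )
    hit = merged[
        (merged["admission_date"] >= merged["interview_date"])
        & (merged["admission_date"] < merged["inhome_visit_date"])
    ]["participant_id"].unique()
    return pd.Series(
        participants["participant_id"].isin(hit).values,
        index=participants["participant_id"],
    )


def apply_eligibility(
    participants: pd.DataFrame,
    adjudicated: pd.DataFrame | None = None,
    followup: pd.DataFrame | None = None,
) -> tuple[pd.Index, EligibilityTally]:
    """Run the main eligibility cascade; return survivor ids and the tally.

    Follow-up status is taken from a ``has_followup`` column when present,
    otherwise from membership in the ``followup`` table.
    """
    _require_unique_ids(participants)
    p = resolve_covariates(participants).set_index("participant_id", drop=False)
    n_start = len(p)
    counts: dict[str, int] = {}

    def _drop(step: str, mask: pd.Series):
        nonlocal p
        if mask.dtype != bool:
            mask = _to_boolean(mask)
        mask = mask.reindex(p.index).fillna(False).astype(bool)
        counts[step] = int(mask.sum())
        logger.info("eligibility step %s: removed %d of %d", step, counts[step], len(p))
        p = p[~mask]

    _drop("anomalous", p.get("anomalous_flag", pd.Series(False, index=p.index)))

    if "has_followup" in p.columns:
        no_fu = ~_to_boolean(p["has_followup"]).fillna(False).astype(bool)
    elif followup is not None:
        no_fu = ~p["participant_id"].isin(followup["participant_id"])
    else:
        no_fu = pd.Series(False, index=p.index)
    _drop("no_followup", no_fu)

    _drop("missing_af", p["af"].isna())
    _drop("missing_meds", p.get("meds_missing_flag", pd.Series(False, index=p.index)))
    _drop("hf_between_interview_and_visit", _hf_between(p, adjudicated))

    tally = EligibilityTally(n_start=n_start, n_eligible=len(p), **counts)
    return p.index, tally


def select_validation_cohort(
    participants: pd.DataFrame,
    adjudicated: pd.DataFrame | None = None,
    min_coverage: float = 6.0,
) -> tuple[pd.Index, EligibilityTally]:
    """Select the Medicare validation subset and re-apply its exclusions.

    Keeps participants with at least ``min_coverage`` months of pre-visit
    fee-for-service claims coverage, then removes those with missing AF,
    missing medication data, or an adjudicated HF hospitalization between
    interview and visit.
    """
    _require_unique_ids(participants)
    p = resolve_covariates(participants).set_index("participant_id", drop=False)
    cov = pd.to_numeric(p["coverage_months_pre_visit"], errors="coerce")
    if (cov.dropna() < 0).any():
        raise ValueError("coverage_months_pre_visit must be non-negative")
    n_start = len(p)
    counts: dict[str, int] = {}

    def _drop(step: str, mask: pd.Series):
        nonlocal p
        if mask.dtype != bool:
            mask = _to_boolean(mask)
        mask = mask.reindex(p.index).fillna(False).astype(bool)
        counts[step] = int(mask.sum())
        p = p[~mask]

    _drop("insufficient_coverage", ~(cov >= min_coverage))
    _drop("missing_af", p["af"].isna())
    _drop("missing_meds", p.get("meds_missing_flag", pd.Series(False, index=p.index)))
    _drop("hf_between_interview_and_visit", _hf_between(p, adjudicated))

    tally = EligibilityTally(n_start=n_start, n_eligible=len(p), **counts)
    return p.index, tally


# ---------------------------------------------------------------------------
# medication-rule labelling

RULE_COLUMNS = (
    "r1_digoxin_no_af",
    "r2_acearb_bb_no_htn",
    "r3_carvedilol",
    "r4_spironolactone",
    "r5_loop_diuretic",
    "r6_hydralazine_nitrate",
)


def participant_class_flags(
    ids: pd.Index, medications: pd.DataFrame, registry: DrugClassRegistry
) -> pd.DataFrame:
    """Per-participant booleans: does the inventory contain each drug class?

    Unique raw names are normalized once, so cost scales with the vocabulary,
    not the table length.
    """
    flags = pd.DataFrame(False, index=ids, columns=list(CLASS_TAGS))
    meds = medications[medications["participant_id"].isin(ids)]
    if not len(meds):
        return flags
    vocab = {
        raw: normalize_medication(raw, registry).ingredients
        for raw in meds["raw_name"].unique()
    }
    tag_by_raw = {
        raw: frozenset().union(*(registry.classes_of(i) for i in ings))
        if ings
        else frozenset()
        for raw, ings in vocab.items()
    }
    for tag in CLASS_TAGS:
        hits = meds.loc[
            meds["raw_name"].map(lambda r: tag in tag_by_raw[r]), "participant_id"
        ].unique()
        flags.loc[flags.index.intersection(pd.Index(hits)), tag] = True
    return flags


def assemble_hf_free(
    participants: pd.DataFrame,
    medications: pd.DataFrame,
    registry: DrugClassRegistry | None = None,
) -> pd.DataFrame:
    """Label each eligible participant ``hf_free`` or ``suspected_hf``.

    ``participants`` must already be the eligibility-cascade survivors with
    af resolved (non-missing) and htn derived.  Returns one row per
    participant with the six rule flags, ``suspected_hf`` and ``status``.
    """
    registry = registry or DrugClassRegistry.default()
    p = resolve_covariates(participants).set_index("participant_id", drop=False)
    if p["af"].isna().any():
        raise ValueError(
            "participants with unresolved af reached assembly; run apply_eligibility first"
        )
    has = participant_class_flags(p.index, medications, registry)
    af = p["af"].astype(bool)
    htn = p["htn"].astype(bool)
    labels = pd.DataFrame(index=p.index)
    labels["r1_digoxin_no_af"] = has["digoxin"] & ~af
    labels["r2_acearb_bb_no_htn"] = (
        (has["ace_inhibitor"] | has["arb"]) & has["beta_blocker"] & ~htn
    )
    labels["r3_carvedilol"] = has["carvedilol"]
    labels["r4_spironolactone"] = has["spironolactone"]
    labels["r5_loop_diuretic"] = has["loop_diuretic"]
    labels["r6_hydralazine_nitrate"] = has["hydralazine"] & has["nitrate"]
    labels["suspected_hf"] = labels[list(RULE_COLUMNS)].any(axis=1)
    labels["status"] = np.where(labels["suspected_hf"], "suspected_hf", "hf_free")
    return labels.rename_axis("participant_id").reset_index()


def flags_for_row(row: pd.Series) -> ExclusionFlags:
    """Repackage one label row as an :class:`ExclusionFlags`."""
    return ExclusionFlags(**{c: bool(row[c]) for c in RULE_COLUMNS})
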