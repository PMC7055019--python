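"""Claims-based referent definitions of heart failure from ICD-9-CM codes.

Three nested referent definitions label a participant as having HF from
fee-for-service inpatient and outpatient claims prior to an index date
(the baseline in-home visit):

a. *Hospitalization for HF* — at least one inpatient claim with an HF code
   as the principal (first-listed) diagnosis.
b. *Principal diagnosis of HF* — definition (a), or at least two outpatient
   physician-visit claims (emergency-department visits included) with an HF
   code as the principal diagnosis.
c. *Any diagnosis of HF* — at least one inpatient claim, or at least two
   outpatient claims, with an HF code in any diagnosis position.

The HF code set is the CMS roster used for publicly reported HF quality
measures: 402.01, 402.11, 402.91, 404.01, 404.03, 404.11, 404.13, 404.91,
404.93, and all of 428.xx.  Codes are handled as dotted text so leading
zeros and sub-code structure survive round-trips through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: exact-match members of the CMS HF code roster
HF_EXACT_CODES = frozenset(
    {
        "402.01",
        "402.11",
        "402.91",
        "404.01",
        "404.03",
        "404.11",
        "404.13",
        "404.91",
        "404.93",
    }
)

#: code roots matching any sub-code ("428.xx")
HF_PREFIX_CODES = frozenset({"428"})

SETTINGS = ("inpatient", "outpatient")


@dataclass(frozen=True)
class HFCodeSet:
    """Membership rule: exact code match, or a prefix root followed by end or '.'."""

    exact_codes: frozenset[str] = HF_EXACT_CODES
    prefix_codes: frozenset[str] = HF_PREFIX_CODES

    def __contains__(self, code: str) -> bool:
        code = str(code).strip()
        if code in self.exact_codes:
            return True
        for p in self.prefix_codes:
            if code == p or code.startswith(p + "."):
                return True
        return False


DEFAULT_CODESET = HFCodeSet()


def is_hf_code(code: str, codeset: HFCodeSet = DEFAULT_CODESET) -> bool:
    """True if a dotted ICD-9-CM code denotes heart failure.

    Matching is on the dotted dialect: ``"4280"`` does not match unless
    first converted with :func:`normalize_icd9`.
    """
    return code in codeset


def normalize_icd9(code: str) -> str:
    """Convert an undotted CMS-export numeric code to dotted form.

    ``"4280" -> "428.0"``; codes already dotted, three digits or shorter, or
    V/E-prefixed are returned stripped but otherwise untouched.
    """
    code = str(code).strip()
    if "." in code or len(code) <= 3:
        return code
    head = 4 if code[:1].upper() == "E" else 3
    if len(code) <= head:
        return code
    return code[:head] + "." + code[head:]


@dataclass(frozen=True)
class ClaimRecord:
    """One claim: setting, service date, and ordered diagnosis codes (1 = principal)."""

    participant_id: object
    service_date: float
    setting: str
    dx_codes: tuple[str, ...]

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")
        if not self.dx_codes:
            raise ValueError("dx_codes must be non-empty")


@dataclass(frozen=True)
class ReferentLabels:
    participant_id: object
    def_a_hosp: bool
    def_b_principal: bool
    def_c_any: bool


def referent_labels(
    claims: Sequence[ClaimRecord],
    index_date: float,
    codeset: HFCodeSet = DEFAULT_CODESET,
    require_distinct_dates: bool = True,
    participant_id: object = None,
) -> ReferentLabels:
    """Label one participant with the three referent definitions.

    Only claims strictly prior to ``index_date`` count; later-dated claims are
    silently ignored.  By default the two qualifying outpatient claims must
    fall on distinct service dates (same-day duplicates are treated as billing
    artifacts); ``require_distinct_dates=False`` counts raw claims.
    """
    inpat_principal = False
    inpat_any = False
    out_principal_dates: list[float] = []
    out_any_dates: list[float] = []
    for c in claims:
        if participant_id is None:
            participant_id = c.participant_id
        if c.service_date >= index_date:
            continue
        principal_hf = c.dx_codes[0] in codeset
        any_hf = principal_hf or any(code in codeset for code in c.dx_codes[1:])
        if c.setting == "inpatient":
            inpat_principal |= principal_hf
            inpat_any |= any_hf
        else:
            if principal_hf:
                out_principal_dates.append(c.service_date)
            if any_hf:
                out_any_dates.append(c.service_date)

    def _at_least_two(dates: list[float]) -> bool:
        n = len(set(dates)) if require_distinct_dates else len(dates)
        return n >= 2

    def_a = inpat_principal
    def_b = def_a or _at_least_two(out_principal_dates)
    def_c = inpat_any or _at_least_two(out_any_dates)
    return ReferentLabels(participant_id, def_a, def_b, def_c)


# ---------------------------------------------------------------------------
# bulk (DataFrame) path


def split_dx(dx_codes) -> tuple[str, ...]:
    """Parse the CSV encoding of a diagnosis-code list ('|'-joined dotted codes)."""
    if isinstance(dx_codes, (tuple, list)):
        return tuple(str(c) for c in dx_codes)
    return tuple(c for c in str(dx_codes).split("|") if c)


def label_cohort(
    claims: pd.DataFrame,
    participants: pd.DataFrame,
    codeset: HFCodeSet = DEFAULT_CODESET,
    require_distinct_dates: bool = True,
    index_col: str = "inhome_visit_date",
) -> pd.DataFrame:
    """Referent labels for every participant, from long-format claims.

    ``claims`` needs columns participant_id, service_date, setting, dx_codes
    (a '|'-joined string or a sequence); ``participants`` supplies the per-
    participant index date.  Participants with no qualifying claims get all-
    False labels.  Returns a frame with columns participant_id, def_a_hosp,
    def_b_principal, def_c_any.
    """
    bad = set(claims["setting"].unique()) - set(SETTINGS)
    if bad:
        raise ValueError(f"malformed claim setting(s): {sorted(bad)}")

    out = pd.DataFrame(
        {
            "participant_id": participants["participant_id"].values,
            "def_a_hosp": False,
            "def_b_principal": False,
            "def_c_any": False,
        }
    ).set_index("participant_id")

    if len(claims):
        idx = participants.set_index("participant_id")[index_col]
        cl = claims.merge(
            idx.rename("index_date"),
            left_on="participant_id",
            right_index=True,
            how="inner",
        )
        cl = cl[cl["service_date"] < cl["index_date"]]
        if len(cl):
            codes = [split_dx(c) for c in cl["dx_codes"]]
            principal_hf = np.array([c[0] in codeset if c else False for c in codes])
            any_hf = np.array(
                [any(code in codeset for code in c) for c in codes]
            )
            cl = cl.assign(principal_hf=principal_hf, any_hf=any_hf)
            inpat = cl[cl["setting"] == "inpatient"]
            outpat = cl[cl["setting"] == "outpatient"]

            inpat_principal = inpat.groupby("participant_id")["principal_hf"].any()
            inpat_any = inpat.groupby("participant_id")["any_hf"].any()

            def _out_pairs(mask_col: str) -> pd.Series:
                qual = outpat[outpat[mask_col]]
                if require_distinct_dates:
                    n = qual.groupby("participant_id")["service_date"].nunique()
                else:
                    n = qual.groupby("participant_id")["service_date"].size()
                return n >= 2

            out_principal2 = _out_pairs("principal_hf")
            out_any2 = _out_pairs("any_hf")

            def _set(col: str, series: pd.Series):
                hit = series[series].index
                out.loc[out.index.intersection(hit), col] = True

            _set("def_a_hosp", inpat_principal)
            _set("def_b_principal", inpat_principal)
            _set("def_b_principal", out_principal2)
            _set("def_c_any", inpat_any)
            _set("def_c_any", out_any2)

    return out.reset_index()
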