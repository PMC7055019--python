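"""Medication normalization and the HF-specific-medication exclusion rules.

A baseline medication inventory (free-text drug names, one row per
participant-drug) is normalized against an offline registry of generic
ingredients, brand synonyms and therapeutic-class tags, and then screened
with six rules that flag *suspected heart failure*:

r1  digoxin in the absence of atrial fibrillation
r2  ACE inhibitor or ARB, plus a beta-blocker, in the absence of hypertension
r3  carvedilol (unconditional)
r4  spironolactone
r5  a loop diuretic (furosemide, bumetanide or torsemide)
r6  hydralazine combined with a nitrate

A participant triggering any rule is excluded from the HF-free cohort.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

#: Therapeutic-class tags used by the exclusion rules.
CLASS_TAGS = (
    "digoxin",
    "ace_inhibitor",
    "arb",
    "beta_blocker",
    "carvedilol",
    "spironolactone",
    "loop_diuretic",
    "hydralazine",
    "nitrate",
)

_SPLIT_CHARS = ("/", "+", ",", "-", ";")


def _norm_token(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class MedicationEntry:
    """One inventoried drug: the raw name and its normalized generic ingredients.

    ``ingredients`` is empty when the raw name was not recognized; that is an
    informative outcome (an unrecognized drug triggers no rule), never an error.
    """

    raw_name: str
    ingredients: frozenset[str]


class DrugClassRegistry:
    """Offline mapping ingredient -> class tags, plus brand -> ingredient synonyms.

    Combination products (brand rows listing several ingredients) expand to all
    constituents.  Matching is exact on normalized tokens; no fuzzy matching.
    """

    def __init__(
        self,
        classes: Mapping[str, frozenset[str]],
        synonyms: Mapping[str, tuple[str, ...]],
    ) -> None:
        self.classes: dict[str, frozenset[str]] = {
            _norm_token(k): frozenset(v) for k, v in classes.items()
        }
        self.synonyms: dict[str, tuple[str, ...]] = {
            _norm_token(k): tuple(_norm_token(i) for i in v)
            for k, v in synonyms.items()
        }
        for brand, ingredients in self.synonyms.items():
            for ing in ingredients:
                if ing not in self.classes:
                    raise ValueError(
                        f"synonym {brand!r} maps to unknown ingredient {ing!r}"
                    )
        for tag in CLASS_TAGS:
            if not any(tag in tags for tags in self.classes.values()):
                raise ValueError(f"class tag {tag!r} has no member ingredient")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "DrugClassRegistry":
        """Load a registry from CSV with columns name,kind,ingredients,classes.

        ``kind`` is ``ingredient`` or ``brand``; multi-valued fields use ``|``.
        """
        classes: dict[str, frozenset[str]] = {}
        synonyms: dict[str, tuple[str, ...]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                name = _norm_token(row["name"])
                if row["kind"] == "ingredient":
                    tags = frozenset(t for t in row["classes"].split("|") if t)
                    classes[name] = tags
                elif row["kind"] == "brand":
                    synonyms[name] = tuple(
                        _norm_token(i) for i in row["ingredients"].split("|") if i
                    )
                else:
                    raise ValueError(f"unknown registry row kind {row['kind']!r}")
        return cls(classes, synonyms)

    @classmethod
    def default(cls) -> "DrugClassRegistry":
        """The registry shipped with the package (mid-2000s US generic rosters)."""
        with resources.as_file(
            resources.files("hffree.data").joinpath("drug_registry.csv")
        ) as path:
            return cls.from_csv(path)

    # -- queries ----------------------------------------------------------

    def lookup(self, token: str) -> tuple[str, ...]:
        """Resolve a normalized token to its ingredient(s); ``()`` if unknown."""
        token = _norm_token(token)
        if token in self.classes:
            return (token,)
        return self.synonyms.get(token, ())

    def classes_of(self, ingredient: str) -> frozenset[str]:
        return self.classes.get(_norm_token(ingredient), frozenset())

    def members(self, tag: str) -> frozenset[str]:
        """All ingredients carrying a class tag."""
        return frozenset(i for i, t in self.classes.items() if tag in t)

    def brands_of(self, ingredient: str) -> tuple[str, ...]:
        ing = _norm_token(ingredient)
        return tuple(
            b for b, ings in self.synonyms.items() if ings == (ing,)
        )


def normalize_medication(raw_name: str, registry: DrugClassRegistry) -> MedicationEntry:
    """Normalize one free-text drug name to its generic ingredients.

    The whole token is matched first (covering multi-word names such as
    "isosorbide dinitrate" and brands such as "Toprol XL"); failing that, the
    name is split on separators so combination spellings such as
    "lisinopril-hydrochlorothiazide" expand to all constituents.  Unrecognized
    names yield an empty ingredient set.
    """
    token = _norm_token(raw_name)
    found: set[str] = set(registry.lookup(token))
    if not found and token:
        # hyphenated spelling of a multi-word name, e.g. "isosorbide-dinitrate"
        found.update(registry.lookup(token.replace("-", " ")))
    if not found:
        parts = [token]
        for ch in _SPLIT_CHARS:
            parts = [p for part in parts for p in part.split(ch)]
        for part in parts:
            found.update(registry.lookup(part))
    if not found:
        logger.debug("unrecognized medication name: %r", raw_name)
    return MedicationEntry(raw_name=raw_name, ingredients=frozenset(found))


def derive_atrial_fibrillation(
    self_report: Optional[bool], ecg_af: Optional[bool]
) -> Optional[bool]:
    """Atrial fibrillation: self-reported diagnosis OR AF on the baseline ECG.

    Missing self-report makes the result missing (such participants are removed
    at eligibility); a missing ECG component simply does not contribute.
    """
    if self_report is None:
        return None
    return bool(self_report) or bool(ecg_af)


def derive_hypertension(
    bp_med_self_report: bool,
    sbp: Optional[float],
    dbp: Optional[float],
    strict: bool = True,
) -> bool:
    """Hypertension: self-reported BP medication use or elevated measured BP.

    The default threshold is strict (> 140 mmHg systolic or > 90 mmHg
    diastolic); ``strict=False`` switches to the conventional >=140/>=90.
    Missing pressures do not contribute.
    """
    for name, v in (("sbp", sbp), ("dbp", dbp)):
        if v is not None and v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    sbp = -1.0 if sbp is None else sbp
    dbp = -1.0 if dbp is None else dbp
    if strict:
        high_bp = sbp > 140 or dbp > 90
    else:
        high_bp = sbp >= 140 or dbp >= 90
    return bool(bp_med_self_report) or high_bp


@dataclass(frozen=True)
class ExclusionFlags:
    """Outcome of the six medication rules for one participant."""

    r1_digoxin_no_af: bool = False
    r2_acearb_bb_no_htn: bool = False
    r3_carvedilol: bool = False
    r4_spironolactone: bool = False
    r5_loop_diuretic: bool = False
    r6_hydralazine_nitrate: bool = False

    @property
    def suspected_hf(self) -> bool:
        return (
            self.r1_digoxin_no_af
            or self.r2_acearb_bb_no_htn
            or self.r3_carvedilol
            or self.r4_spironolactone
            or self.r5_loop_diuretic
            or self.r6_hydralazine_nitrate
        )

    def as_dict(self) -> dict[str, bool]:
        return {
            "r1_digoxin_no_af": self.r1_digoxin_no_af,
            "r2_acearb_bb_no_htn": self.r2_acearb_bb_no_htn,
            "r3_carvedilol": self.r3_carvedilol,
            "r4_spironolactone": self.r4_spironolactone,
            "r5_loop_diuretic": self.r5_loop_diuretic,
            "r6_hydralazine_nitrate": self.r6_hydralazine_nitrate,
            "suspected_hf": self.suspected_hf,
        }


def inventory_class_flags(
    inventory: Iterable[MedicationEntry], registry: DrugClassRegistry
) -> dict[str, bool]:
    """Which therapeutic classes are represented anywhere in an inventory."""
    present: set[str] = set()
    for entry in inventory:
        for ing in entry.ingredients:
            present.update(registry.classes_of(ing))
    return {tag: tag in present for tag in CLASS_TAGS}


def classify_exclusion(
    inventory: Iterable[MedicationEntry],
    af: bool,
    htn: bool,
    registry: DrugClassRegistry,
) -> ExclusionFlags:
    """Evaluate the six suspected-HF rules on one participant's inventory.

    ``af`` and ``htn`` must be resolved (non-missing): participants with
    missing atrial-fibrillation data are removed at eligibility, and the
    hypertension derivation cannot be missing by construction.
    """
    if af is None:
        raise ValueError("af must be resolved before rule classification")
    if htn is None:
        raise ValueError("htn must be resolved before rule classification")
    has = inventory_class_flags(inventory, registry)
    return ExclusionFlags(
        r1_digoxin_no_af=has["digoxin"] and not af,
        r2_acearb_bb_no_htn=(
            (has["ace_inhibitor"] or has["arb"]) and has["beta_blocker"] and not htn
        ),
        r3_carvedilol=has["carvedilol"],
        r4_spironolactone=has["spironolactone"],
        r5_loop_diuretic=has["loop_diuretic"],
        r6_hydralazine_nitrate=has["hydralazine"] and has["nitrate"],
    )
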