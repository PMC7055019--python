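"""Diagnostic performance of the HF-free cohort against claims referents.

Orientation: "test positive" means *excluded* from the HF-free cohort
(suspected HF by the medication rules), so

    NPV         = tn / (tn + fn)   — proportion of the HF-free cohort without
                                     claims evidence of HF (headline metric)
    PPV         = tp / (tp + fp)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)

Confidence intervals are 95% normal-approximation (Wald) intervals
p ± 1.96·sqrt(p(1−p)/m) on the metric's own denominator m, truncated to
[0, 100]% — matching how the validation tables are reported.  Exact
Clopper–Pearson intervals are available behind ``interval="exact"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.96

DEFINITION_COLUMNS = {
    "a": "def_a_hosp",
    "b": "def_b_principal",
    "c": "def_c_any",
}

METRIC_NAMES = ("NPV", "PPV", "sensitivity", "specificity")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Excluded/included × referent-positive/negative counts.

    tp: excluded and referent-positive; fp: excluded, referent-negative;
    fn: included (HF-free) but referent-positive; tn: included and negative.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion-type metric in percent with its 95% CI and denominator.

    A zero denominator yields an explicitly undefined estimate (NaN point and
    bounds, ``defined`` False) — never a silent zero.
    """

    name: str
    point: float
    ci_low: float
    ci_high: float
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round(self.point, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def _proportion_estimate(
    name: str, numerator: int, denominator: int, interval: str = "wald"
) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(name, math.nan, math.nan, math.nan, 0)
    p = numerator / denominator
    if interval == "wald":
        half = Z95 * math.sqrt(p * (1 - p) / denominator)
        lo, hi = p - half, p + half
    elif interval == "exact":
        lo, hi = stats.beta.ppf(
            [0.025, 0.975],
            [numerator, numerator + 1],
            [denominator - numerator + 1, denominator - numerator],
        )
        lo = 0.0 if numerator == 0 else float(lo)
        hi = 1.0 if numerator == denominator else float(hi)
    else:
        raise ValueError(f"unknown interval type {interval!r}")
    lo, hi = max(lo, 0.0), min(hi, 1.0)
    return MetricEstimate(name, 100 * p, 100 * lo, 100 * hi, denominator)


def build_two_by_two(
    cohort_labels: pd.DataFrame,
    referent_labels: pd.DataFrame,
    definition: str = "a",
) -> TwoByTwoTable:
    """Cross-tabulate cascade exclusion against one referent definition.

    Both label frames must cover exactly the same participant ids.
    """
    col = DEFINITION_COLUMNS[definition]
    left = cohort_labels.set_index("participant_id")["suspected_hf"].astype(bool)
    right = referent_labels.set_index("participant_id")[col].astype(bool)
    if not left.index.sort_values().equals(right.index.sort_values()):
        raise ValueError("cohort and referent labels cover different participants")
    right = right.reindex(left.index)
    return TwoByTwoTable(
        tp=int((left & right).sum()),
        fp=int((left & ~right).sum()),
        fn=int((~left & right).sum()),
        tn=int((~left & ~right).sum()),
    )


def diagnostic_metrics(
    t: TwoByTwoTable, interval: str = "wald"
) -> dict[str, MetricEstimate]:
    """NPV, PPV, sensitivity and specificity for one 2×2 table."""
    return {
        "NPV": _proportion_estimate("NPV", t.tn, t.tn + t.fn, interval),
        "PPV": _proportion_estimate("PPV", t.tp, t.tp + t.fp, interval),
        "sensitivity": _proportion_estimate("sensitivity", t.tp, t.tp + t.fn, interval),
        "specificity": _proportion_estimate("specificity", t.tn, t.tn + t.fp, interval),
    }


# ---------------------------------------------------------------------------
# subgroups


def age_stratum(age: float, boundary: float = 75.0) -> str | None:
    """A-priori age strata for the Medicare validation subset: 65–74 vs ≥75.

    A participant aged exactly 75 belongs to the older stratum; under-65
    participants fall outside both strata (None).
    """
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return None
    if age >= boundary:
        return "75+"
    if age >= 65:
        return "65-74"
    return None


def stratified_metrics(
    cohort_labels: pd.DataFrame,
    referent_labels: pd.DataFrame,
    participants: pd.DataFrame,
    strata_spec: Mapping[str, str] | None = None,
    definitions: Iterable[str] = ("a", "b", "c"),
    interval: str = "wald",
) -> pd.DataFrame:
    """Per-stratum 2×2 tables and metrics, tidy long format.

    ``strata_spec`` maps a stratum-variable name to a participant column
    (default: age group, sex, race).  Empty strata are reported with
    undefined metrics rather than dropped.
    """
    p = participants.set_index("participant_id")
    if strata_spec is None:
        p = p.assign(age_group=p["age"].map(age_stratum))
        strata_spec = {"age_group": "age_group", "sex": "sex", "race": "race"}

    rows = []
    ids = cohort_labels["participant_id"]
    for var, col in strata_spec.items():
        values = p.loc[ids, col]
        for level in sorted(values.dropna().unique()):
            members = ids[(values == level).values]
            cl = cohort_labels[cohort_labels["participant_id"].isin(members)]
            rl = referent_labels[referent_labels["participant_id"].isin(members)]
            for d in definitions:
                if len(cl):
                    t = build_two_by_two(cl, rl, d)
                else:
                    t = TwoByTwoTable(0, 0, 0, 0)
                m = diagnostic_metrics(t, interval)
                for name, est in m.items():
                    rows.append(
                        {
                            "stratum_var": var,
                            "stratum": level,
                            "definition": d,
                            "metric": name,
                            "point": est.point,
                            "ci_low": est.ci_low,
                            "ci_high": est.ci_high,
                            "denominator": est.denominator,
                            "n_stratum": t.total,
                            **t.as_dict(),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity-analysis variants

VARIANTS = ("symptoms", "adjudicated_1yr")

DAYS_PER_YEAR = 365.25


def sensitivity_variant(
    cohort_labels: pd.DataFrame,
    participants: pd.DataFrame,
    adjudicated: pd.DataFrame | None = None,
    variant: str = "symptoms",
) -> pd.DataFrame:
    """Enlarge the excluded set per one of the two sensitivity analyses.

    ``symptoms``: additionally exclude HF-free participants with self-reported
    orthopnea and/or paroxysmal nocturnal dyspnea.  ``adjudicated_1yr``:
    additionally exclude HF-free participants with an adjudicated HF
    hospitalization within one year after the in-home visit.  The original
    rule flags are preserved; the move is recorded in ``variant_excluded``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    labels = cohort_labels.copy()
    p = participants.set_index("participant_id")
    ids = labels["participant_id"]

    if variant == "symptoms":
        orth = p.loc[ids, "orthopnea"].fillna(False).astype(bool).values
        pnd = p.loc[ids, "pnd"].fillna(False).astype(bool).values
        extra = orth | pnd
    else:
        if adjudicated is None:
            raise ValueError("adjudicated table required for adjudicated_1yr variant")
        adj = adjudicated
        if "hf" in adj.columns:
            adj = adj[adj["hf"].astype(bool)]
        merged = adj.merge(
            p[["inhome_visit_date"]], left_on="participant_id", right_index=True
        )
        within = merged[
            (merged["admission_date"] >= merged["inhome_visit_date"])
            & (
                merged["admission_date"]
                < merged["inhome_visit_date"] + DAYS_PER_YEAR
            )
        ]["participant_id"].unique()
        extra = ids.isin(within).values

    labels["variant_excluded"] = extra & ~labels["suspected_hf"].astype(bool).values
    labels["suspected_hf"] = labels["suspected_hf"].astype(bool) | extra
    labels["status"] = np.where(labels["suspected_hf"], "suspected_hf", "hf_free")
    return labels
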