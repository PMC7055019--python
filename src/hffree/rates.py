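"""First-event HF-hospitalization rates per 1000 person-years.

Person-time runs from the in-home visit to the earlier of the first
adjudicated HF hospitalization and the censor date.  The 95% CI uses the
normal approximation rate ± 1.96·rate/sqrt(events); a Poisson-exact
(chi-square) interval is available behind ``method="poisson-exact"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
Z95 = 1.96


@dataclass(frozen=True)
class PersonTime:
    participant_id: object
    start: float
    end: float
    event: bool

    @property
    def person_years(self) -> float:
        return (self.end - self.start) / DAYS_PER_YEAR


@dataclass(frozen=True)
class RateEstimate:
    """Events per 1000 person-years with a 95% CI.

    ``ci_defined`` is False when events == 0 (the normal approximation
    degenerates); the bounds are then reported as (0, 0).
    """

    events: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float
    ci_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "events": self.events,
            "person_years": self.person_years,
            "rate_per_1000py": self.rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_defined": self.ci_defined,
        }


def compute_person_time(
    participants: pd.DataFrame,
    adjudicated: pd.DataFrame | None,
    followup: pd.DataFrame,
) -> pd.DataFrame:
    """Per-participant follow-up intervals with first-event termination.

    Events dated before the in-home visit are ignored here with a warning
    (such participants are removed at eligibility).  Returns columns
    participant_id, start, end, event, person_years.
    """
    p = participants.set_index("participant_id")
    fu = followup.set_index("participant_id")["censor_date"]
    out = pd.DataFrame(
        {
            "start": p["inhome_visit_date"],
            "end": fu.reindex(p.index),
        }
    ).dropna(subset=["end"])

    out["event"] = False
    if adjudicated is not None and len(adjudicated):
        adj = adjudicated
        if "hf" in adj.columns:
            adj = adj[adj["hf"].astype(bool)]
        adj = adj.merge(
            out[["start"]], left_on="participant_id", right_index=True, how="inner"
        ).reset_index(drop=True)
        early = adj["admission_date"] < adj["start"]
        if early.any():
            logger.warning(
                "%d adjudicated HF event(s) precede the in-home visit; ignored "
                "(handled at eligibility)",
                int(early.sum()),
            )
        adj = adj[~early]
        first = adj.groupby("participant_id")["admission_date"].min()
        first = first.reindex(out.index)
        hit = first.notna() & (first <= out["end"])
        out.loc[hit, "end"] = first[hit]
        out.loc[hit, "event"] = True

    out["person_years"] = (out["end"] - out["start"]) / DAYS_PER_YEAR
    if (out["person_years"] < 0).any():
        raise ValueError("negative person-time: censor date precedes in-home visit")
    return out.rename_axis("participant_id").reset_index()


def rate_estimate(
    events: int, person_years: float, method: str = "normal"
) -> RateEstimate:
    """Rate per 1000 person-years with 95% CI.

    ``normal``: rate ± 1.96·rate/sqrt(events), truncated at 0.
    ``poisson-exact``: chi-square bounds on the event count.
    """
    if person_years <= 0:
        raise ValueError(f"person_years must be positive, got {person_years}")
    if events < 0:
        raise ValueError("events must be non-negative")
    rate = 1000.0 * events / person_years
    if events == 0:
        return RateEstimate(0, person_years, 0.0, 0.0, 0.0, ci_defined=False)
    if method == "normal":
        half = Z95 * rate / math.sqrt(events)
        lo, hi = max(rate - half, 0.0), rate + half
    elif method == "poisson-exact":
        lo = 1000.0 * stats.chi2.ppf(0.025, 2 * events) / 2 / person_years
        hi = 1000.0 * stats.chi2.ppf(0.975, 2 * events + 2) / 2 / person_years
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return RateEstimate(events, person_years, rate, lo, hi)


def group_rates(
    person_time: pd.DataFrame,
    cohort_labels: pd.DataFrame,
    method: str = "normal",
) -> dict[str, RateEstimate]:
    """Rates for the full sample and the hf_free / suspected_hf partitions."""
    pt = person_time.merge(
        cohort_labels[["participant_id", "status"]], on="participant_id", how="inner"
    )
    out: dict[str, RateEstimate] = {}
    groups = {
        "full_sample": pt,
        "hf_free": pt[pt["status"] == "hf_free"],
        "suspected_hf": pt[pt["status"] == "suspected_hf"],
    }
    for name, g in groups.items():
        py = float(g["person_years"].sum())
        ev = int(g["event"].sum())
        out[name] = (
            rate_estimate(ev, py, method)
            if py > 0
            else RateEstimate(ev, 0.0, math.nan, math.nan, math.nan, ci_defined=False)
        )
    return out
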