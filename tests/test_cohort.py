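"""Eligibility cascade, HF-free assembly, and validation-subset selection."""

import numpy as np
import pandas as pd
import pytest

from hffree import GeneratorConfig, generate_cohort
from hffree.cohort import (
    apply_eligibility,
    assemble_hf_free,
    select_validation_cohort,
)
from hffree.medications import DrugClassRegistry
from hffree.synthetic import CondProb

from conftest import make_participants


def plant_cascade(n, counts, seed=0):
    """Participants with disjoint planted removal reasons, in cascade order."""
    p = make_participants(n, seed=seed)
    adj_rows = []
    i = 0
    for step, k in counts.items():
        sl = slice(i, i + k)
        if step == "anomalous":
            p.loc[p.index[sl], "anomalous_flag"] = True
        elif step == "no_followup":
            p.loc[p.index[sl], "has_followup"] = False
        elif step == "missing_af":
            p.loc[p.index[sl], "af"] = pd.NA
        elif step == "missing_meds":
            p.loc[p.index[sl], "meds_missing_flag"] = True
        elif step == "hf_between":
            for pid in p.loc[p.index[sl], "participant_id"]:
                adj_rows.append(
                    {"participant_id": pid, "admission_date": 10, "hf": True}
                )
        i += k
    adj = pd.DataFrame(adj_rows, columns=["participant_id", "admission_date", "hf"])
    return p, adj


def test_planted_step_counts_are_recovered():
    counts = {"anomalous": 5, "no_followup": 4, "missing_af": 3, "missing_meds": 2, "hf_between": 1}
    p, adj = plant_cascade(200, counts)
    ids, tally = apply_eligibility(p, adj)
    assert tally.as_dict() == {
        "n_start": 200,
        "anomalous": 5,
        "no_followup": 4,
        "missing_af": 3,
        "missing_meds": 2,
        "hf_between_interview_and_visit": 1,
        "insufficient_coverage": 0,
        "n_eligible": 185,
    }
    assert len(ids) == 185


def test_no_flags_means_no_attrition():
    p = make_participants(50)
    ids, tally = apply_eligibility(p, None, None)
    assert tally.n_eligible == 50
    assert sum(v for k, v in tally.as_dict().items() if k not in ("n_start", "n_eligible")) == 0


def test_duplicate_ids_rejected():
    p = make_participants(10)
    p.loc[5, "participant_id"] = p.loc[4, "participant_id"]
    with pytest.raises(ValueError, match="duplicate"):
        apply_eligibility(p, None, None)


def test_same_day_visit_event_belongs_to_followup():
    """The interview-to-visit window is half-open: [interview, visit)."""
    p = make_participants(3)
    adj = pd.DataFrame(
        {
            "participant_id": [1, 2, 3],
            "admission_date": [0, 29, 30],  # interview day, inside, visit day
            "hf": True,
        }
    )
    _, tally = apply_eligibility(p, adj)
    assert tally.hf_between_interview_and_visit == 2


def test_tally_conservation_on_random_inputs():
    rng = np.random.default_rng(3)
    for seed in range(5):
        p = make_participants(300, seed=seed)
        p["anomalous_flag"] = rng.random(300) < 0.1
        p["has_followup"] = rng.random(300) > 0.1
        p.loc[rng.random(300) < 0.1, "af"] = pd.NA
        p["meds_missing_flag"] = rng.random(300) < 0.1
        _, tally = apply_eligibility(p, None)
        d = tally.as_dict()
        removed = sum(v for k, v in d.items() if k not in ("n_start", "n_eligible"))
        assert d["n_start"] - removed == d["n_eligible"]


def test_final_set_is_order_independent():
    """The filters are independent predicates: only attribution depends on order."""
    rng = np.random.default_rng(4)
    n = 400
    p = make_participants(n, seed=9)
    p["anomalous_flag"] = rng.random(n) < 0.15
    p["has_followup"] = rng.random(n) > 0.15
    p.loc[rng.random(n) < 0.15, "af"] = pd.NA
    p["meds_missing_flag"] = rng.random(n) < 0.15
    ids, _ = apply_eligibility(p, None)
    keep = (
        ~p["anomalous_flag"]
        & p["has_followup"]
        & p["af"].notna()
        & ~p["meds_missing_flag"]
    )
    assert set(ids) == set(p.loc[keep, "participant_id"])


# ---------------------------------------------------------------------------
# assembly


def test_nobody_on_registry_drugs_means_all_hf_free(registry):
    p = make_participants(30)
    meds = pd.DataFrame(
        {"participant_id": [1, 2, 3], "raw_name": ["aspirin", "metformin", "vitamin q"]}
    )
    labels = assemble_hf_free(p, meds, registry)
    assert (labels["status"] == "hf_free").all()
    assert len(labels) == 30


def test_planted_rule_triggers_recovered_exactly(registry):
    p = make_participants(10, af=pd.array([False] * 10, dtype="boolean"), htn=False)
    meds = pd.DataFrame(
        {
            "participant_id": [2, 3, 3, 5, 7, 7],
            "raw_name": ["digoxin", "lisinopril", "Toprol XL", "Lasix", "hydralazine", "Imdur"],
        }
    )
    labels = assemble_hf_free(p, meds, registry).set_index("participant_id")
    assert set(labels.index[labels["suspected_hf"]]) == {2, 3, 5, 7}
    assert labels.loc[2, "r1_digoxin_no_af"]
    assert labels.loc[3, "r2_acearb_bb_no_htn"]
    assert labels.loc[5, "r5_loop_diuretic"]
    assert labels.loc[7, "r6_hydralazine_nitrate"]


def test_labels_partition_the_eligible_set(default_cohort, registry):
    ids, _ = apply_eligibility(
        default_cohort.participants, default_cohort.adjudicated, default_cohort.followup
    )
    from hffree.cohort import resolve_covariates

    eligible = resolve_covariates(default_cohort.participants)
    eligible = eligible[eligible["participant_id"].isin(ids)]
    labels = assemble_hf_free(eligible, default_cohort.medications, registry)
    assert len(labels) == len(ids)
    assert set(labels["status"]) <= {"hf_free", "suspected_hf"}
    assert (
        (labels["status"] == "suspected_hf") == labels["suspected_hf"].astype(bool)
    ).all()


def test_unresolved_af_at_assembly_is_a_logic_error(registry):
    p = make_participants(5)
    p.loc[2, "af"] = pd.NA
    with pytest.raises(ValueError, match="unresolved af"):
        assemble_hf_free(p, pd.DataFrame(columns=["participant_id", "raw_name"]), registry)


# ---------------------------------------------------------------------------
# validation subset


def test_validation_counts_with_planted_exclusions():
    counts = {"missing_af": 12, "missing_meds": 3, "hf_between": 2}
    p, adj = plant_cascade(500, counts, seed=2)
    ids, tally = select_validation_cohort(p, adj, min_coverage=6)
    assert tally.insufficient_coverage == 0
    assert tally.missing_af == 12
    assert tally.missing_meds == 3
    assert tally.hf_between_interview_and_visit == 2
    assert tally.n_eligible == 483 == len(ids)


def test_zero_min_coverage_keeps_everyone():
    p = make_participants(100, coverage_months_pre_visit=0.0)
    ids, tally = select_validation_cohort(p, None, min_coverage=0)
    assert tally.insufficient_coverage == 0 and len(ids) == 100


def test_negative_coverage_rejected():
    p = make_participants(5, coverage_months_pre_visit=-1.0)
    with pytest.raises(ValueError, match="coverage"):
        select_validation_cohort(p, None)


def test_coverage_filter_matches_configured_distribution():
    """Coverage ~ U(0, 12) months: about half the cohort reaches 6 months."""
    from hffree.synthetic import Distribution

    cfg = GeneratorConfig(
        n_participants=6000,
        seed=21,
        coverage_months_distribution=Distribution(kind="uniform", low=0, high=12),
        p_missing_af=0.0,
        p_missing_meds=0.0,
        p_hf_between_interview_and_visit=0.0,
    )
    cohort = generate_cohort(cfg)
    ids, tally = select_validation_cohort(cohort.participants, cohort.adjudicated)
    frac = tally.n_eligible / tally.n_start
    tol = 4 * np.sqrt(0.5 * 0.5 / 6000)
    assert abs(frac - 0.5) < tol
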