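"""The synthetic cohort generator: determinism, marginals, forced constructions."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from hffree import GeneratorConfig, generate_cohort, truth_referent_alignment
from hffree.cohort import apply_eligibility, assemble_hf_free, resolve_covariates
from hffree.synthetic import ClaimsParams, CondProb, Distribution, SettingClaims


def all_rules_off(**hf_overrides):
    """med_use with every no-HF probability zero, optionally forcing HF classes."""
    from hffree.synthetic import _default_med_use

    med = {k: CondProb(hf=0.0, no_hf=0.0) for k in _default_med_use()}
    for k, p in hf_overrides.items():
        med[k] = CondProb(hf=p, no_hf=0.0)
    return med


def test_empty_cohort_has_empty_tables():
    c = generate_cohort(GeneratorConfig(n_participants=0))
    for name in c.TABLES:
        assert len(getattr(c, name)) == 0
    assert len(truth_referent_alignment(c)) == 0


def test_seed_determinism(tmp_path):
    cfg = GeneratorConfig(n_participants=800, seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    for name in a.TABLES:
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    for name in a.TABLES:
        assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (
            tmp_path / "b" / f"{name}.csv"
        ).read_bytes()


def test_different_seeds_differ():
    a = generate_cohort(GeneratorConfig(n_participants=500, seed=1))
    b = generate_cohort(GeneratorConfig(n_participants=500, seed=2))
    assert not a.participants.equals(b.participants)


def test_csv_round_trip_preserves_dotted_codes(tmp_path):
    from hffree.synthetic import SyntheticCohort

    c = generate_cohort(GeneratorConfig(n_participants=300, seed=3))
    c.write(tmp_path)
    back = SyntheticCohort.read(tmp_path)
    codes = {x for dx in back.claims["dx_codes"] for x in str(dx).split("|")}
    assert any(code.startswith("428.") for code in codes)
    assert all(isinstance(code, str) for code in codes)


def test_invalid_probability_names_offending_field():
    with pytest.raises(ValidationError, match="hf_prevalence"):
        GeneratorConfig(hf_prevalence=1.5)
    with pytest.raises(ValidationError, match="med_use"):
        GeneratorConfig(med_use={"nonsense_class": CondProb(hf=0.1, no_hf=0.1)})
    with pytest.raises(ValidationError):
        SettingClaims(
            mean_hf=1, mean_no_hf=1,
            p_principal_hf=0.7, p_secondary_hf=0.5,
            p_principal_no_hf=0.0, p_secondary_no_hf=0.0,
        )


def test_foreign_keys_resolve_and_dates_ordered():
    c = generate_cohort(GeneratorConfig(n_participants=1500, seed=4))
    ids = set(c.participants["participant_id"])
    for name in ("medications", "claims", "adjudicated", "followup", "truth"):
        assert set(getattr(c, name)["participant_id"]) <= ids
    p = c.participants.set_index("participant_id")
    assert (p["interview_date"] <= p["inhome_visit_date"]).all()
    assert (p["age"] >= 45).all()
    visit = p.loc[c.claims["participant_id"], "inhome_visit_date"].values
    assert (c.claims["service_date"].values < visit).all()
    fu = c.followup.set_index("participant_id")["censor_date"]
    post = c.adjudicated[
        c.adjudicated["admission_date"].values
        >= p.loc[c.adjudicated["participant_id"], "inhome_visit_date"].values
    ]
    inside = post["participant_id"].isin(fu.index)
    assert (
        post.loc[inside, "admission_date"].values
        <= fu[post.loc[inside, "participant_id"]].values
    ).all()


def test_marginal_recovery_within_binomial_tolerance():
    cfg = GeneratorConfig(n_participants=20_000, seed=5)
    c = generate_cohort(cfg)
    truth = c.truth.set_index("participant_id")["latent_hf"]
    p = c.participants.set_index("participant_id")

    def check(observed, expected, n):
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < tol, (observed, expected, tol)

    check(truth.mean(), cfg.hf_prevalence, len(truth))
    hf = truth[truth].index
    no = truth[~truth].index
    af = resolve_covariates(c.participants).set_index("participant_id")["af"]
    check(af[hf].dropna().astype(bool).mean(), cfg.p_af.hf, len(hf))
    check(af[no].dropna().astype(bool).mean(), cfg.p_af.no_hf, len(no))
    check(p.loc[hf, "orthopnea"].mean(), cfg.p_orthopnea.hf, len(hf))
    check(p.loc[no, "pnd"].mean(), cfg.p_pnd.no_hf, len(no))
    # a medication-class marginal, via the inventory itself
    loop_names = {"furosemide", "bumetanide", "torsemide", "lasix", "bumex", "demadex"}
    takers = set(
        c.medications.loc[
            c.medications["raw_name"].str.lower().isin(loop_names), "participant_id"
        ]
    )
    flagged = set(p.index[p["meds_missing_flag"]])
    obs = len(takers & set(hf)) / max(len(set(hf) - flagged), 1)
    check(obs, cfg.med_use["loop_diuretic"].hf, len(hf))


def test_forced_construction_gives_perfect_cascade_sensitivity(registry):
    """Every latent-HF participant on a loop diuretic, nobody else on anything."""
    cfg = GeneratorConfig(
        n_participants=3000,
        seed=6,
        med_use=all_rules_off(loop_diuretic=1.0),
        p_missing_meds=0.0,
    )
    c = generate_cohort(cfg)
    ids, _ = apply_eligibility(c.participants, c.adjudicated, c.followup)
    eligible = resolve_covariates(c.participants)
    eligible = eligible[eligible["participant_id"].isin(ids)]
    labels = assemble_hf_free(eligible, c.medications, registry).set_index(
        "participant_id"
    )
    truth = c.truth.set_index("participant_id")["latent_hf"].loc[labels.index]
    assert (labels.loc[truth, "suspected_hf"]).all()  # sensitivity 100%
    assert (~labels.loc[~truth, "suspected_hf"]).all()  # specificity 100%


def test_forced_claims_make_referent_equal_latent_truth():
    cp = ClaimsParams(
        inpatient=SettingClaims(
            mean_hf=0.5, mean_no_hf=0.3,
            p_principal_hf=1.0, p_principal_no_hf=0.0,
            p_secondary_hf=0.0, p_secondary_no_hf=0.0,
        ),
        outpatient=SettingClaims(
            mean_hf=1.0, mean_no_hf=1.0,
            p_principal_hf=0.0, p_principal_no_hf=0.0,
            p_secondary_hf=0.0, p_secondary_no_hf=0.0,
        ),
        force_inpatient_principal_if_hf=True,
    )
    c = generate_cohort(GeneratorConfig(n_participants=2000, seed=7, claims_params=cp))
    align = truth_referent_alignment(c)
    assert (align["def_c_any"] == align["latent_hf"]).all()
    assert (align["def_a_hosp"] == align["latent_hf"]).all()


def test_calibrated_referent_prevalence_tracks_latent_prevalence():
    """Default claims conditionals put the any-diagnosis prevalence near 11.3%."""
    cfg = GeneratorConfig(n_participants=10_000, seed=8)
    align = truth_referent_alignment(generate_cohort(cfg))
    frac = align["def_c_any"].mean()
    tol = 4 * np.sqrt(0.113 * 0.887 / 10_000)
    assert abs(frac - 0.113) < tol + 0.01  # calibration slack on top of binomial noise


def test_hospitalization_rates_recover_configured_values():
    cfg = GeneratorConfig(n_participants=30_000, seed=9)
    c = generate_cohort(cfg)
    truth = c.truth.set_index("participant_id")["latent_hf"]
    from hffree.rates import compute_person_time

    pt = compute_person_time(c.participants, c.adjudicated, c.followup).set_index(
        "participant_id"
    )
    for status, conf in ((True, cfg.hosp_rate_hf), (False, cfg.hosp_rate_no_hf)):
        sub = pt.loc[pt.index.intersection(truth[truth == status].index)]
        rate = 1000 * sub["event"].sum() / sub["person_years"].sum()
        tol = 4 * conf / np.sqrt(max(sub["event"].sum(), 1))
        assert abs(rate - conf) < tol, (status, rate, conf, tol)


def test_distribution_validation():
    with pytest.raises(ValidationError):
        Distribution(kind="uniform", low=5, high=1)
    d = Distribution(kind="constant", value=7.5)
    rng = np.random.default_rng(0)
    assert (d.sample(rng, 4) == 7.5).all()
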