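"""End-to-end orchestration: simulate -> assemble -> phenotype -> validate -> rates.

``run_full_pipeline`` wires the stage modules together and produces a
:class:`RunReport` holding the eligibility tallies, cohort sizes, a baseline
characteristics summary, hospitalization rates by cascade status, the
validation 2x2 tables and metrics per referent definition, the two
sensitivity-analysis variants, and a-priori subgroup results, plus a
provenance block sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .claims import DEFAULT_CODESET, label_cohort
from .cohort import (
    apply_eligibility,
    assemble_hf_free,
    resolve_covariates,
    select_validation_cohort,
)
from .medications import DrugClassRegistry
from .metrics import (
    build_two_by_two,
    diagnostic_metrics,
    sensitivity_variant,
    stratified_metrics,
)
from .rates import compute_person_time, group_rates
from .synthetic import GeneratorConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Exactly one of ``generator`` (simulation mode) or ``input_dir`` (five CSV
    tables on disk) must be supplied.
    """

    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None
    registry_path: Optional[str] = None
    definitions: tuple[str, ...] = ("a", "b", "c")
    variants: tuple[str, ...] = ("symptoms", "adjudicated_1yr")
    run_strata: bool = True
    min_coverage_months: float = 6.0
    seed: Optional[int] = None
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("supply exactly one of generator config or input_dir")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)


@dataclass
class RunReport:
    eligibility: dict
    validation_eligibility: dict
    cohort_sizes: dict
    baseline: dict
    rates: dict
    metrics: dict
    variant_metrics: dict
    strata: list
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "eligibility": self.eligibility,
            "validation_eligibility": self.validation_eligibility,
            "cohort_sizes": self.cohort_sizes,
            "baseline": self.baseline,
            "rates": self.rates,
            "metrics": self.metrics,
            "variant_metrics": self.variant_metrics,
            "strata": self.strata,
            "provenance": self.provenance,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonable, **kw)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# baseline summary

BASELINE_SPEC = {
    "age": "continuous",
    "af": "binary",
    "htn": "binary",
    "orthopnea": "binary",
    "pnd": "binary",
}


def summarize_baseline(
    participants: pd.DataFrame,
    cohort_labels: pd.DataFrame,
    spec: dict[str, str] = BASELINE_SPEC,
) -> dict:
    """Mean (SD) / n (%) summaries split by hf_free vs suspected_hf.

    Percentages are computed after dropping missing values per field; an SD
    over fewer than two observations and a percentage over an empty
    denominator are reported as None (explicit undefined markers).
    """
    p = resolve_covariates(participants).set_index("participant_id")
    lab = cohort_labels.set_index("participant_id")["status"]
    groups = {
        "all": p.loc[lab.index],
        "hf_free": p.loc[lab[lab == "hf_free"].index],
        "suspected_hf": p.loc[lab[lab == "suspected_hf"].index],
    }
    out: dict = {}
    for gname, g in groups.items():
        rows: dict = {"n": int(len(g))}
        for col, kind in spec.items():
            if col not in g.columns:
                continue
            vals = g[col].dropna()
            if kind == "continuous":
                rows[col] = {
                    "mean": float(vals.mean()) if len(vals) else None,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
                    "n_obs": int(len(vals)),
                }
            else:
                denom = int(len(vals))
                count = int(vals.astype(bool).sum())
                rows[col] = {
                    "n": count,
                    "pct": 100.0 * count / denom if denom else None,
                    "denominator": denom,
                }
        out[gname] = rows
    return out


# ---------------------------------------------------------------------------


def _metrics_block(table, interval="wald") -> dict:
    m = diagnostic_metrics(table, interval)
    return {
        "counts": table.as_dict(),
        **{
            name: {
                "point": est.point if est.defined else None,
                "ci_low": est.ci_low if est.defined else None,
                "ci_high": est.ci_high if est.defined else None,
                "denominator": est.denominator,
                "point_1dp": round(est.point, 1) if est.defined else None,
            }
            for name, est in m.items()
        },
    }


def run_full_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage on generated or loaded tables; deterministic per seed."""
    t0 = time.time()
    registry = (
        DrugClassRegistry.from_csv(config.registry_path)
        if config.registry_path
        else DrugClassRegistry.default()
    )

    if config.generator is not None:
        gen = config.generator
        if config.seed is not None:
            gen = gen.model_copy(update={"seed": config.seed})
        cohort = generate_cohort(gen, registry=registry)
        source = {"mode": "simulation", "seed": gen.seed}
    else:
        cohort = SyntheticCohort.read(config.input_dir)
        source = {"mode": "files", "input_dir": str(config.input_dir)}
    logger.info("stage load: %d participants", len(cohort.participants))

    # eligibility cascade and medication-rule labelling
    if len(cohort.participants):
        eligible_ids, tally = apply_eligibility(
            cohort.participants, cohort.adjudicated, cohort.followup
        )
        eligible = resolve_covariates(cohort.participants)
        eligible = eligible[eligible["participant_id"].isin(eligible_ids)]
        labels = assemble_hf_free(eligible, cohort.medications, registry)
    else:
        from .cohort import EligibilityTally

        tally = EligibilityTally(n_start=0, n_eligible=0)
        eligible = cohort.participants
        labels = pd.DataFrame(
            columns=["participant_id", "suspected_hf", "status"]
        )
    logger.info(
        "stage assemble: %d eligible, %d hf_free",
        len(eligible),
        int((labels["status"] == "hf_free").sum()) if len(labels) else 0,
    )

    # hospitalization rates over follow-up, by cascade status
    if len(eligible):
        pt = compute_person_time(eligible, cohort.adjudicated, cohort.followup)
        rates = {k: v.as_dict() for k, v in group_rates(pt, labels).items()}
    else:
        rates = {}

    # Medicare-style validation subset
    if len(eligible):
        val_ids, val_tally = select_validation_cohort(
            eligible, cohort.adjudicated, config.min_coverage_months
        )
        validation = eligible[eligible["participant_id"].isin(val_ids)]
        val_labels = labels[labels["participant_id"].isin(val_ids)]
        referents = label_cohort(cohort.claims, validation, DEFAULT_CODESET)
    else:
        from .cohort import EligibilityTally

        val_tally = EligibilityTally(n_start=0, n_eligible=0)
        validation = eligible
        val_labels = labels
        referents = pd.DataFrame(
            columns=["participant_id", "def_a_hosp", "def_b_principal", "def_c_any"]
        )

    metrics_out: dict = {}
    for d in config.definitions:
        if len(val_labels):
            metrics_out[d] = _metrics_block(build_two_by_two(val_labels, referents, d))
        else:
            metrics_out[d] = {"counts": {"tp": 0, "fp": 0, "fn": 0, "tn": 0}}

    variant_out: dict = {}
    for variant in config.variants:
        if not len(val_labels):
            variant_out[variant] = {}
            continue
        vlab = sensitivity_variant(val_labels, validation, cohort.adjudicated, variant)
        variant_out[variant] = {
            d: _metrics_block(build_two_by_two(vlab, referents, d))
            for d in config.definitions
        }

    strata_records: list = []
    if config.run_strata and len(val_labels):
        strata = stratified_metrics(val_labels, referents, validation)
        strata_records = strata.to_dict(orient="records")

    baseline = (
        summarize_baseline(eligible, labels) if len(labels) else {"all": {"n": 0}}
    )

    cohort_sizes = {
        "n_input": int(len(cohort.participants)),
        "n_eligible": tally.n_eligible,
        "n_hf_free": int((labels["status"] == "hf_free").sum()) if len(labels) else 0,
        "n_suspected_hf": int((labels["status"] == "suspected_hf").sum())
        if len(labels)
        else 0,
        "n_validation": val_tally.n_eligible,
        "n_validation_hf_free": int((val_labels["status"] == "hf_free").sum())
        if len(val_labels)
        else 0,
    }

    cfg_json = config.model_dump_json()
    provenance = {
        "package_version": __version__,
        "seed": source.get("seed"),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "source": source,
        "runtime_s": round(time.time() - t0, 3),
    }

    report = RunReport(
        eligibility=tally.as_dict(),
        validation_eligibility=val_tally.as_dict(),
        cohort_sizes=cohort_sizes,
        baseline=baseline,
        rates=rates,
        metrics=metrics_out,
        variant_metrics=variant_out,
        strata=strata_records,
        provenance=provenance,
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(render_markdown(report))
        labels.to_csv(out / "cohort_labels.csv", index=False)
        referents.to_csv(out / "referent_labels.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# human-readable report


def _md_table(headers: list[str], rows: list[list]) -> str:
    def fmt(x):
        if isinstance(x, float):
            return f"{x:.1f}" if math.isfinite(x) else "–"
        return "–" if x is None else str(x)

    lines = [
        "| " + " | ".join(headers) + " |",
        "| " + " | ".join("---" for _ in headers) + " |",
    ]
    for r in rows:
        lines.append("| " + " | ".join(fmt(x) for x in r) + " |")
    return "\n".join(lines)


DEFINITION_TITLES = {
    "a": "Hospitalization for HF",
    "b": "Principal diagnosis of HF",
    "c": "Any diagnosis of HF",
}


def render_markdown(report: RunReport) -> str:
    """A compact report mirroring the cascade figure and validation tables."""
    parts = ["# HF-free cohort assembly report", ""]

    parts.append("## Eligibility cascade")
    el = report.eligibility
    rows = [[k, v] for k, v in el.items()]
    parts.append(_md_table(["step", "count"], rows))
    parts.append("")

    parts.append("## Cohort sizes")
    parts.append(_md_table(["quantity", "n"], [[k, v] for k, v in report.cohort_sizes.items()]))
    parts.append("")

    if report.rates:
        parts.append("## HF hospitalization rates (per 1000 person-years)")
        rows = [
            [
                g,
                r["events"],
                round(r["person_years"], 1),
                round(r["rate_per_1000py"], 2) if r["person_years"] else None,
                round(r["ci_low"], 2) if r["ci_defined"] else None,
                round(r["ci_high"], 2) if r["ci_defined"] else None,
            ]
            for g, r in report.rates.items()
        ]
        parts.append(
            _md_table(["group", "events", "person-years", "rate", "ci low", "ci high"], rows)
        )
        parts.append("")

    parts.append("## Diagnostic performance vs claims referents")
    rows = []
    for d, block in report.metrics.items():
        c = block.get("counts", {})
        row = [DEFINITION_TITLES.get(d, d), c.get("tp"), c.get("fp"), c.get("fn"), c.get("tn")]
        for m in ("NPV", "PPV", "sensitivity", "specificity"):
            est = block.get(m)
            row.append(est["point_1dp"] if est and est.get("point_1dp") is not None else None)
        rows.append(row)
    parts.append(
        _md_table(
            ["referent", "tp", "fp", "fn", "tn", "NPV %", "PPV %", "Sens %", "Spec %"], rows
        )
    )
    parts.append("")
    return "\n".join(parts)
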