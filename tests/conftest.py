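import numpy as np
import pandas as pd
import pytest

from hffree import DrugClassRegistry, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return DrugClassRegistry.default()


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(n_participants=4000, seed=11))


def make_participants(n, seed=0, **overrides):
    """Minimal hand-rolled participant frame for unit tests."""
    rng = np.random.default_rng(seed)
    base = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "age": rng.uniform(45, 95, n).round(1),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "race": np.where(rng.random(n) < 0.4, "black", "white"),
            "interview_date": np.zeros(n, dtype=int),
            "inhome_visit_date": np.full(n, 30),
            "af": pd.array(rng.random(n) < 0.1, dtype="boolean"),
            "htn": rng.random(n) < 0.5,
            "orthopnea": rng.random(n) < 0.1,
            "pnd": rng.random(n) < 0.05,
            "anomalous_flag": False,
            "meds_missing_flag": False,
            "has_followup": True,
            "coverage_months_pre_visit": 12.0,
        }
    )
    for k, v in overrides.items():
        base[k] = v
    return base
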