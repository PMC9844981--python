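import numpy as np
import pandas as pd
import pytest

from bayesbias import (
    CohortSpec,
    ElicitedInterval,
    build_analysis_records,
    build_expert_prior_set,
    simulate_cohort,
)

EXPERT1_INTERVALS = {"P1": (0.025, 0.095), "P0": (0.01, 0.06), "RR_UY": (1.1, 2.2)}
EXPERT2_INTERVALS = {"P1": (0.20, 0.40), "P0": (0.10, 0.20), "RR_UY": (1.1, 5.0)}


def intervals_for(expert_id, table):
    return [ElicitedInterval(name, lo, hi, expert_id)
            for name, (lo, hi) in table.items()]


@pytest.fixture(scope="session")
def expert1_priors():
    return build_expert_prior_set(intervals_for("expert 1", EXPERT1_INTERVALS))


@pytest.fixture(scope="session")
def expert2_priors():
    return build_expert_prior_set(intervals_for("expert 2", EXPERT2_INTERVALS))


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort, shared read-only across tests."""
    return simulate_cohort(CohortSpec(seed=20260901))


@pytest.fixture(scope="session")
def default_records(default_cohort):
    return build_analysis_records(default_cohort.visits)


def make_visits(rows):
    """Visit table from (subject, visit, exposure, nbt, hiv) tuples."""
    df = pd.DataFrame(rows, columns=["subject_id", "visit_index",
                                     "unsafe_injection", "nbt", "hiv_positive"])
    n = len(df)
    df["gender"] = "male"
    df["age"] = 24.0
    df["education"] = 0
    df["incarcerated_baseline"] = 0
    df["incarcerated_recent"] = 0
    df["ever_tested_baseline"] = 0
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
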