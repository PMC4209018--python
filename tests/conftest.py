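import numpy as np
import pandas as pd
import pytest

from msmarkov import (
    CdsStateClassifier,
    GroundTruthModel,
    default_model,
    load_fixture_matrix,
    simulate_cohort,
    stationary_distribution,
)
from msmarkov.states import N_STATES


@pytest.fixture(scope="session")
def table2():
    return load_fixture_matrix("table2")


@pytest.fixture(scope="session")
def small_model():
    """8-stratum demo model, small enough for fast end-to-end tests."""
    return default_model(n_per_stratum=300, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_model):
    return simulate_cohort(small_model)


@pytest.fixture(scope="session")
def classified_small(small_cohort):
    return CdsStateClassifier().fit_transform(small_cohort)


def single_stratum_model(fixture_name: str, n: int, seed: int, **kwargs) -> GroundTruthModel:
    """Ground-truth model over one stratum, baseline mix pulled toward health."""
    tm = load_fixture_matrix(fixture_name)
    key = tm.stratum
    pi = stationary_distribution(tm)
    e0 = np.zeros(N_STATES)
    e0[0] = 1.0
    init = 0.5 * pi + 0.5 * e0
    return GroundTruthModel(
        matrices={key: tm}, initial={key: init / init.sum()}, n_subjects={key: n},
        seed=seed, **kwargs,
    )


def toy_classified(visits: dict[str, list[tuple[int, int]]], sex="M", age=30.0) -> pd.DataFrame:
    """Hand-built classified table: subject -> [(visit_year, state), ...]."""
    rows = []
    for sid, seq in visits.items():
        for year, state in seq:
            rows.append(
                {"subject_id": sid, "visit_year": year, "age": age, "sex": sex,
                 "state": state, "stratum": f"{sex}_18-40" if age < 40 else f"{sex}_40-49"}
            )
    return pd.DataFrame(rows)
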