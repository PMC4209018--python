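"""CDS component rules, state assignment, exclusions and stratification."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msmarkov import (
    CdsStateClassifier,
    CdsThresholds,
    MSState,
    age_group_of,
    apply_exclusions,
    profile_to_state,
)
from msmarkov.classify import assign_state, evaluate_components
from msmarkov.states import COMPONENTS, StratumKey


def make_record(**over):
    base = dict(
        subject_id="s1", visit_year=2007, age=30.0, sex="M",
        bmi=22.0, sbp=120.0, dbp=75.0, tg=1.2, hdl=1.1, fpg=5.0, pg2h=np.nan,
        dx_hypertension=0, dx_hyperglycemia=0, hx_chd=0, hx_t1dm=0, hx_fam_hyperlipidemia=0,
    )
    base.update(over)
    return pd.DataFrame([base])


@pytest.mark.parametrize(
    "over, expected",
    [
        # overweight only
        (dict(bmi=26.0), (True, False, False, False)),
        # boundary values at >= cuts count as present; BMI just below its cut
        (dict(bmi=24.0, sbp=138.0, dbp=92.0, tg=1.7, hdl=1.0, fpg=6.1), (False, True, True, True)),
        # strict-< HDL clause and the 2h post-meal glucose clause
        (dict(bmi=24.9, sbp=130.0, dbp=80.0, tg=1.0, hdl=0.89, fpg=5.5, pg2h=8.0),
         (False, False, True, True)),
        # prior diagnoses alone are sufficient
        (dict(dx_hypertension=1, dx_hyperglycemia=1), (False, True, False, True)),
    ],
)
def test_component_rules(over, expected):
    profile = evaluate_components(make_record(**over))
    assert tuple(profile.iloc[0][list(COMPONENTS)]) == expected


def test_pg2h_missingness_is_irrelevant_when_fpg_triggers():
    with_pg = evaluate_components(make_record(fpg=6.5, pg2h=9.0))
    without = evaluate_components(make_record(fpg=6.5, pg2h=np.nan))
    assert with_pg.iloc[0]["hyperglycemia"] and without.iloc[0]["hyperglycemia"]


def test_missing_mandatory_field_raises():
    with pytest.raises(ValueError, match="missing mandatory"):
        evaluate_components(make_record(tg=np.nan))


def test_state_assignment_is_total_and_surjective():
    """All 16 profiles map onto the 7 states with multiplicities {1, 4, 6, 5}."""
    states = [profile_to_state(*p) for p in product([False, True], repeat=4)]
    assert set(states) == set(MSState)
    counts = {
        "none": sum(s == MSState.NO_COMPONENT for s in states),
        "isolated": sum(1 <= s <= 4 for s in states),
        "two": sum(s == MSState.TWO_COMPONENT for s in states),
        "ms": sum(s == MSState.MS for s in states),
    }
    assert counts == {"none": 1, "isolated": 4, "two": 6, "ms": 5}


def test_vectorized_assign_state_matches_scalar():
    profiles = pd.DataFrame(list(product([False, True], repeat=4)), columns=COMPONENTS)
    vec = assign_state(profiles)
    scalar = [profile_to_state(*row) for row in profiles.itertuples(index=False)]
    assert list(vec) == scalar


@settings(max_examples=200, derandomize=True)
@given(
    bmi=st.floats(15, 45), sbp=st.floats(90, 200), dbp=st.floats(50, 130),
    tg=st.floats(0.3, 6), hdl=st.floats(0.3, 3), fpg=st.floats(3, 15),
    bump=st.floats(0, 10),
)
def test_raising_a_geq_measurement_never_removes_components(bmi, sbp, dbp, tg, hdl, fpg, bump):
    """Monotonicity: increasing any measurement used only in >= clauses."""
    lo = evaluate_components(make_record(bmi=bmi, sbp=sbp, dbp=dbp, tg=tg, hdl=hdl, fpg=fpg))
    hi = evaluate_components(
        make_record(bmi=bmi + bump, sbp=sbp + bump, dbp=dbp + bump, tg=tg + bump,
                    hdl=hdl, fpg=fpg + bump)
    )
    assert (hi.to_numpy() >= lo.to_numpy()).all()


@pytest.mark.parametrize(
    "age, group",
    [(18, "18-40"), (39.9, "18-40"), (40, "40-49"), (49.9, "40-49"),
     (50, "50-59"), (59.9, "50-59"), (60, "60+"), (85, "60+")],
)
def test_age_partition_is_half_open(age, group):
    assert age_group_of(age) == group


def test_age_below_18_has_no_group():
    assert age_group_of(17.9) is None


def test_stratum_key_rejects_bad_values():
    with pytest.raises(ValueError):
        StratumKey(sex="X", age_group="18-40")
    with pytest.raises(ValueError):
        StratumKey(sex="M", age_group="18-39")


def test_thresholds_must_be_positive():
    with pytest.raises(ValueError, match="positive"):
        CdsThresholds(tg=0.0)


class TestExclusions:
    def _cohort(self):
        rows = []
        for sid, hx, tg in [("a", 0, 1.0), ("b", 1, 1.0), ("c", 0, np.nan), ("d", 0, 1.2)]:
            for year in (2007, 2008):
                rows.append(
                    dict(subject_id=sid, visit_year=year, age=30.0, sex="M", bmi=22.0,
                         sbp=120.0, dbp=75.0, tg=tg if year == 2008 else 1.0, hdl=1.1,
                         fpg=5.0, pg2h=np.nan, dx_hypertension=0, dx_hyperglycemia=0,
                         hx_chd=0, hx_t1dm=hx if year == 2007 else 0, hx_fam_hyperlipidemia=0)
                )
        return pd.DataFrame(rows)

    def test_history_flag_drops_all_visits(self):
        kept, log = apply_exclusions(self._cohort())
        assert "b" not in set(kept["subject_id"])  # flagged at one visit only
        assert log["history of type I diabetes"] == 1

    def test_incomplete_subject_dropped_entirely(self):
        kept, log = apply_exclusions(self._cohort())
        assert "c" not in set(kept["subject_id"])
        assert log["incomplete information"] == 1
        assert set(kept["subject_id"]) == {"a", "d"}

    def test_underage_subject_excluded(self):
        df = self._cohort()
        df.loc[df["subject_id"] == "a", "age"] = 17.0
        kept, log = apply_exclusions(df)
        assert "a" not in set(kept["subject_id"])
        assert log["age under 18"] == 1

    def test_empty_input(self):
        kept, log = apply_exclusions(self._cohort().iloc[0:0])
        assert kept.empty and log["subjects_out"] == 0


def test_classifier_transform_adds_expected_columns(small_cohort):
    out = CdsStateClassifier().fit_transform(small_cohort)
    for col in (*COMPONENTS, "n_components", "state", "state_name", "age_group", "stratum"):
        assert col in out.columns
    assert out["state"].between(0, 6).all()
    # exactly-one-state semantics: state index agrees with component count
    n = out["n_components"]
    assert (out.loc[n == 0, "state"] == 0).all()
    assert out.loc[n == 1, "state"].between(1, 4).all()
    assert (out.loc[n == 2, "state"] == 5).all()
    assert (out.loc[n >= 3, "state"] == 6).all()


def test_classifier_is_sklearn_compatible(small_cohort):
    from sklearn.base import clone

    clf = CdsStateClassifier(exclusions=False)
    assert clone(clf).get_params()["exclusions"] is False
    clf.set_params(exclusions=True)
    assert clf.fit(small_cohort) is clf
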