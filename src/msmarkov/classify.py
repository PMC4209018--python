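"""Record-level classification: CDS component rules, state assignment, exclusions, strata.

Operates on a cohort table with one row per subject-visit (see
:data:`COHORT_COLUMNS` for the schema).  All rules are vectorised over the
whole table; :class:`CdsStateClassifier` wraps them as a scikit-learn
transformer so classification can sit in a pipeline ahead of transition
estimation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .states import (
    COMPONENTS,
    MSState,
    CdsThresholds,
    age_group_of,
)

__all__ = [
    "COHORT_COLUMNS",
    "MANDATORY_MEASUREMENTS",
    "evaluate_components",
    "assign_state",
    "apply_exclusions",
    "assign_stratum",
    "CdsStateClassifier",
]

#: Column order of the cohort CSV schema.
COHORT_COLUMNS = [
    "subject_id",
    "visit_year",
    "age",
    "sex",
    "bmi",
    "sbp",
    "dbp",
    "tg",
    "hdl",
    "fpg",
    "pg2h",
    "dx_hypertension",
    "dx_hyperglycemia",
    "hx_chd",
    "hx_t1dm",
    "hx_fam_hyperlipidemia",
]

#: Fields that must be non-missing for a record to be classifiable; pg2h is optional.
MANDATORY_MEASUREMENTS = ["age", "sex", "bmi", "sbp", "dbp", "tg", "hdl", "fpg"]

_HISTORY_EXCLUSIONS = {
    "hx_chd": "history of coronary heart disease",
    "hx_t1dm": "history of type I diabetes",
    "hx_fam_hyperlipidemia": "history of familial hyperlipidemia",
}


def evaluate_components(records: pd.DataFrame, cuts: Optional[CdsThresholds] = None) -> pd.DataFrame:
    """Evaluate the four CDS component rules for every record.

    Returns a boolean DataFrame with columns ``overweight``, ``hypertension``,
    ``dyslipidemia``, ``hyperglycemia`` aligned to ``records``.  Records must
    already be complete (see :func:`apply_exclusions`); missing mandatory
    values raise.
    """
    cuts = cuts or CdsThresholds()
    for col in ("bmi", "sbp", "dbp", "tg", "hdl", "fpg"):
        if records[col].isna().any():
            bad = records.loc[records[col].isna(), "subject_id"].iloc[0]
            raise ValueError(
                f"record with missing mandatory field {col!r} (subject {bad!r}); "
                "run apply_exclusions first"
            )
    dx_htn = records.get("dx_hypertension", pd.Series(0, index=records.index)).fillna(0).astype(bool)
    dx_hg = records.get("dx_hyperglycemia", pd.Series(0, index=records.index)).fillna(0).astype(bool)
    pg2h = records.get("pg2h", pd.Series(np.nan, index=records.index))

    out = pd.DataFrame(index=records.index)
    out["overweight"] = records["bmi"] >= cuts.bmi
    out["hypertension"] = (records["sbp"] >= cuts.sbp) | (records["dbp"] >= cuts.dbp) | dx_htn
    out["dyslipidemia"] = (records["tg"] >= cuts.tg) | (records["hdl"] < cuts.hdl)
    out["hyperglycemia"] = (records["fpg"] >= cuts.fpg) | (pg2h >= cuts.pg2h) | dx_hg
    return out


def assign_state(profile: pd.DataFrame) -> pd.Series:
    """Map component profiles to state indices (0..6).

    ``profile`` is the boolean frame from :func:`evaluate_components`.  The
    mapping is total over the 16 profiles: 0 components -> no-component,
    exactly 1 -> the matching isolated state, 2 -> two-component, >=3 -> MS.
    """
    flags = profile[list(COMPONENTS)].to_numpy(dtype=bool)
    n = flags.sum(axis=1)
    # isolated states occupy indices 1..4 in component order
    iso = flags.argmax(axis=1) + 1
    state = np.select(
        [n == 0, n == 1, n == 2],
        [MSState.NO_COMPONENT, iso, MSState.TWO_COMPONENT],
        default=MSState.MS,
    )
    return pd.Series(state.astype(int), index=profile.index, name="state")


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the study's subject-level exclusion rules.

    A subject is removed entirely (all visits) if any visit carries a
    positive history flag for coronary heart disease, type I diabetes or
    familial hyperlipidemia, if any visit is missing a mandatory
    measurement ("did not provide complete information"), or if their age at
    any visit is below 18.  Returns the filtered table and a log of subject
    counts per exclusion reason.
    """
    log = {reason: 0 for reason in (*_HISTORY_EXCLUSIONS.values(), "incomplete information", "age under 18")}
    log["subjects_in"] = records["subject_id"].nunique()
    if records.empty:
        log["subjects_out"] = 0
        return records.copy(), log

    excluded: set = set()
    for col, reason in _HISTORY_EXCLUSIONS.items():
        if col in records:
            flagged = set(records.loc[records[col].fillna(0).astype(bool), "subject_id"])
        else:
            flagged = set()
        log[reason] = len(flagged - excluded)
        excluded |= flagged

    incomplete_mask = records[MANDATORY_MEASUREMENTS].isna().any(axis=1)
    if "sex" in records:
        incomplete_mask |= ~records["sex"].isin(("M", "F"))
    incomplete = set(records.loc[incomplete_mask, "subject_id"])
    log["incomplete information"] = len(incomplete - excluded)
    excluded |= incomplete

    underage = set(records.loc[records["age"] < 18, "subject_id"])
    log["age under 18"] = len(underage - excluded)
    excluded |= underage

    kept = records[~records["subject_id"].isin(excluded)].copy()
    log["subjects_out"] = kept["subject_id"].nunique()
    return kept, log


def assign_stratum(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``age_group`` and ``stratum`` labels (sex x age group) to records.

    Ages must be >= 18 (enforced by :func:`apply_exclusions`).
    """
    if (records["age"] < 18).any():
        bad = records.loc[records["age"] < 18, "subject_id"].iloc[0]
        raise ValueError(f"age below 18 for subject {bad!r}; apply exclusions first")
    out = records.copy()
    out["age_group"] = age_group_of(out["age"].to_numpy())
    out["stratum"] = out["sex"].astype(str) + "_" + out["age_group"]
    return out


class CdsStateClassifier(TransformerMixin, BaseEstimator):
    """Classify check-up records into the 7 metabolic states under CDS criteria.

    Parameters
    ----------
    thresholds
        Diagnostic cut-offs; defaults to the CDS values.
    exclusions
        If True (default), drop excluded subjects before classifying and
        record counts per reason in ``exclusion_log_``.

    After ``transform`` the returned frame carries the four component flags,
    ``n_components``, ``state`` (index), ``state_name``, ``age_group`` and
    ``stratum`` columns in addition to the input schema.
    """

    def __init__(self, thresholds: Optional[CdsThresholds] = None, exclusions: bool = True):
        self.thresholds = thresholds
        self.exclusions = exclusions

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in ("subject_id", "visit_year", "age", "sex") if c not in X.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns: {missing}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cuts = self.thresholds or CdsThresholds()
        if self.exclusions:
            X, self.exclusion_log_ = apply_exclusions(X)
        else:
            self.exclusion_log_ = None
        profile = evaluate_components(X, cuts)
        out = pd.concat([X.reset_index(drop=True), profile.reset_index(drop=True)], axis=1)
        out["n_components"] = profile.to_numpy(dtype=bool).sum(axis=1)
        out["state"] = assign_state(profile).to_numpy()
        out["state_name"] = [MSState(s).name.lower() for s in out["state"]]
        return assign_stratum(out)

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
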