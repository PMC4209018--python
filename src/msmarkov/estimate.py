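"""Annual transition-probability estimation from classified panel records.

The estimator follows the study's two-step recipe: tabulate state
transitions between every pair of consecutive calendar years within each
sex x age stratum, convert each year-pair's counts into a row-conditional
incidence-rate matrix (percent), and average those annual matrices cell-wise
into a single annual transition matrix per stratum.  Rows never observed in
a year-pair are excluded from that row's mean (not zero-filled); a row never
observed at all is emitted as unobserved and cannot be projected through.

An unweighted mean across year-pairs is the primary estimator; pooling the
counts before forming rates is available as a sensitivity alternative (the
two coincide when the year-pair row denominators are equal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrices import TransitionMatrix
from .states import COMPONENTS, N_STATES, MSState, StratumKey

__all__ = [
    "TransitionCounts",
    "pair_consecutive_visits",
    "count_transitions",
    "annual_rate_matrix",
    "average_annual_matrices",
    "descriptive_summary",
    "TransitionMatrixEstimator",
]


@dataclass
class TransitionCounts:
    """Integer transition tally for one stratum and one (y, y+1) year pair."""

    stratum: str
    year_from: int
    counts: np.ndarray  # 7x7 ints, counts[i, j] = n(i -> j)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def _stratum_key(label: str) -> StratumKey:
    sex, age_group = label.split("_", 1)
    return StratumKey(sex=sex, age_group=age_group)


def pair_consecutive_visits(classified: pd.DataFrame, stratum_mode: str = "per_pair") -> pd.DataFrame:
    """Extract one transition event per subject per consecutive-year visit pair.

    A pair of visits in adjacent calendar years (y, y+1) yields one event
    (state_y -> state_{y+1}); a gap of more than one year yields no event
    across it.  ``stratum_mode`` controls which stratum an event belongs to:
    ``"per_pair"`` uses the subject's stratum at the first year of the pair
    (age kept current), ``"baseline"`` freezes the stratum of the subject's
    first visit.

    Raises on duplicate subject-year rows, naming the subject.
    """
    if stratum_mode not in ("per_pair", "baseline"):
        raise ValueError(f"stratum_mode must be 'per_pair' or 'baseline', got {stratum_mode!r}")
    if classified.empty:
        return pd.DataFrame(columns=["subject_id", "year_from", "state_from", "state_to", "stratum"])

    dup = classified.duplicated(subset=["subject_id", "visit_year"])
    if dup.any():
        sid = classified.loc[dup, "subject_id"].iloc[0]
        year = classified.loc[dup, "visit_year"].iloc[0]
        raise ValueError(f"duplicate visit-year {year} for subject {sid!r}")

    df = classified.sort_values(["subject_id", "visit_year"], kind="mergesort")
    if stratum_mode == "baseline":
        stratum = df.groupby("subject_id", sort=False)["stratum"].transform("first")
    else:
        stratum = df["stratum"]

    same = df["subject_id"].to_numpy()[1:] == df["subject_id"].to_numpy()[:-1]
    adjacent = np.diff(df["visit_year"].to_numpy()) == 1
    take = same & adjacent
    return pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy()[:-1][take],
            "year_from": df["visit_year"].to_numpy()[:-1][take],
            "state_from": df["state"].to_numpy()[:-1][take],
            "state_to": df["state"].to_numpy()[1:][take],
            "stratum": stratum.to_numpy()[:-1][take],
        }
    )


def count_transitions(events: pd.DataFrame) -> list[TransitionCounts]:
    """Tabulate events into 7x7 count matrices per stratum per year pair."""
    out = []
    if events.empty:
        return out
    for (stratum, year), grp in events.groupby(["stratum", "year_from"], sort=True):
        counts = np.zeros((N_STATES, N_STATES), dtype=int)
        np.add.at(counts, (grp["state_from"].to_numpy(), grp["state_to"].to_numpy()), 1)
        out.append(TransitionCounts(stratum=str(stratum), year_from=int(year), counts=counts))
    return out


def annual_rate_matrix(counts: TransitionCounts) -> np.ndarray:
    """Row-conditional incidence rates in percent for one year pair.

    rate(i -> j) = 100 * n(i -> j) / n(i) for rows with n(i) > 0; rows with
    no observations are NaN (unobserved), never zero-filled.
    """
    totals = counts.row_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = 100.0 * counts.counts / totals[:, None]
    rates[totals == 0] = np.nan
    return rates


def average_annual_matrices(
    rate_matrices: list[np.ndarray],
    stratum: str | None = None,
    provenance: str = "estimated",
) -> TransitionMatrix:
    """Cell-wise unweighted mean of annual rate matrices, renormalized per row.

    Only year-pairs where a row was observed contribute to that row's mean;
    the per-row count of contributing year-pairs is recorded in
    ``row_support``.  Rows observed in no year-pair remain NaN (unobserved).
    """
    if not rate_matrices:
        raise ValueError("need at least one annual rate matrix")
    stack = np.stack(rate_matrices)  # (k, 7, 7)
    row_observed = ~np.isnan(stack).any(axis=2)  # (k, 7)
    support = row_observed.sum(axis=0)
    # a row observed in a year-pair has no NaN cells, so the per-cell
    # denominator is the row's support count
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(stack, axis=0) / support[:, None]
    mean[support == 0] = np.nan
    # renormalize observed rows to exactly 100 (guards averaging drift)
    sums = np.nansum(mean, axis=1)
    obs = support > 0
    mean[obs] = mean[obs] * (100.0 / sums[obs, None])
    return TransitionMatrix(
        percent=mean,
        stratum=_stratum_key(stratum) if stratum else None,
        row_support=support,
        provenance=provenance,
        source=stratum,
    )


def _pooled_matrix(counts_list: list[TransitionCounts], stratum: str) -> TransitionMatrix:
    total = np.zeros((N_STATES, N_STATES), dtype=int)
    for c in counts_list:
        total += c.counts
    pooled = TransitionCounts(stratum=stratum, year_from=-1, counts=total)
    rates = annual_rate_matrix(pooled)
    support = (np.stack([c.row_totals for c in counts_list]) > 0).sum(axis=0)
    return TransitionMatrix(
        percent=rates, stratum=_stratum_key(stratum), row_support=support,
        provenance="estimated", source=stratum,
    )


def descriptive_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Cohort description per follow-up year (baseline = each subject's first visit).

    Returns one row per follow-up year with the number of subjects seen,
    mean age, percent male, prevalence (%) of each of the four components
    and of MS — the study's Table-1-style read-out.
    """
    cols = ["followup_year", "n", "mean_age", "pct_male"] + [f"pct_{c}" for c in COMPONENTS] + ["pct_ms"]
    if classified.empty:
        return pd.DataFrame(columns=cols)
    df = classified.copy()
    df["followup_year"] = df["visit_year"] - df.groupby("subject_id")["visit_year"].transform("min")
    rows = []
    for fy, grp in df.groupby("followup_year", sort=True):
        n = len(grp)
        row = {
            "followup_year": int(fy),
            "n": n,
            "mean_age": grp["age"].mean(),
            "pct_male": 100.0 * (grp["sex"] == "M").mean(),
        }
        for c in COMPONENTS:
            row[f"pct_{c}"] = 100.0 * grp[c].mean()
        row["pct_ms"] = 100.0 * (grp["state"] == MSState.MS).mean()
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


class TransitionMatrixEstimator(BaseEstimator):
    """Estimate per-stratum annual transition matrices from classified records.

    Parameters
    ----------
    averaging
        ``"mean"`` (default): unweighted mean of the per-year-pair rate
        matrices, the study's estimator.  ``"pooled"``: pool counts over
        year-pairs before forming rates (count-weighted sensitivity variant).
    stratum_mode
        ``"per_pair"`` (default) assigns each transition event to the
        subject's stratum at the first year of the pair; ``"baseline"``
        freezes the baseline stratum.

    Fitted attributes
    -----------------
    matrices_ : dict[str, TransitionMatrix]
        One matrix per stratum label present in the data.
    counts_ : list[TransitionCounts]
        The underlying per-stratum, per-year-pair tallies.
    n_events_ : int
        Total number of transition events used.
    """

    def __init__(self, averaging: str = "mean", stratum_mode: str = "per_pair"):
        self.averaging = averaging
        self.stratum_mode = stratum_mode

    def fit(self, X: pd.DataFrame, y=None):
        if self.averaging not in ("mean", "pooled"):
            raise ValueError(f"averaging must be 'mean' or 'pooled', got {self.averaging!r}")
        events = pair_consecutive_visits(X, stratum_mode=self.stratum_mode)
        self.counts_ = count_transitions(events)
        self.n_events_ = int(len(events))
        self.matrices_ = {}
        by_stratum: dict[str, list[TransitionCounts]] = {}
        for c in self.counts_:
            by_stratum.setdefault(c.stratum, []).append(c)
        for stratum, clist in sorted(by_stratum.items()):
            if self.averaging == "mean":
                rates = [annual_rate_matrix(c) for c in clist]
                self.matrices_[stratum] = average_annual_matrices(rates, stratum=stratum)
            else:
                self.matrices_[stratum] = _pooled_matrix(clist, stratum)
        return self
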