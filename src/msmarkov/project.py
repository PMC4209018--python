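"""Occupancy projection through an annual transition matrix, with validation.

Propagates a cohort's distribution over the 7 metabolic states through
cycles of one year, pi_{t+1}(j) = sum_i pi_t(i) p(i->j), under the model's
two simplifying assumptions: the next state depends only on the current one
(Markov property) and the annual matrix is constant over the horizon (time
homogeneity).  A Monte-Carlo microsimulation of individual chains serves as
an independent oracle for the matrix-power computation, and projected MS
prevalence can be checked against the prevalence actually observed in a
cohort at a given follow-up year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrices import TransitionMatrix
from .states import N_STATES, STATE_NAMES, MSState

__all__ = [
    "ProjectionTrajectory",
    "project",
    "predict_by_initial_state",
    "microsimulation_oracle",
    "validate_against_empiric",
    "stationary_distribution",
    "MarkovProjector",
    "trajectories_to_frame",
]

MatrixLike = Union[TransitionMatrix, np.ndarray]


def _as_matrix(matrix: MatrixLike) -> TransitionMatrix:
    if isinstance(matrix, TransitionMatrix):
        return matrix
    return TransitionMatrix(percent=np.asarray(matrix, dtype=float))


def _unit_vector(state: int) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[int(state)] = 1.0
    return v


@dataclass
class ProjectionTrajectory:
    """Occupancy vectors pi_t for t = 0..T from one starting distribution."""

    occupancy: np.ndarray  # (T+1, 7); row t is pi_t
    start: np.ndarray
    matrix: TransitionMatrix
    stratum: Optional[str] = None

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def ms_curve(self, percent: bool = True) -> np.ndarray:
        """MS occupancy per cycle, in percent by default (figure read-out)."""
        curve = self.occupancy[:, MSState.MS]
        return 100.0 * curve if percent else curve

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for t, pi in enumerate(self.occupancy):
            for j, name in enumerate(STATE_NAMES):
                recs.append({"cycle": t, "state": name, "occupancy": pi[j]})
        df = pd.DataFrame(recs)
        df["stratum"] = self.stratum
        return df


def project(
    matrix: MatrixLike,
    start: Union[int, Sequence[float]],
    cycles: int = 10,
    renormalize: bool = True,
) -> ProjectionTrajectory:
    """Propagate an occupancy vector through ``cycles`` annual steps.

    ``start`` is a state index (unit-vector start) or a length-7
    distribution.  With ``renormalize`` (default) the matrix rows are made
    exactly stochastic before propagation, so every pi_t sums to 1 to 1e-9;
    with ``renormalize=False`` printed rows are used verbatim so a one-cycle
    read-out from a unit vector reproduces the printed cells exactly.

    Raises if an unobserved matrix row is reachable with positive
    probability, or if ``cycles`` is negative.
    """
    if cycles < 0:
        raise ValueError(f"cycles must be >= 0, got {cycles}")
    tm = _as_matrix(matrix)
    pi0 = _unit_vector(start) if np.isscalar(start) else np.asarray(start, dtype=float)
    if pi0.shape != (N_STATES,) or (pi0 < 0).any() or abs(pi0.sum() - 1.0) > 1e-9:
        raise ValueError("start must be a state index or a length-7 distribution summing to 1")

    P = tm.as_fraction(renormalize=renormalize)
    unobserved = ~tm.observed_rows()
    P = np.where(np.isnan(P), 0.0, P)
    out = np.empty((cycles + 1, N_STATES))
    out[0] = pi0
    for t in range(cycles):
        if (out[t][unobserved] > 0).any():
            i = int(np.flatnonzero(unobserved & (out[t] > 0))[0])
            raise ValueError(
                f"state {STATE_NAMES[i]} is reachable at cycle {t} but its matrix row "
                "was never observed; cannot project through it"
            )
        out[t + 1] = out[t] @ P
    return ProjectionTrajectory(occupancy=out, start=pi0, matrix=tm,
                                stratum=tm.stratum.label if tm.stratum else None)


def predict_by_initial_state(
    matrix: MatrixLike, horizon: int = 10, renormalize: bool = True
) -> list[ProjectionTrajectory]:
    """One trajectory per starting state (all 7), over ``horizon`` cycles."""
    return [project(matrix, s, horizon, renormalize=renormalize) for s in range(N_STATES)]


def microsimulation_oracle(
    matrix: MatrixLike,
    start: int,
    cycles: int,
    n: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Empirical occupancy from ``n`` independently simulated chains.

    Independent Monte-Carlo check of :func:`project`: returns the (cycles+1,
    7) matrix of empirical state frequencies; each cell agrees with the
    matrix-power result to binomial Monte-Carlo error.
    """
    tm = _as_matrix(matrix)
    P = tm.as_fraction(renormalize=True)
    if np.isnan(P[int(start)]).any():
        raise ValueError(f"starting row {STATE_NAMES[int(start)]} unobserved")
    P = np.where(np.isnan(P), 0.0, P)
    cum = np.cumsum(P, axis=1)
    rng = np.random.default_rng(seed)
    states = np.full(n, int(start), dtype=np.int8)
    occ = np.zeros((cycles + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n
    for t in range(cycles):
        u = rng.random(n)
        states = (u[:, None] > cum[states]).sum(axis=1).astype(np.int8)
        occ[t + 1] = np.bincount(states, minlength=N_STATES) / n
    return occ


def stationary_distribution(matrix: MatrixLike, tol: float = 1e-9, max_doublings: int = 60) -> np.ndarray:
    """Fixed point of the renormalized matrix, via repeated squaring.

    Valid for the irreducible aperiodic matrices this model produces; used
    for mixing diagnostics (all starting states converge toward it).
    """
    tm = _as_matrix(matrix)
    P = tm.as_fraction(renormalize=True)
    if np.isnan(P).any():
        raise ValueError("stationary distribution undefined with unobserved rows")
    Q = P.copy()
    for _ in range(max_doublings):
        nxt = Q @ Q
        if np.abs(nxt - Q).max() < tol:
            Q = nxt
            break
        Q = nxt
    pi = Q.mean(axis=0)
    return pi / pi.sum()


def validate_against_empiric(
    matrices: dict[str, TransitionMatrix],
    classified: pd.DataFrame,
    horizon: int = 5,
) -> pd.DataFrame:
    """Compare projected MS occupancy with observed prevalence at a follow-up year.

    For each stratum (assigned at baseline), the baseline occupancy of its
    subjects is projected ``horizon`` cycles through the stratum's matrix
    and compared with the observed MS prevalence among subjects actually
    seen at that follow-up year.  The report is descriptive — projected and
    observed values with their absolute difference — with no pass/fail
    threshold; strata with nobody at the horizon are marked not validatable.
    """
    df = classified.copy()
    df["followup_year"] = df["visit_year"] - df.groupby("subject_id")["visit_year"].transform("min")
    base_stratum = df[df["followup_year"] == 0].set_index("subject_id")["stratum"]
    df["baseline_stratum"] = df["subject_id"].map(base_stratum)

    rows = []
    for stratum, matrix in sorted(matrices.items()):
        grp = df[df["baseline_stratum"] == stratum]
        base = grp[grp["followup_year"] == 0]
        at_h = grp[grp["followup_year"] == horizon]
        row = {"stratum": stratum, "horizon": horizon, "n_baseline": len(base), "n_at_horizon": len(at_h)}
        if len(base) == 0 or len(at_h) == 0:
            row.update(projected_ms_pct=np.nan, observed_ms_pct=np.nan,
                       abs_difference=np.nan, validatable=False)
        else:
            pi0 = np.bincount(base["state"].to_numpy(), minlength=N_STATES) / len(base)
            try:
                proj = project(matrix, pi0, horizon).occupancy[-1, MSState.MS] * 100.0
            except ValueError:
                # an unobserved matrix row is reachable: too little data to project
                row.update(projected_ms_pct=np.nan, observed_ms_pct=np.nan,
                           abs_difference=np.nan, validatable=False)
                rows.append(row)
                continue
            obs = 100.0 * (at_h["state"] == MSState.MS).mean()
            row.update(projected_ms_pct=proj, observed_ms_pct=obs,
                       abs_difference=abs(proj - obs), validatable=True)
        rows.append(row)
    return pd.DataFrame(rows)


def trajectories_to_frame(trajectories: list[ProjectionTrajectory]) -> pd.DataFrame:
    """Tidy (stratum, start_state, cycle, state, occupancy) table for export."""
    frames = []
    for traj in trajectories:
        df = traj.to_frame()
        if np.isclose(traj.start.max(), 1.0):
            df["start_state"] = STATE_NAMES[int(np.argmax(traj.start))]
        else:
            df["start_state"] = "mixed"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[["stratum", "start_state", "cycle", "state", "occupancy"]]


class MarkovProjector(BaseEstimator):
    """Project state occupancy through a fitted or supplied annual matrix.

    scikit-learn-style wrapper: ``fit`` accepts either a
    :class:`TransitionMatrix` / 7x7 percent array directly, or a classified
    cohort DataFrame (in which case a :class:`TransitionMatrixEstimator` is
    fitted internally and ``stratum`` selects the matrix).  ``predict``
    returns the occupancy trajectory from a starting state or distribution.

    Parameters
    ----------
    cycles : projection horizon in years (default 10, the study's).
    renormalize : make rows exactly stochastic before propagation.
    stratum : stratum label to project when fitting from a cohort.
    """

    def __init__(self, cycles: int = 10, renormalize: bool = True, stratum: Optional[str] = None):
        self.cycles = cycles
        self.renormalize = renormalize
        self.stratum = stratum

    def fit(self, X, y=None):
        if isinstance(X, TransitionMatrix):
            self.matrix_ = X
        elif isinstance(X, (np.ndarray, list)):
            self.matrix_ = _as_matrix(np.asarray(X, dtype=float))
        elif isinstance(X, pd.DataFrame):
            from .estimate import TransitionMatrixEstimator

            est = TransitionMatrixEstimator().fit(X)
            if self.stratum is None:
                raise ValueError("stratum must be set when fitting from a cohort table")
            if self.stratum not in est.matrices_:
                raise ValueError(f"stratum {self.stratum!r} not in data; have {sorted(est.matrices_)}")
            self.matrix_ = est.matrices_[self.stratum]
        else:
            raise TypeError(f"cannot fit from {type(X).__name__}")
        return self

    def predict(self, start: Union[int, Sequence[float]]) -> ProjectionTrajectory:
        return project(self.matrix_, start, self.cycles, renormalize=self.renormalize)

    def predict_all_starts(self) -> list[ProjectionTrajectory]:
        return predict_by_initial_state(self.matrix_, self.cycles, renormalize=self.renormalize)
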