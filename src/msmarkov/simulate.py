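"""Synthetic longitudinal check-up cohorts with known Markov ground truth.

The generator emulates the study design this package analyses: subjects
attend 2-6 annual health check-ups inside a fixed 6-calendar-year window,
with loss to follow-up, and each subject's latent metabolic state evolves as
a discrete-time Markov chain under a per-stratum annual transition matrix.
Clinical measurements (BMI, blood pressure, lipids, glucose, diagnosis
flags) are then rendered so that CDS classification recovers the latent
state exactly — a round-trip guarantee that makes every downstream stage
testable without real data.

Only threshold-consistency is guaranteed: the joint physiological
distribution of the rendered biomarkers is deliberately simple (uniform
within side-of-threshold ranges), not a model of real physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .classify import COHORT_COLUMNS
from .matrices import TransitionMatrix
from .states import N_STATES, CdsThresholds, MSState, StratumKey

__all__ = [
    "GroundTruthModel",
    "MeasurementRenderer",
    "sample_trajectories",
    "render_measurements",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "default_model",
]

#: Age range sampled at baseline per age group (the open-ended group is capped).
_AGE_RANGES = {"18-40": (18.0, 40.0), "40-49": (40.0, 50.0), "50-59": (50.0, 60.0), "60+": (60.0, 75.0)}

# component index order matches states.COMPONENTS
_PAIRS = np.array(
    [[1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 1], [0, 1, 1, 0], [0, 1, 0, 1], [0, 0, 1, 1]], dtype=bool
)
_MS_COMBOS = np.array(
    [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0], [1, 1, 1, 1]], dtype=bool
)


@dataclass
class GroundTruthModel:
    """Per-stratum ground truth driving the cohort simulation.

    Parameters
    ----------
    matrices
        Annual transition matrix per stratum (rows renormalized on load;
        a non-stochastic row is rejected with a diagnostic naming it).
    initial
        Length-7 baseline state distribution per stratum (sums to 1).
    n_subjects
        Cohort size per stratum.
    n_visits
        Maximum annual visits per subject (study window allows 2-6).
    dropout
        Per-visit Bernoulli drop probability after the second visit; 0.30
        reproduces the study's mean follow-up of ~3.74 visit-years.
    seed
        Seed for all stochastic draws of the simulation.
    start_year, n_years
        Calendar window; baselines are staggered so each subject's visits
        fit inside it, mirroring rolling enrolment.
    """

    matrices: dict[StratumKey, TransitionMatrix]
    initial: dict[StratumKey, np.ndarray]
    n_subjects: dict[StratumKey, int]
    n_visits: int = 6
    dropout: float = 0.30
    seed: int = 0
    start_year: int = 2006
    n_years: int = 6

    def __post_init__(self) -> None:
        if not 2 <= self.n_visits <= self.n_years:
            raise ValueError(f"n_visits must be in [2, {self.n_years}], got {self.n_visits}")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError(f"dropout must be in [0, 1], got {self.dropout}")
        for key, tm in self.matrices.items():
            tm.validate()
            init = np.asarray(self.initial[key], dtype=float)
            if init.shape != (N_STATES,) or (init < 0).any() or abs(init.sum() - 1.0) > 1e-9:
                raise ValueError(f"initial distribution for {key.label} is not a length-7 simplex vector")
            self.initial[key] = init

    @classmethod
    def from_yaml(cls, path) -> "GroundTruthModel":
        raw = yaml.safe_load(Path(path).read_text())
        matrices, initial, sizes = {}, {}, {}
        for label, entry in raw["strata"].items():
            key = StratumKey(sex=entry["sex"], age_group=entry["age_group"])
            matrices[key] = TransitionMatrix(
                percent=np.asarray(entry["matrix_percent"], dtype=float),
                stratum=key,
                provenance=entry.get("provenance", "fixture"),
            )
            initial[key] = np.asarray(entry["initial"], dtype=float)
            sizes[key] = int(entry["n_subjects"])
        opts = {k: raw[k] for k in ("n_visits", "dropout", "seed", "start_year", "n_years") if k in raw}
        return cls(matrices=matrices, initial=initial, n_subjects=sizes, **opts)

    def to_yaml(self, path) -> None:
        strata = {}
        for key, tm in self.matrices.items():
            strata[key.label] = {
                "sex": key.sex,
                "age_group": key.age_group,
                "matrix_percent": np.round(tm.percent, 6).tolist(),
                "initial": np.round(self.initial[key], 8).tolist(),
                "n_subjects": int(self.n_subjects[key]),
                "provenance": tm.provenance,
            }
        doc = {
            "strata": strata,
            "n_visits": self.n_visits,
            "dropout": self.dropout,
            "seed": self.seed,
            "start_year": self.start_year,
            "n_years": self.n_years,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class MeasurementRenderer:
    """Renders latent states into CDS-consistent clinical measurements.

    Each component, when present, is triggered through one of its rule
    clauses chosen at random (e.g. hypertension via high SBP, high DBP or a
    prior-diagnosis flag); when absent, every clause of the rule fails.
    Value ranges sit strictly on one side of their threshold, with a margin
    so that 2-decimal rounding cannot cross it; a range straddling its
    threshold is a configuration error.
    """

    thresholds: CdsThresholds = field(default_factory=CdsThresholds)
    bmi_high: tuple = (25.5, 34.9)
    bmi_normal: tuple = (19.5, 24.5)
    sbp_high: tuple = (141.0, 179.0)
    sbp_normal: tuple = (96.0, 138.0)
    dbp_high: tuple = (91.0, 109.0)
    dbp_normal: tuple = (61.0, 88.0)
    tg_high: tuple = (1.75, 4.5)
    tg_normal: tuple = (0.7, 1.65)
    hdl_low: tuple = (0.5, 0.85)
    hdl_normal: tuple = (0.95, 1.9)
    fpg_high: tuple = (6.2, 11.0)
    fpg_normal: tuple = (4.2, 5.9)
    pg2h_high: tuple = (7.9, 14.0)
    pg2h_normal: tuple = (4.5, 7.5)
    # clause mix when a component is present: hypertension (SBP, DBP, dx),
    # dyslipidemia (TG, HDL), hyperglycemia (FPG, 2h-PG, dx)
    htn_clause_probs: tuple = (0.5, 0.3, 0.2)
    dys_clause_probs: tuple = (0.6, 0.4)
    hg_clause_probs: tuple = (0.6, 0.2, 0.2)
    pg2h_measured_rate: float = 0.3  # among records not triggering via 2h-PG
    history_flag_rate: float = 0.0  # per-subject rate of each exclusion-history flag

    def validate(self) -> None:
        t = self.thresholds
        checks = [
            ("bmi_high", self.bmi_high[0] >= t.bmi), ("bmi_normal", self.bmi_normal[1] < t.bmi),
            ("sbp_high", self.sbp_high[0] >= t.sbp), ("sbp_normal", self.sbp_normal[1] < t.sbp),
            ("dbp_high", self.dbp_high[0] >= t.dbp), ("dbp_normal", self.dbp_normal[1] < t.dbp),
            ("tg_high", self.tg_high[0] >= t.tg), ("tg_normal", self.tg_normal[1] < t.tg),
            ("hdl_low", self.hdl_low[1] < t.hdl), ("hdl_normal", self.hdl_normal[0] >= t.hdl),
            ("fpg_high", self.fpg_high[0] >= t.fpg), ("fpg_normal", self.fpg_normal[1] < t.fpg),
            ("pg2h_high", self.pg2h_high[0] >= t.pg2h), ("pg2h_normal", self.pg2h_normal[1] < t.pg2h),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"renderer ranges straddle their threshold: {bad}")
        for name in ("htn_clause_probs", "dys_clause_probs", "hg_clause_probs"):
            p = np.asarray(getattr(self, name))
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")


def _retained_lengths(n: int, n_visits: int, dropout: float, rng: np.random.Generator) -> np.ndarray:
    """Visits retained per subject: 2 plus a run of Bernoulli(1-dropout) successes."""
    if n_visits == 2:
        return np.full(n, 2, dtype=int)
    keep = rng.random((n, n_visits - 2)) >= dropout
    return 2 + np.cumprod(keep, axis=1).sum(axis=1).astype(int)


def sample_trajectories(model: GroundTruthModel, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw latent state sequences for every synthetic subject.

    Returns one row per subject-visit with columns ``subject_id``,
    ``true_stratum``, ``sex``, ``baseline_age``, ``age``, ``visit_year``,
    ``visit_index`` and the latent ``true_state``.  State at visit t+1 is
    drawn from row state(t) of the subject's stratum matrix; every subject
    keeps at least two visits.
    """
    rng = rng or np.random.default_rng(model.seed)
    frames = []
    offset = 0
    for key in sorted(model.matrices):
        tm = model.matrices[key]
        P = tm.as_fraction(renormalize=True)
        if np.isnan(P).any():
            raise ValueError(f"ground-truth matrix for {key.label} has unobserved rows")
        cum = np.cumsum(P, axis=1)
        n = model.n_subjects[key]
        L = _retained_lengths(n, model.n_visits, model.dropout, rng)
        T = model.n_visits
        states = np.empty((n, T), dtype=np.int8)
        states[:, 0] = rng.choice(N_STATES, size=n, p=model.initial[key])
        for t in range(1, T):
            u = rng.random(n)
            states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
        lo, hi = _AGE_RANGES[key.age_group]
        base_age = np.round(rng.uniform(lo, hi, size=n), 1)
        base_year = model.start_year + rng.integers(0, model.n_years - L + 1)
        ids = np.array([f"S{offset + i:07d}" for i in range(n)])
        offset += n
        visit_idx = np.arange(T)
        mask = visit_idx[None, :] < L[:, None]
        rows, cols = np.nonzero(mask)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": ids[rows],
                    "true_stratum": key.label,
                    "sex": key.sex,
                    "baseline_age": base_age[rows],
                    "age": np.round(base_age[rows] + cols, 1),
                    "visit_year": base_year[rows] + cols,
                    "visit_index": cols,
                    "true_state": states[rows, cols].astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _component_flags(states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Component profile per record consistent with its latent state.

    Composite states pick uniformly among their valid combinations (the 6
    pairs for the two-component state; the 4 triples and the quadruple for
    MS) — downstream classification depends only on the count, so the choice
    is immaterial there.
    """
    n = len(states)
    flags = np.zeros((n, 4), dtype=bool)
    for iso, comp in zip(
        (MSState.ISO_OVERWEIGHT, MSState.ISO_HYPERTENSION, MSState.ISO_DYSLIPIDEMIA, MSState.ISO_HYPERGLYCEMIA),
        range(4),
    ):
        flags[states == iso, comp] = True
    m2 = states == MSState.TWO_COMPONENT
    flags[m2] = _PAIRS[rng.integers(0, len(_PAIRS), size=int(m2.sum()))]
    m3 = states == MSState.MS
    flags[m3] = _MS_COMBOS[rng.integers(0, len(_MS_COMBOS), size=int(m3.sum()))]
    return flags


def _uniform(rng, rng_pair, size, decimals=2):
    return np.round(rng.uniform(rng_pair[0], rng_pair[1], size=size), decimals)


def render_measurements(
    trajectories: pd.DataFrame,
    renderer: Optional[MeasurementRenderer] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Render check-up records whose CDS classification equals the latent state."""
    renderer = renderer or MeasurementRenderer()
    renderer.validate()
    rng = rng or np.random.default_rng(0)
    n = len(trajectories)
    states = trajectories["true_state"].to_numpy()
    ow, htn, dys, hg = _component_flags(states, rng).T

    out = trajectories.copy()
    out["bmi"] = np.where(ow, _uniform(rng, renderer.bmi_high, n), _uniform(rng, renderer.bmi_normal, n))

    # hypertension: pick the triggering clause per positive record
    htn_clause = rng.choice(3, size=n, p=renderer.htn_clause_probs)
    sbp = _uniform(rng, renderer.sbp_normal, n, 0)
    dbp = _uniform(rng, renderer.dbp_normal, n, 0)
    dx_htn = np.zeros(n, dtype=int)
    hi_sbp = htn & (htn_clause == 0)
    hi_dbp = htn & (htn_clause == 1)
    sbp[hi_sbp] = _uniform(rng, renderer.sbp_high, int(hi_sbp.sum()), 0)
    dbp[hi_dbp] = _uniform(rng, renderer.dbp_high, int(hi_dbp.sum()), 0)
    dx_htn[htn & (htn_clause == 2)] = 1
    out["sbp"], out["dbp"], out["dx_hypertension"] = sbp.astype(int), dbp.astype(int), dx_htn

    dys_clause = rng.choice(2, size=n, p=renderer.dys_clause_probs)
    tg = _uniform(rng, renderer.tg_normal, n)
    hdl = _uniform(rng, renderer.hdl_normal, n)
    hi_tg = dys & (dys_clause == 0)
    lo_hdl = dys & (dys_clause == 1)
    tg[hi_tg] = _uniform(rng, renderer.tg_high, int(hi_tg.sum()))
    hdl[lo_hdl] = _uniform(rng, renderer.hdl_low, int(lo_hdl.sum()))
    out["tg"], out["hdl"] = tg, hdl

    hg_clause = rng.choice(3, size=n, p=renderer.hg_clause_probs)
    fpg = _uniform(rng, renderer.fpg_normal, n)
    pg2h = np.full(n, np.nan)
    dx_hg = np.zeros(n, dtype=int)
    hi_fpg = hg & (hg_clause == 0)
    hi_pg = hg & (hg_clause == 1)
    fpg[hi_fpg] = _uniform(rng, renderer.fpg_high, int(hi_fpg.sum()))
    pg2h[hi_pg] = _uniform(rng, renderer.pg2h_high, int(hi_pg.sum()))
    dx_hg[hg & (hg_clause == 2)] = 1
    # a fraction of the remaining records carries a (normal) 2h-PG measurement
    measured = ~hi_pg & (rng.random(n) < renderer.pg2h_measured_rate)
    pg2h[measured] = _uniform(rng, renderer.pg2h_normal, int(measured.sum()))
    out["fpg"], out["pg2h"], out["dx_hyperglycemia"] = fpg, pg2h, dx_hg

    # exclusion-history flags are per subject, constant across visits
    subjects = out["subject_id"].unique()
    for col in ("hx_chd", "hx_t1dm", "hx_fam_hyperlipidemia"):
        flagged = subjects[rng.random(len(subjects)) < renderer.history_flag_rate]
        out[col] = out["subject_id"].isin(flagged).astype(int)
    return out


def simulate_cohort(
    model: GroundTruthModel, renderer: Optional[MeasurementRenderer] = None
) -> pd.DataFrame:
    """Full generator: latent trajectories plus rendered measurements.

    The returned frame carries the cohort CSV schema columns plus the latent
    ``true_state``/``true_stratum`` bookkeeping columns used by tests.  All
    randomness flows from ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    traj = sample_trajectories(model, rng)
    return render_measurements(traj, renderer, rng)


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write the cohort CSV (schema columns only, bit-stable given a seed)."""
    df = records.copy()
    for col in COHORT_COLUMNS:
        if col not in df:
            raise ValueError(f"cohort is missing column {col!r}")
    df[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def default_model(
    n_per_stratum: int = 940,
    n_visits: int = 6,
    dropout: float = 0.30,
    seed: int = 0,
    include_synthetic: bool = True,
) -> GroundTruthModel:
    """Demo ground-truth model over all 8 strata.

    Uses the five printed fixture matrices plus the three synthetic
    stand-ins.  The baseline state distribution is the matrix's stationary
    distribution pulled halfway toward the no-component state, giving a
    screening cohort healthier than the long-run mix whose MS prevalence
    rises over follow-up.  The default stratum size (940 ~ 7510/8) and
    dropout mirror the study's cohort size and mean follow-up.
    """
    from .fixtures import load_all_fixtures
    from .project import stationary_distribution

    matrices, initial, sizes = {}, {}, {}
    for name, tm in load_all_fixtures(include_synthetic=include_synthetic).items():
        key = tm.stratum
        pi = stationary_distribution(tm)
        e0 = np.zeros(N_STATES)
        e0[0] = 1.0
        init = 0.5 * pi + 0.5 * e0
        matrices[key] = tm
        initial[key] = init / init.sum()
        sizes[key] = n_per_stratum
    return GroundTruthModel(
        matrices=matrices, initial=initial, n_subjects=sizes,
        n_visits=n_visits, dropout=dropout, seed=seed,
    )
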