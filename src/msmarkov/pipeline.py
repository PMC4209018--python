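"""End-to-end pipeline: simulate -> classify -> estimate -> project -> validate -> report.

Produces a deterministic artifact bundle (given a seed) in an output
directory: the cohort and classified CSVs, per-stratum matrices (CSV for
display, JSON with full precision and provenance), tidy projection
trajectories, the validation report, a Table-1-style descriptive summary,
MS-development plots, and a run log with exclusion counts and per-stratum
event counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .classify import CdsStateClassifier
from .estimate import TransitionMatrixEstimator, descriptive_summary
from .matrices import TransitionMatrix
from .project import project, trajectories_to_frame, validate_against_empiric
from .simulate import GroundTruthModel, MeasurementRenderer, default_model, read_cohort, simulate_cohort, write_cohort
from .states import CdsThresholds, STATE_NAMES

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; echoed into the run log."""

    out_dir: str = "msmarkov_run"
    cohort_path: Optional[str] = None  # existing cohort CSV; None -> simulate
    model_path: Optional[str] = None  # ground-truth YAML; None -> packaged demo model
    seed: int = 0
    n_per_stratum: int = 940
    thresholds: dict = field(default_factory=dict)  # CDS cut-off overrides
    stratum_mode: str = "per_pair"  # or "baseline"
    averaging: str = "mean"  # or "pooled"
    projection_horizon: int = 10
    validation_horizon: int = 5
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.stratum_mode not in ("per_pair", "baseline"):
            raise ValueError(f"invalid stratum_mode {self.stratum_mode!r}")
        if self.averaging not in ("mean", "pooled"):
            raise ValueError(f"invalid averaging {self.averaging!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _dump_matrices(matrices: dict[str, TransitionMatrix], out: Path) -> None:
    mdir = out / "matrices"
    mdir.mkdir(exist_ok=True)
    payload = {}
    for label, tm in sorted(matrices.items()):
        tm.to_dataframe().round(2).to_csv(mdir / f"{label.replace('+', 'plus')}.csv")
        payload[label] = {
            "percent": np.where(np.isnan(tm.percent), None, tm.percent).tolist(),
            "row_support": tm.row_support.tolist(),
            "provenance": tm.provenance,
            "source": tm.source,
        }
    (out / "matrices.json").write_text(json.dumps(payload, indent=1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the artifact bundle; returns it in memory too."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config)}

    # --- cohort -----------------------------------------------------------
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
        log["cohort"] = {"source": config.cohort_path}
    else:
        if config.model_path:
            model = GroundTruthModel.from_yaml(config.model_path)
            model.seed = config.seed
        else:
            model = default_model(n_per_stratum=config.n_per_stratum, seed=config.seed)
        renderer = MeasurementRenderer(history_flag_rate=0.01)
        cohort = simulate_cohort(model, renderer)
        log["cohort"] = {"source": "simulated", "n_subjects": int(cohort["subject_id"].nunique())}
    write_cohort(cohort, out / "cohort.csv")

    # --- classification ---------------------------------------------------
    thresholds = CdsThresholds(**config.thresholds) if config.thresholds else None
    clf = CdsStateClassifier(thresholds=thresholds)
    classified = clf.fit_transform(cohort)
    classified.to_csv(out / "classified.csv", index=False)
    log["exclusions"] = clf.exclusion_log_

    # --- estimation -------------------------------------------------------
    est = TransitionMatrixEstimator(averaging=config.averaging, stratum_mode=config.stratum_mode)
    est.fit(classified)
    _dump_matrices(est.matrices_, out)
    log["n_transition_events"] = est.n_events_
    log["events_per_stratum_year"] = {
        f"{c.stratum}:{c.year_from}": int(c.counts.sum()) for c in est.counts_
    }

    # --- projection -------------------------------------------------------
    all_traj = []
    skipped = []
    for label, tm in sorted(est.matrices_.items()):
        for start in range(len(STATE_NAMES)):
            try:
                all_traj.append(project(tm, start, config.projection_horizon))
            except ValueError:
                skipped.append(f"{label}:{STATE_NAMES[start]}")
    traj_frame = trajectories_to_frame(all_traj)
    traj_frame.to_csv(out / "trajectories.csv", index=False)
    log["projection_skipped"] = skipped

    # --- validation & description ----------------------------------------
    validation = validate_against_empiric(est.matrices_, classified, horizon=config.validation_horizon)
    validation.to_csv(out / "validation.csv", index=False)
    summary = descriptive_summary(classified)
    summary.to_csv(out / "summary.csv", index=False)

    if config.make_plots:
        from .plots import plot_ms_development

        pdir = out / "plots"
        pdir.mkdir(exist_ok=True)
        for label in sorted(est.matrices_):
            sub = [t for t in all_traj if t.stratum == label]
            if sub:
                plot_ms_development(sub, f"Projected MS development — {label}",
                                    pdir / f"ms_{label.replace('+', 'plus')}.png")

    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return {
        "cohort": cohort,
        "classified": classified,
        "matrices": est.matrices_,
        "trajectories": all_traj,
        "validation": validation,
        "summary": summary,
        "log": log,
    }


def render_report(bundle_dir) -> str:
    """Render a human-readable Markdown report from a saved bundle.

    Every number in the report is read back from the bundle files — no
    report-only computation — so regenerating from the same bundle is
    byte-identical.
    """
    out = Path(bundle_dir)
    log = json.loads((out / "run_log.json").read_text())
    matrices = json.loads((out / "matrices.json").read_text())
    summary = pd.read_csv(out / "summary.csv")
    validation = pd.read_csv(out / "validation.csv")

    lines = ["# Metabolic-syndrome Markov pipeline report", ""]
    lines += ["## Run configuration", "", "```json", json.dumps(log["config"], indent=1), "```", ""]
    if log.get("exclusions"):
        lines += ["## Exclusions", ""]
        for reason, n in log["exclusions"].items():
            lines.append(f"- {reason}: {n}")
        lines.append("")
    lines += ["## Cohort description by follow-up year", "", summary.round(2).to_markdown(index=False), ""]
    lines += ["## Annual transition matrices (%)", ""]
    for label, entry in sorted(matrices.items()):
        lines.append(f"### {label} ({entry['provenance']})")
        arr = np.array([[np.nan if v is None else v for v in row] for row in entry["percent"]])
        if np.isnan(arr).all():
            lines += ["", "_insufficient data_", ""]
            continue
        df = pd.DataFrame(arr, index=STATE_NAMES, columns=STATE_NAMES)
        lines += ["", df.round(2).to_markdown(), ""]
    lines += ["## Validation at the 5-year horizon", "",
              validation.round(2).to_markdown(index=False), ""]
    report = "\n".join(lines)
    (out / "report.md").write_text(report)
    return report
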