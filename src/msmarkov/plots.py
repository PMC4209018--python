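"""Figure-style plots: MS occupancy versus cycle for each starting state."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .project import ProjectionTrajectory
from .states import STATE_NAMES

__all__ = ["plot_ms_development"]

_STYLE = {
    "no_component": ("#1f77b4", "-"),
    "iso_overweight": ("#ff7f0e", "-"),
    "iso_hypertension": ("#2ca02c", "-"),
    "iso_dyslipidemia": ("#d62728", "-"),
    "iso_hyperglycemia": ("#9467bd", "-"),
    "two_component": ("#8c564b", "--"),
    "ms": ("#7f7f7f", ":"),
}


def plot_ms_development(trajectories: list[ProjectionTrajectory], title: str, path) -> None:
    """Line plot of projected MS occupancy (%) per cycle, one line per starting state.

    Mirrors the study's figures, which plot the six non-MS starting states;
    an MS start is drawn dotted for reference when present.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for traj in trajectories:
        start_idx = int(traj.start.argmax())
        name = STATE_NAMES[start_idx]
        color, ls = _STYLE[name]
        ax.plot(range(traj.cycles + 1), traj.ms_curve(), color=color, linestyle=ls,
                label=name.replace("_", " "))
    ax.set_xlabel("cycle (years)")
    ax.set_ylabel("MS occupancy (%)")
    ax.set_title(title)
    ax.set_ylim(0, 100)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
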