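"""The annual transition-matrix container shared by estimation, fixtures and projection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .states import N_STATES, STATE_NAMES, StratumKey

__all__ = ["TransitionMatrix", "ROW_SUM_TOL"]

#: Printed tables round to 2 decimals, so a 7-entry row can drift from 100 by
#: up to 7 * 0.005; estimated rows are exact.  Anything worse is a data error.
ROW_SUM_TOL = 0.05


@dataclass
class TransitionMatrix:
    """A 7x7 annual transition matrix in percent, with provenance.

    Rows follow the fixed state order (no component, four isolated states,
    two-component, MS).  A row that was never observed is stored as NaN and
    flagged by :meth:`observed_rows`; projecting through such a row is an
    error downstream.

    Attributes
    ----------
    percent
        7x7 float array of transition probabilities in percent.
    stratum
        The sex x age-group cell the matrix belongs to, when known.
    row_support
        Per-row count of annual (year-pair) rate estimates that contributed.
        Fixture matrices use the study's 5 year-pairs.
    provenance
        ``"estimated"``, ``"fixture"`` (printed study table) or
        ``"synthetic"`` (constructed stand-in).
    """

    percent: np.ndarray
    stratum: Optional[StratumKey] = None
    row_support: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES, dtype=int))
    provenance: str = "estimated"
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if self.percent.shape != (N_STATES, N_STATES):
            raise ValueError(f"matrix must be {N_STATES}x{N_STATES}, got {self.percent.shape}")
        self.row_support = np.asarray(self.row_support, dtype=int)
        self.validate()

    def observed_rows(self) -> np.ndarray:
        """Boolean mask of rows carrying data (no NaN)."""
        return ~np.isnan(self.percent).any(axis=1)

    def validate(self, tol: float = ROW_SUM_TOL) -> None:
        """Check non-negativity and row sums of 100 (percent) on observed rows."""
        obs = self.observed_rows()
        block = self.percent[obs]
        if (block < 0).any():
            i = int(np.argwhere((self.percent < 0).any(axis=1))[0, 0])
            raise ValueError(f"negative transition probability in row {i} ({STATE_NAMES[i]})")
        sums = block.sum(axis=1)
        bad = np.abs(sums - 100.0) > tol
        if bad.any():
            rows = np.flatnonzero(obs)[bad]
            i = int(rows[0])
            raise ValueError(
                f"row {i} ({STATE_NAMES[i]}) sums to {self.percent[i].sum():.4f}%, not 100%"
            )

    def as_fraction(self, renormalize: bool = True) -> np.ndarray:
        """Return the matrix on the probability scale.

        With ``renormalize`` (default) each observed row is divided by its own
        sum so rows are exactly stochastic — required for multi-cycle
        propagation.  Without it, printed rows are used verbatim (percent/100)
        so a one-cycle read-out reproduces the printed cells bit-for-bit.
        """
        p = self.percent / 100.0
        if renormalize:
            sums = np.nansum(p, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(sums > 0, p / sums, p)
        return p

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent, index=STATE_NAMES, columns=STATE_NAMES)

    def round_trip_label(self) -> str:
        lbl = self.stratum.label if self.stratum else "unstratified"
        return f"{lbl} ({self.provenance})"
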