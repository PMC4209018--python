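"""Core domain vocabulary: the 7-state space, CDS thresholds and sex/age strata.

The model classifies each subject-visit into one of seven mutually exclusive,
collectively exhaustive metabolic states built from four binary risk
components (overweight/obesity, hypertension, dyslipidemia, hyperglycemia):
no component, four isolated single-component states, an any-two-component
state, and metabolic syndrome (>= 3 components).  The integer values of
:class:`MSState` fix the row/column order used by every matrix in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import IntEnum

import numpy as np

__all__ = [
    "MSState",
    "N_STATES",
    "STATE_NAMES",
    "COMPONENTS",
    "CdsThresholds",
    "StratumKey",
    "AGE_GROUPS",
    "AGE_EDGES",
    "SEXES",
    "age_group_of",
    "profile_to_state",
]

N_STATES = 7

#: The four metabolic risk components, in the order used throughout.
COMPONENTS = ("overweight", "hypertension", "dyslipidemia", "hyperglycemia")


class MSState(IntEnum):
    """The 7 metabolic states; integer value = matrix row/column index."""

    NO_COMPONENT = 0
    ISO_OVERWEIGHT = 1
    ISO_HYPERTENSION = 2
    ISO_DYSLIPIDEMIA = 3
    ISO_HYPERGLYCEMIA = 4
    TWO_COMPONENT = 5
    MS = 6


STATE_NAMES = tuple(s.name.lower() for s in MSState)


@dataclass(frozen=True)
class CdsThresholds:
    """Diagnostic cut-offs of the CDS (Chinese Diabetes Society) criteria.

    A component is present when the record satisfies any clause of its rule:

    * overweight/obesity: BMI >= ``bmi`` (kg/m^2)
    * hypertension: SBP >= ``sbp`` (mmHg) or DBP >= ``dbp`` (mmHg) or a
      prior hypertension diagnosis
    * dyslipidemia: TG >= ``tg`` (mmol/L) or HDL < ``hdl`` (mmol/L)
    * hyperglycemia: FPG >= ``fpg`` (mmol/L) or 2-h post-meal glucose >=
      ``pg2h`` (mmol/L, when measured) or a prior hyperglycemia diagnosis

    Boundary semantics follow the printed inequalities exactly: ``>=`` for
    every cut except HDL, which uses strict ``<``.
    """

    bmi: float = 25.0
    sbp: float = 140.0
    dbp: float = 90.0
    tg: float = 1.7
    hdl: float = 0.9
    fpg: float = 6.1
    pg2h: float = 7.8

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"threshold {f.name!r} must be positive, got {v!r}")


SEXES = ("M", "F")

#: Half-open age partition [18,40), [40,50), [50,60), [60,inf).
AGE_EDGES = (18.0, 40.0, 50.0, 60.0)
AGE_GROUPS = ("18-40", "40-49", "50-59", "60+")


@dataclass(frozen=True, order=True)
class StratumKey:
    """One sex x age-group cell; a single transition matrix is estimated per cell."""

    sex: str
    age_group: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}")

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.age_group}"


def age_group_of(age):
    """Map age(s) to age-group labels via the half-open partition.

    Accepts a scalar or array; ages below 18 map to ``None`` / ``''`` and are
    expected to be excluded upstream.
    """
    arr = np.asarray(age, dtype=float)
    idx = np.digitize(arr, AGE_EDGES) - 1  # -1 for age<18
    labels = np.array([""] + list(AGE_GROUPS))
    out = labels[idx + 1]
    if np.isscalar(age) or arr.ndim == 0:
        s = str(out)
        return s if s else None
    return out


_ISOLATED = (
    MSState.ISO_OVERWEIGHT,
    MSState.ISO_HYPERTENSION,
    MSState.ISO_DYSLIPIDEMIA,
    MSState.ISO_HYPERGLYCEMIA,
)


def profile_to_state(overweight, hypertension, dyslipidemia, hyperglycemia) -> MSState:
    """Classify a 4-bool component profile into one of the 7 states.

    Total on all 16 profiles: 0 components -> NO_COMPONENT, exactly one ->
    the matching isolated state, exactly two -> TWO_COMPONENT, three or four
    -> MS.
    """
    profile = (bool(overweight), bool(hypertension), bool(dyslipidemia), bool(hyperglycemia))
    n = sum(profile)
    if n == 0:
        return MSState.NO_COMPONENT
    if n == 1:
        return _ISOLATED[profile.index(True)]
    if n == 2:
        return MSState.TWO_COMPONENT
    return MSState.MS
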