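"""Packaged transition-matrix fixtures.

Five matrices are the study's printed per-stratum tables (men/women 18-40
and 40-49, men 50-59).  The remaining three strata (women 50-59, men >=60,
women >=60) ship as clearly-labelled synthetic stand-ins constructed from
adjacent printed strata, because the study published those tables only in a
supplement; they let the full 8-stratum pipeline run but are not study
estimates.

Fixtures are addressed by stratum label (``"men_18-40"``) or by table alias
(``"table2"`` .. ``"table6"``).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .matrices import TransitionMatrix
from .states import N_STATES, StratumKey

__all__ = [
    "PRINTED_FIXTURES",
    "SYNTHETIC_FIXTURES",
    "TABLE_ALIASES",
    "available_fixtures",
    "load_fixture_matrix",
    "load_all_fixtures",
]

TABLE_ALIASES = {
    "table2": "men_18-40",
    "table3": "women_18-40",
    "table4": "men_40-49",
    "table5": "women_40-49",
    "table6": "men_50-59",
}

PRINTED_FIXTURES = tuple(TABLE_ALIASES.values())
SYNTHETIC_FIXTURES = ("women_50-59", "men_60+", "women_60+")


def _load_yaml(name: str) -> dict:
    with resources.files("msmarkov.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _catalog() -> dict:
    cat = {}
    for fname, prov in (
        ("printed_matrices.yaml", "fixture"),
        ("synthetic_standin_matrices.yaml", "synthetic"),
    ):
        for key, entry in _load_yaml(fname).items():
            cat[key] = (entry, prov)
    return cat


def available_fixtures() -> tuple[str, ...]:
    """Stratum labels of all packaged fixtures (printed first, then synthetic)."""
    return PRINTED_FIXTURES + SYNTHETIC_FIXTURES


def load_fixture_matrix(name: str) -> TransitionMatrix:
    """Load one packaged matrix by stratum label or ``tableN`` alias.

    Printed cells are preserved verbatim in ``.percent``; renormalization to
    exact stochasticity happens only in :meth:`TransitionMatrix.as_fraction`.
    """
    key = TABLE_ALIASES.get(name.removeprefix("fixture:"), name.removeprefix("fixture:"))
    cat = _catalog()
    if key not in cat:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(cat)}")
    entry, provenance = cat[key]
    return TransitionMatrix(
        percent=np.asarray(entry["matrix_percent"], dtype=float),
        stratum=StratumKey(sex=entry["sex"], age_group=entry["age_group"]),
        row_support=np.full(N_STATES, 5, dtype=int),
        provenance=provenance,
        source=entry["source"],
    )


def load_all_fixtures(include_synthetic: bool = True) -> dict[str, TransitionMatrix]:
    names = available_fixtures() if include_synthetic else PRINTED_FIXTURES
    return {n: load_fixture_matrix(n) for n in names}
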