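"""Published reference tables of DE proportions for the replication grid.

Six small CSV fixtures ship with the package, one per (DV type, IV
distribution) pair, in the same long schema the simulator writes.  They are
the values the comparison harness (and the acceptance checks) measure
against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["REFERENCE_TABLES", "reference_table_names", "load_reference_table"]

#: Canonical fixture names with their table-number aliases.
REFERENCE_TABLES = {
    "continuous_uniform": "table1",
    "continuous_skewed": "table2",
    "balanced_uniform": "table3",
    "imbalanced_uniform": "table4",
    "balanced_skewed": "table5",
    "imbalanced_skewed": "table6",
}

_ALIASES = {alias: name for name, alias in REFERENCE_TABLES.items()}


def reference_table_names() -> list[str]:
    return sorted(REFERENCE_TABLES)


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one reference table by canonical name or ``tableN`` alias."""
    canonical = _ALIASES.get(name, name)
    if canonical not in REFERENCE_TABLES:
        valid = ", ".join(sorted(REFERENCE_TABLES) + sorted(_ALIASES))
        raise KeyError(f"unknown reference table {name!r}; valid names: {valid}")
    path = resources.files("nnde").joinpath("reference", f"{canonical}.csv")
    with resources.as_file(path) as file_path:
        return pd.read_csv(file_path)
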