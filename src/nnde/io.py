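"""Result-table IO: CSV in the documented long schema, bit-faithful round trips."""

from __future__ import annotations

import pandas as pd

from .montecarlo import RESULT_COLUMNS

__all__ = ["write_results", "read_results"]

_DTYPES = {
    "sample_size": "int64",
    "n_iv": "int64",
    "criterion_threshold": "float64",
    "reps": "int64",
    "excluded": "int64",
    "de_count": "int64",
    "de_proportion": "float64",
}


def write_results(results: pd.DataFrame, path) -> None:
    """Write the results table as CSV at full float precision (repr round-trip)."""
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table is missing columns {missing}")
    try:
        results[RESULT_COLUMNS].to_csv(path, index=False, float_format=None)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read results from {path}: {exc}") from exc
    return frame.astype({k: v for k, v in _DTYPES.items() if k in frame.columns})
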