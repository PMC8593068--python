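"""Reading and writing the flat trial-data CSV.

The table is one row per clinician-round with a fixed header; the reader
validates every invariant it can check locally and reports offending
1-based file line numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrialDataParseError
from .simulate import ARMS, COLUMNS, CONDITIONS, CONTROL, NETWORK, OPTIONS


def write_trial_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write the trial-data table with the canonical header."""
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise TrialDataParseError(f"records table lacks column(s) {missing}")
    records[COLUMNS].to_csv(path, index=False)


def _lines(index: pd.Index | np.ndarray) -> list[int]:
    # +2: 1-based numbering plus the header line
    return [int(i) + 2 for i in np.asarray(index)[:20]]


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-data CSV.

    Raises :class:`TrialDataParseError` naming file line numbers for any
    malformed row; an empty table with a valid header is not an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != COLUMNS:
        raise TrialDataParseError(
            f"{path}: header mismatch; expected {COLUMNS}, got {list(raw.columns)}"
        )
    if raw.empty:
        return _typed(raw)

    def fail(mask: pd.Series, message: str) -> None:
        if mask.any():
            lines = _lines(raw.index[mask])
            raise TrialDataParseError(f"{path}: {message} (line(s) {lines})", lines)

    fail(~raw["trial_id"].str.fullmatch(r"-?\d+"), "trial_id is not an integer")
    fail(~raw["condition"].isin(CONDITIONS), "unknown condition")
    fail(~raw["arm"].isin(ARMS), "unknown arm")
    fail(raw["clinician_id"].str.len() == 0, "empty clinician_id")
    fail(~raw["round"].isin(["1", "2", "3"]), "round must be 1, 2 or 3")
    est = pd.to_numeric(raw["estimate"], errors="coerce")
    fail(est.isna(), "estimate is not a number")
    fail((est < 0) | (est > 100), "estimate outside [0,100]")
    fail(~raw["recommendation"].isin(OPTIONS), "unknown recommendation")
    fail(~raw["completed"].isin(["0", "1"]), "completed must be 0 or 1")
    pos_empty = raw["network_position"].str.len() == 0
    fail((raw["condition"] == CONTROL) & ~pos_empty, "control rows must have empty network_position")
    fail((raw["condition"] == NETWORK) & pos_empty, "network rows must have a network_position")
    fail(
        (~pos_empty) & ~raw["network_position"].str.fullmatch(r"\d+"),
        "network_position is not a non-negative integer",
    )
    dup = raw.duplicated(subset=["clinician_id", "round"], keep=False)
    fail(dup, "duplicate (clinician_id, round)")
    return _typed(raw)


def _typed(raw: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "trial_id": pd.to_numeric(raw["trial_id"]).astype(int) if len(raw) else pd.Series([], dtype=int),
            "condition": raw["condition"].astype(object),
            "arm": raw["arm"].astype(object),
            "clinician_id": raw["clinician_id"].astype(object),
            "round": pd.to_numeric(raw["round"]).astype(int) if len(raw) else pd.Series([], dtype=int),
            "estimate": pd.to_numeric(raw["estimate"]).astype(float) if len(raw) else pd.Series([], dtype=float),
            "recommendation": raw["recommendation"].astype(object),
            "network_position": pd.array(
                [int(v) if v != "" else pd.NA for v in raw["network_position"]], dtype="Int64"
            ),
            "completed": pd.to_numeric(raw["completed"]).astype(int) if len(raw) else pd.Series([], dtype=int),
        }
    )
    return out[COLUMNS]
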