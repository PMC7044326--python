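"""Canonical session table: one row per trial, CSV-backed.

All analysis modules consume this format and nothing else.  A session
table is a pandas DataFrame with the columns

    session_id    identifier (string)
    trial_index   1-based, strictly increasing within a session
    block         "repeating" | "alternating"
    category      rewarded side, −1 (left) or +1 (right)
    strength      stimulus strength s in [0, 1]
    evidence      signed stimulus evidence e = category · strength
    frame_1..N    per-frame instantaneous evidence in [−1, 1]
    response      −1 / +1, empty for invalid trials
    outcome       "correct" | "error", empty for invalid trials

plus the derived columns ``prev_response`` / ``prev_outcome`` (lag-1
within session; NaN/empty on session-initial trials).  Invalid trials
(missing response) are retained in the file but excluded from fits, as
are the trials immediately following them where history is ill-defined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "STIMULUS_COLUMNS",
    "frame_columns",
    "validate_session",
    "add_derived_columns",
    "read_session",
    "write_session",
    "read_osf_session",
]

STIMULUS_COLUMNS = ("session_id", "trial_index", "block", "category", "strength", "evidence")


def frame_columns(table: pd.DataFrame) -> list[str]:
    """Names of the frame evidence columns, in frame order."""
    cols = [c for c in table.columns if c.startswith("frame_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


class SessionValidationError(ValueError):
    """A session table violates the format's invariants."""


def validate_session(table: pd.DataFrame, require_responses: bool = False) -> pd.DataFrame:
    """Check the session-table invariants; return the table unchanged.

    Raises :class:`SessionValidationError` on missing columns,
    non-monotone trial indices, categories/responses outside {−1, +1},
    or outcomes inconsistent with ``response == category``.
    """
    missing = [c for c in STIMULUS_COLUMNS if c not in table.columns]
    if missing:
        raise SessionValidationError(f"missing required columns: {missing}")
    if not frame_columns(table):
        raise SessionValidationError("no frame_* columns present")
    for sid, sub in table.groupby("session_id", sort=False):
        idx = sub["trial_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise SessionValidationError(f"trial_index not strictly increasing in session {sid!r}")
    if not np.isin(table["category"].to_numpy(), (-1, 1)).all():
        raise SessionValidationError("category values must be -1 or +1")
    if require_responses and "response" not in table.columns:
        raise SessionValidationError("response column required")
    if "response" in table.columns:
        resp = table["response"]
        valid = resp.notna()
        if not np.isin(resp[valid].to_numpy(), (-1, 1)).all():
            raise SessionValidationError("response values must be -1 or +1")
        if "outcome" in table.columns:
            out = table.loc[valid, "outcome"]
            expected = np.where(
                resp[valid].to_numpy() == table.loc[valid, "category"].to_numpy(),
                "correct",
                "error",
            )
            mismatch = out.notna() & (out.to_numpy() != expected)
            if mismatch.any():
                raise SessionValidationError(
                    "outcome inconsistent with response == category on "
                    f"{int(mismatch.sum())} trials"
                )
    return table


def add_derived_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append within-session lag-1 ``prev_response`` / ``prev_outcome``."""
    table = table.copy()
    if "response" in table.columns:
        table["prev_response"] = table.groupby("session_id", sort=False)["response"].shift(1)
    if "outcome" in table.columns:
        table["prev_outcome"] = table.groupby("session_id", sort=False)["outcome"].shift(1)
    return table


def write_session(table: pd.DataFrame, path) -> None:
    """Write a session table as UTF-8 CSV (empty fields for missing)."""
    out = table.drop(columns=[c for c in ("prev_response", "prev_outcome") if c in table.columns])
    out.to_csv(path, index=False)


def read_session(path, validate: bool = True) -> pd.DataFrame:
    """Read a session CSV, validate and append derived columns."""
    # round_trip parsing keeps write→read lossless for float columns
    table = pd.read_csv(path, dtype={"session_id": str}, float_precision="round_trip")
    if "response" in table.columns:
        table["response"] = pd.to_numeric(table["response"], errors="coerce")
    if validate:
        validate_session(table)
    return add_derived_columns(table)


def read_osf_session(path):  # pragma: no cover - extension point
    """Adapter for the publicly deposited behavioral data (not implemented).

    The public deposit's column naming is not standardized here; mapping
    it onto the canonical session format is a documented extension
    point, not required by any analysis in this package.
    """
    raise NotImplementedError(
        "mapping of the public data deposit onto the session format is an "
        "extension point; supply a canonical session CSV instead"
    )
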