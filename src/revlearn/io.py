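"""Readers and writers for trial tables and fit tables.

File dialect: comma-delimited UTF-8 with a header row; missing values
(chosen/outcome on lost trials) are empty strings; booleans are written as
0/1. The trial-table header is the bit-exact contract
``subject,condition,block,trial,sym_left,sym_right,chosen,outcome,lost``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agents import TRIAL_COLUMNS
from .exceptions import DataError, SchemaError
from .fitting import FIT_COLUMNS
from .task import TrialSchedule


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table (core columns only; hp_symbol is schedule-side)."""
    out = trials[TRIAL_COLUMNS].copy()
    out["lost"] = out["lost"].astype(int)
    for col in ("chosen", "outcome"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table.

    Checks the header for the exact required columns and every row for
    integrity: a lost trial has empty chosen/outcome; otherwise the chosen
    symbol must be one of the shown pair and the outcome must be 0 or 1.
    Violations report the offending file line (header = line 1).
    """
    df = pd.read_csv(path, dtype={"subject": str, "condition": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial file {path} missing column(s): {', '.join(missing)}")

    for col in ("chosen", "outcome"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["lost"] = df["lost"].astype(bool)

    lost = df["lost"].to_numpy()
    chosen = df["chosen"].to_numpy(dtype=float)
    outcome = df["outcome"].to_numpy(dtype=float)
    s_left = df["sym_left"].to_numpy(dtype=float)
    s_right = df["sym_right"].to_numpy(dtype=float)

    bad = np.zeros(len(df), dtype=bool)
    bad |= lost & (~np.isnan(chosen) | ~np.isnan(outcome))
    ok = ~lost
    bad |= ok & (np.isnan(chosen) | np.isnan(outcome))
    bad |= ok & ~np.isnan(chosen) & (chosen != s_left) & (chosen != s_right)
    bad |= ok & ~np.isnan(outcome) & ~np.isin(outcome, (0.0, 1.0))
    if bad.any():
        row = int(np.nonzero(bad)[0][0])
        raise DataError(
            f"trial file {path}, line {row + 2}: integrity violation "
            "(lost trials must have empty chosen/outcome; otherwise chosen must be "
            "one of the shown pair and outcome 0/1)")
    return df


def attach_schedule_info(trials: pd.DataFrame,
                         schedules: dict[tuple, TrialSchedule]) -> pd.DataFrame:
    """Merge ``hp_symbol`` into a loaded trial table.

    ``schedules`` is keyed by ``(subject, condition)``; each schedule is
    matched on (block, trial).
    """
    frames = []
    for (subject, condition), sess in trials.groupby(["subject", "condition"], sort=False):
        key = (subject, condition)
        if key not in schedules:
            raise DataError(f"no schedule supplied for session {key}")
        sched = schedules[key].table[["block", "trial", "hp_symbol"]]
        merged = sess.drop(columns=["hp_symbol"], errors="ignore").merge(
            sched, on=["block", "trial"], how="left", validate="one_to_one")
        if merged["hp_symbol"].isna().any():
            raise DataError(f"session {key}: trials not covered by the schedule")
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


def write_fits(fits: pd.DataFrame, path) -> None:
    """Write a fit table with the canonical column layout."""
    out = fits[FIT_COLUMNS].copy()
    out["converged"] = out["converged"].astype(int)
    out.to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"fit file {path} missing column(s): {', '.join(missing)}")
    df["converged"] = df["converged"].astype(bool)
    return df
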