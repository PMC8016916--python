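"""Trial-table and trajectory persistence.

Trial-level scalar results go to a CSV with one row per trial; cursor
trajectories go to a separate long-format CSV (``trial_id, t_ms, x_px,
y_px``), the same schema as empirical 125 Hz cursor logs, so recorded
human trajectories can be classified without conversion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import RESULT_COLUMNS

_BOOL_COLS = ["early", "miss", "perceptual_correct",
              "colour_correct_initial", "colour_correct_final"]
_INT_COLS = ["direction", "chosen_colour", "first_choice", "final_choice", "n_events"]

TRAJECTORY_COLUMNS = ["trial_id", "t_ms", "x_px", "y_px"]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the scalar fields of a trial table as CSV."""
    if len(df) == 0:
        raise ValueError("refusing to write an empty trial table")
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path)
    for c in _BOOL_COLS:
        if c in df.columns:
            df[c] = df[c].astype(bool)
    for c in _INT_COLS:
        if c in df.columns:
            df[c] = df[c].astype(int)
    return df


def write_trajectories(df: pd.DataFrame, path) -> None:
    """Write recorded trajectories in long format (one row per sample)."""
    if "trajectory" not in df.columns:
        raise ValueError("trial table carries no trajectories; simulate with record=True")
    frames = []
    for trial_id, traj in enumerate(df["trajectory"]):
        traj = np.asarray(traj)
        if traj.size == 0:
            continue
        frames.append(pd.DataFrame({
            "trial_id": trial_id,
            "t_ms": traj[:, 0],
            "x_px": traj[:, 1],
            "y_px": traj[:, 2],
        }))
    if not frames:
        raise ValueError("no non-empty trajectories to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> dict[int, np.ndarray]:
    """Read a long-format trajectory CSV into per-trial (t, x, y) arrays."""
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns {sorted(missing)}")
    out = {}
    for trial_id, grp in df.groupby("trial_id"):
        grp = grp.sort_values("t_ms")
        out[int(trial_id)] = grp[["t_ms", "x_px", "y_px"]].to_numpy(dtype=float)
    return out
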