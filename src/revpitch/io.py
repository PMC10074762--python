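"""Tabular serialization of sessions, kernels and reports.

Session-log CSV schema (one row per trial):
    participant_id, group, condition, trial_index,
    a_bp_1..a_bp_K, b_bp_1..b_bp_K, choice
Kernel CSV schema (one row per participant-condition):
    participant_id, condition, k_1..k_K
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .contour_noise import ContourStimulus, SessionLog, TrialRecord
from .kernels import Kernel

__all__ = ["sessions_to_frame", "frame_to_sessions", "save_sessions",
           "load_sessions", "save_kernels", "load_kernels"]


def sessions_to_frame(sessions: list[SessionLog]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            k = len(t.stim_a.shifts)
            row = {"participant_id": s.participant_id, "group": s.group,
                   "condition": s.condition, "trial_index": t.trial_index}
            row.update({f"a_bp_{j + 1}": t.stim_a.shifts[j] for j in range(k)})
            row.update({f"b_bp_{j + 1}": t.stim_b.shifts[j] for j in range(k)})
            row["choice"] = t.choice
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_sessions(df: pd.DataFrame) -> list[SessionLog]:
    all_a = sorted((c for c in df.columns if c.startswith("a_bp_")),
                   key=lambda c: int(c.rsplit("_", 1)[1]))
    all_b = sorted((c for c in df.columns if c.startswith("b_bp_")),
                   key=lambda c: int(c.rsplit("_", 1)[1]))
    if not all_a or len(all_a) != len(all_b):
        raise ValueError("malformed session table: breakpoint columns missing")
    sessions = []
    for (pid, cond), block in df.groupby(["participant_id", "condition"], sort=False):
        block = block.sort_values("trial_index")
        # conditions with fewer breakpoints leave trailing columns empty
        a_cols = [c for c in all_a if block[c].notna().all()]
        b_cols = [c for c in all_b if block[c].notna().all()]
        if len(a_cols) != len(b_cols) or not a_cols:
            raise ValueError(f"inconsistent breakpoint columns for {pid}/{cond}")
        idx = block["trial_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError(f"trial_index not 1..n for {pid}/{cond}")
        group = str(block["group"].iloc[0])
        trials = []
        for _, r in block.iterrows():
            i = int(r["trial_index"])
            a = ContourStimulus(f"{pid}_{cond}_{i}a",
                                np.array([r[c] for c in a_cols]), str(cond))
            b = ContourStimulus(f"{pid}_{cond}_{i}b",
                                np.array([r[c] for c in b_cols]), str(cond))
            choice = str(r["choice"])
            if choice not in ("A", "B"):
                raise ValueError(f"invalid choice {choice!r}")
            trials.append(TrialRecord(trial_index=i, stim_a=a, stim_b=b,
                                      choice=choice))
        sessions.append(SessionLog(participant_id=str(pid), group=group,
                                   condition=str(cond), trials=trials))
    return sessions


def save_sessions(sessions: list[SessionLog], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def load_sessions(path: str | Path) -> list[SessionLog]:
    return frame_to_sessions(pd.read_csv(path))


def save_kernels(kernels: list[Kernel], path: str | Path) -> None:
    rows = []
    for k in kernels:
        row = {"participant_id": k.participant_id, "condition": k.condition}
        row.update({f"k_{j + 1}": k.values[j] for j in range(len(k.values))})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_kernels(path: str | Path) -> list[Kernel]:
    df = pd.read_csv(path)
    k_cols = sorted((c for c in df.columns if c.startswith("k_")),
                    key=lambda c: int(c.split("_")[1]))
    out = []
    for _, r in df.iterrows():
        vals = np.array([r[c] for c in k_cols if not pd.isna(r[c])])
        out.append(Kernel(values=vals, n_trials=0,
                          condition=str(r["condition"]),
                          participant_id=str(r["participant_id"])))
    return out
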