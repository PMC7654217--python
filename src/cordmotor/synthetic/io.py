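"""On-disk containers for synthetic fixtures.

EMG sessions are stored as HDF5 (datasets ``signals`` [channels x
samples], ``stim_times``, ``stim_intensities``, ``attempt_windows``;
attrs ``fs``, ``channel_names``, tasks) with a documented CSV fallback
(long format: time, channel, value; events and windows in a JSON
sidecar). Cohorts are CSV with ``mri_*``/``motor_*`` column naming and
a YAML sidecar declaring per-column families. Datasets are written with
``track_times=False`` so identical content yields identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from cordmotor.emg import AttemptWindow, EMGSession

__all__ = [
    "save_emg_session",
    "load_emg_session",
    "save_emg_session_csv",
    "load_emg_session_csv",
    "save_cohort",
    "load_cohort",
]


def _windows_array(windows: list[AttemptWindow]) -> np.ndarray:
    rows = []
    for w in windows:
        bg = w.background or (np.nan, np.nan)
        rows.append([w.start, w.end, bg[0], bg[1]])
    return np.asarray(rows, dtype=float).reshape(-1, 4)


def save_emg_session(session: EMGSession, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=session.signals, track_times=False)
        f.create_dataset(
            "stim_times",
            data=np.array([t for t, _ in session.stim_events], dtype=float),
            track_times=False,
        )
        f.create_dataset(
            "stim_intensities",
            data=np.array([i for _, i in session.stim_events], dtype=float),
            track_times=False,
        )
        f.create_dataset(
            "attempt_windows", data=_windows_array(session.attempt_windows), track_times=False
        )
        f.attrs["fs"] = session.fs
        f.attrs["channel_names"] = session.channel_names
        f.attrs["tasks"] = [w.task for w in session.attempt_windows]
        f.attrs["subject_id"] = session.subject_id


def load_emg_session(path) -> EMGSession:
    with h5py.File(path, "r") as f:
        signals = f["signals"][()]
        stim_times = f["stim_times"][()]
        stim_int = f["stim_intensities"][()]
        win = f["attempt_windows"][()]
        fs = float(f.attrs["fs"])
        channels = [str(c) for c in f.attrs["channel_names"]]
        tasks = [str(t) for t in f.attrs["tasks"]]
        subject = str(f.attrs.get("subject_id", ""))
    windows = []
    for k, (a0, a1, b0, b1) in enumerate(win):
        bg = None if np.isnan(b0) else (float(b0), float(b1))
        task = tasks[k] if k < len(tasks) else ""
        windows.append(AttemptWindow(float(a0), float(a1), task, bg))
    return EMGSession(
        signals=signals,
        fs=fs,
        channel_names=channels,
        stim_events=[(float(t), float(i)) for t, i in zip(stim_times, stim_int)],
        attempt_windows=windows,
        subject_id=subject,
    )


def save_emg_session_csv(session: EMGSession, csv_path, sidecar_path=None) -> None:
    """CSV fallback: long table (time, channel, value) + JSON event sidecar."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    n = session.signals.shape[1]
    t = np.arange(n) / session.fs
    frames = [
        pd.DataFrame({"time": t, "channel": ch, "value": session.signals[i]})
        for i, ch in enumerate(session.channel_names)
    ]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    meta = {
        "fs": session.fs,
        "subject_id": session.subject_id,
        "channel_names": session.channel_names,
        "stim_events": [[t0, i0] for t0, i0 in session.stim_events],
        "attempt_windows": [
            {
                "start": w.start,
                "end": w.end,
                "task": w.task,
                "background": list(w.background) if w.background else None,
            }
            for w in session.attempt_windows
        ],
    }
    sidecar_path.write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_emg_session_csv(csv_path, sidecar_path=None) -> EMGSession:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    long = pd.read_csv(csv_path)
    channels = meta["channel_names"]
    signals = np.vstack(
        [long.loc[long["channel"] == ch, "value"].to_numpy() for ch in channels]
    )
    windows = [
        AttemptWindow(
            w["start"], w["end"], w.get("task", ""),
            tuple(w["background"]) if w.get("background") else None,
        )
        for w in meta["attempt_windows"]
    ]
    return EMGSession(
        signals=signals,
        fs=float(meta["fs"]),
        channel_names=list(channels),
        stim_events=[(float(t), float(i)) for t, i in meta["stim_events"]],
        attempt_windows=windows,
        subject_id=meta.get("subject_id", ""),
    )


def save_cohort(table: pd.DataFrame, families: dict[str, str], csv_path, sidecar_path=None) -> None:
    """Cohort CSV plus YAML sidecar mapping motor columns to families."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".families.yaml")
    table.to_csv(csv_path, index=False)
    sidecar_path.write_text(yaml.safe_dump({"families": families}, sort_keys=True))


def load_cohort(csv_path, sidecar_path=None) -> tuple[pd.DataFrame, dict[str, str]]:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".families.yaml")
    table = pd.read_csv(csv_path)
    families = {}
    if sidecar_path.exists():
        families = yaml.safe_load(sidecar_path.read_text()).get("families", {})
    return table, families
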