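"""File formats: HDF5 for trajectories and recordings, CSV/JSON for event
tables.  All round-trips are lossless; times are serialized in seconds
(frames and samples are derived quantities)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import ContinuousRecording
from .topology import EVENT_COLUMNS
from .trajectory import TrialTrajectory

__all__ = [
    "write_trials",
    "read_trials",
    "write_event_table",
    "read_event_table",
    "write_recording",
    "read_recording",
]


def write_trials(path, trials: list[TrialTrajectory]) -> None:
    """One HDF5 group per trial: positions plus frame_rate / target_ids /
    match_condition attributes."""
    with h5py.File(path, "w") as f:
        for t in trials:
            g = f.create_group(f"trial_{t.trial_id:05d}")
            g.create_dataset("positions", data=t.positions, track_times=False)
            g.attrs["frame_rate"] = t.frame_rate
            g.attrs["target_ids"] = np.asarray(t.target_ids, dtype=int)
            g.attrs["trial_id"] = int(t.trial_id)
            g.attrs["match_condition"] = int(t.match_condition)


def read_trials(path) -> list[TrialTrajectory]:
    trials = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            trials.append(
                TrialTrajectory(
                    positions=g["positions"][()],
                    frame_rate=float(g.attrs["frame_rate"]),
                    target_ids=np.asarray(g.attrs["target_ids"], dtype=int),
                    trial_id=int(g.attrs["trial_id"]),
                    match_condition=int(g.attrs["match_condition"]),
                )
            )
    return trials


def trials_to_frame(trials: list[TrialTrajectory]) -> pd.DataFrame:
    """Long-format positions (trial, frame, item, x, y)."""
    rows = []
    for t in trials:
        n_items, n_frames, _ = t.positions.shape
        idx = np.indices((n_items, n_frames))
        rows.append(
            pd.DataFrame(
                {
                    "trial": t.trial_id,
                    "frame": idx[1].ravel(),
                    "item": idx[0].ravel(),
                    "x": t.positions[..., 0].ravel(),
                    "y": t.positions[..., 1].ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_event_table(path, events: pd.DataFrame) -> None:
    """Event table as CSV or JSON (by extension)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(events[EVENT_COLUMNS].to_dict(orient="records"), indent=1))
    else:
        events[EVENT_COLUMNS].to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()), columns=EVENT_COLUMNS)
    else:
        df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} is missing column(s): {missing}")
    return df.astype(
        {"trial_id": int, "set_label": str, "event_type": str, "time_s": float, "frame": int}
    )[EVENT_COLUMNS]


def write_recording(path, rec: ContinuousRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, track_times=False)
        f.attrs["subject_id"] = int(rec.subject_id)
        f.attrs["sampling_rate"] = float(rec.sampling_rate)
        f.attrs["trial_n_samples"] = int(rec.trial_n_samples)
        f.create_dataset("trial_onsets", data=np.asarray(rec.trial_onsets, dtype=int), track_times=False)
        f.create_dataset("trial_ids", data=np.asarray(rec.trial_ids, dtype=int), track_times=False)
        f.create_dataset(
            "ch_names",
            data=np.array(rec.ch_names, dtype=h5py.string_dtype()),
            track_times=False,
        )


def read_recording(path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        return ContinuousRecording(
            subject_id=int(f.attrs["subject_id"]),
            data=f["data"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            trial_onsets=f["trial_onsets"][()],
            trial_ids=f["trial_ids"][()],
            trial_n_samples=int(f.attrs["trial_n_samples"]),
            ch_names=tuple(s.decode() for s in f["ch_names"][()]),
        )
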