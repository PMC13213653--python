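"""On-disk formats: event logs as CSV+JSON sidecar, EEG as HDF5 or CSV.

Layout written by :func:`write_dataset` under a root directory::

    team00/game00.events.csv      tick,event rows (0-based ticks)
    team00/game00.events.json     team id, game id, tick_rate, n_ticks
    team00/game00.Shooter.h5      samples x electrodes matrix + metadata
    team00/game00.Bait.h5

Event names on disk use the upper-snake forms KILL / SHOOTER_DEATH /
BAIT_DEATH.  The HDF5 container round-trips float64 samples bit-exactly;
CSV is provided for interchange.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import pandas as pd

from .preprocess import BAIT_DEATH, KILL, SHOOTER_DEATH, EEGRecording
from .simulate import EventTimeline, GameData

__all__ = [
    "write_event_log",
    "read_event_log",
    "write_eeg_h5",
    "read_eeg_h5",
    "write_eeg_csv",
    "read_eeg_csv",
    "write_dataset",
    "read_dataset",
]

_TO_DISK = {KILL: "KILL", SHOOTER_DEATH: "SHOOTER_DEATH", BAIT_DEATH: "BAIT_DEATH"}
_FROM_DISK = {v: k for k, v in _TO_DISK.items()}


def write_event_log(path, timeline: EventTimeline) -> None:
    """Write tick/event CSV plus a JSON sidecar of game metadata."""
    path = Path(path)
    df = pd.DataFrame(
        [(t, _TO_DISK[c]) for t, c in timeline.events], columns=["tick", "event"]
    )
    df.to_csv(path, index=False)
    meta = {
        "team_id": timeline.team_id,
        "game_id": timeline.game_id,
        "tick_rate": 60.0,
        "n_ticks": timeline.n_ticks,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_event_log(path) -> EventTimeline:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    events = [(int(t), _FROM_DISK[e]) for t, e in zip(df["tick"], df["event"])]
    return EventTimeline(
        game_id=int(meta["game_id"]),
        team_id=int(meta["team_id"]),
        n_ticks=int(meta["n_ticks"]),
        events=events,
    )


def write_eeg_h5(path, rec: EEGRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("eeg", data=rec.data)
        d.attrs["electrodes"] = list(rec.electrodes)
        d.attrs["sfreq"] = rec.sfreq
        d.attrs["units"] = "uV"
        d.attrs["game_id"] = rec.game_id
        d.attrs["team_id"] = rec.team_id
        d.attrs["role"] = rec.role


def read_eeg_h5(path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        d = f["eeg"]
        return EEGRecording(
            data=d[()],
            electrodes=tuple(str(e) for e in d.attrs["electrodes"]),
            sfreq=float(d.attrs["sfreq"]),
            game_id=int(d.attrs["game_id"]),
            team_id=int(d.attrs["team_id"]),
            role=str(d.attrs["role"]),
        )


def write_eeg_csv(path, rec: EEGRecording) -> None:
    """CSV with an electrode-label header row; JSON sidecar holds rate/units."""
    path = Path(path)
    pd.DataFrame(rec.data, columns=list(rec.electrodes)).to_csv(path, index=False)
    meta = {
        "sfreq": rec.sfreq,
        "units": "uV",
        "game_id": rec.game_id,
        "team_id": rec.team_id,
        "role": rec.role,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_eeg_csv(path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    return EEGRecording(
        data=df.to_numpy(dtype=float),
        electrodes=tuple(df.columns),
        sfreq=float(meta["sfreq"]),
        game_id=int(meta["game_id"]),
        team_id=int(meta["team_id"]),
        role=str(meta["role"]),
    )


def write_dataset(root, dataset: list[GameData]) -> None:
    root = Path(root)
    for gd in dataset:
        tl = gd.timeline
        tdir = root / f"team{tl.team_id:02d}"
        tdir.mkdir(parents=True, exist_ok=True)
        stem = f"game{tl.game_id:02d}"
        write_event_log(tdir / f"{stem}.events.csv", tl)
        write_eeg_h5(tdir / f"{stem}.Shooter.h5", gd.shooter)
        write_eeg_h5(tdir / f"{stem}.Bait.h5", gd.bait)


def read_dataset(root) -> list[GameData]:
    root = Path(root)
    out: list[GameData] = []
    for log in sorted(root.glob("team*/game*.events.csv")):
        stem = log.name[: -len(".events.csv")]
        tl = read_event_log(log)
        out.append(
            GameData(
                timeline=tl,
                shooter=read_eeg_h5(log.parent / f"{stem}.Shooter.h5"),
                bait=read_eeg_h5(log.parent / f"{stem}.Bait.h5"),
            )
        )
    return out
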