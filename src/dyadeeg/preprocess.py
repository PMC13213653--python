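"""Recordings, per-game standardization, tick windows, and event epochs.

Two parallel preparation paths feed the analysis:

* the *classification* path z-scores each electrode over the whole game and
  slices a 1-s window (61 samples at 60 Hz) around every interior tick into
  a flat feature vector;
* the *ERP* path keeps the signal in microvolts and stacks event-locked
  61-sample epochs per event class for averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "KILL",
    "SHOOTER_DEATH",
    "BAIT_DEATH",
    "NULL",
    "EVENT_CLASSES",
    "TICK_CLASSES",
    "EEGRecording",
    "TickFeatureSet",
    "zscore_per_game",
    "extract_tick_vectors",
    "label_ticks",
    "extract_event_epochs",
]

KILL = "Kill"
SHOOTER_DEATH = "ShooterDeath"
BAIT_DEATH = "BaitDeath"
NULL = "Null"

#: The three critical-event classes, in canonical order.
EVENT_CLASSES: tuple[str, ...] = (KILL, SHOOTER_DEATH, BAIT_DEATH)
#: The four tick classes used for classification.
TICK_CLASSES: tuple[str, ...] = (KILL, SHOOTER_DEATH, BAIT_DEATH, NULL)

HALF_WINDOW = 30  # ticks either side of the centre tick; 61-sample window
WINDOW = 2 * HALF_WINDOW + 1


@dataclass
class EEGRecording:
    """One player's EEG for one game: samples x electrodes, in microvolts
    (or z-units after standardization), sampled at the game tick rate."""

    data: np.ndarray  # (n_samples, n_electrodes)
    electrodes: tuple[str, ...]
    sfreq: float
    game_id: int = 0
    team_id: int = 0
    role: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (samples x electrodes)")
        if self.data.shape[1] != len(self.electrodes):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.electrodes)} labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def electrode_index(self, label: str) -> int:
        try:
            return self.electrodes.index(label)  # type: ignore[union-attr]
        except ValueError:
            raise KeyError(f"electrode {label!r} not in recording") from None


@dataclass
class TickFeatureSet:
    """Per-tick flattened window vectors with optional class labels.

    Layout is electrode-major: the vector for tick *j* is the concatenation,
    electrode by electrode in recording order, of the 61 samples
    ``j-30 .. j+30``.  The same fixed layout is used for training and test.
    """

    ticks: np.ndarray          # (n,) interior tick indices
    vectors: np.ndarray        # (n, 61 * n_electrodes)
    electrodes: tuple[str, ...]
    labels: np.ndarray | None = None  # (n,) strings from TICK_CLASSES
    game_id: int = 0
    team_id: int = 0
    role: str = ""

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != self.ticks.shape[0]:
            raise ValueError("ticks and vectors misaligned")
        if self.labels is not None and len(self.labels) != len(self.ticks):
            raise ValueError("labels misaligned with ticks")


def zscore_per_game(rec: EEGRecording, *, drop_dead: bool = False) -> EEGRecording:
    """Standardize each electrode trace to mean 0, SD 1 over the whole game.

    A constant (dead) electrode raises by default; with ``drop_dead`` the
    channel is removed instead.
    """
    mean = rec.data.mean(axis=0)
    sd = rec.data.std(axis=0)
    dead = sd < 1e-12
    if np.any(dead):
        labels = [e for e, d in zip(rec.electrodes, dead) if d]
        if not drop_dead:
            raise ValueError(f"dead (constant) electrode(s): {labels}")
        keep = ~dead
        return replace(
            rec,
            data=(rec.data[:, keep] - mean[keep]) / sd[keep],
            electrodes=tuple(e for e, k in zip(rec.electrodes, keep) if k),
        )
    return replace(rec, data=(rec.data - mean) / sd)


def extract_tick_vectors(
    rec: EEGRecording, half_window_ticks: int = HALF_WINDOW, dtype=np.float32
) -> TickFeatureSet:
    """Flatten a (2h+1)-sample window around every interior tick.

    Ticks within ``half_window_ticks`` of either end of the game have no
    complete window and get no vector.
    """
    h = int(half_window_ticks)
    w = 2 * h + 1
    T = rec.n_samples
    if T < w:
        raise ValueError(f"recording of {T} samples shorter than window {w}")
    # (n_elec, T-w+1, w) windows; reorder to (tick, electrode-major flat)
    wins = sliding_window_view(rec.data.T, w, axis=1)
    vectors = np.ascontiguousarray(wins.transpose(1, 0, 2), dtype=dtype)
    vectors = vectors.reshape(T - w + 1, len(rec.electrodes) * w)
    ticks = np.arange(h, T - h)
    return TickFeatureSet(
        ticks=ticks,
        vectors=vectors,
        electrodes=tuple(rec.electrodes),
        game_id=rec.game_id,
        team_id=rec.team_id,
        role=rec.role,
    )


def label_ticks(timeline, ticks: np.ndarray) -> tuple[np.ndarray, list]:
    """Assign each tick its event class, Null elsewhere.

    Returns ``(labels, dropped)`` where ``dropped`` lists events whose tick
    is outside ``ticks`` (edge ticks with no feature vector); they are
    excluded from supervised sets.
    """
    ticks = np.asarray(ticks)
    labels = np.full(ticks.shape[0], NULL, dtype=object)
    pos = {int(t): i for i, t in enumerate(ticks)}
    seen: set[int] = set()
    dropped = []
    for tick, cls in timeline.events:
        if tick in seen:
            raise ValueError(f"duplicate event at tick {tick}")
        seen.add(tick)
        i = pos.get(int(tick))
        if i is None:
            dropped.append((int(tick), cls))
        else:
            labels[i] = cls
    return labels, dropped


def extract_event_epochs(
    rec: EEGRecording, timeline, half_window_ticks: int = HALF_WINDOW
) -> dict[str, np.ndarray]:
    """Stack event-locked epochs per class from a microvolt-scale recording.

    Returns ``{class: (n_events, 61, n_electrodes)}``; classes with no
    usable event map to an empty stack.  Events too close to the game edge
    for a full window are skipped.
    """
    h = int(half_window_ticks)
    w = 2 * h + 1
    stacks: dict[str, list[np.ndarray]] = {c: [] for c in EVENT_CLASSES}
    for tick, cls in timeline.events:
        if cls not in stacks:
            raise ValueError(f"unknown event class {cls!r}")
        if tick - h < 0 or tick + h >= rec.n_samples:
            continue
        stacks[cls].append(rec.data[tick - h : tick + h + 1, :])
    n_el = len(rec.electrodes)
    return {
        c: (np.stack(v) if v else np.empty((0, w, n_el)))
        for c, v in stacks.items()
    }
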