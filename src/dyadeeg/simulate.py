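"""Synthetic dyadic game-EEG generator.

Emulates the statistical structure of a two-player fortress game recorded
together with both players' EEG at the 60 Hz game tick rate:

* fortress *Kills* recur through the game following shifted-gamma
  inter-event intervals (the first interval, game start to first kill, is
  shorter on average than kill-to-kill intervals because the ships start
  in position);
* rare *Shooter/Bait deaths* (about 0.7 per game per role) fall strictly
  inside kill-bounded segments, their position drawn from the product of a
  start-anchored and an end-anchored duration density;
* every event evokes a P300-like positive half-cosine deflection in both
  players' EEG, largest over the midline electrodes FZ/CZ/PZ, whose
  amplitude and latency depend on role x event class (each player responds
  most strongly and earliest to the events that matter most to them);
* ongoing background activity is white or AR(1) noise with SD ~9 uV.

Everything is deterministic given a seed, so downstream stages can be
tested against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .durations import DurationModel
from .montage import CENTRAL_ELECTRODES, DEFAULT_MONTAGE, ROLES
from .preprocess import (
    BAIT_DEATH,
    EVENT_CLASSES,
    KILL,
    SHOOTER_DEATH,
    EEGRecording,
)

__all__ = [
    "GameConfig",
    "ErpTemplate",
    "DyadEEGConfig",
    "EventTimeline",
    "simulate_game_timeline",
    "simulate_dyad_eeg",
    "generate_dataset",
    "template_waveform",
]

_TICK_RATE = 60.0

# Death-timing duration models (ticks): minimum 1 s from a kill before a
# death is possible, and 1 s from a death to the next kill.
_DEATH_START = DurationModel.gamma_from_mean(mean=360.0, shape=2.0, shift=60.0)
_DEATH_END = DurationModel.gamma_from_mean(mean=360.0, shape=2.0, shift=60.0)


def _default_death_models() -> dict:
    return {
        SHOOTER_DEATH: (_DEATH_START, _DEATH_END),
        BAIT_DEATH: (_DEATH_START, _DEATH_END),
    }


@dataclass(frozen=True)
class GameConfig:
    """Event-statistics configuration for one simulated game."""

    game_length_s: float = 180.0
    tick_rate: float = _TICK_RATE
    # ticks: mean 9.9 s from game start to first kill, 12.3 s between kills
    start_to_kill: DurationModel = field(
        default_factory=lambda: DurationModel.gamma_from_mean(594.0, shape=3.0, shift=180.0)
    )
    kill_to_kill: DurationModel = field(
        default_factory=lambda: DurationModel.gamma_from_mean(738.0, shape=3.0, shift=240.0)
    )
    death_rate_per_game: float = 0.7
    death_models: dict = field(default_factory=_default_death_models)
    # probability that a Bait death is of the "shell in flight" type landing
    # just after a kill rather than drawn from the segment product density
    bait_near_kill_prob: float = 0.0
    near_kill_window: tuple[int, int] = (6, 30)  # ticks after the kill

    def __post_init__(self) -> None:
        n_ticks = self.game_length_s * self.tick_rate
        if abs(n_ticks - round(n_ticks)) > 1e-9:
            raise ValueError("game_length_s x tick_rate must be a whole tick count")
        if self.death_rate_per_game < 0:
            raise ValueError("death_rate_per_game must be >= 0")
        for m in (self.start_to_kill, self.kill_to_kill):
            if m.mean <= 0:
                raise ValueError("duration means must be positive")
        if self.start_to_kill.shift >= n_ticks:
            raise ValueError("minimum start-to-kill duration exceeds game length")

    @property
    def n_ticks(self) -> int:
        return int(round(self.game_length_s * self.tick_rate))


@dataclass(frozen=True)
class ErpTemplate:
    """Positive half-cosine ERP bump: peak ``amplitude_uv`` at
    ``latency_s`` after the event, support ``width_s`` wide."""

    amplitude_uv: float
    latency_s: float
    width_s: float = 0.3

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude_uv):
            raise ValueError("amplitude must be finite")
        if not (0.0 < self.latency_s < 0.5):
            raise ValueError("peak latency must lie in (0, 0.5) s")
        if self.width_s <= 0:
            raise ValueError("width must be positive")


def _default_templates() -> dict:
    # Role x event defaults: each role responds most strongly to its own
    # death; Shooters are more positive than Baits after Kills and Shooter
    # Deaths, less positive after Bait Deaths; Kills are registered
    # earliest by both roles, and each player registers their own death
    # earlier than their partner's.
    return {
        ("Shooter", KILL): ErpTemplate(6.0, 0.28),
        ("Shooter", SHOOTER_DEATH): ErpTemplate(10.0, 0.33),
        ("Shooter", BAIT_DEATH): ErpTemplate(6.0, 0.40),
        ("Bait", KILL): ErpTemplate(4.0, 0.32),
        ("Bait", SHOOTER_DEATH): ErpTemplate(7.0, 0.38),
        ("Bait", BAIT_DEATH): ErpTemplate(11.0, 0.35),
    }


@dataclass(frozen=True)
class DyadEEGConfig:
    """EEG-synthesis configuration shared by the two players."""

    electrodes: tuple[str, ...] = DEFAULT_MONTAGE
    noise_sd: float = 9.0          # uV
    noise_model: str = "white"     # "white" | "ar1"
    ar_coef: float = 0.95
    templates: dict = field(default_factory=_default_templates)
    central_electrodes: tuple[str, ...] = CENTRAL_ELECTRODES
    spatial_falloff: float = 0.5   # template gain off the midline
    latency_jitter_sd_s: float = 1.0 / _TICK_RATE

    def __post_init__(self) -> None:
        if self.noise_model not in ("white", "ar1"):
            raise ValueError("noise_model must be 'white' or 'ar1'")
        for label in self.central_electrodes:
            if label not in self.electrodes:
                raise ValueError(f"unknown electrode label {label!r} in template spec")

    def scaled(self, amplitude_scale: float) -> "DyadEEGConfig":
        """Copy with every template amplitude scaled (SNR sweeps)."""
        scaled = {
            k: dataclasses.replace(t, amplitude_uv=t.amplitude_uv * amplitude_scale)
            for k, t in self.templates.items()
        }
        return dataclasses.replace(self, templates=scaled)


@dataclass
class EventTimeline:
    """Tick-indexed ground-truth event record for one game."""

    game_id: int
    team_id: int
    n_ticks: int
    events: list  # ordered [(tick:int, class:str)]

    def __post_init__(self) -> None:
        self.events = sorted((int(t), c) for t, c in self.events)
        ticks = [t for t, _ in self.events]
        if ticks and (min(ticks) < 0 or max(ticks) >= self.n_ticks):
            raise ValueError("event tick outside [0, n_ticks)")
        if len(set(ticks)) != len(ticks):
            raise ValueError("two events share a tick")
        for t, c in self.events:
            if c not in EVENT_CLASSES:
                raise ValueError(f"unknown event class {c!r}")
        kt = self.kill_ticks
        if np.any(np.diff(kt) <= 0):
            raise ValueError("kill ticks must be strictly increasing")

    @property
    def kill_ticks(self) -> np.ndarray:
        return np.array([t for t, c in self.events if c == KILL], dtype=int)

    def death_ticks(self, cls: str) -> np.ndarray:
        return np.array([t for t, c in self.events if c == cls], dtype=int)

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Kill-bounded segments [(start, end)] covering the whole game:
        game start to first kill, kill to kill, last kill to game end."""
        bounds = [0, *self.kill_ticks.tolist(), self.n_ticks]
        return list(zip(bounds[:-1], bounds[1:]))


def _segment_death_weights(seg: tuple[int, int], start_m, end_m) -> tuple[np.ndarray, np.ndarray]:
    """Candidate death ticks in a segment and their unnormalized product
    density f_start(t - start) * f_end(end - t)."""
    start, end = seg
    ticks = np.arange(start + 1, end)
    if ticks.size == 0:
        return ticks, np.empty(0)
    w = np.exp(start_m.logpdf(ticks - start) + end_m.logpdf(end - ticks))
    return ticks, w


def simulate_game_timeline(config: GameConfig, rng_seed) -> EventTimeline:
    """Simulate kill and death ticks for one game.

    Kills: draw start-to-kill, then kill-to-kill durations until the game
    ends.  Deaths per role: Poisson(``death_rate_per_game``) count, at most
    one per kill-bounded segment, host segments chosen with probability
    proportional to their admissible density mass, the tick itself from the
    normalized product of the start- and end-anchored densities.
    """
    rng = np.random.default_rng(rng_seed)
    T = config.n_ticks

    kills: list[int] = []
    t = float(config.start_to_kill.rvs(rng))
    while round(t) < T:
        tick = int(round(t))
        if kills and tick <= kills[-1]:
            tick = kills[-1] + 1
        if tick >= T:
            break
        kills.append(tick)
        t = tick + float(config.kill_to_kill.rvs(rng))

    events: list[tuple[int, str]] = [(k, KILL) for k in kills]
    taken = set(kills)

    bounds = [0, *kills, T]
    segments = list(zip(bounds[:-1], bounds[1:]))

    for cls in (SHOOTER_DEATH, BAIT_DEATH):
        if config.death_rate_per_game == 0 or cls not in config.death_models:
            continue
        start_m, end_m = config.death_models[cls]
        n_deaths = rng.poisson(config.death_rate_per_game)
        if n_deaths == 0:
            continue
        cand = [_segment_death_weights(seg, start_m, end_m) for seg in segments]
        mass = np.array([w.sum() for _, w in cand])
        usable = np.flatnonzero(mass > 0)
        n_deaths = min(n_deaths, usable.size)
        if n_deaths == 0:
            continue
        p = mass[usable] / mass[usable].sum()
        chosen = rng.choice(usable, size=n_deaths, replace=False, p=p)
        for si in chosen:
            seg = segments[si]
            if cls == BAIT_DEATH and rng.random() < config.bait_near_kill_prob and seg[0] > 0:
                # shell already in flight when the fortress died: death
                # lands just after the kill, ahead of the usual minimum
                lo, hi = config.near_kill_window
                tick = seg[0] + int(rng.integers(lo, hi + 1))
                if tick >= seg[1]:
                    continue
            else:
                ticks, w = cand[si]
                tick = int(rng.choice(ticks, p=w / w.sum()))
            while tick in taken:  # avoid tick collisions across roles
                tick += 1
            if tick >= seg[1]:
                continue
            taken.add(tick)
            events.append((tick, cls))

    return EventTimeline(game_id=0, team_id=0, n_ticks=T, events=events)


def template_waveform(
    template: ErpTemplate,
    n_ticks: int,
    event_tick: int,
    tick_rate: float = _TICK_RATE,
    latency_shift_s: float = 0.0,
) -> np.ndarray:
    """Sampled half-cosine bump a single event adds to one full-gain
    electrode trace of length ``n_ticks``."""
    out = np.zeros(n_ticks)
    centre = template.latency_s + latency_shift_s
    half = template.width_s / 2.0
    lo = max(0, int(np.floor((centre - half) * tick_rate)) + event_tick)
    hi = min(n_ticks - 1, int(np.ceil((centre + half) * tick_rate)) + event_tick)
    if hi < lo:
        return out
    s = np.arange(lo, hi + 1)
    tau = (s - event_tick) / tick_rate - centre
    mask = np.abs(tau) <= half
    out[s[mask]] = template.amplitude_uv * np.cos(np.pi * tau[mask] / template.width_s)
    return out


def _noise(rng: np.random.Generator, shape, config: DyadEEGConfig) -> np.ndarray:
    if config.noise_model == "white":
        return rng.normal(0.0, config.noise_sd, size=shape)
    # AR(1) per electrode with stationary SD = noise_sd
    phi = config.ar_coef
    innov_sd = config.noise_sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=shape)
    out = np.empty(shape)
    out[0] = rng.normal(0.0, config.noise_sd, size=shape[1])
    for i in range(1, shape[0]):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def simulate_dyad_eeg(
    timeline: EventTimeline, config: DyadEEGConfig, rng_seed
) -> tuple[EEGRecording, EEGRecording]:
    """Synthesize the (Shooter, Bait) EEG pair for one game timeline.

    Each recording is background noise plus, for every event, that role's
    ERP template at the event tick — full gain on the central electrodes,
    ``spatial_falloff`` gain elsewhere — with independent per-player,
    per-event latency jitter.
    """
    rng = np.random.default_rng(rng_seed)
    T = timeline.n_ticks
    n_el = len(config.electrodes)
    gain = np.full(n_el, config.spatial_falloff)
    for label in config.central_electrodes:
        gain[config.electrodes.index(label)] = 1.0

    recordings = []
    for role in ROLES:
        data = _noise(rng, (T, n_el), config)
        for tick, cls in timeline.events:
            template = config.templates[(role, cls)]
            jitter = (
                rng.normal(0.0, config.latency_jitter_sd_s)
                if config.latency_jitter_sd_s > 0
                else 0.0
            )
            wave = template_waveform(template, T, tick, _TICK_RATE, jitter)
            data += wave[:, None] * gain[None, :]
        recordings.append(
            EEGRecording(
                data=data,
                electrodes=tuple(config.electrodes),
                sfreq=_TICK_RATE,
                game_id=timeline.game_id,
                team_id=timeline.team_id,
                role=role,
            )
        )
    return recordings[0], recordings[1]


@dataclass
class GameData:
    """One simulated game: ground truth plus the two players' EEG."""

    timeline: EventTimeline
    shooter: EEGRecording
    bait: EEGRecording

    def recording(self, role: str) -> EEGRecording:
        return self.shooter if role == "Shooter" else self.bait


def generate_dataset(
    n_teams: int,
    n_games: int,
    game_config: GameConfig | None = None,
    eeg_config: DyadEEGConfig | None = None,
    master_seed: int = 0,
    out_dir=None,
) -> list[GameData]:
    """Simulate ``n_teams`` x ``n_games`` games with reproducible per-game
    child seeds spawned from ``master_seed``.  With ``out_dir`` set, the
    event logs (CSV+JSON) and EEG matrices (HDF5) are also written out."""
    if n_teams < 1 or n_games < 1:
        raise ValueError("counts must be >= 1")
    game_config = game_config or GameConfig()
    eeg_config = eeg_config or DyadEEGConfig()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_teams * n_games)
    dataset: list[GameData] = []
    for team in range(n_teams):
        for game in range(n_games):
            child = children[team * n_games + game]
            tl_seed, eeg_seed = child.spawn(2)
            timeline = simulate_game_timeline(game_config, tl_seed)
            timeline.team_id = team
            timeline.game_id = game
            shooter, bait = simulate_dyad_eeg(timeline, eeg_config, eeg_seed)
            dataset.append(GameData(timeline=timeline, shooter=shooter, bait=bait))
    if out_dir is not None:
        from . import io as dio

        dio.write_dataset(out_dir, dataset)
    return dataset
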