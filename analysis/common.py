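"""Shared study definition for the analysis scripts.

The reference study: 6 teams x 10 three-minute games at 19 electrodes,
default event statistics and ERP templates.  The evaluated likelihoods
are cached under scratch/ so the numbered scripts can be run in sequence
without recomputing the expensive stages.
"""

from __future__ import annotations

import pickle
from pathlib import Path

from dyadeeg.pipeline import (
    ExperimentConfig,
    ExperimentResult,
    evaluate_likelihoods,
)
from dyadeeg.simulate import generate_dataset

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY = dict(n_teams=6, n_games=10)


def study_config(seed: int = 1) -> ExperimentConfig:
    return ExperimentConfig(seed=seed, **STUDY)


def get_dataset(seed: int = 1):
    cfg = study_config(seed)
    return generate_dataset(cfg.n_teams, cfg.n_games, cfg.game, cfg.eeg, cfg.seed)


def get_result(seed: int = 1) -> ExperimentResult:
    """Full evaluated study, cached on disk across scripts."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"study_seed{seed}.pkl"
    if cache.exists():
        with cache.open("rb") as f:
            return pickle.load(f)
    cfg = study_config(seed)
    dataset = get_dataset(seed)
    evals, pca = evaluate_likelihoods(dataset, cfg)
    result = ExperimentResult(config=cfg, dataset=dataset, evals=evals, pca=pca)
    with cache.open("wb") as f:
        pickle.dump(result, f)
    return result
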