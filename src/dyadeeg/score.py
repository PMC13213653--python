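"""Temporal accuracy measures for event placements.

The mismatch score combines a recall distance (true event to nearest
prediction) and a precision distance (prediction to nearest true event),
each averaged and capped at ``bound`` ticks; the reported score is their
mean, ranging 0 (perfect) to ``bound`` (worst).  ``within_k`` is the
fraction of true events with a prediction within k ticks.  Ticks are at
60 Hz, so 1 tick = 1/60 s.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mismatch", "within_k", "rank_reconstructions", "TICK_SECONDS"]

TICK_SECONDS = 1.0 / 60.0


def _nearest_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Distance from each tick in ``src`` to its nearest tick in ``dst``."""
    dst = np.sort(dst)
    idx = np.searchsorted(dst, src)
    left = np.abs(src - dst[np.clip(idx - 1, 0, dst.size - 1)])
    right = np.abs(src - dst[np.clip(idx, 0, dst.size - 1)])
    return np.minimum(left, right)


def mismatch(
    true_ticks, predicted_ticks, bound: int = 100
) -> tuple[float, float, float]:
    """Return ``(recall_dist, precision_dist, mean)``.

    Empty predictions (or truths) pin the corresponding component at
    ``bound``; both empty scores a perfect 0.
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    t = np.asarray(true_ticks, dtype=float).ravel()
    p = np.asarray(predicted_ticks, dtype=float).ravel()
    if (t.size and t.min() < 0) or (p.size and p.min() < 0):
        raise ValueError("negative ticks")
    if t.size == 0 and p.size == 0:
        return 0.0, 0.0, 0.0
    if t.size == 0 or p.size == 0:
        return float(bound), float(bound), float(bound)
    recall = float(np.minimum(_nearest_distances(t, p), bound).mean())
    precision = float(np.minimum(_nearest_distances(p, t), bound).mean())
    return recall, precision, (recall + precision) / 2.0


def within_k(true_ticks, predicted_ticks, k: int = 2) -> float:
    """Fraction of true events with a prediction within ``k`` ticks."""
    if k < 0:
        raise ValueError("k must be >= 0")
    t = np.asarray(true_ticks, dtype=float).ravel()
    p = np.asarray(predicted_ticks, dtype=float).ravel()
    if t.size == 0:
        return float("nan")
    if p.size == 0:
        return 0.0
    return float((_nearest_distances(t, p) <= k).mean())


def rank_reconstructions(
    true_by_game: list, reconstruction_by_game: list, bound: int = 100
) -> dict:
    """Rank each game's own reconstruction against every reconstruction.

    For game *i*, the mismatch mean is computed against all G
    reconstructions; the rank of reconstruction *i* (1 = best, ties get
    the mean rank) measures how uniquely the reconstruction identifies its
    game.  Games with no true events follow the mismatch empty-set
    conventions and are flagged.  Chance mean rank is (G + 1) / 2.
    """
    from scipy.stats import rankdata

    G = len(true_by_game)
    if G < 2 or len(reconstruction_by_game) != G:
        raise ValueError("need >= 2 games with one reconstruction each")
    ranks = np.empty(G)
    flagged = [i for i, t in enumerate(true_by_game) if len(np.atleast_1d(t)) == 0]
    for i, truth in enumerate(true_by_game):
        scores = np.array(
            [mismatch(truth, rec, bound)[2] for rec in reconstruction_by_game]
        )
        ranks[i] = rankdata(scores, method="average")[i]
    return {
        "ranks": ranks,
        "mean_rank": float(ranks.mean()),
        "n_rank_one": int((ranks == 1).sum()),
        "chance_rank": (G + 1) / 2.0,
        "empty_truth_games": flagged,
    }
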