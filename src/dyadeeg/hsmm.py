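"""Duration-aware semi-Markov placement of kills and deaths.

Kills are placed over the whole game by an explicit-duration Viterbi
dynamic program.  A placement of k kills at ticks t_1 < ... < t_k scores

    sum_m llr(t_m) + log f_start(t_1) + sum_{m>=2} log f_between(t_m - t_{m-1})
        + log S_between(T - t_k)

where ``llr`` is the per-tick Kill-vs-Null emission log-likelihood ratio,
``f_start`` / ``f_between`` are the fitted start-to-kill / kill-to-kill
duration densities, and the censored final interval contributes the
log-survival of the between-kill model (the game ending is not a kill).
The empty placement scores ``log S_start(T)``.  The DP returns the exact
maximizer over every kill count and position, in O(T x D_max).

Deaths are placed within a kill-bounded segment known to contain exactly
one death: a duration prior over the segment (product of a start-anchored
and an end-anchored density, normalized over admissible ticks) is combined
with the per-tick death emission score, and the argmax tick is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .durations import DurationModel, fit_duration_model  # noqa: F401  (re-export)

__all__ = [
    "SegmentSpec",
    "EmptySegmentError",
    "place_kills",
    "placement_score",
    "death_prior",
    "place_death",
]

DEFAULT_MARGIN = 30  # ticks without conditional probabilities at segment ends


class EmptySegmentError(ValueError):
    """Segment too short to admit any candidate death tick."""


@dataclass(frozen=True)
class SegmentSpec:
    """A kill-bounded segment with the edge margins excluded."""

    start: int
    end: int
    margin: int = DEFAULT_MARGIN

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def admissible_ticks(self) -> np.ndarray:
        """Absolute candidate ticks: [start + margin, end - margin]."""
        return np.arange(self.start + self.margin, self.end - self.margin + 1)


def placement_score(
    kill_ticks,
    llr_by_tick: dict[int, float],
    start_model: DurationModel,
    between_model: DurationModel,
    n_ticks: int,
    censor_final: bool = True,
) -> float:
    """Objective value of one kill placement (used by tests as the shared
    definition for brute-force enumeration)."""
    kill_ticks = sorted(int(t) for t in kill_ticks)
    if not kill_ticks:
        return float(start_model.logsf(n_ticks))
    score = float(start_model.logpdf(kill_ticks[0]))
    score += sum(llr_by_tick[t] for t in kill_ticks)
    for prev, cur in zip(kill_ticks[:-1], kill_ticks[1:]):
        score += float(between_model.logpdf(cur - prev))
    if censor_final:
        score += float(between_model.logsf(n_ticks - kill_ticks[-1]))
    return score


def place_kills(
    ticks,
    llr,
    start_model: DurationModel,
    between_model: DurationModel,
    n_ticks: int,
    d_max: int | None = None,
    censor_final: bool = True,
) -> np.ndarray:
    """Maximum-likelihood kill placement over candidate ``ticks``.

    Parameters
    ----------
    ticks, llr:
        Candidate ticks (sorted, typically the interior ticks that have
        feature vectors) and the Kill-vs-Null emission log-ratio at each.
    start_model, between_model:
        Fitted start-to-kill and kill-to-kill duration models.
    n_ticks:
        Game length T in ticks.
    d_max:
        Optional bound on the modelled inter-kill duration; ``None`` (the
        default) allows transitions across the whole game.
    censor_final:
        Score the final interval by the between-model survival function
        (default); ``False`` drops the term.

    Returns the optimal kill ticks (possibly empty).  Ties break toward
    the earliest predecessor.
    """
    ticks = np.asarray(ticks, dtype=int)
    llr = np.asarray(llr, dtype=float)
    if ticks.size == 0:
        raise ValueError("empty candidate tick set")
    if ticks.shape != llr.shape:
        raise ValueError("ticks and llr misaligned")
    if np.any(np.diff(ticks) <= 0):
        raise ValueError("candidate ticks must be strictly increasing")

    n = ticks.size
    log_start = start_model.logpdf(ticks.astype(float))
    lut = between_model.logpdf(np.arange(n_ticks + 1, dtype=float))

    best = np.empty(n)
    parent = np.full(n, -1, dtype=int)
    for i in range(n):
        t = ticks[i]
        lo = 0
        if d_max is not None:
            lo = int(np.searchsorted(ticks, t - d_max, side="left"))
        score = log_start[i]
        if i > lo:
            trans = best[lo:i] + lut[t - ticks[lo:i]]
            j = int(np.argmax(trans))
            if trans[j] > score:
                score = trans[j]
                parent[i] = lo + j
        best[i] = llr[i] + score

    if censor_final:
        final = best + between_model.logsf((n_ticks - ticks).astype(float))
    else:
        final = best
    empty_score = float(start_model.logsf(float(n_ticks)))
    i_best = int(np.argmax(final))
    if final[i_best] <= empty_score or not np.isfinite(final[i_best]):
        return np.empty(0, dtype=int)

    placement = []
    i = i_best
    while i >= 0:
        placement.append(int(ticks[i]))
        i = parent[i]
    return np.array(placement[::-1], dtype=int)


def death_prior(
    segment_length: int,
    start_model: DurationModel,
    end_model: DurationModel,
    margin: int = DEFAULT_MARGIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized log-prior over death offsets within a segment.

    ``prior(t) ∝ f_start(t) * f_end(L - t)`` for offsets
    ``t in [margin, L - margin]``; zero below the minimum start duration
    and above L minus the minimum end duration.  Returns
    ``(offsets, log_prior)``; raises :class:`EmptySegmentError` when no
    offset has positive mass.
    """
    L = int(segment_length)
    offsets = np.arange(margin, L - margin + 1)
    if offsets.size == 0:
        raise EmptySegmentError(f"segment of {L} ticks shorter than 2 x margin")
    lp = start_model.logpdf(offsets.astype(float)) + end_model.logpdf(
        (L - offsets).astype(float)
    )
    total = logsumexp(lp)
    if not np.isfinite(total):
        raise EmptySegmentError(f"no admissible death tick in segment of {L} ticks")
    return offsets, lp - total


def place_death(
    segment: SegmentSpec,
    log_prior: np.ndarray,
    death_llr: np.ndarray,
) -> int:
    """Most probable death tick in a segment: argmax of duration log-prior
    plus emission score over the admissible ticks.  Ties break toward the
    earlier tick.  Returns an absolute tick index."""
    ticks = segment.admissible_ticks
    if ticks.size == 0:
        raise EmptySegmentError("segment admits no candidate ticks")
    log_prior = np.asarray(log_prior, dtype=float)
    death_llr = np.asarray(death_llr, dtype=float)
    if log_prior.shape != ticks.shape or death_llr.shape != ticks.shape:
        raise ValueError("prior / emission scores misaligned with segment ticks")
    score = log_prior + death_llr
    if not np.any(score > -np.inf):
        raise EmptySegmentError("all candidate ticks have zero prior mass")
    return int(ticks[int(np.argmax(score))])
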