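"""Threshold-free discrimination measures and tabular summaries.

AUC is computed as the exact Mann-Whitney rank statistic — the fraction of
(positive, negative) score pairs where the positive outranks the negative,
ties counted half — not a trapezoid approximation.  Team-level summaries
average per-team AUCs (each team one observation) and attach a two-sided
sign test on the count of teams above chance.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .classify import TickLikelihoods
from .preprocess import TICK_CLASSES

__all__ = [
    "auc",
    "sign_test_p",
    "pairwise_auc_table",
    "confusion_and_agreement",
    "CLASS_PAIRS",
]

#: The 6 pairwise discriminations between the 4 tick classes.
CLASS_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(TICK_CLASSES, 2))

SOURCES = ("Shooter", "Bait", "Combined")


def auc(scores_positive, scores_negative) -> float:
    """P(random positive > random negative), ties counted 0.5 (exact)."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def sign_test_p(n_above: int, n_total: int) -> float:
    """Two-sided sign-test p-value for ``n_above`` of ``n_total`` teams
    exceeding chance (ties already excluded by the caller)."""
    if n_total == 0:
        return float("nan")
    return float(stats.binomtest(n_above, n_total, 0.5).pvalue)


def pairwise_auc_table(
    likelihoods_by_team: Mapping[int, Mapping[str, TickLikelihoods]],
    labels_by_team: Mapping[int, np.ndarray],
) -> pd.DataFrame:
    """AUCs for the 6 class-pair discriminations x 3 sources.

    For pair (A, B) the score is the per-tick log-likelihood ratio
    log P(E|A) - log P(E|B); class A ticks are positives.  Each cell
    reports the mean AUC over teams, the number of teams with AUC > 0.5
    (exact 0.5 excluded), the teams contributing (teams missing either
    class are excluded from that cell), and the sign-test p-value.
    """
    rows = []
    for cls_a, cls_b in CLASS_PAIRS:
        row: dict = {"positive": cls_a, "negative": cls_b}
        for source in SOURCES:
            per_team = []
            for team, by_source in likelihoods_by_team.items():
                labels = np.asarray(labels_by_team[team])
                tl = by_source[source]
                sel_a = labels == cls_a
                sel_b = labels == cls_b
                if not sel_a.any() or not sel_b.any():
                    continue  # class absent for this team
                score = tl.llr(cls_a, cls_b)
                per_team.append(auc(score[sel_a], score[sel_b]))
            per_team = np.array(per_team)
            n_above = int((per_team > 0.5).sum())
            n_eval = int((per_team != 0.5).sum())
            row[(source, "mean_auc")] = per_team.mean() if per_team.size else np.nan
            row[(source, "n_gt_half")] = n_above
            row[(source, "n_teams")] = per_team.size
            row[(source, "p_sign")] = sign_test_p(n_above, n_eval)
        rows.append(row)
    df = pd.DataFrame(rows).set_index(["positive", "negative"])
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


def confusion_and_agreement(
    truth: np.ndarray,
    shooter_pred: np.ndarray,
    bait_pred: np.ndarray,
    combined_pred: np.ndarray,
    positive: str = "Kill",
    negative: str = "Null",
) -> dict[str, pd.DataFrame]:
    """Binary confusion counts per source and cross-source agreement.

    ``truth`` is a boolean array (True = positive class); the three
    prediction arrays are booleans at a common threshold.  Returns:

    * ``"confusion"`` — per source, counts of predicted positive/negative
      within each true class;
    * ``"agreement"`` — per true class, the 2x2 Shooter-by-Bait prediction
      counts, with the fraction of combined-classifier correct calls
      inside each disagreement cell.
    """
    truth = np.asarray(truth, dtype=bool)
    preds = {
        "Shooter": np.asarray(shooter_pred, dtype=bool),
        "Bait": np.asarray(bait_pred, dtype=bool),
        "Combined": np.asarray(combined_pred, dtype=bool),
    }
    for name, p in preds.items():
        if p.shape != truth.shape:
            raise ValueError(f"{name} predictions misaligned with truth")

    conf_rows = []
    for source, p in preds.items():
        for true_is_pos, true_name in ((True, positive), (False, negative)):
            sel = truth == true_is_pos
            conf_rows.append(
                {
                    "source": source,
                    "true": true_name,
                    f"pred_{positive}": int((p & sel).sum()),
                    f"pred_{negative}": int((~p & sel).sum()),
                }
            )
    confusion = pd.DataFrame(conf_rows).set_index(["source", "true"])

    agree_rows = []
    s, b, c = preds["Shooter"], preds["Bait"], preds["Combined"]
    for true_is_pos, true_name in ((True, positive), (False, negative)):
        sel = truth == true_is_pos
        correct = c == true_is_pos
        for s_pos in (True, False):
            for b_pos in (True, False):
                cell = sel & (s == s_pos) & (b == b_pos)
                n = int(cell.sum())
                frac = float(correct[cell].mean()) if n and s_pos != b_pos else np.nan
                agree_rows.append(
                    {
                        "true": true_name,
                        "shooter_pred": positive if s_pos else negative,
                        "bait_pred": positive if b_pos else negative,
                        "count": n,
                        "combined_correct_frac": frac,
                    }
                )
    agreement = pd.DataFrame(agree_rows).set_index(
        ["true", "shooter_pred", "bait_pred"]
    )
    return {"confusion": confusion, "agreement": agreement}
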