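"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
placements are scored straight from the duration models' log-densities and
enumerated exhaustively (vectorized over all tick combinations).
"""

import numpy as np


def score_placement(kills, llr_by_tick, start_m, between_m, T, censor_final=True):
    """Score one placement directly from the model definition."""
    kills = sorted(int(t) for t in kills)
    if not kills:
        return float(start_m.logsf(float(T)))
    s = float(start_m.logpdf(float(kills[0])))
    s += sum(llr_by_tick[t] for t in kills)
    for a, b in zip(kills[:-1], kills[1:]):
        s += float(between_m.logpdf(float(b - a)))
    if censor_final:
        s += float(between_m.logsf(float(T - kills[-1])))
    return s


def brute_force_place_kills(
    ticks, llr, start_m, between_m, T, censor_final=True, max_kills=3
):
    """Exhaustively enumerate all placements with up to ``max_kills`` kills
    over the candidate ticks; returns (best_score, best_placement)."""
    ticks = np.asarray(ticks, dtype=int)
    llr = np.asarray(llr, dtype=float)
    t = ticks.astype(float)
    n = t.size
    with np.errstate(invalid="ignore"):
        f_start = start_m.logpdf(t)
        tail = between_m.logsf(T - t) if censor_final else np.zeros(n)

        best_score = float(start_m.logsf(float(T)))
        best: tuple = ()

        if max_kills >= 1:
            s1 = llr + f_start + tail
            i = int(np.argmax(s1))
            if s1[i] > best_score:
                best_score, best = float(s1[i]), (ticks[i],)

        if max_kills >= 2 and n >= 2:
            gap = t[None, :] - t[:, None]          # (i, j): t_j - t_i
            f_gap = np.where(gap > 0, between_m.logpdf(np.maximum(gap, 1e-9)), -np.inf)
            s2 = (llr + f_start)[:, None] + llr[None, :] + f_gap + tail[None, :]
            i, j = np.unravel_index(np.argmax(s2), s2.shape)
            if s2[i, j] > best_score:
                best_score, best = float(s2[i, j]), (ticks[i], ticks[j])

        if max_kills >= 3 and n >= 3:
            first = (llr + f_start)[:, None, None]
            s3 = (
                first
                + llr[None, :, None]
                + llr[None, None, :]
                + f_gap[:, :, None]
                + f_gap[None, :, :]
                + tail[None, None, :]
            )
            i, j, k = np.unravel_index(np.argmax(s3), s3.shape)
            if s3[i, j, k] > best_score:
                best_score = float(s3[i, j, k])
                best = (ticks[i], ticks[j], ticks[k])

    return best_score, np.array(best, dtype=int)
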