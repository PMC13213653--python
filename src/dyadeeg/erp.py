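"""Event-locked ERP summaries: condition means, P300 window statistics.

Works on microvolt-scale epoch stacks (see
:func:`dyadeeg.preprocess.extract_event_epochs`).  The P300 analysis
window is 0.25-0.50 s post-event — at 60 Hz, samples +15..+30 relative to
the event, exactly 16 time points per electrode.
"""

from __future__ import annotations

import numpy as np

from .montage import CENTRAL_ELECTRODES
from .preprocess import HALF_WINDOW

__all__ = [
    "P300_WINDOW_SLICE",
    "condition_means",
    "mean_activity",
    "peak_latency",
    "scalp_profile",
]

# samples +15..+30 after the event (epoch centre at index HALF_WINDOW)
_W_LO, _W_HI = 15, 30
P300_WINDOW_SLICE = slice(HALF_WINDOW + _W_LO, HALF_WINDOW + _W_HI + 1)


def condition_means(
    stacks: dict[str, np.ndarray],
) -> dict[str, tuple[np.ndarray, np.ndarray | None]]:
    """Per class: (mean trace, standard error) across events.

    Input stacks are (n_events, 61, n_electrodes); the SE is ``None`` for
    single-epoch classes and empty classes map to ``None`` entirely
    (flagged by absence).
    """
    out: dict[str, tuple[np.ndarray, np.ndarray | None]] = {}
    for cls, stack in stacks.items():
        if stack.shape[0] == 0:
            out[cls] = None  # type: ignore[assignment]
            continue
        mean = stack.mean(axis=0)
        se = (
            stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
            if stack.shape[0] > 1
            else None
        )
        out[cls] = (mean, se)
    return out


def _electrode_columns(electrodes, wanted) -> list[int]:
    cols = []
    for label in wanted:
        if label not in electrodes:
            raise KeyError(f"electrode {label!r} missing from trace")
        cols.append(list(electrodes).index(label))
    return cols


def mean_activity(
    mean_trace: np.ndarray,
    electrodes,
    central=CENTRAL_ELECTRODES,
) -> float:
    """Mean amplitude (uV) over the P300 window, averaged over the 16
    window samples of each central electrode and then across electrodes."""
    cols = _electrode_columns(electrodes, central)
    window = mean_trace[P300_WINDOW_SLICE, :][:, cols]
    assert window.shape[0] == 16
    return float(window.mean())


def peak_latency(
    mean_trace: np.ndarray,
    electrodes,
    central=CENTRAL_ELECTRODES,
) -> float:
    """Latency (s post-event) of maximal positive amplitude in the P300
    window, found per central electrode and averaged across them.  Ties
    take the earliest sample."""
    cols = _electrode_columns(electrodes, central)
    window = mean_trace[P300_WINDOW_SLICE, :][:, cols]
    peak_samples = _W_LO + np.argmax(window, axis=0)
    return float(np.mean(peak_samples) / 60.0)


def scalp_profile(
    mean_trace: np.ndarray, electrodes
) -> tuple[np.ndarray, bool]:
    """Per-electrode P300-window mean, scaled to range from zero to the
    maximum value for display (negative means floored at zero, then
    divided by the maximum).

    Returns ``(profile, flat)``; a map with no positive activity cannot
    be scaled and is returned as zeros with ``flat=True``.
    """
    window_mean = mean_trace[P300_WINDOW_SLICE, :].mean(axis=0)
    floored = np.clip(window_mean, 0.0, None)
    peak = floored.max()
    if peak < 1e-12:
        return np.zeros(len(electrodes)), True
    return floored / peak, False
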