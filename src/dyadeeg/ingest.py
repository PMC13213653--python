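"""Optional thin ingestion stage for externally recorded EEG.

Standardizes a raw acquisition-rate recording into the 60 Hz tick-aligned
form the rest of the pipeline expects: mastoid re-referencing, 0.1-40 Hz
bandpass, and polyphase decimation to 60 Hz.  The synthetic path generates
data directly at 60 Hz and bypasses this module.  Native vendor file
readers are out of scope; callers load samples into
:class:`~dyadeeg.preprocess.EEGRecording` first.
"""

from __future__ import annotations

from dataclasses import replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .preprocess import EEGRecording

__all__ = ["rereference_to_mastoids", "bandpass", "downsample_to_ticks"]


def rereference_to_mastoids(
    rec: EEGRecording, left: str = "A1", right: str = "A2"
) -> EEGRecording:
    """Re-reference to the average of the two mastoid channels and drop
    them from the montage."""
    li, ri = rec.electrode_index(left), rec.electrode_index(right)
    ref = rec.data[:, [li, ri]].mean(axis=1, keepdims=True)
    keep = [i for i in range(len(rec.electrodes)) if i not in (li, ri)]
    return replace(
        rec,
        data=rec.data[:, keep] - ref,
        electrodes=tuple(rec.electrodes[i] for i in keep),
    )


def bandpass(
    rec: EEGRecording, low_hz: float = 0.1, high_hz: float = 40.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth bandpass."""
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rec.sfreq, output="sos"
    )
    return replace(rec, data=signal.sosfiltfilt(sos, rec.data, axis=0))


def downsample_to_ticks(rec: EEGRecording, tick_rate: float = 60.0) -> EEGRecording:
    """Polyphase anti-aliased resampling from the acquisition rate (e.g.
    512 or 300 Hz) to the game tick rate."""
    frac = Fraction(tick_rate / rec.sfreq).limit_denominator(10_000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=0)
    return replace(rec, data=np.ascontiguousarray(data), sfreq=tick_rate)
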