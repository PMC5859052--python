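"""Filtering and segmentation.

All filters are 4th-order Butterworth applied forward-backward
(zero-phase), so band-limited signals keep their timing — essential for the
downstream phase-lag analysis.  The mains notch is a 2 Hz-wide band-stop.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import BandSpec, EEGRecording


def _check_edges(lo: float, hi: float, sfreq: float) -> None:
    nyq = sfreq / 2
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist ({nyq} Hz)")


def bandpass_notch(
    rec: EEGRecording,
    lo: float = 0.5,
    hi: float = 100.0,
    notch: float | None = 50.0,
    notch_width: float = 2.0,
) -> EEGRecording:
    """Zero-phase band-pass [lo, hi] plus mains notch, per channel.

    Defaults follow the study conventions: 0.5-100 Hz pass band and a 50 Hz
    notch.  Pass ``notch=None`` to skip the notch.
    """
    _check_edges(lo, hi, rec.sfreq)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.sfreq, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=-1)
    if notch is not None:
        if notch >= rec.sfreq / 2:
            raise ValueError(f"notch {notch} Hz at or above Nyquist")
        stop = [notch - notch_width / 2, notch + notch_width / 2]
        sos_n = sps.butter(4, stop, btype="bandstop", fs=rec.sfreq, output="sos")
        data = sps.sosfiltfilt(sos_n, data, axis=-1)
    return rec.copy_with(data=data)


def band_filter(rec: EEGRecording, band: BandSpec) -> EEGRecording:
    """Zero-phase band-pass to a named analysis band; tags the output."""
    _check_edges(band.lo, band.hi, rec.sfreq)
    sos = sps.butter(4, [band.lo, band.hi], btype="bandpass", fs=rec.sfreq, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(data=data, band=band.name)


def trim_state_segment(
    rec: EEGRecording, head_s: float = 10.0, tail_s: float = 10.0
) -> EEGRecording:
    """Drop transition intervals at segment boundaries.

    State changes contaminate the signal around the switch, so the first
    ``head_s`` and last ``tail_s`` seconds are discarded (defaults 10 s each).
    """
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim durations must be >= 0")
    if rec.duration <= head_s + tail_s:
        raise ValueError(
            f"segment of {rec.duration:.3f}s too short to trim "
            f"{head_s}+{tail_s}s"
        )
    a = int(round(head_s * rec.sfreq))
    b = rec.n_samples - int(round(tail_s * rec.sfreq))
    return rec.copy_with(data=rec.data[:, a:b].copy())
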