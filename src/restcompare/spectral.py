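"""Power spectra and the two spectral indices: alpha blocking and
prefrontal lateralization.

Alpha blocking quantifies the eyes-open suppression of the 8-12 Hz rhythm:
per channel i, summing over integer frequency bins f = 8..12 Hz,

    dP_alpha = mean_i sum_f [log10 Pclose_i(f) - log10 Popen_i(f)] / log10 Pclose_i(f)

(positive when opening the eyes suppresses alpha).  The lateralization index
is the normalized left-minus-right asymmetry of summed log alpha power over
the prefrontal electrode sets,

    LI = (P_left - P_right) / (P_left + P_right),

negative for right-dominant alpha.  Because log power is negative below
1 uV^2/Hz — which would unbound LI — band powers are rescaled so the band
minimum is 1 before taking logs (a documented normalization that keeps LI
in [-1, 1] and leaves equal-power symmetry intact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .montage import PREFRONTAL_LEFT, PREFRONTAL_RIGHT
from .recording import BANDS, BandSpec, EEGRecording


@dataclass
class Spectrum:
    """Per-channel power spectral density (uV^2/Hz) on a fixed grid."""

    freqs: np.ndarray
    power: np.ndarray  # (channels, freqs)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if self.power.shape != (len(self.labels), len(self.freqs)):
            raise ValueError("power must be (channels, freqs)")

    def band_bins(self, lo: float, hi: float) -> np.ndarray:
        """Indices of grid points within [lo, hi] inclusive."""
        return np.where((self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9))[0]

    def channel_rows(self, labels: Sequence[str]) -> np.ndarray:
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"channels missing from spectrum: {missing}")
        lookup = {l: i for i, l in enumerate(self.labels)}
        return np.array([lookup[l] for l in labels])


@dataclass
class AlphaBlockResult:
    delta_p_alpha: float
    per_channel: np.ndarray


@dataclass
class LateralizationResult:
    li: float
    p_left: float
    p_right: float


def power_spectrum(rec: EEGRecording, resolution: float = 1.0) -> Spectrum:
    """Averaged-periodogram (Welch) PSD: Hann taper, 50% overlap, segment
    length 1/resolution seconds, grid spacing ``resolution`` Hz."""
    nperseg = int(round(rec.sfreq / resolution))
    if rec.n_samples < 2 * nperseg:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than two "
            f"{nperseg}-sample segments at {resolution} Hz resolution"
        )
    freqs, power = sps.welch(
        rec.data,
        fs=rec.sfreq,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        axis=-1,
    )
    return Spectrum(freqs=freqs, power=power, labels=tuple(rec.labels))


def alpha_blocking_index(
    spec_close: Spectrum,
    spec_open: Spectrum,
    lo: float = 8.0,
    hi: float = 12.0,
    denominator: str = "per_bin",
) -> AlphaBlockResult:
    """Channel-averaged reduction of alpha power, eyes closed vs. open.

    ``denominator="per_bin"`` normalizes each bin's log-power difference by
    that bin's closed-state log power (the formula as printed);
    ``"band_sum"`` instead normalizes the summed difference by the summed
    closed-state log power.
    """
    if spec_close.labels != spec_open.labels:
        raise ValueError("channel sets differ between spectra")
    if len(spec_close.freqs) != len(spec_open.freqs) or np.any(
        np.abs(spec_close.freqs - spec_open.freqs) > 1e-9
    ):
        raise ValueError("frequency grids differ between spectra")
    bins = spec_close.band_bins(lo, hi)
    if bins.size == 0:
        raise ValueError(f"no grid points in [{lo}, {hi}] Hz")
    pc, po = spec_close.power[:, bins], spec_open.power[:, bins]
    for name, p in (("closed", pc), ("open", po)):
        if np.any(p <= 0):
            ch, fb = np.argwhere(p <= 0)[0]
            raise ValueError(
                f"nonpositive {name}-state power at channel "
                f"{spec_close.labels[ch]}, {spec_close.freqs[bins[fb]]:g} Hz"
            )
    lc, lo_ = np.log10(pc), np.log10(po)
    if denominator == "per_bin":
        if np.any(lc == 0):
            ch, fb = np.argwhere(lc == 0)[0]
            raise ValueError(
                f"log10 closed-state power is exactly 0 at channel "
                f"{spec_close.labels[ch]}, {spec_close.freqs[bins[fb]]:g} Hz"
            )
        per_channel = np.sum((lc - lo_) / lc, axis=1)
    elif denominator == "band_sum":
        denom = lc.sum(axis=1)
        if np.any(denom == 0):
            raise ValueError("summed log closed-state power is 0 for a channel")
        per_channel = (lc - lo_).sum(axis=1) / denom
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return AlphaBlockResult(float(per_channel.mean()), per_channel)


def lateralization_index(
    spec: Spectrum,
    left: Sequence[str] = tuple(PREFRONTAL_LEFT),
    right: Sequence[str] = tuple(PREFRONTAL_RIGHT),
    band: BandSpec = BANDS["alpha"],
) -> LateralizationResult:
    """Normalized left-right asymmetry of summed log band power."""
    li_rows = spec.channel_rows(left)
    ri_rows = spec.channel_rows(right)
    bins = spec.band_bins(band.lo, band.hi)
    if bins.size == 0:
        raise ValueError(f"no grid points in band {band.name}")
    block = spec.power[np.concatenate([li_rows, ri_rows])][:, bins]
    if np.any(block <= 0):
        raise ValueError("nonpositive band power in lateralization electrodes")
    # rescale so the band minimum is 1: keeps all logs >= 0 and LI in [-1, 1]
    pmin = block.min()
    if pmin < 1.0:
        block = block / pmin
    nl = len(li_rows)
    p_left = float(np.log10(block[:nl]).sum())
    p_right = float(np.log10(block[nl:]).sum())
    if p_left + p_right == 0:
        raise ValueError("total log band power is zero; LI undefined")
    return LateralizationResult((p_left - p_right) / (p_left + p_right), p_left, p_right)
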