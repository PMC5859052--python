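"""Instantaneous phase and the phase lag index (PLI).

The PLI between two channels is the absolute time average of the sign of
their wrapped instantaneous phase difference,

    PLI_ab = | (1/N) sum_n sign(phi_a(n) - phi_b(n)) |,

with phases from the analytic signal (Hilbert transform).  It is 1 under
strict phase locking at a constant nonzero lag and 0 when the phase
difference is symmetric around 0 mod pi — which is why it discounts the
zero-lag correlations produced by volume conduction.  ``sign(0)`` is defined
as 0, so identical signals give PLI 0 rather than an undefined value; exact
zeros still count toward N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import band_filter
from .recording import BandSpec, EEGRecording


@dataclass
class PhaseSeries:
    """Instantaneous phase (radians, (-pi, pi]) per channel and sample."""

    phase: np.ndarray
    analytic_imag: np.ndarray
    sfreq: float
    labels: tuple[str, ...]


@dataclass
class PLIMatrix:
    """Symmetric channels x channels PLI matrix; entries double as the
    weighted network's adjacency downstream."""

    values: np.ndarray
    labels: tuple[str, ...]
    band: BandSpec | None
    n_samples: int

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("PLI matrix must be square and match labels")
        if not np.allclose(v, v.T):
            raise ValueError("PLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("PLI diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI entries must lie in [0, 1]")


def instantaneous_phase(rec: EEGRecording) -> PhaseSeries:
    """Analytic-signal phase of each (already band-limited) channel."""
    power = np.sum(rec.data**2, axis=1)
    if np.any(power == 0):
        dead = [rec.labels[i] for i in np.where(power == 0)[0]]
        raise ValueError(f"phase undefined for all-zero channels: {dead}")
    analytic = sps.hilbert(rec.data, axis=-1)
    phase = np.arctan2(analytic.imag, analytic.real)
    return PhaseSeries(phase, analytic.imag, rec.sfreq, tuple(rec.labels))


def phase_difference(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Wrapped phase difference phi_a - phi_b in (-pi, pi]."""
    pa, pb = np.asarray(pa), np.asarray(pb)
    if pa.shape != pb.shape:
        raise ValueError(f"length mismatch: {pa.shape} vs {pb.shape}")
    d = pa - pb
    wrapped = np.angle(np.exp(1j * d))
    # np.angle returns [-pi, pi]; fold the open end onto +pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def pli_from_phase_difference(diff: np.ndarray) -> float:
    """PLI of a wrapped phase-difference series, with sign(0) = 0."""
    return float(np.abs(np.mean(np.sign(diff))))


def pli_matrix(
    rec: EEGRecording,
    band: BandSpec | None = None,
    edge_trim_fraction: float = 0.05,
    epoch_s: float | None = None,
) -> PLIMatrix:
    """All-pairs PLI of a recording, band-filtered internally.

    Parameters
    ----------
    band
        Analysis band; filtering happens inside so the matrix's band tag is
        authoritative.  ``None`` uses the data as given.
    edge_trim_fraction
        Fraction of samples dropped at each end (default 5%) to suppress
        analytic-signal edge artifacts.
    epoch_s
        When set, the retained segment is cut into epochs of this length and
        per-epoch PLI values are averaged; default is a single whole-segment
        estimate (N = all retained samples).
    """
    if rec.n_channels < 2:
        raise ValueError("PLI needs at least 2 channels")
    if not (0 <= edge_trim_fraction < 0.5):
        raise ValueError("edge_trim_fraction must be in [0, 0.5)")
    filtered = band_filter(rec, band) if band is not None else rec
    phases = instantaneous_phase(filtered).phase
    n = phases.shape[1]
    trim = int(round(edge_trim_fraction * n))
    kept = phases[:, trim : n - trim] if trim else phases
    n_kept = kept.shape[1]
    if n_kept < 100:
        raise ValueError(f"only {n_kept} samples retained after trimming; need >= 100")

    if epoch_s is None:
        slices = [slice(0, n_kept)]
    else:
        ep = int(round(epoch_s * rec.sfreq))
        if ep < 100:
            raise ValueError("epochs must span at least 100 samples")
        slices = [slice(a, a + ep) for a in range(0, n_kept - ep + 1, ep)]
        if not slices:
            raise ValueError("retained segment shorter than one epoch")

    nch = rec.n_channels
    values = np.zeros((nch, nch))
    for sl in slices:
        seg = kept[:, sl]
        for i in range(nch):
            d = phase_difference(
                np.broadcast_to(seg[i], seg[i + 1 :].shape), seg[i + 1 :]
            )
            values[i, i + 1 :] += np.abs(np.mean(np.sign(d), axis=1))
    values /= len(slices)
    values = values + values.T
    return PLIMatrix(values, tuple(rec.labels), band, n_kept)
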