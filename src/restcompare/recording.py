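"""Core containers: multichannel EEG recordings and frequency-band definitions.

An :class:`EEGRecording` is the object every pipeline stage consumes and
returns: a channels x samples matrix in microvolts together with the sampling
rate, ordered channel labels, a reference descriptor and a behavioural state
label.

Reference descriptors are plain strings so they survive serialization:

* ``"infinity"``        -- potentials against an ideal neutral (zero) point
* ``"average"``         -- instantaneous mean across channels subtracted
* ``"common:<LABEL>"``  -- recorded against a single scalp electrode
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

STATES = ("eyes_closed", "eyes_open", "music", "unknown")

REF_INFINITY = "infinity"
REF_AVERAGE = "average"


def common_reference(label: str) -> str:
    """Reference descriptor for a recording referenced at a scalp electrode."""
    return f"common:{label}"


def is_common_reference(ref: str) -> bool:
    return ref.startswith("common:")


def common_reference_label(ref: str) -> str:
    if not is_common_reference(ref):
        raise ValueError(f"not a common-electrode reference: {ref!r}")
    return ref.split(":", 1)[1]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band edges must satisfy 0 < lo < hi, got ({self.lo}, {self.hi})")


#: Conventional band edges. Only alpha (8-12 Hz) is canonical for this
#: analysis; the neighbours are the standard clinical conventions and are
#: overridable wherever a BandSpec is accepted.
BANDS: dict[str, BandSpec] = {
    "full": BandSpec("full", 0.5, 80.0),
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 80.0),
}


@dataclass
class EEGRecording:
    """Multichannel scalp EEG: ``data`` is (n_channels, n_samples) microvolts."""

    data: np.ndarray
    sfreq: float
    labels: list[str]
    reference: str = common_reference("Cz")
    state: str = "unknown"
    band: str | None = None  # set by band_filter; None = broadband

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if not self.sfreq > 0:
            raise ValueError("sfreq must be positive")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")

    # -- convenience -------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def copy_with(self, **changes) -> "EEGRecording":
        """A copy with selected fields replaced; data is copied if untouched."""
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)

    def channel_index(self, labels: Sequence[str]) -> np.ndarray:
        """Row indices of the named channels, erroring on absentees."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        lookup = {l: i for i, l in enumerate(self.labels)}
        return np.array([lookup[l] for l in labels], dtype=int)
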