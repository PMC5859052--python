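"""Electrode montages: extended 10-10 layouts on a spherical scalp.

Coordinates come from MNE's built-in extended 10-05 template (head frame:
+x right, +y anterior, +z superior, metres).  Because the downstream forward
model is a concentric-sphere head, template positions are re-centred by a
least-squares sphere fit and projected radially onto the scalp shell, so
every electrode sits exactly on the outer head-model radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: actiCAP-style 64-channel layout (extended 10-10): the classic 32-channel
#: ring first, then the second ring of intermediate sites.
LABELS_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]

LABELS_32 = LABELS_64[:32]

#: Prefrontal electrode sets used for the alpha-band lateralization index.
PREFRONTAL_LEFT = ["Fp1", "AF7", "AF3", "F7", "F5", "F3", "F1"]
PREFRONTAL_RIGHT = ["Fp2", "AF8", "AF4", "F8", "F6", "F4", "F2"]


@dataclass(frozen=True)
class Montage:
    """Named electrodes with 3-D positions (metres) on the scalp sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def position_of(self, label: str) -> np.ndarray:
        try:
            return self.positions[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def subset(self, labels) -> "Montage":
        idx = [self.labels.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])

    def pairwise_distances(self) -> np.ndarray:
        """Straight-line 3-D distances between all electrode pairs (m)."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    # -- plain-text export -------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tx\ty\tz\n")
            for label, p in zip(self.labels, self.positions):
                fh.write(f"{label}\t{p[0]:.9g}\t{p[1]:.9g}\t{p[2]:.9g}\n")

    @classmethod
    def from_tsv(cls, path) -> "Montage":
        labels, rows = [], []
        with open(path) as fh:
            header = fh.readline().split()
            if header != ["label", "x", "y", "z"]:
                raise ValueError(f"unexpected montage header {header}")
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:4]])
        return cls(tuple(labels), np.array(rows))


def _template_positions(labels) -> np.ndarray:
    """Template 10-05 positions for the requested labels (head frame, m)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        tpl = mne.channels.make_standard_montage("standard_1005")
    pos = tpl.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos]
    if missing:
        raise ValueError(f"labels absent from 10-05 template: {missing}")
    return np.array([pos[l] for l in labels])


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Least-squares sphere centre of a point cloud (linearized fit)."""
    # |p - c|^2 = r^2  ->  2 p.c - |c|^2 + r^2 = |p|^2 : linear in (c, r^2-|c|^2)
    A = np.hstack([2 * points, np.ones((len(points), 1))])
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def standard_montage(n_channels: int, scalp_radius_m: float = 0.100) -> Montage:
    """Extended 10-10 montage with electrodes on a sphere of ``scalp_radius_m``.

    Parameters
    ----------
    n_channels
        32 or 64. The 64-channel layout includes the full prefrontal set
        (Fp1/2, AF3/4/7/8, F1-F8) used by the lateralization analysis, plus Cz.
    scalp_radius_m
        Radius of the outer (scalp) shell the electrodes are projected onto.
    """
    if n_channels == 64:
        labels = LABELS_64
    elif n_channels == 32:
        labels = LABELS_32
    else:
        raise ValueError(f"unsupported channel count {n_channels}; choose 32 or 64")
    raw = _template_positions(labels)
    centered = raw - _fit_sphere_center(raw)
    radii = np.linalg.norm(centered, axis=1)
    positions = centered / radii[:, None] * scalp_radius_m
    return Montage(tuple(labels), positions)
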