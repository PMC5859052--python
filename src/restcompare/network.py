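"""Weighted graph measures over thresholded PLI networks.

Edges: channel pairs whose PLI exceeds a threshold keep the PLI as weight
w_ij in (0, 1]; all other pairs have w = 0.

* Functional connectivity density (FCD): per-channel count of
  suprathreshold partners, either over the whole montage (global) or within
  a 5 cm neighbourhood (local).
* Weighted clustering coefficient (triangle-intensity form):
  C_i = sum_{j!=k} w_ij w_ik w_jk / sum_{j!=k} w_ij w_ik, zero when the
  vertex has fewer than two neighbours; C is the mean over all vertices.
* Characteristic path length: reciprocal of global efficiency with edge
  lengths 1/w; unreachable pairs contribute zero efficiency, and a network
  with no finite path at all is flagged disconnected (L infinite).
* Small-world value SW = C / L, swept over thresholds 0.01..0.99.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import PLIMatrix
from .montage import Montage
from .recording import BandSpec


@dataclass
class FCDMap:
    """Per-channel suprathreshold connection counts."""

    counts: np.ndarray
    labels: tuple[str, ...]
    tc: float
    kind: str  # "global" | "local"
    radius_m: float | None = None


@dataclass
class SWCurve:
    """Clustering, path length and small-world value vs. threshold."""

    thresholds: np.ndarray
    c_values: np.ndarray
    l_values: np.ndarray  # inf where the network has no finite path
    sw_values: np.ndarray
    band: BandSpec | None = None


def _thresholded(pli: PLIMatrix | np.ndarray, threshold: float) -> np.ndarray:
    w = pli.values if isinstance(pli, PLIMatrix) else np.asarray(pli, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    out = np.where(w > threshold, w, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def fcd(
    pli: PLIMatrix,
    tc: float,
    kind: str = "global",
    montage: Montage | None = None,
    radius_m: float = 0.05,
) -> FCDMap:
    """Connectivity density: count of partners with PLI > tc per channel.

    ``kind="local"`` restricts partners to electrodes within ``radius_m``
    (straight-line 3-D distance, default 5 cm); a montage is then required.
    """
    if not (0 < tc < 1):
        raise ValueError(f"threshold must be in (0, 1), got {tc}")
    above = pli.values > tc
    np.fill_diagonal(above, False)
    if kind == "global":
        counts = above.sum(axis=1)
        return FCDMap(counts, pli.labels, tc, "global")
    if kind == "local":
        if montage is None:
            raise ValueError("local FCD requires a montage for electrode geometry")
        sub = montage.subset(pli.labels)
        near = sub.pairwise_distances() <= radius_m
        np.fill_diagonal(near, False)
        counts = (above & near).sum(axis=1)
        return FCDMap(counts, pli.labels, tc, "local", radius_m)
    raise ValueError(f"unknown FCD kind {kind!r}")


def weighted_clustering(
    pli: PLIMatrix | np.ndarray, threshold: float
) -> tuple[np.ndarray, float]:
    """Per-vertex weighted clustering C_i and the network mean C.

    With weights in [0, 1] the triangle numerator is termwise bounded by the
    denominator, so C_i (and C) stay in [0, 1].
    """
    w = _thresholded(pli, threshold)
    strength = w.sum(axis=1)
    numer = np.diag(w @ w @ w)  # sum_{j,k} w_ij w_jk w_ki; zero diagonal kills j=k
    denom = strength**2 - np.sum(w**2, axis=1)  # sum_{j != k} w_ij w_ik
    ci = np.where(denom > 0, numer / np.where(denom == 0, 1, denom), 0.0)
    return ci, float(ci.mean())


def characteristic_path_length(
    pli: PLIMatrix | np.ndarray, threshold: float
) -> tuple[float, bool]:
    """Reciprocal of global efficiency with edge lengths 1/w.

    Returns (L, disconnected).  Efficiency averages 1/d_ij over ordered
    pairs, zero for unreachable pairs; if no pair is reachable, efficiency
    is 0 and L is reported infinite with the flag set.
    """
    w = _thresholded(pli, threshold)
    n = w.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 vertices")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w == 0, 1, w), 0.0)
    d = dijkstra(csr_matrix(lengths), directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d == 0, np.inf, d), 0.0)
    efficiency = inv[off].sum() / (n * (n - 1))
    if efficiency == 0:
        return float("inf"), True
    return float(1.0 / efficiency), False


def small_world_sweep(
    pli: PLIMatrix,
    start: float = 0.01,
    step: float = 0.01,
    stop: float = 0.99,
) -> SWCurve:
    """C, L and SW = C/L over a threshold grid (99 points by default).

    SW is set to 0 where the thresholded network has no finite path.
    """
    n_points = int(round((stop - start) / step)) + 1
    thresholds = start + step * np.arange(n_points)
    c = np.empty(n_points)
    l = np.empty(n_points)
    sw = np.empty(n_points)
    for k, t in enumerate(thresholds):
        _, c[k] = weighted_clustering(pli, t)
        l[k], disconnected = characteristic_path_length(pli, t)
        sw[k] = 0.0 if disconnected else c[k] / l[k]
    return SWCurve(thresholds, c, l, sw, pli.band if isinstance(pli, PLIMatrix) else None)


def sw_area(curve: SWCurve, lo: float = 0.2, hi: float = 0.5) -> float:
    """Sum of small-world values at grid points within [lo, hi] inclusive."""
    mask = (curve.thresholds >= lo - 1e-9) & (curve.thresholds <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"no sweep thresholds inside [{lo}, {hi}]")
    return float(curve.sw_values[mask].sum())
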