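"""Concentric three-shell spherical head model and dipole lead fields.

The scalp potential of a current dipole inside a three-shell (brain, skull,
scalp) conductor sphere is computed by Legendre-harmonic expansion.  For each
harmonic degree ``n`` the radial profile in every shell is
``A r^n + B r^-(n+1)``; the five unknown coefficients are fixed by potential
and radial-current continuity at the two inner interfaces and a no-current
condition at the scalp surface, with the dipole's primary (free-medium)
expansion as the source term in the innermost shell.  The per-degree linear
systems are tiny (5x5) and solved exactly, so the only approximation is the
series truncation, which is checked explicitly.

The lead field is expressed against an ideal reference at infinity (no row
centring), in microvolts per nA.m of dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage


@dataclass(frozen=True)
class HeadModel:
    """Three concentric shells: brain < skull < scalp.

    Defaults are the conventional adult values: radii 8.7/9.2/10.0 cm and
    conductivities 0.33/0.0042/0.33 S/m (skull ~80x more resistive).
    """

    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)

    def __post_init__(self) -> None:
        r = self.radii
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must be strictly increasing and positive")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[2]


@dataclass(frozen=True)
class LeadField:
    """Electrode x source gain matrix (uV per nA.m), infinity-referenced.

    ``gain[i, j]`` is the potential at electrode ``i`` of a unit dipole at
    ``source_positions[j]`` oriented along ``source_orientations[j]``.
    Row order matches the montage label order it was built with.
    """

    gain: np.ndarray
    labels: tuple[str, ...]
    source_positions: np.ndarray
    source_orientations: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite entries")
        if self.gain.shape != (len(self.labels), len(self.source_positions)):
            raise ValueError("gain shape inconsistent with labels/sources")


def surface_factors(head: HeadModel, n_max: int) -> np.ndarray:
    """Per-degree transfer factors F_n of the three-shell sphere.

    F_n maps the dipole's primary expansion coefficient (the ``c_n / r^(n+1)``
    term of the free-medium potential in the innermost shell) to the harmonic
    amplitude of the potential on the scalp surface.  For equal conductivities
    F_n reduces to the homogeneous-sphere value ``(2n+1)/n / R^(n+1)``.
    """
    r1, r2, r3 = head.radii
    s1, s2, s3 = head.conductivities
    # Work in units of the scalp radius to keep the 5x5 systems well scaled.
    x1, x2 = r1 / r3, r2 / r3
    out = np.empty(n_max)
    for n in range(1, n_max + 1):
        # unknowns: [A1, A2, B2, A3, B3]; radial profiles A x^n + B x^-(n+1)
        # source term in shell 1: x^-(n+1) (unit primary coefficient, scaled)
        a = np.zeros((5, 5))
        b = np.zeros(5)
        p1, q1 = x1**n, x1 ** -(n + 1)
        p2, q2 = x2**n, x2 ** -(n + 1)
        # potential continuity at r1: q1 + A1 p1 = A2 p1 + B2 q1
        a[0] = [p1, -p1, -q1, 0, 0]
        b[0] = -q1
        # current continuity at r1: s1 (-(n+1) q1/x1 + A1 n p1/x1) = s2 (...)
        a[1] = [s1 * n * p1, -s2 * n * p1, s2 * (n + 1) * q1, 0, 0]
        b[1] = s1 * (n + 1) * q1
        # potential continuity at r2
        a[2] = [0, p2, q2, -p2, -q2]
        # current continuity at r2
        a[3] = [0, s2 * n * p2, -s2 * (n + 1) * q2, -s3 * n * p2, s3 * (n + 1) * q2]
        # insulating scalp surface at r3 (x = 1): n A3 - (n+1) B3 = 0
        a[4] = [0, 0, 0, n, -(n + 1)]
        A1, A2, B2, A3, B3 = np.linalg.solve(a, b)
        # surface potential amplitude for unit primary coefficient c_n:
        # primary was c_n / r^(n+1) = (c_n / r3^(n+1)) x^-(n+1)
        out[n - 1] = (A3 + B3) / r3 ** (n + 1)
    return out


def _legendre_pair(x: np.ndarray, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n^1(x) for n = 1..n_max by upward recurrence.

    P_n^1 uses the Condon-Shortley phase (P_1^1 = -sqrt(1-x^2)).
    """
    x = np.asarray(x, dtype=float)
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    P = np.empty((n_max + 1,) + x.shape)
    P1 = np.empty_like(P)
    P[0], P1[0] = 1.0, 0.0
    P[1], P1[1] = x, -s
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        P1[n + 1] = ((2 * n + 1) * x * P1[n] - (n + 1) * P1[n - 1]) / n
    return P[1:], P1[1:]


def build_lead_field(
    head: HeadModel,
    montage: Montage,
    source_positions: np.ndarray,
    source_orientations: np.ndarray,
    n_terms: int = 100,
    tail_tol: float = 1e-6,
) -> LeadField:
    """Infinity-referenced lead field of fixed-orientation dipoles.

    Parameters
    ----------
    source_positions, source_orientations
        (S, 3) arrays, metres and unit vectors.  Sources must lie strictly
        inside the brain shell; the series must have decayed below
        ``tail_tol`` (relative) at ``n_terms`` or the offending source is
        reported.
    """
    pos = np.atleast_2d(np.asarray(source_positions, dtype=float))
    ori = np.atleast_2d(np.asarray(source_orientations, dtype=float))
    if pos.shape != ori.shape or pos.shape[1] != 3:
        raise ValueError("source positions/orientations must be matching (S, 3) arrays")
    norms = np.linalg.norm(ori, axis=1)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise ValueError("source orientations must be unit vectors")

    elec = montage.positions
    er = np.linalg.norm(elec, axis=1)
    R = head.scalp_radius
    if np.any(np.abs(er - R) > 1e-6 * R):
        raise ValueError("electrodes must lie on the scalp shell")
    e_hat = elec / er[:, None]

    F = surface_factors(head, n_terms)  # (N,)
    ns = np.arange(1, n_terms + 1, dtype=float)
    sigma_brain = head.conductivities[0]
    # 1 nA.m = 1e-9 A.m; output in uV -> net 1e-3 / (4 pi sigma)
    unit_scale = 1e-3 / (4 * np.pi * sigma_brain)

    gain = np.empty((montage.n_channels, len(pos)))
    for j, (p, m) in enumerate(zip(pos, ori)):
        b = np.linalg.norm(p)
        if b >= head.brain_radius:
            raise ValueError(
                f"source {j} at radius {b:.4f} m is not strictly inside the "
                f"brain shell (radius {head.brain_radius} m)"
            )
        if b / R > tail_tol ** (1.0 / n_terms):
            raise ValueError(
                f"series not converged for source {j}: eccentricity {b / R:.3f} "
                f"leaves a relative tail above {tail_tol:g} at {n_terms} terms"
            )
        if b < 1e-12:
            # central dipole: only n=1 survives; potential axis = moment axis
            cos_m = e_hat @ m
            gain[:, j] = unit_scale * F[0] * cos_m
            continue
        r_hat = p / b
        m_r = float(m @ r_hat)
        cosg = e_hat @ r_hat
        sing = np.sqrt(np.clip(1 - cosg**2, 0, None))
        # unit tangent at each electrode, in the (r_hat, e_hat) plane
        t_vec = e_hat - cosg[:, None] * r_hat
        with np.errstate(invalid="ignore", divide="ignore"):
            t_hat = np.where(sing[:, None] > 1e-12, t_vec / np.where(sing == 0, 1, sing)[:, None], 0.0)
        m_t = t_hat @ m  # tangential moment component seen by each electrode
        P, P1 = _legendre_pair(cosg, n_terms)  # (N, E)
        w = F * b ** (ns - 1)  # (N,)
        # radial part: sum_n w_n * n * m_r * P_n; tangential: -w_n * m_t * P_n^1
        v = (w * ns) @ P * m_r - (w @ P1) * m_t
        gain[:, j] = unit_scale * v
    return LeadField(gain, tuple(montage.labels), pos, ori)


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """``n`` nearly uniformly distributed points on a sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    s = np.sqrt(1 - z**2)
    return radius * np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def equivalent_source_layer(
    head: HeadModel, n_sources: int = 300, depth_fraction: float = 0.86
) -> tuple[np.ndarray, np.ndarray]:
    """Radial dipole layer used by the infinity-reference standardization.

    Returns (positions, orientations): ``n_sources`` radial dipoles evenly
    spread on a sphere at ``depth_fraction`` x brain radius.
    """
    pos = fibonacci_sphere(n_sources, radius=depth_fraction * head.brain_radius)
    ori = pos / np.linalg.norm(pos, axis=1)[:, None]
    return pos, ori
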