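"""Analytic model systems: a valence-force-field water and 1D spring chains.

These stand in for quantum-chemistry Hessians: the water model is a simple
valence force field (two stretches, one bend, stretch-stretch coupling)
whose default constants are tuned so the harmonic frequencies fall within
10% of the experimental fundamentals of H2O (3657, 1595, 3756 cm^-1).
Chains of point masses with nearest-neighbor springs provide
low-dimensional systems whose marginals can be checked against dense
quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .system import HessianMatrix, MolecularSystem


@dataclass(frozen=True)
class ValenceForceField:
    """Harmonic valence force field for a bent symmetric triatomic.

    V = 1/2 k_r (dr1^2 + dr2^2) + k_rr dr1 dr2 + 1/2 k_theta dtheta^2

    with dr the bond-length displacements (bohr) and dtheta the bond-angle
    displacement (rad).  Units: k_r, k_rr in E_h/bohr^2; k_theta in
    E_h/rad^2.
    """

    r_e: float = 1.8088          # bohr
    theta_e: float = math.radians(104.52)
    k_r: float = 0.4928          # E_h/bohr^2
    k_theta: float = 0.14776     # E_h/rad^2
    k_rr: float = -0.00603       # E_h/bohr^2

    def __post_init__(self):
        if self.k_r <= 0 or self.k_theta <= 0:
            raise ValueError("force constants k_r and k_theta must be positive")
        if abs(self.k_rr) >= self.k_r:
            raise ValueError("|k_rr| must be smaller than k_r")

    def potential(self, x: np.ndarray) -> float:
        """Valence potential at Cartesian coordinates (x_O, x_H1, x_H2), flat 9-vector."""
        p = np.asarray(x, dtype=float).reshape(3, 3)
        b1 = p[1] - p[0]
        b2 = p[2] - p[0]
        r1 = np.linalg.norm(b1)
        r2 = np.linalg.norm(b2)
        cosq = np.clip(b1 @ b2 / (r1 * r2), -1.0, 1.0)
        theta = math.acos(cosq)
        dr1, dr2, dth = r1 - self.r_e, r2 - self.r_e, theta - self.theta_e
        return (
            0.5 * self.k_r * (dr1 * dr1 + dr2 * dr2)
            + self.k_rr * dr1 * dr2
            + 0.5 * self.k_theta * dth * dth
        )


def finite_difference_hessian(potential, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar potential."""
    x0 = np.asarray(x0, dtype=float).ravel()
    n = x0.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += step; xpp[j] += step
            xpm = x0.copy(); xpm[i] += step; xpm[j] -= step
            xmp = x0.copy(); xmp[i] -= step; xmp[j] += step
            xmm = x0.copy(); xmm[i] -= step; xmm[j] -= step
            H[i, j] = H[j, i] = (
                potential(xpp) - potential(xpm) - potential(xmp) + potential(xmm)
            ) / (4.0 * step * step)
    return 0.5 * (H + H.T)


def water_model(
    ff: ValenceForceField | None = None,
    isotopes=("O", "H", "H"),
    masses=None,
) -> tuple[MolecularSystem, HessianMatrix]:
    """Bent water-like molecule in the xy plane, O at the origin.

    The C2 axis is the y axis (hydrogens at negative y); the molecular
    plane is z = 0.  ``isotopes`` relabels nuclei (e.g. ``("O", "D", "H")``
    for HDO); the Hessian is mass-independent, so isotopologues share it.
    Explicit per-nucleus ``masses`` (m_e) override the label lookup.
    """
    ff = ff or ValenceForceField()
    if not 0 < ff.theta_e < math.pi:
        raise ValueError("bond angle must describe a bent geometry")
    a = 0.5 * ff.theta_e
    r = ff.r_e
    x_eq = np.array(
        [
            0.0, 0.0, 0.0,
            r * math.sin(a), -r * math.cos(a), 0.0,
            -r * math.sin(a), -r * math.cos(a), 0.0,
        ]
    )
    system = MolecularSystem(isotopes, x_eq, masses=masses)
    H = finite_difference_hessian(ff.potential, x_eq)
    return system, HessianMatrix(H)


def chain_model(
    n_particles: int,
    masses=None,
    spring_constants=None,
    spacing: float = 2.0,
    labels=None,
) -> tuple[MolecularSystem, HessianMatrix]:
    """Point masses on the x axis joined by nearest-neighbor distance springs.

    The potential is sum_i 1/2 k_i (|r_{i+1} - r_i| - spacing)^2; at a
    collinear equilibrium the curvature is purely longitudinal, so for
    n >= 3 the transverse directions are flat in addition to translation
    and rotation (pass ``n_zero=chain_zero_modes(n)`` to the normal-mode
    analysis).  Masses default to 1 m_e each; springs to 1 E_h/bohr^2.
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    n = n_particles
    masses = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    ks = (
        np.ones(max(n - 1, 0))
        if spring_constants is None
        else np.asarray(spring_constants, dtype=float)
    )
    if ks.size != max(n - 1, 0):
        raise ValueError("one spring constant per adjacent pair required")
    if labels is None:
        labels = ("X",) * n
    x_eq = np.zeros(3 * n)
    x_eq[0::3] = spacing * np.arange(n)
    system = MolecularSystem(labels, x_eq, masses=masses)

    H = np.zeros((3 * n, 3 * n))
    for i, k in enumerate(ks):
        a, b = 3 * i, 3 * (i + 1)  # x components of particles i, i+1
        H[a, a] += k
        H[b, b] += k
        H[a, b] -= k
        H[b, a] -= k
    return system, HessianMatrix(H)


def chain_zero_modes(n_particles: int) -> int:
    """Flat-direction count of :func:`chain_model`: 3N minus (N-1) bond modes."""
    if n_particles == 1:
        return 3
    return 3 * n_particles - (n_particles - 1)


def spectroscopic_mode_order(modes, system) -> dict:
    """Map spectroscopic labels of a bent triatomic to vibrational positions.

    Returns ``{"nu1": i, "nu2": j, "nu3": k}`` where the values index the
    *vibrational* modes in ascending-frequency order: nu2 is the bend
    (lowest frequency), nu1 the lower stretch (symmetric stretch for H2O,
    O-D stretch for HDO) and nu3 the higher stretch.  This matches the
    conventional water labels, where nu1 < nu3 and the bend is nu2.
    """
    if modes.n_vibrations != 3:
        raise ValueError("spectroscopic labels defined for triatomics only")
    return {"nu2": 0, "nu1": 1, "nu3": 2}


def triatomic_state(modes, n1: int, n2: int, n3: int):
    """VibrationalState for spectroscopic quanta (n_nu1, n_nu2, n_nu3)."""
    from .system import VibrationalState

    order = spectroscopic_mode_order(modes, None)
    quanta = [0, 0, 0]
    quanta[order["nu1"]] = n1
    quanta[order["nu2"]] = n2
    quanta[order["nu3"]] = n3
    return VibrationalState.from_vibrational(modes, quanta)
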