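"""Normal-mode analysis of a Cartesian Hessian.

Mass weighting, diagonalization, classification of zero-frequency
translation/rotation modes, and the Cartesian <-> normal coordinate map.
The input frame is taken as the frame of the localized, oriented molecule;
no Eckart rotation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import TRANS_ROT_FREQUENCY, WAVENUMBER_PER_HARTREE
from .system import HessianMatrix, MolecularSystem

#: eigenvalues below this (absolute, mass-weighted a.u.) count as zero modes
ZERO_TOL = 1e-8
#: eigenvalues below -NEG_TOL mean the geometry is not a minimum
NEG_TOL = 1e-6
#: ratio of smallest to largest principal moment of inertia below which a
#: geometry is treated as linear
LIN_TOL = 1e-6


@dataclass(frozen=True)
class NormalModeSet:
    """Result of a normal-mode analysis.

    Attributes
    ----------
    L
        3N x 3N orthogonal matrix; column k is the mass-weighted eigenvector
        of mode k.
    omega
        Per-mode angular frequency in E_h/hbar.  Translation/rotation modes
        carry the localization frequency (0.5 E_h/hbar) rather than zero.
    kind
        Per-mode label, ``"vibration"`` or ``"translation_rotation"``.
        Translation/rotation modes come first; vibrations follow in
        ascending frequency.
    """

    L: np.ndarray
    omega: np.ndarray
    kind: tuple

    @property
    def n_modes(self) -> int:
        return self.L.shape[1]

    @property
    def vibrational_indices(self) -> tuple:
        return tuple(i for i, k in enumerate(self.kind) if k == "vibration")

    @property
    def trans_rot_indices(self) -> tuple:
        return tuple(i for i, k in enumerate(self.kind) if k == "translation_rotation")

    @property
    def n_vibrations(self) -> int:
        return len(self.vibrational_indices)

    @property
    def vibrational_frequencies(self) -> np.ndarray:
        """Frequencies of the vibrational modes only (E_h/hbar, ascending)."""
        return self.omega[list(self.vibrational_indices)]

    def frequencies_cm1(self) -> np.ndarray:
        """Vibrational frequencies in cm^-1."""
        return self.vibrational_frequencies * WAVENUMBER_PER_HARTREE


def mass_weighted_hessian(system: MolecularSystem, hessian: HessianMatrix) -> np.ndarray:
    """Return ``M^{-1/2} H M^{-1/2}``, symmetrized.

    ``M`` is the diagonal mass matrix with each nuclear mass repeated three
    times.  The eigenvalues of the result are the squared vibrational
    angular frequencies.
    """
    H = hessian.matrix if isinstance(hessian, HessianMatrix) else HessianMatrix(hessian).matrix
    if H.shape[0] != 3 * system.n_nuclei:
        raise ValueError(
            f"Hessian side {H.shape[0]} does not match 3N = {3 * system.n_nuclei}"
        )
    inv_sqrt_m = 1.0 / np.sqrt(system.masses_3n)
    A = H * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    return 0.5 * (A + A.T)


def detect_linearity(system: MolecularSystem, lin_tol: float = LIN_TOL) -> bool:
    """True iff the equilibrium geometry is linear.

    Uses the principal moments of inertia: linear iff the smallest moment is
    below ``lin_tol`` times the largest.  One or two nuclei are always
    linear.
    """
    n = system.n_nuclei
    if n <= 2:
        return True
    pos = system.positions
    m = system.masses
    com = (m[:, None] * pos).sum(axis=0) / m.sum()
    d = pos - com
    # inertia tensor I = sum_i m_i (|d_i|^2 1 - d_i d_i^T)
    r2 = (d * d).sum(axis=1)
    inertia = (m * r2).sum() * np.eye(3) - np.einsum("i,ij,ik->jk", m, d, d)
    moments = np.linalg.eigvalsh(inertia)
    if moments[-1] <= 0:
        return True  # all nuclei coincide with the COM
    return moments[0] < lin_tol * moments[-1]


def expected_zero_modes(system: MolecularSystem) -> int:
    """6 for nonlinear, 5 for linear, 3 for a single nucleus."""
    if system.n_nuclei == 1:
        return 3
    return 5 if detect_linearity(system) else 6


def _sign_fix(L: np.ndarray) -> np.ndarray:
    """Make the largest-|component| entry of each column positive."""
    idx = np.argmax(np.abs(L), axis=0)
    signs = np.sign(L[idx, np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    return L * signs


def normal_mode_analysis(
    system: MolecularSystem,
    hessian: HessianMatrix,
    *,
    zero_tol: float = ZERO_TOL,
    neg_tol: float = NEG_TOL,
    n_zero: int | None = None,
    trans_rot_frequency: float = TRANS_ROT_FREQUENCY,
) -> NormalModeSet:
    """Diagonalize the mass-weighted Hessian and classify the modes.

    The ``n_zero`` lowest-|eigenvalue| modes are classified as
    translation/rotation and must have |eigenvalue| < ``zero_tol``; by
    default ``n_zero`` is 6 (nonlinear), 5 (linear) or 3 (single nucleus).
    Model systems whose potential deliberately leaves extra directions flat
    (e.g. collinear chains with springs acting along the axis only) may pass
    ``n_zero`` explicitly; all such flat modes are treated like
    translation/rotation, i.e. localized at ``trans_rot_frequency``.

    Raises
    ------
    ValueError
        If an eigenvalue is below ``-neg_tol`` (not a minimum) or the zero
        modes are inconsistent with the detected linearity ("bad Hessian").
    """
    A = mass_weighted_hessian(system, hessian)
    evals, evecs = np.linalg.eigh(A)

    if evals.min() < -neg_tol:
        raise ValueError(
            f"not a minimum: mass-weighted Hessian eigenvalue {evals.min():.3e} < -{neg_tol:g}"
        )

    if n_zero is None:
        n_zero = expected_zero_modes(system)
        strict = True
    else:
        strict = False

    order = np.argsort(np.abs(evals))
    zero_idx = order[:n_zero]
    vib_idx = order[n_zero:]

    if np.abs(evals[zero_idx]).max(initial=0.0) >= zero_tol:
        raise ValueError(
            "bad Hessian: expected "
            f"{n_zero} zero-frequency modes but |eigenvalue| up to "
            f"{np.abs(evals[zero_idx]).max():.3e} exceeds zero_tol={zero_tol:g}"
        )
    if strict and vib_idx.size and np.abs(evals[vib_idx]).min() < zero_tol:
        raise ValueError(
            "bad Hessian: more near-zero modes than the detected linearity allows"
        )

    vib_idx = vib_idx[np.argsort(evals[vib_idx])]
    # stable ordering of the degenerate zero block: by eigenvalue
    zero_idx = zero_idx[np.argsort(evals[zero_idx])]

    cols = np.concatenate([zero_idx, vib_idx])
    L = _sign_fix(evecs[:, cols])
    omega = np.empty(len(cols))
    omega[:n_zero] = trans_rot_frequency
    omega[n_zero:] = np.sqrt(np.maximum(evals[vib_idx], 0.0))
    kind = ("translation_rotation",) * n_zero + ("vibration",) * len(vib_idx)
    return NormalModeSet(L=L, omega=omega, kind=kind)


def cartesian_to_normal(
    modes: NormalModeSet, system: MolecularSystem, X: np.ndarray
) -> np.ndarray:
    """Normal coordinates ``q = L^T M^{1/2} (X - X_eq)``."""
    X = np.asarray(X, dtype=float).ravel()
    if X.size != system.x_eq.size:
        raise ValueError("coordinate dimension mismatch")
    return modes.L.T @ (np.sqrt(system.masses_3n) * (X - system.x_eq))


def normal_to_cartesian(
    modes: NormalModeSet, system: MolecularSystem, q: np.ndarray
) -> np.ndarray:
    """Inverse map ``X = X_eq + M^{-1/2} L q``."""
    q = np.asarray(q, dtype=float).ravel()
    if q.size != modes.n_modes:
        raise ValueError("normal-coordinate dimension mismatch")
    return system.x_eq + (modes.L @ q) / np.sqrt(system.masses_3n)
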