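"""Molecular system containers: geometry, masses, Hessian, vibrational state."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import mass_of


@dataclass(frozen=True)
class MolecularSystem:
    """Equilibrium geometry and nuclear masses, in atomic units.

    Parameters
    ----------
    labels
        Per-nucleus element/isotope tags (e.g. ``["O", "H", "D"]``).
    x_eq
        Flat array of 3N equilibrium Cartesian coordinates (bohr), in the
        order ``x1 y1 z1 x2 ...``.
    masses
        Per-nucleus masses in electron masses.  If omitted, standard
        isotope-averaged masses are looked up from the labels (``D``/``T``
        select the exact isotope mass).
    """

    labels: tuple
    x_eq: np.ndarray
    masses: np.ndarray

    def __init__(self, labels, x_eq, masses=None):
        labels = tuple(labels)
        x_eq = np.asarray(x_eq, dtype=float).ravel()
        n = len(labels)
        if n < 1:
            raise ValueError("a system needs at least one nucleus")
        if x_eq.size != 3 * n:
            raise ValueError(f"expected {3 * n} coordinates for {n} nuclei, got {x_eq.size}")
        if masses is None:
            masses = np.array([mass_of(lab) for lab in labels])
        else:
            masses = np.asarray(masses, dtype=float).ravel()
        if masses.size != n:
            raise ValueError("one mass per nucleus required")
        if not np.all(masses > 0):
            raise ValueError("all masses must be positive")
        if not np.all(np.isfinite(x_eq)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "x_eq", x_eq)
        object.__setattr__(self, "masses", masses)

    @property
    def n_nuclei(self) -> int:
        return len(self.labels)

    @property
    def positions(self) -> np.ndarray:
        """Equilibrium positions as an (N, 3) array (bohr)."""
        return self.x_eq.reshape(-1, 3)

    @property
    def masses_3n(self) -> np.ndarray:
        """Each nuclear mass repeated three times, matching the coordinate order."""
        return np.repeat(self.masses, 3)


@dataclass(frozen=True)
class HessianMatrix:
    """Cartesian Hessian of the potential, E_h/bohr^2, coordinate order x1 y1 z1 x2 ..."""

    matrix: np.ndarray

    def __init__(self, matrix):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("Hessian must be square")
        if matrix.shape[0] % 3 != 0:
            raise ValueError("Hessian side must be a multiple of 3")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("Hessian has non-finite entries")
        scale = max(np.abs(matrix).max(), 1e-300)
        if np.abs(matrix - matrix.T).max() > 1e-8 * scale:
            raise ValueError("Hessian is not symmetric (relative tolerance 1e-8)")
        object.__setattr__(self, "matrix", matrix)

    @property
    def n_coords(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class VibrationalState:
    """One non-negative quantum number per normal mode (all 3N of them).

    Translation/rotation modes must carry ``n = 0``; only vibrational modes
    may be excited.  Use :meth:`from_vibrational` to build a state from the
    quanta of the vibrational modes alone (ascending-frequency order).
    """

    n: tuple = field(default=())

    def __init__(self, n):
        n = tuple(int(v) for v in n)
        if any(v < 0 for v in n):
            raise ValueError("quantum numbers must be non-negative")
        object.__setattr__(self, "n", n)

    @classmethod
    def from_vibrational(cls, modes, vib_quanta) -> "VibrationalState":
        """State with the given quanta on the vibrational modes of ``modes``.

        ``vib_quanta`` is indexed in the mode set's vibrational order
        (ascending frequency); translation/rotation modes get ``n = 0``.
        """
        vib_idx = modes.vibrational_indices
        vib_quanta = tuple(int(v) for v in vib_quanta)
        if len(vib_quanta) != len(vib_idx):
            raise ValueError(
                f"expected {len(vib_idx)} vibrational quanta, got {len(vib_quanta)}"
            )
        n = [0] * modes.n_modes
        for i, q in zip(vib_idx, vib_quanta):
            n[i] = q
        return cls(n)

    def total_quanta(self) -> int:
        return sum(self.n)

    def validate_against(self, modes) -> None:
        if len(self.n) != modes.n_modes:
            raise ValueError(
                f"state has {len(self.n)} entries for {modes.n_modes} modes"
            )
        for i, kind in enumerate(modes.kind):
            if kind == "translation_rotation" and self.n[i] != 0:
                raise ValueError(
                    f"mode {i} is translation/rotation and must have n = 0"
                )
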