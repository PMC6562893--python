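"""Vibrational-state nuclear densities and their exact 3D marginals.

The N-nucleus density of a harmonic vibrational eigenstate is a product of
1D harmonic-oscillator densities in the normal coordinates, i.e. a
polynomial times a Gaussian in the 3N Cartesian coordinates.  The
one-nucleus density of nucleus j is obtained by integrating out the other
3(N-1) coordinates; this is done in closed form by
:meth:`~nucdens.polygauss.PolyGaussian.marginalize`, so densities are exact
up to floating point, never gridded approximations.

Translation/rotation modes enter as harmonic-oscillator ground states at a
narrow localization frequency (0.5 E_h/hbar by default), which pins the
molecule in place and orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import hermite as H
from scipy import ndimage

from .harmonic import NormalModeSet
from .polygauss import PolyGaussian, _linear_form_power, poly_mul
from .system import MolecularSystem, VibrationalState

#: refuse to expand polynomials beyond this total degree
MAX_POLY_DEGREE = 40


def _hermite_sq_coeffs(n: int, omega: float) -> np.ndarray:
    """Power coefficients of H_n(sqrt(omega) q)^2 in q (physicists' Hermite)."""
    coef = H.herm2poly([0.0] * n + [1.0])  # H_n(x) as powers of x
    scaled = coef * np.sqrt(omega) ** np.arange(n + 1)  # x -> sqrt(omega) q
    return np.convolve(scaled, scaled)


def ho_density_1d(n: int, omega: float) -> PolyGaussian:
    """Probability density |phi_n(q)|^2 of the 1D harmonic oscillator.

    |phi_n(q)|^2 = [sqrt(omega/pi) / (2^n n!)] * H_n(sqrt(omega) q)^2
                   * exp(-omega q^2),

    normalized to 1.  ``omega`` is the angular frequency in E_h/hbar and q
    a mass-weighted normal coordinate.
    """
    if n < 0:
        raise ValueError("quantum number must be non-negative")
    if omega <= 0:
        raise ValueError("frequency must be positive")
    sq = _hermite_sq_coeffs(n, omega)
    poly = {(k,): c for k, c in enumerate(sq) if c != 0.0}
    logZ = 0.5 * math.log(omega / math.pi) - n * math.log(2.0) - math.lgamma(n + 1)
    return PolyGaussian(dim=1, poly=poly, A=np.array([[omega]]), c=np.zeros(1), logZ=logZ)


def assemble_state_density(
    modes: NormalModeSet,
    state: VibrationalState,
    system: MolecularSystem,
) -> PolyGaussian:
    """The 3N-dimensional density |psi_nuc(X)|^2 of a vibrational eigenstate.

    Composes the product of per-mode HO densities with the linear map
    ``q = L^T M^{1/2} (X - X_eq)`` and includes the mass-weighting Jacobian,
    so the result integrates to 1 over Cartesian coordinates.  The returned
    PolyGaussian is centered at the equilibrium geometry and is evaluated at
    absolute coordinates X (bohr).
    """
    state.validate_against(modes)
    dim = 3 * system.n_nuclei
    if modes.n_modes != dim:
        raise ValueError("mode set does not match the system size")
    if 2 * state.total_quanta() > MAX_POLY_DEGREE:
        raise ValueError(
            f"state polynomial degree {2 * state.total_quanta()} exceeds "
            f"the supported maximum {MAX_POLY_DEGREE}"
        )

    sqrt_m = np.sqrt(system.masses_3n)
    G = sqrt_m[:, None] * modes.L  # column k: gradient of q_k w.r.t. X
    omega = modes.omega

    A = (G * omega) @ G.T
    logZ = 1.5 * np.log(system.masses).sum()
    poly = {(0,) * dim: 1.0}
    for k in range(modes.n_modes):
        w = omega[k]
        nk = state.n[k]
        logZ += 0.5 * math.log(w / math.pi) - nk * math.log(2.0) - math.lgamma(nk + 1)
        if nk > 0:
            sq = _hermite_sq_coeffs(nk, w)
            factor = {(0,) * dim: 0.0}
            for p, coeff in enumerate(sq):
                if coeff != 0.0:
                    mono = _linear_form_power(tuple(G[:, k]), 0.0, p, dim)
                    for e, c in mono.items():
                        factor[e] = factor.get(e, 0.0) + coeff * c
            poly = poly_mul(poly, factor)
    return PolyGaussian(dim=dim, poly=poly, A=0.5 * (A + A.T), c=system.x_eq, logZ=logZ)


def marginalize_to_nucleus(
    full: PolyGaussian, j: int, system: MolecularSystem | None = None
) -> PolyGaussian:
    """One-nucleus density rho_j: integrate out all nuclei except nucleus j.

    ``j`` is a 0-based nucleus index.  If ``system`` is given, the
    marginalization is carried out in mass-weighted coordinates (better
    conditioned when masses differ strongly) and rescaled back at the end;
    the result is identical in exact arithmetic.
    """
    n = full.dim // 3
    if full.dim != 3 * n:
        raise ValueError("full density dimension must be a multiple of 3")
    if not 0 <= j < n:
        raise ValueError(f"nucleus index {j} out of range for {n} nuclei")
    keep = [3 * j, 3 * j + 1, 3 * j + 2]
    if system is None:
        return full.marginalize(keep)
    if system.n_nuclei != n:
        raise ValueError("system does not match the density dimension")
    inv_sqrt_m = 1.0 / np.sqrt(system.masses_3n)
    pg_u = full.change_variables(np.diag(inv_sqrt_m))
    marg_u = pg_u.marginalize(keep)
    sqrt_mj = math.sqrt(system.masses[j])
    return marg_u.change_variables(np.eye(3) * sqrt_mj)


class TotalDensity:
    """Sum of the per-nucleus densities: rho(R) = sum_j rho_j(R).

    Integrates to the number of nuclei.  Callable on (m, 3) point arrays.
    """

    def __init__(self, per_nucleus):
        per_nucleus = list(per_nucleus)
        if not per_nucleus:
            raise ValueError("need at least one one-nucleus density")
        self.per_nucleus = per_nucleus

    def value(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(pts.shape[0])
        for pg in self.per_nucleus:
            out += pg.value(pts)
        return out if np.asarray(points).ndim > 1 else float(out[0])

    __call__ = value


def one_nucleus_density_total(per_nucleus) -> TotalDensity:
    """The molecule's one-nucleus density: the sum over all nuclei."""
    return TotalDensity(per_nucleus)


@dataclass(frozen=True)
class DensityGrid:
    """Scalar field sampled on a regular 1D/2D/3D grid embedded in 3D space.

    ``origin`` is the position of index (0, ..., 0); ``axes[k]`` is the
    spacing vector of grid direction k (orthogonal); ``values[i0, i1, ...]``
    is the density (bohr^-3) at ``origin + sum_k i_k * axes[k]``.
    """

    origin: np.ndarray
    axes: np.ndarray  # (ndim_grid, 3)
    shape: tuple
    values: np.ndarray

    @property
    def points(self) -> np.ndarray:
        """All grid points, shape (prod(shape), 3), C-index order."""
        idx = np.indices(self.shape).reshape(len(self.shape), -1).T
        return self.origin + idx @ self.axes

    def axis_coords(self, k: int) -> np.ndarray:
        """Signed 1D coordinate along grid direction k (bohr from origin)."""
        return np.arange(self.shape[k]) * np.linalg.norm(self.axes[k])

    def integral(self) -> float:
        """Riemann sum; volumetric only for 3D grids (element = |a0.(a1 x a2)|)."""
        if len(self.shape) == 3:
            vol = abs(np.linalg.det(self.axes))
        else:
            vol = np.prod([np.linalg.norm(a) for a in self.axes])
        return float(self.values.sum() * vol)


def evaluate_on_grid(density, origin, axes, shape) -> DensityGrid:
    """Evaluate a density (PolyGaussian or callable on (m,3) arrays) on a grid.

    ``axes`` are the spacing vectors (one per grid dimension, mutually
    orthogonal, bohr); ``shape`` the point counts.
    """
    origin = np.asarray(origin, dtype=float).ravel()
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    shape = tuple(int(s) for s in shape)
    if origin.size != 3 or axes.shape[1] != 3:
        raise ValueError("grids are embedded in 3D space")
    if len(shape) != axes.shape[0] or not 1 <= len(shape) <= 3:
        raise ValueError("need one spacing vector per grid dimension (1-3)")
    norms = np.linalg.norm(axes, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate grid axis (zero length)")
    for a in range(len(shape)):
        for b in range(a + 1, len(shape)):
            if abs(axes[a] @ axes[b]) > 1e-10 * norms[a] * norms[b]:
                raise ValueError("grid axes must be orthogonal")
    idx = np.indices(shape).reshape(len(shape), -1).T
    pts = origin + idx @ axes
    fn = density.value if hasattr(density, "value") else density
    vals = np.asarray(fn(pts), dtype=float).reshape(shape)
    # exact densities may round to tiny negatives near depleted regions
    floor = -1e-10 * max(vals.max(), 0.0)
    if vals.min() < floor:
        raise ValueError("density is significantly negative on the grid")
    vals = np.maximum(vals, 0.0)
    return DensityGrid(origin=origin, axes=axes, shape=shape, values=vals)


def count_local_maxima(grid: DensityGrid, window=None) -> int:
    """Number of strict local maxima of the sampled field.

    A grid point counts if it is strictly greater than every neighbor
    (including diagonals) and is not on the grid boundary.  ``window``
    optionally restricts counting to an index region given as a sequence of
    (lo, hi) index bounds per grid dimension (hi exclusive).
    """
    v = grid.values
    footprint = np.ones((3,) * v.ndim, dtype=bool)
    footprint[(1,) * v.ndim] = False
    neighbor_max = ndimage.maximum_filter(v, footprint=footprint, mode="constant", cval=-np.inf)
    is_max = v > neighbor_max
    # boundary points cannot be verified against all neighbors
    for ax in range(v.ndim):
        sl = [slice(None)] * v.ndim
        sl[ax] = 0
        is_max[tuple(sl)] = False
        sl[ax] = -1
        is_max[tuple(sl)] = False
    if window is not None:
        if len(window) != v.ndim:
            raise ValueError("window must give (lo, hi) per grid dimension")
        mask = np.zeros_like(is_max)
        sl = tuple(slice(int(lo), int(hi)) for lo, hi in window)
        for (lo, hi), size in zip(window, v.shape):
            if not 0 <= lo < hi <= size:
                raise ValueError("window outside grid")
        mask[sl] = True
        is_max &= mask
    return int(is_max.sum())
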