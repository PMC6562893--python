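"""Exact algebra of polynomial-times-Gaussian functions.

A :class:`PolyGaussian` represents

    f(u) = exp(logZ) * P(u - c) * exp(-(u - c)^T A (u - c))

with ``P`` a sparse multivariate polynomial, ``A`` symmetric positive
definite and ``c`` the center.  The family is closed under products,
invertible affine changes of variables, and marginalization, which is what
makes harmonic vibrational densities exactly reducible: a product of 1D
harmonic-oscillator densities in normal coordinates is a PolyGaussian in
Cartesian displacements, and integrating out any subset of coordinates
stays in the family.

Marginalization completes the square in the integrated coordinates and
replaces their monomials by Gaussian moments (Isserlis' theorem), so no
grids or quadrature are involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

Poly = dict  # {exponent tuple: coefficient}


# ---------------------------------------------------------------------------
# sparse polynomial helpers
# ---------------------------------------------------------------------------

def poly_mul(p: Poly, q: Poly) -> Poly:
    out: Poly = {}
    for ea, ca in p.items():
        for eb, cb in q.items():
            key = tuple(a + b for a, b in zip(ea, eb))
            out[key] = out.get(key, 0.0) + ca * cb
    return _prune(out)


def poly_degree(p: Poly) -> int:
    return max((sum(e) for e in p), default=0)


def _prune(p: Poly, tol: float = 0.0) -> Poly:
    return {e: c for e, c in p.items() if c != 0.0 and abs(c) > tol}


def _linear_form_power(coeffs: tuple, const: float, power: int, dim: int) -> Poly:
    """(const + sum_j coeffs[j] w_j) ** power as a sparse polynomial."""
    base: Poly = {}
    if const != 0.0:
        base[(0,) * dim] = const
    for j, cj in enumerate(coeffs):
        if cj != 0.0:
            e = [0] * dim
            e[j] = 1
            base[tuple(e)] = cj
    out: Poly = {(0,) * dim: 1.0}
    for _ in range(power):
        out = poly_mul(out, base)
    return out


def poly_affine(p: Poly, T: np.ndarray, t: np.ndarray) -> Poly:
    """Substitute v = T w + t into P(v); returns a polynomial in w."""
    d_old, d_new = T.shape
    t = np.asarray(t, dtype=float).ravel()
    # cache powers of each substituted variable
    pow_cache: dict[tuple[int, int], Poly] = {}

    def var_power(i: int, a: int) -> Poly:
        key = (i, a)
        if key not in pow_cache:
            pow_cache[key] = _linear_form_power(tuple(T[i]), float(t[i]), a, d_new)
        return pow_cache[key]

    out: Poly = {}
    for exps, coeff in p.items():
        term: Poly = {(0,) * d_new: coeff}
        for i, a in enumerate(exps):
            if a:
                term = poly_mul(term, var_power(i, a))
        for e, c in term.items():
            out[e] = out.get(e, 0.0) + c
    return _prune(out)


def poly_eval(p: Poly, pts: np.ndarray) -> np.ndarray:
    """Evaluate P at points of shape (m, dim)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    m, dim = pts.shape
    if not p:
        return np.zeros(m)
    max_deg = [0] * dim
    for e in p:
        for i, a in enumerate(e):
            max_deg[i] = max(max_deg[i], a)
    # power tables per variable
    powers = [None] * dim
    for i in range(dim):
        tab = np.ones((max_deg[i] + 1, m))
        for a in range(1, max_deg[i] + 1):
            tab[a] = tab[a - 1] * pts[:, i]
        powers[i] = tab
    out = np.zeros(m)
    for e, c in p.items():
        term = np.full(m, c)
        for i, a in enumerate(e):
            if a:
                term = term * powers[i][a]
        out += term
    return out


# ---------------------------------------------------------------------------
# Gaussian moments (Isserlis recurrence)
# ---------------------------------------------------------------------------

def gaussian_moments(cov: np.ndarray, monomials) -> dict:
    """E[z^alpha] for a zero-mean Gaussian with covariance ``cov``.

    Uses the Isserlis recurrence
    ``E[z_i z^beta] = sum_j cov[i, j] * beta_j * E[z^(beta - e_j)]``.
    """
    cov = np.asarray(cov, dtype=float)
    memo: dict = {}

    def mom(alpha: tuple) -> float:
        if sum(alpha) == 0:
            return 1.0
        if sum(alpha) % 2 == 1:
            return 0.0
        if alpha in memo:
            return memo[alpha]
        i = next(k for k, a in enumerate(alpha) if a > 0)
        beta = list(alpha)
        beta[i] -= 1
        total = 0.0
        for j, bj in enumerate(beta):
            if bj > 0:
                gamma = list(beta)
                gamma[j] -= 1
                total += cov[i, j] * bj * mom(tuple(gamma))
        memo[alpha] = total
        return total

    return {tuple(a): mom(tuple(a)) for a in monomials}


# ---------------------------------------------------------------------------
# the PolyGaussian class
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolyGaussian:
    """P(u - c) * exp(logZ - (u - c)^T A (u - c)) on R^dim."""

    dim: int
    poly: Poly
    A: np.ndarray
    c: np.ndarray
    logZ: float = 0.0

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        c = np.asarray(self.c, dtype=float).ravel()
        if A.shape != (self.dim, self.dim):
            raise ValueError("exponent matrix shape mismatch")
        if c.size != self.dim:
            raise ValueError("center dimension mismatch")
        if np.abs(A - A.T).max() > 1e-10 * max(np.abs(A).max(), 1.0):
            raise ValueError("exponent matrix must be symmetric")
        object.__setattr__(self, "A", 0.5 * (A + A.T))
        object.__setattr__(self, "c", c)
        for e in self.poly:
            if len(e) != self.dim:
                raise ValueError("polynomial exponent tuple of wrong length")

    # -- evaluation ---------------------------------------------------------

    def value(self, points: np.ndarray) -> np.ndarray:
        """Evaluate at points of shape (m, dim) (or a single point)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.dim:
            raise ValueError(f"points must have {self.dim} columns")
        d = pts - self.c
        expo = -np.einsum("mi,ij,mj->m", d, self.A, d) + self.logZ
        vals = poly_eval(self.poly, d) * np.exp(expo)
        return vals if np.asarray(points).ndim > 1 else float(vals[0])

    def __call__(self, points):
        return self.value(points)

    def degree(self) -> int:
        return poly_degree(self.poly)

    # -- algebra ------------------------------------------------------------

    def multiply(self, other: "PolyGaussian") -> "PolyGaussian":
        """Pointwise product of two PolyGaussians on the same space."""
        if other.dim != self.dim:
            raise ValueError("dimension mismatch")
        A = self.A + other.A
        rhs = self.A @ self.c + other.A @ other.c
        c = np.linalg.solve(A, rhs)
        # constant from completing the square
        const = -(self.c @ self.A @ self.c) - (other.c @ other.A @ other.c) + c @ A @ c
        eye = np.eye(self.dim)
        p1 = poly_affine(self.poly, eye, c - self.c)
        p2 = poly_affine(other.poly, eye, c - other.c)
        return PolyGaussian(
            dim=self.dim,
            poly=poly_mul(p1, p2),
            A=A,
            c=c,
            logZ=self.logZ + other.logZ + const,
        )

    def change_variables(
        self, T: np.ndarray, t: np.ndarray | None = None, *, jacobian: bool = True
    ) -> "PolyGaussian":
        """Density pullback under u = T w + t.

        Returns g(w) = f(T w + t) * |det T| (the |det T| factor keeps a
        probability density normalized; pass ``jacobian=False`` for a plain
        function composition).
        """
        T = np.asarray(T, dtype=float)
        if T.shape != (self.dim, self.dim):
            raise ValueError("T must be square of the same dimension")
        t = np.zeros(self.dim) if t is None else np.asarray(t, dtype=float).ravel()
        A = T.T @ self.A @ T
        c = np.linalg.solve(T, self.c - t)
        poly = poly_affine(self.poly, T, np.zeros(self.dim))
        sign, logdet = np.linalg.slogdet(T)
        if sign == 0:
            raise ValueError("singular change of variables")
        logZ = self.logZ + (logdet if jacobian else 0.0)
        return PolyGaussian(dim=self.dim, poly=poly, A=0.5 * (A + A.T), c=c, logZ=logZ)

    def marginalize(self, keep) -> "PolyGaussian":
        """Integrate out all coordinates not in ``keep`` (exactly).

        Completes the square of the exponent in the integrated block and
        replaces integrated-variable monomials with moments of the
        fluctuation Gaussian.
        """
        keep = list(keep)
        drop = [i for i in range(self.dim) if i not in keep]
        if not drop:
            # permutation only
            if keep == list(range(self.dim)):
                return self
            P = np.zeros((self.dim, self.dim))
            for new, old in enumerate(keep):
                P[old, new] = 1.0
            return self.change_variables(P, jacobian=False)
        d_r, d_y = len(keep), len(drop)

        A_rr = self.A[np.ix_(keep, keep)]
        A_ry = self.A[np.ix_(keep, drop)]
        A_yy = self.A[np.ix_(drop, drop)]
        try:
            cho = np.linalg.cholesky(A_yy)
        except np.linalg.LinAlgError:
            raise ValueError(
                "exponent matrix not positive definite on the integrated block"
            ) from None
        Ayy_inv_Ayr = np.linalg.solve(A_yy, A_ry.T)
        S = A_rr - A_ry @ Ayy_inv_Ayr
        S = 0.5 * (S + S.T)

        # rewrite P(delta_r, delta_y) with delta_y = -A_yy^{-1} A_yr delta_r + z:
        # substitution (delta_r, delta_y) = T (delta_r, z)
        T = np.zeros((self.dim, self.dim))
        for new, old in enumerate(keep):
            T[old, new] = 1.0
        for new, old in enumerate(drop):
            T[old, d_r + new] = 1.0
        for row_new, old in enumerate(drop):
            T[old, :d_r] = -Ayy_inv_Ayr[row_new]
        p_sub = poly_affine(self.poly, T, np.zeros(self.dim))

        # integrate z-monomials against the normalized Gaussian exp(-z^T A_yy z)
        cov = 0.5 * np.linalg.inv(A_yy)
        z_monos = {e[d_r:] for e in p_sub}
        moments = gaussian_moments(cov, z_monos)
        out: Poly = {}
        for e, coeff in p_sub.items():
            mom = moments[e[d_r:]]
            if mom != 0.0:
                key = e[:d_r]
                out[key] = out.get(key, 0.0) + coeff * mom
        logdet_Ayy = 2.0 * np.log(np.diag(cho)).sum()
        logZ = self.logZ + 0.5 * d_y * math.log(math.pi) - 0.5 * logdet_Ayy
        return PolyGaussian(
            dim=d_r, poly=_prune(out), A=S, c=self.c[keep], logZ=logZ
        )

    def integral(self) -> float:
        """Exact integral over R^dim."""
        cho = np.linalg.cholesky(self.A)
        cov = 0.5 * np.linalg.inv(self.A)
        moments = gaussian_moments(cov, set(self.poly))
        total = sum(c * moments[e] for e, c in self.poly.items())
        logdet = 2.0 * np.log(np.diag(cho)).sum()
        return total * math.exp(
            self.logZ + 0.5 * self.dim * math.log(math.pi) - 0.5 * logdet
        )

    def normalized(self) -> "PolyGaussian":
        """Rescale so the integral is exactly 1."""
        z = self.integral()
        if z <= 0:
            raise ValueError("cannot normalize: non-positive integral")
        return PolyGaussian(
            dim=self.dim, poly=self.poly, A=self.A, c=self.c,
            logZ=self.logZ - math.log(z),
        )
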