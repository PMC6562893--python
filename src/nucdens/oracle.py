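"""Brute-force marginalization oracles and independent density formulas.

Everything here deliberately avoids the closed-form PolyGaussian
marginalization so it can serve as an independent check:

* :func:`product_density_evaluator` evaluates the N-nucleus density
  directly as a product of 1D harmonic-oscillator densities (Clenshaw
  Hermite evaluation, no polynomial expansion).
* :func:`brute_force_marginal` integrates the high-dimensional density
  literally, by iterated Gauss-Hermite quadrature (few integrated
  dimensions) or importance-sampled Monte Carlo (many).
* :func:`schur_gaussian_marginal` is the closed-form marginal of the
  all-ground-state Gaussian via the covariance block (Schur route).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from numpy.polynomial import hermite as H

from .harmonic import NormalModeSet
from .polygauss import PolyGaussian
from .system import MolecularSystem, VibrationalState


def product_density_evaluator(
    modes: NormalModeSet, state: VibrationalState, system: MolecularSystem
):
    """Direct evaluator of |psi_nuc(X)|^2 as a product over modes.

    Returns a callable on (m, 3N) arrays of absolute Cartesian coordinates.
    """
    state.validate_against(modes)
    sqrt_m = np.sqrt(system.masses_3n)
    G = sqrt_m[:, None] * modes.L  # q = G^T (X - X_eq)
    omega = modes.omega
    n = state.n
    log_jac = 1.5 * np.log(system.masses).sum()
    herm_coef = [np.array([0.0] * nk + [1.0]) for nk in n]

    def evaluate(points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = (pts - system.x_eq) @ G  # (m, 3N)
        log_vals = np.full(q.shape[0], log_jac)
        for k in range(modes.n_modes):
            w, nk = omega[k], n[k]
            xi = math.sqrt(w) * q[:, k]
            norm = 0.5 * math.log(w / math.pi) - nk * math.log(2.0) - math.lgamma(nk + 1)
            hval = H.hermval(xi, herm_coef[k]) if nk else np.ones_like(xi)
            with np.errstate(divide="ignore"):
                log_vals += norm - w * q[:, k] ** 2 + 2.0 * np.log(np.abs(hval))
        return np.exp(log_vals)

    return evaluate


def schur_gaussian_marginal(
    modes: NormalModeSet, system: MolecularSystem, j: int
) -> PolyGaussian:
    """Ground-state one-nucleus density via the Gaussian covariance block.

    For the all-n=0 state the N-nucleus density is the Gaussian
    N(X_eq, Sigma) with Sigma = M^{-1/2} L diag(1/(2 omega)) L^T M^{-1/2};
    its marginal for nucleus j is the normal density with the corresponding
    3x3 covariance block — no square completion or moment algebra involved.
    """
    inv_sqrt_m = 1.0 / np.sqrt(system.masses_3n)
    B = inv_sqrt_m[:, None] * modes.L
    sigma = (B / (2.0 * modes.omega)) @ B.T
    sl = slice(3 * j, 3 * j + 3)
    block = sigma[sl, sl]
    prec = np.linalg.inv(block)
    _, logdet = np.linalg.slogdet(block)
    logZ = -1.5 * math.log(2.0 * math.pi) - 0.5 * logdet
    return PolyGaussian(
        dim=3, poly={(0, 0, 0): 1.0}, A=0.5 * prec, c=system.x_eq[sl], logZ=logZ
    )


def _conditional(full: PolyGaussian, j: int):
    """Partition the exponent of ``full`` for nucleus j: returns
    (keep, drop, A_yy, Ayy_inv_Ayr, S) in the coordinates of ``full``."""
    keep = [3 * j, 3 * j + 1, 3 * j + 2]
    drop = [i for i in range(full.dim) if i not in keep]
    A_rr = full.A[np.ix_(keep, keep)]
    A_ry = full.A[np.ix_(keep, drop)]
    A_yy = full.A[np.ix_(drop, drop)]
    Ayy_inv_Ayr = np.linalg.solve(A_yy, A_ry.T)
    S = A_rr - A_ry @ Ayy_inv_Ayr
    return keep, drop, A_yy, Ayy_inv_Ayr, S


def brute_force_marginal(
    full: PolyGaussian,
    j: int,
    points,
    method: str = "quadrature",
    seed: int | None = None,
    *,
    n_nodes: int = 60,
    n_samples: int = 1_000_000,
    evaluator=None,
):
    """Literal high-dimensional integration of the one-nucleus density.

    Integrates the N-nucleus density over all coordinates except those of
    nucleus ``j`` at each 3D evaluation point.  ``method="quadrature"``
    uses iterated Gauss-Hermite centered on the conditional Gaussian of the
    exponent (allowed for at most 4 integrated dimensions; exact for
    polynomial-times-Gaussian integrands).  ``method="monte_carlo"``
    importance-samples the conditional Gaussian and reports a standard
    error.  ``evaluator`` optionally replaces ``full.value`` as the density
    evaluator (e.g. :func:`product_density_evaluator`).

    Returns ``(values, stderr)``; ``stderr`` is None for quadrature.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("evaluation points must be 3D")
    keep, drop, A_yy, Ayy_inv_Ayr, _ = _conditional(full, j)
    d_y = len(drop)
    fn = evaluator if evaluator is not None else full.value
    c_r = full.c[keep]
    c_y = full.c[drop]

    if method == "quadrature":
        if d_y > 4:
            raise ValueError(
                f"quadrature limited to 4 integrated dimensions, got {d_y}"
            )
        if n_nodes < 2:
            raise ValueError("need at least 2 quadrature nodes")
        nodes, weights = H.hermgauss(n_nodes)
        evals, vecs = np.linalg.eigh(A_yy)
        scale = vecs / np.sqrt(evals)  # y = y_hat + scale @ t
        log_jac = -0.5 * np.log(evals).sum()
        grids = np.array(list(itertools.product(nodes, repeat=d_y)))  # (G, d_y)
        # modified weights w * e^{x^2}: the GH weight is divided back out of
        # the integrand without ever forming the overflowing e^{|t|^2}
        log_w = np.log(weights) + nodes**2
        wmod = np.exp(
            np.array(list(itertools.product(log_w, repeat=d_y))).sum(axis=1)
        )
        offsets = grids @ scale.T  # (G, d_y)
        values = np.empty(pts.shape[0])
        for m, R in enumerate(pts):
            y_hat = c_y - Ayy_inv_Ayr @ (R - c_r)
            u = np.empty((grids.shape[0], full.dim))
            u[:, keep] = R
            u[:, drop] = y_hat + offsets
            values[m] = np.sum(wmod * fn(u)) * math.exp(log_jac)
        return values, None

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        cov = 0.5 * np.linalg.inv(A_yy)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((n_samples, d_y)) @ chol.T
        _, logdet_cov = np.linalg.slogdet(cov)
        log_q0 = -0.5 * d_y * math.log(2.0 * math.pi) - 0.5 * logdet_cov
        # q(y) = N(y_hat, cov);  estimate E_q[f / q]
        quad = np.einsum("mi,ij,mj->m", z, A_yy, z)  # = z^T A_yy z = half-prec form
        log_q = log_q0 - quad  # since cov^{-1}/2 = A_yy
        values = np.empty(pts.shape[0])
        stderr = np.empty(pts.shape[0])
        for m, R in enumerate(pts):
            y_hat = c_y - Ayy_inv_Ayr @ (R - c_r)
            u = np.empty((n_samples, full.dim))
            u[:, keep] = R
            u[:, drop] = y_hat + z
            ratio = fn(u) * np.exp(-log_q)
            values[m] = ratio.mean()
            stderr[m] = ratio.std(ddof=1) / math.sqrt(n_samples)
        return values, stderr

    raise ValueError(f"unknown method {method!r}")
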