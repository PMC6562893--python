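"""Analytic-vs-brute-force validation suite.

Every closed-form marginal the package produces is checked here against a
literal integration of the N-nucleus density: iterated Gauss-Hermite
quadrature where few dimensions are integrated out (exact for
polynomial-times-Gaussian integrands), importance-sampled Monte Carlo for
water.  The suite backs the ``nucdens oracle-check`` subcommand and is
reused by the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import assemble_state_density, marginalize_to_nucleus
from .fixtures import chain_model, chain_zero_modes, water_model
from .harmonic import normal_mode_analysis
from .oracle import brute_force_marginal, product_density_evaluator, schur_gaussian_marginal
from .system import VibrationalState


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    value: float
    detail: str


#: fixed probe-point offsets, in units of the nucleus' largest marginal
#: std dev; the first sits on the equilibrium position
PROBE_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 0.5, 0.0],
        [-1.0, 0.5, 0.2],
        [0.5, -1.0, 0.0],
        [1.5, 1.0, 0.5],
    ]
)


def nucleus_sigma_max(modes, system, j: int) -> float:
    """Largest std dev of the ground-state marginal of nucleus j (bohr)."""
    cov = np.linalg.inv(2.0 * schur_gaussian_marginal(modes, system, j).A)
    return float(np.sqrt(np.linalg.eigvalsh(cov).max()))


def probe_points(modes, system, j: int) -> np.ndarray:
    """Five fixed probe points around nucleus j, scaled to its spread."""
    sig = nucleus_sigma_max(modes, system, j)
    return system.positions[j] + sig * PROBE_OFFSETS


def chain_quadrature_error(
    n_quanta: int, masses=(1.0, 1.0), spring: float = 1.0, n_points: int = 50,
    n_nodes: int = 60,
) -> float:
    """Max relative deviation, analytic marginal vs Gauss-Hermite, 2-chain.

    The first particle's density is compared on ``n_points`` positions along
    the chain axis spanning +-4 ground widths.
    """
    system, hess = chain_model(2, masses=np.asarray(masses), spring_constants=[spring])
    modes = normal_mode_analysis(system, hess, n_zero=chain_zero_modes(2))
    state = VibrationalState.from_vibrational(modes, [n_quanta])
    full = assemble_state_density(modes, state, system)
    rho = marginalize_to_nucleus(full, 0, system)

    sig = nucleus_sigma_max(modes, system, 0)
    x = np.linspace(-4 * sig, 4 * sig, n_points)
    pts = system.positions[0] + x[:, None] * np.array([1.0, 0.0, 0.0])
    analytic = rho.value(pts)
    oracle, _ = brute_force_marginal(full, 0, pts, "quadrature", n_nodes=n_nodes)
    return float(np.max(np.abs(analytic - oracle) / np.abs(oracle)))


def water_mc_deviation(
    vib_quanta, nucleus: int, seed: int, n_samples: int, isotopes=("O", "H", "H")
):
    """Monte-Carlo check of one water-state marginal at 5 probe points.

    Returns (max |analytic - MC| / stderr, analytic values, MC values,
    stderr); the direct product-form evaluator feeds the integrator, so the
    check is independent of the polynomial expansion and of the closed-form
    marginalization.
    """
    system, hess = water_model(isotopes=isotopes)
    modes = normal_mode_analysis(system, hess)
    state = VibrationalState.from_vibrational(modes, vib_quanta)
    full = assemble_state_density(modes, state, system)
    rho = marginalize_to_nucleus(full, nucleus, system)
    pts = probe_points(modes, system, nucleus)
    analytic = rho.value(pts)
    evaluator = product_density_evaluator(modes, state, system)
    mc, stderr = brute_force_marginal(
        full, nucleus, pts, "monte_carlo", seed=seed,
        n_samples=n_samples, evaluator=evaluator,
    )
    # for states where the importance ratio is exactly constant (pure
    # Gaussians) the sample stderr collapses to roundoff; floor it at
    # float precision of the estimate itself
    denom = np.maximum(stderr, 1e-12 * np.abs(mc))
    n_dev = float(np.max(np.abs(analytic - mc) / denom))
    return n_dev, analytic, mc, stderr


def groundstate_schur_deviation() -> float:
    """Max relative deviation of the all-n=0 analytic marginals from the
    Schur-complement Gaussian, over all water nuclei at their probe points."""
    system, hess = water_model()
    modes = normal_mode_analysis(system, hess)
    state = VibrationalState.from_vibrational(modes, [0, 0, 0])
    full = assemble_state_density(modes, state, system)
    worst = 0.0
    for j in range(system.n_nuclei):
        rho = marginalize_to_nucleus(full, j, system)
        schur = schur_gaussian_marginal(modes, system, j)
        pts = probe_points(modes, system, j)
        a, b = rho.value(pts), schur.value(pts)
        worst = max(worst, float(np.max(np.abs(a - b) / np.abs(b))))
    return worst


def normalization_errors(vib_quanta=(0, 1, 0)) -> tuple[float, float]:
    """(max |integral(rho_j) - 1|, |integral(total) - N|) for a water state."""
    system, hess = water_model()
    modes = normal_mode_analysis(system, hess)
    state = VibrationalState.from_vibrational(modes, vib_quanta)
    full = assemble_state_density(modes, state, system)
    integrals = [
        marginalize_to_nucleus(full, j, system).integral()
        for j in range(system.n_nuclei)
    ]
    per = float(np.max(np.abs(np.array(integrals) - 1.0)))
    total = float(abs(sum(integrals) - system.n_nuclei))
    return per, total


def inplane_maxima(
    modes, system, state, j: int, *, n_sigma: float = 10.0, n_points: int = 401,
    plane=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
) -> int:
    """Strict local maxima of rho_j on a molecular-plane grid around nucleus j.

    The window is scaled to the nucleus: half-width ``n_sigma`` times the
    largest ground-state marginal std dev, sampled with ``n_points`` per
    side, which resolves even the weak inner maxima of higher excitations
    (adjacent maxima stay several samples apart).
    """
    from .density import count_local_maxima, evaluate_on_grid

    full = assemble_state_density(modes, state, system)
    rho = marginalize_to_nucleus(full, j, system)
    half = n_sigma * nucleus_sigma_max(modes, system, j)
    plane = np.asarray(plane, dtype=float)
    axes = plane * (2.0 * half / (n_points - 1))
    origin = system.positions[j] - half * (plane[0] + plane[1])
    grid = evaluate_on_grid(rho, origin, axes, (n_points, n_points))
    return count_local_maxima(grid)


def loco_density_consistency(isotopes=("O", "H", "H"), thresholds=None):
    """Compare LOCO verdicts with computed maxima changes, per first excitation.

    For every vibrational mode's first excited state and every nucleus,
    the LOCO verdict 'visible' should coincide with a change of the strict
    maxima count relative to the ground state.  Returns a list of dicts
    with the verdicts, counts and agreement flags.
    """
    from .loco import loco_predict, mode_displacements

    system, hess = water_model(isotopes=isotopes)
    modes = normal_mode_analysis(system, hess)
    disp = mode_displacements(modes, system)
    ground = VibrationalState.from_vibrational(modes, [0] * modes.n_vibrations)
    base = [inplane_maxima(modes, system, ground, j) for j in range(system.n_nuclei)]
    rows = []
    for pos, k in enumerate(modes.vibrational_indices):
        quanta = [0] * modes.n_vibrations
        quanta[pos] = 1
        state = VibrationalState.from_vibrational(modes, quanta)
        for j in range(system.n_nuclei):
            verdict = loco_predict(disp, {k}, j, thresholds).verdict
            count = inplane_maxima(modes, system, state, j)
            changed = count != base[j]
            rows.append(
                {
                    "isotopes": tuple(isotopes),
                    "mode": k,
                    "nucleus": j,
                    "label": system.labels[j],
                    "verdict": verdict,
                    "maxima": count,
                    "ground_maxima": base[j],
                    "consistent": (verdict == "visible") == changed,
                }
            )
    return rows


def run_oracle_suite(seed: int = 1, mc_samples: int = 200_000):
    """Run all analytic-vs-oracle checks; returns a list of CheckResult."""
    results = []

    for n in (1, 2, 3):
        err = chain_quadrature_error(n)
        results.append(
            CheckResult(
                name=f"chain2 quadrature, n={n}",
                passed=err < 1e-8,
                value=err,
                detail=f"max rel err {err:.2e} (tol 1e-8)",
            )
        )
    err = chain_quadrature_error(1, masses=(1.0, 10.0))
    results.append(
        CheckResult(
            name="chain2 quadrature, unequal masses",
            passed=err < 1e-8,
            value=err,
            detail=f"max rel err {err:.2e} (tol 1e-8)",
        )
    )

    dev = groundstate_schur_deviation()
    results.append(
        CheckResult(
            name="water ground state vs Schur marginal",
            passed=dev < 1e-10,
            value=dev,
            detail=f"max rel dev {dev:.2e} (tol 1e-10)",
        )
    )

    per, total = normalization_errors()
    results.append(
        CheckResult(
            name="water normalization",
            passed=per < 1e-10 and total < 1e-10,
            value=per,
            detail=f"max |int rho_j - 1| = {per:.2e}, |int rho - N| = {total:.2e}",
        )
    )

    seeds = np.random.SeedSequence(seed).generate_state(8)
    for i, quanta in enumerate(
        [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    ):
        n_dev, *_ = water_mc_deviation(quanta, 1, int(seeds[i] % 2**31), mc_samples)
        results.append(
            CheckResult(
                name=f"water MC, state {quanta}, nucleus H",
                passed=n_dev < 3.0,
                value=n_dev,
                detail=f"max deviation {n_dev:.2f} stderr (tol 3)",
            )
        )
    return results
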