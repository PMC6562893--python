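"""State densities, analytic marginals, grids and maxima counting."""

import math

import numpy as np
import pytest

from nucdens.density import (
    assemble_state_density,
    count_local_maxima,
    evaluate_on_grid,
    ho_density_1d,
    marginalize_to_nucleus,
    one_nucleus_density_total,
)
from nucdens.fixtures import triatomic_state, water_model
from nucdens.harmonic import normal_mode_analysis
from nucdens.system import HessianMatrix, MolecularSystem, VibrationalState
from nucdens.validation import nucleus_sigma_max


def _state(modes, *quanta):
    return VibrationalState.from_vibrational(modes, quanta)


def test_single_nucleus_density_is_isotropic_gaussian():
    # one free nucleus: three translation modes at the localization
    # frequency give (m w / pi)^{3/2} exp(-m w |dX|^2) with w = 0.5
    m = 100.0
    system = MolecularSystem(["X"], np.array([0.3, -0.2, 0.1]), masses=[m])
    modes = normal_mode_analysis(system, HessianMatrix(np.zeros((3, 3))))
    full = assemble_state_density(modes, _state(modes), system)
    rng = np.random.default_rng(3)
    pts = system.x_eq + rng.normal(0, 0.05, size=(20, 3))
    d2 = ((pts - system.x_eq) ** 2).sum(axis=1)
    expected = (m * 0.5 / math.pi) ** 1.5 * np.exp(-m * 0.5 * d2)
    np.testing.assert_allclose(full.value(pts), expected, rtol=1e-12)
    # nothing to integrate out: the marginal equals the full density
    marg = marginalize_to_nucleus(full, 0, system)
    np.testing.assert_allclose(marg.value(pts), full.value(pts), rtol=1e-12)


def test_state_density_normalization(water):
    system, _, modes = water
    for quanta in [(0, 0, 0), (1, 0, 1), (0, 0, 3)]:
        full = assemble_state_density(modes, _state(modes, *quanta), system)
        assert full.integral() == pytest.approx(1.0, abs=1e-10)


def test_state_mode_mismatch_rejected(water, chain2):
    system, _, modes = water
    _, _, chain_modes = chain2
    state = _state(chain_modes, 1)
    with pytest.raises(ValueError):
        assemble_state_density(modes, state, system)


def test_excited_state_vanishes_on_mode_node(water, rng):
    # state with one quantum in the bend: |psi|^2 = 0 wherever q_bend(X) = 0
    system, _, modes = water
    state = triatomic_state(modes, 0, 1, 0)
    full = assemble_state_density(modes, state, system)
    bend = modes.vibrational_indices[0]
    # reference scale: density at a point off the node (one quantum-width
    # displacement along the bend)
    q_ref = np.zeros(modes.n_modes)
    q_ref[bend] = 1.0 / np.sqrt(modes.omega[bend])
    X_ref = system.x_eq + (modes.L @ q_ref) / np.sqrt(system.masses_3n)
    scale = full.value(X_ref[None, :])[0]
    assert scale > 0
    for _ in range(10):
        q = rng.normal(0, 0.3, size=modes.n_modes)
        q[bend] = 0.0
        X = system.x_eq + (modes.L @ q) / np.sqrt(system.masses_3n)
        assert full.value(X[None, :])[0] <= 1e-16 * scale


def test_marginals_normalized_and_nonnegative(water, rng):
    system, _, modes = water
    state = triatomic_state(modes, 1, 0, 1)
    full = assemble_state_density(modes, state, system)
    for j in range(3):
        rho = marginalize_to_nucleus(full, j, system)
        assert rho.integral() == pytest.approx(1.0, abs=1e-10)
        pts = system.positions[j] + rng.normal(0, 0.3, size=(200, 3))
        assert (rho.value(pts) >= -1e-12).all()


def test_total_density_sums_and_integrates_to_n(water):
    system, _, modes = water
    full = assemble_state_density(modes, _state(modes, 0, 0, 0), system)
    per = [marginalize_to_nucleus(full, j, system) for j in range(3)]
    total = one_nucleus_density_total(per)
    pts = np.vstack([system.positions, [[0.5, -0.5, 0.0]]])
    vals = total.value(pts)
    for rho in per:
        assert (vals >= rho.value(pts) - 1e-14).all()
    assert sum(r.integral() for r in per) == pytest.approx(3.0, abs=1e-10)
    with pytest.raises(ValueError):
        one_nucleus_density_total([])


def test_grid_integral_converges(water):
    # Riemann sum of rho_H on a converged 3D grid reproduces the analytic norm
    system, _, modes = water
    full = assemble_state_density(modes, _state(modes, 0, 0, 0), system)
    rho = marginalize_to_nucleus(full, 1, system)
    sig = nucleus_sigma_max(modes, system, 1)
    half, n = 8.0 * sig, 101
    step = 2 * half / (n - 1)
    origin = system.positions[1] - half
    grid = evaluate_on_grid(rho, origin, np.eye(3) * step, (n, n, n))
    assert grid.integral() == pytest.approx(1.0, abs=1e-6)


def test_evaluate_on_grid_matches_direct_evaluation(water, rng):
    system, _, modes = water
    full = assemble_state_density(modes, _state(modes, 0, 0, 0), system)
    rho = marginalize_to_nucleus(full, 0, system)
    origin = system.positions[0] - np.array([0.5, 0.5, 0.0])
    axes = np.array([[0.01, 0, 0], [0, 0.01, 0]])
    grid = evaluate_on_grid(rho, origin, axes, (101, 101))
    idx = rng.integers(0, 101, size=(10, 2))
    pts = origin + idx @ axes
    np.testing.assert_allclose(
        grid.values[idx[:, 0], idx[:, 1]], rho.value(pts), rtol=1e-12
    )


def test_molecular_plane_grid_respects_c2_symmetry(water):
    # H2O in our frame is symmetric under x -> -x; a grid centered on the
    # C2 axis must mirror onto itself
    system, _, modes = water
    full = assemble_state_density(modes, _state(modes, 0, 1, 0), system)
    per = [marginalize_to_nucleus(full, j, system) for j in range(3)]
    total = one_nucleus_density_total(per)
    n = 121
    origin = np.array([-1.8, -2.5, 0.0])
    axes = np.array([[3.6 / (n - 1), 0, 0], [0, 3.0 / (n - 1), 0]])
    grid = evaluate_on_grid(total, origin, axes, (n, n))
    np.testing.assert_allclose(grid.values, grid.values[::-1, :], atol=1e-10 * grid.values.max())


def test_grid_rejects_degenerate_axes():
    pg = ho_density_1d(0, 1.0)  # placeholder density; never evaluated
    with pytest.raises(ValueError, match="orthogonal"):
        evaluate_on_grid(pg, np.zeros(3), [[1, 0, 0], [1, 1e-3, 0]], (5, 5))
    with pytest.raises(ValueError, match="degenerate|zero"):
        evaluate_on_grid(pg, np.zeros(3), [[0, 0, 0]], (5,))


@pytest.mark.parametrize("n_quanta,expected", [(0, 1), (2, 3), (3, 4)])
def test_count_maxima_of_1d_ho_density(n_quanta, expected):
    pg = ho_density_1d(n_quanta, 1.0)

    def line_density(pts):
        return pg.value(pts[:, :1])

    grid = evaluate_on_grid(
        line_density, np.array([-6.0, 0, 0]), [[12.0 / 800, 0, 0]], (801,)
    )
    assert count_local_maxima(grid) == expected


def test_count_maxima_window(water):
    system, _, modes = water
    full = assemble_state_density(modes, _state(modes, 0, 0, 0), system)
    per = [marginalize_to_nucleus(full, j, system) for j in range(3)]
    total = one_nucleus_density_total(per)
    n = 201
    origin = np.array([-2.5, -3.0, 0.0])
    axes = np.array([[5.0 / (n - 1), 0, 0], [0, 4.0 / (n - 1), 0]])
    grid = evaluate_on_grid(total, origin, axes, (n, n))
    assert count_local_maxima(grid) == 3  # one per nucleus
    with pytest.raises(ValueError, match="window outside grid"):
        count_local_maxima(grid, window=[(0, 300), (0, 201)])


def test_no_exact_node_but_strong_depletion(water):
    # exciting the bend leaves rho_H strictly positive at the H equilibrium
    # position, but depleted by more than an order of magnitude
    system, _, modes = water
    pt = system.positions[1][None, :]
    vals = {}
    for name, quanta in {"ground": (0, 0, 0), "bend": (0, 1, 0)}.items():
        full = assemble_state_density(modes, triatomic_state(modes, *quanta), system)
        vals[name] = marginalize_to_nucleus(full, 1, system).value(pt)[0]
    assert vals["bend"] > 0.0
    assert vals["ground"] / vals["bend"] >= 10.0


def test_polynomial_degree_guard(chain2):
    system, _, modes = chain2
    state = VibrationalState.from_vibrational(modes, [21])
    with pytest.raises(ValueError, match="degree"):
        assemble_state_density(modes, state, system)
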