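"""Normal-mode analysis: mass weighting, classification, coordinate maps."""

import math

import numpy as np
import pytest

from nucdens.constants import WAVENUMBER_PER_HARTREE
from nucdens.fixtures import ValenceForceField, chain_model, chain_zero_modes, water_model
from nucdens.harmonic import (
    cartesian_to_normal,
    detect_linearity,
    mass_weighted_hessian,
    normal_mode_analysis,
    normal_to_cartesian,
)
from nucdens.system import HessianMatrix, MolecularSystem


def test_mass_weighting_scales_diagonal_hessian():
    # H = k*I with all masses m must give (k/m)*I
    m, k = 3.5, 0.8
    system = MolecularSystem(["X", "X"], np.array([0, 0, 0, 2.0, 0, 0]), masses=[m, m])
    out = mass_weighted_hessian(system, HessianMatrix(k * np.eye(6)))
    np.testing.assert_allclose(out, (k / m) * np.eye(6), rtol=1e-14)


def test_mass_weighting_identity_for_unit_masses(rng):
    system = MolecularSystem(["X"], np.zeros(3), masses=[1.0])
    H = rng.normal(size=(3, 3))
    H = 0.5 * (H + H.T)
    out = mass_weighted_hessian(system, HessianMatrix(H))
    np.testing.assert_allclose(out, H, atol=1e-15)


def test_mass_weighting_rejects_dimension_mismatch():
    system = MolecularSystem(["X", "X"], np.array([0, 0, 0, 2.0, 0, 0]), masses=[1.0, 1.0])
    with pytest.raises(ValueError, match="does not match"):
        mass_weighted_hessian(system, HessianMatrix(np.eye(3)))


def _wilson_gf_frequencies(ff: ValenceForceField, m_o, m_1, m_2):
    """Independent oracle: internal-coordinate GF eigenproblem for bent XY2.

    Internal coordinates (dr1, dr2, dtheta) with Wilson G-matrix elements
    for a bent triatomic; eigenvalues of GF are the squared frequencies.
    """
    mu_o, mu_1, mu_2 = 1.0 / m_o, 1.0 / m_1, 1.0 / m_2
    r, th = ff.r_e, ff.theta_e
    F = np.array(
        [
            [ff.k_r, ff.k_rr, 0.0],
            [ff.k_rr, ff.k_r, 0.0],
            [0.0, 0.0, ff.k_theta],
        ]
    )
    G = np.array(
        [
            [mu_1 + mu_o, mu_o * math.cos(th), -mu_o * math.sin(th) / r],
            [mu_o * math.cos(th), mu_2 + mu_o, -mu_o * math.sin(th) / r],
            [
                -mu_o * math.sin(th) / r,
                -mu_o * math.sin(th) / r,
                (mu_1 + mu_2) / r**2 + 2.0 * mu_o * (1.0 - math.cos(th)) / r**2,
            ],
        ]
    )
    lam = np.sort(np.linalg.eigvals(G @ F).real)
    return np.sqrt(lam)


@pytest.mark.parametrize("isotopes", [("O", "H", "H"), ("O", "D", "H")])
def test_water_frequencies_match_gf_oracle(isotopes):
    ff = ValenceForceField()
    system, hess = water_model(ff, isotopes=isotopes)
    modes = normal_mode_analysis(system, hess)
    expected = _wilson_gf_frequencies(ff, *system.masses)
    np.testing.assert_allclose(modes.vibrational_frequencies, expected, rtol=1e-6)


def test_water_zero_mode_count_and_cleanliness(water):
    system, hess, modes = water
    assert modes.kind.count("translation_rotation") == 6
    assert modes.n_vibrations == 3
    # the six zero modes have |eigenvalue| < 1e-10 in mass-weighted a.u.
    A = mass_weighted_hessian(system, hess)
    evals = np.sort(np.abs(np.linalg.eigvalsh(A)))
    assert evals[:6].max() < 1e-10
    assert all(w > 0 for w in modes.vibrational_frequencies)


def test_diatomic_has_five_zero_modes(chain2):
    _, _, modes = chain2
    assert modes.kind.count("translation_rotation") == 5
    assert modes.n_vibrations == 1
    np.testing.assert_allclose(modes.vibrational_frequencies, [math.sqrt(2.0)], rtol=1e-12)


def test_single_free_nucleus_is_all_translation():
    system = MolecularSystem(["He"], np.zeros(3))
    modes = normal_mode_analysis(system, HessianMatrix(np.zeros((3, 3))))
    assert modes.kind == ("translation_rotation",) * 3
    assert modes.n_vibrations == 0


def test_saddle_point_rejected():
    system, _ = chain_model(2)
    H = np.zeros((6, 6))
    H[0, 0] = H[3, 3] = -1.0
    H[0, 3] = H[3, 0] = 1.0  # inverted spring: negative curvature along the bond
    with pytest.raises(ValueError, match="not a minimum"):
        normal_mode_analysis(system, HessianMatrix(H))


def test_eigenvector_orthogonality(water, hdo, chain2):
    for _, _, modes in (water, hdo, chain2):
        gram = modes.L.T @ modes.L
        assert np.abs(gram - np.eye(modes.n_modes)).max() < 1e-10


def test_detect_linearity():
    water_sys, _ = water_model()
    assert not detect_linearity(water_sys)
    diatomic, _ = chain_model(2)
    assert detect_linearity(diatomic)
    collinear = MolecularSystem(
        ["C", "O", "O"], np.array([0, 0, 0, 2.2, 0, 0, -2.2, 0, 0])
    )
    assert detect_linearity(collinear)


def test_coordinate_map_round_trip(water, rng):
    system, _, modes = water
    assert np.allclose(cartesian_to_normal(modes, system, system.x_eq), 0.0)
    # single-mode displacement maps to a single normal coordinate
    s = 0.37
    col = 2
    X = system.x_eq + s * (modes.L[:, col] / np.sqrt(system.masses_3n))
    q = cartesian_to_normal(modes, system, X)
    expected = np.zeros(9)
    expected[col] = s
    np.testing.assert_allclose(q, expected, atol=1e-12)
    # random displacements round-trip through both maps
    for _ in range(5):
        X = system.x_eq + rng.normal(0, 0.1, 9)
        back = normal_to_cartesian(modes, system, cartesian_to_normal(modes, system, X))
        np.testing.assert_allclose(back, X, atol=1e-12)


def test_frequencies_invariant_under_rigid_rotation(water):
    system, hess, modes = water
    # rotate geometry and Hessian consistently by a random rotation
    rng = np.random.default_rng(7)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    R = np.kron(np.eye(3), Q)
    rotated = MolecularSystem(system.labels, R @ system.x_eq, masses=system.masses)
    hess_rot = HessianMatrix(R @ hess.matrix @ R.T)
    modes_rot = normal_mode_analysis(rotated, hess_rot)
    np.testing.assert_allclose(
        modes_rot.vibrational_frequencies,
        modes.vibrational_frequencies,
        rtol=1e-10,
    )


def test_isotope_substitution_localizes_stretches(water, hdo):
    w_sys, w_hess, w_modes = water
    d_sys, d_hess, d_modes = hdo
    # the Hessian is a property of the potential alone
    np.testing.assert_array_equal(w_hess.matrix, d_hess.matrix)
    assert not np.allclose(
        w_modes.vibrational_frequencies, d_modes.vibrational_frequencies
    )
    # HDO stretches localize: lower stretch on D, upper stretch on H
    inv_sqrt_m = 1.0 / np.sqrt(d_sys.masses_3n)
    D = inv_sqrt_m[:, None] * d_modes.L
    vib = d_modes.vibrational_indices
    lower_stretch, upper_stretch = vib[1], vib[2]
    d_idx, h_idx = 1, 2  # labels ("O", "D", "H")

    def disp(mode, j):
        return np.linalg.norm(D[3 * j : 3 * j + 3, mode])

    assert disp(lower_stretch, d_idx) > 5 * disp(lower_stretch, h_idx)
    assert disp(upper_stretch, h_idx) > 5 * disp(upper_stretch, d_idx)


def test_wavenumber_conversion(water):
    _, _, modes = water
    np.testing.assert_allclose(
        modes.frequencies_cm1(),
        modes.vibrational_frequencies * WAVENUMBER_PER_HARTREE,
        rtol=1e-15,
    )
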