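# Methods

## Model

The nuclei of a localized, oriented molecule are described in the harmonic
approximation around a minimum X_eq of the potential. Diagonalizing the
mass-weighted Hessian M^{-1/2} H M^{-1/2} (masses in m_e, H in E_h/bohr²)
gives orthonormal mode vectors L and eigenvalues λ_k = ω_k²; the nuclear
wavefunction of a vibrational eigenstate is a product of 1D
harmonic-oscillator functions in the normal coordinates
q = Lᵀ M^{1/2}(X − X_eq), one quantum number per mode. Rotation–vibration
coupling is neglected, no anharmonicity is included, and identical nuclei
are not exchange-symmetrized (they are localized, with large barriers to
exchange, so each nucleus keeps its own marginal).

The 6 zero-frequency modes (5 for linear geometries, 3 for a single
nucleus) describe overall translation and rotation. They are assigned HO
ground-state factors at ω = 0.5 E_h/ℏ — not delta functions — which
localizes and orients the molecule while keeping the full density a product
of HO densities. This width is configurable (`trans_rot_frequency`); at
0.5 E_h/ℏ the localization Gaussians are far narrower than any vibrational
amplitude, so they add no visible structure.

## Exact marginalization

|ψ_nuc(X)|² is a polynomial times a Gaussian in the 3N Cartesian
coordinates. The `PolyGaussian` class represents
P(u−c)·exp(logZ −(u−c)ᵀA(u−c)) with a sparse exponent-map polynomial and is
closed under products, invertible affine maps and marginalization.
Marginals complete the square in the integrated block (Cholesky of A_yy,
Schur complement for the kept block) and replace integrated-variable
monomials by central Gaussian moments computed with the Isserlis
recurrence, memoized per exponent tuple. The polynomial degree of a state
with Σn quanta is 2Σn; assembly refuses degrees above 40, far beyond any
state of interest here.

Numerical choices:

* Marginalization to a nucleus is carried out in mass-weighted coordinates
  and rescaled at the end (`marginalize_to_nucleus(..., system=...)`);
  exponent matrices mixing O and H masses are otherwise needlessly
  ill-conditioned.
* Zero-mode identification uses |λ| < 1e-8 (mass-weighted a.u.); the
  analytic fixtures give zero modes clean to ~1e-12. Eigenvalues below
  −1e-6 raise "not a minimum" rather than being zeroed.
* Mode columns are sign-fixed (largest-|component| entry positive) and
  ordered translation/rotation first, then vibrations by ascending
  frequency, so output is reproducible across platforms. For degenerate
  vibrational frequencies any orthonormal basis of the degenerate subspace
  is admissible; no additional convention is imposed.
* The input frame is taken as the laboratory frame of the localized
  molecule; no Eckart rotation is applied.
* Grid evaluation clamps roundoff negatives (below 1e-10 of the grid
  maximum in magnitude) to zero; genuinely negative values raise.

States are indexed over vibrational modes in ascending frequency. For the
water fixtures this means (bend, lower stretch, upper stretch); the helper
`triatomic_state(modes, n1, n2, n3)` accepts the conventional spectroscopic
order (n_ν1, n_ν2, n_ν3) = (symmetric stretch, bend, antisymmetric
stretch) and maps it internally, since the spectroscopic ν1 is *not* the
lowest mode.

## LOCO rules and thresholds

Visibility of an excitation at nucleus j is a local competition of spatial
widths. Mode k contributes at nucleus j the displacement d_jk (nucleus-j
block of M^{-1/2}L_k) with ground-state spatial spread
σ_jk = |d_jk|/√(2ω_k). For a single excited mode k, competitors are the
other vibrational modes m with |cos∠(d_jk, d_jm)| ≥ 0.9; the verdict is
masked iff Σ_m (σ_jm cos∠)² ≥ 2 σ_jk². The factor 2 is derived, not
fitted: convolving a 1D first-excited-state density (x² Gaussian, width σ_k)
with a transverse Gaussian of width σ_c keeps two strict maxima iff
σ_c² < 2σ_k². Two or more excited modes sharing a direction at the nucleus
(same cosine gate) give "combination". A mode whose extent at the nucleus
is below 5% of the largest extent there cannot produce a visible change.
All three thresholds are configurable (`LocoThresholds`). An alternative
parameterization on bare |d_jk| with a dominance ratio and a similarity
band was considered and rejected: on the water fixture it cannot
simultaneously reproduce the bend-visible / symmetric-stretch-masked
pattern at oxygen and the computed density changes at hydrogen.

The verdicts are invariant under rigid rotations of the input frame and
under uniform rescaling of all displacement vectors (only ratios and
angles enter).

## Fixtures and oracles

The package ships no data files; all test systems are analytic.

* **Water / HDO**: a valence force field V = ½k_r(Δr₁²+Δr₂²) + k_rr Δr₁Δr₂
  + ½k_θ Δθ², geometry r_OH = 1.8088 bohr, θ = 104.52°, O at the origin,
  C₂ axis along y, molecular plane z = 0. The force constants
  (k_r = 0.4928, k_θ = 0.14776, k_rr = −0.00603 a.u.) were fit once so the
  harmonic fundamentals match H₂O (3657/1595/3756 cm⁻¹); isotopologues
  reuse the same Hessian with different masses (D = 2.014102 u; other
  elements use isotope-averaged standard masses). The Hessian is obtained
  by central finite differences (step 1e-4 bohr), which keeps the
  mass-weighted zero modes clean to ~1e-12 and frequencies accurate to
  better than 1e-6 relative. An independent internal-coordinate GF
  eigenproblem (Wilson G matrix of a bent triatomic) cross-checks the
  frequencies in the tests.
* **Chains**: point masses on a line with nearest-neighbor distance
  springs. For n ≥ 3 the transverse directions are flat in addition to
  translation/rotation, so `normal_mode_analysis` accepts an explicit
  zero-mode count for such deliberately flat models; all flat modes are
  localized like translation/rotation. For n = 2 this reduces to the usual
  5 zero modes of a diatomic.

What the fixtures emulate — and what they do not: they give genuine bent /
linear geometries, realistic frequency ratios and mass contrasts, exactly
harmonic potentials, and exact translation/rotation invariance. They do not
model anharmonicity, rotation–vibration coupling, electronic-structure
error in the Hessian, or environment-induced localization; tests passing on
them validate the algebra and the categorical LOCO logic, not the accuracy
of a harmonic Hessian for any real molecule.

Two independent brute-force routes check every closed-form marginal
(`nucdens oracle-check`):

* **Iterated Gauss–Hermite quadrature** (≤ 4 integrated dimensions,
  ≥ 60 nodes per dimension, centered on the conditional Gaussian of the
  exponent, with the weight folded back analytically). For
  polynomial-times-Gaussian integrands this is exact to roundoff, and
  doubling the node count changes results by < 1e-10.
* **Importance-sampled Monte Carlo** (water: 6 integrated dimensions):
  samples the conditional Gaussian and averages the density ratio, with the
  density evaluated by the direct product-of-HO-functions formula (Clenshaw
  Hermite evaluation) — independent of both the polynomial expansion and
  the moment algebra. The reported standard error is floored at 1e-12 of
  the estimate when comparing, because for pure-Gaussian states the
  importance ratio is exactly constant and the sample error collapses to
  roundoff.
* **Schur route**: for all-ground states the marginal is also computed as
  the covariance-block Gaussian N(X_eq,j, Σ_jj) with
  Σ = M^{-1/2} L (2Ω)^{-1} Lᵀ M^{-1/2} — a derivation that never touches
  the square-completion code path.

## Problem sizes

Default analysis sizes, chosen to keep every check comfortably converged:
maxima counting uses per-nucleus in-plane windows of half-width 10× the
largest ground-state marginal standard deviation with 401 points per side
(≈0.0024 bohr spacing at O), which separates even the weak inner maxima of
the (003) state by several samples; 2D figure grids default to 301 points;
Monte-Carlo cross-checks use 10⁶ samples per state at 5 probe points per
nucleus, probes spread over ±1.5 ground widths; chain quadrature uses 60
nodes per integrated dimension at 50 probe points.

## Known limitations

Harmonic only — no anharmonic or VSCF corrections, no rotation–vibration
coupling, no exchange symmetrization, no time-dependent or flux densities.
Quadrature oracles are limited to 4 integrated dimensions (tensor-grid
cost); larger systems rely on the Monte-Carlo route. Polynomial assembly
cost grows combinatorially with total quanta; the degree guard (40)
reflects that this implementation targets low-lying states. The LOCO rules
are categorical: they predict whether structure appears, not depletion
depths or amplitudes.
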