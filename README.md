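# nucdens

Exact one-nucleus probability densities of vibrationally excited molecules
in the harmonic approximation, with visibility rules for excitations.

## The problem

For a localized, oriented molecule, the quantum state of the nuclei lives
on a 3N-dimensional configuration space, but chemistry reasons about nuclei
as points in ordinary 3D space. The bridge is the *one-nucleus density*
ρ(R⃗): the probability of finding any nucleus at a point in space,
irrespective of where the others are — the nuclear analogue of the
one-electron density. For nucleus *j* it is the marginal

ρ_j(R⃗) = ∫ |ψ_nuc(X)|² dX⃗₁ … dX⃗_{j−1} dX⃗_{j+1} … dX⃗_N ,  ρ(R⃗) = Σ_j ρ_j(R⃗).

In the normal-mode (harmonic) approximation the nuclear wavefunction is a
product of harmonic-oscillator (HO) eigenfunctions in the normal
coordinates q_k = (Lᵀ M^{1/2} (X − X_eq))_k,

ψ_nuc(X) = ∏_k φ(q_k; n_k),

with the six (five for linear molecules) zero-frequency
translation/rotation modes replaced by narrow HO ground-state Gaussians at
ω = 0.5 E_h/ℏ, which pins the molecule in place and orientation. |ψ_nuc|²
is then a *polynomial times a Gaussian* in the 3N Cartesian coordinates — a
family closed under marginalization — so every ρ_j is obtained in closed
form (complete the square in the integrated coordinates, replace their
monomials by Gaussian moments via Isserlis' theorem). No grids, no
quadrature, exact up to floating point.

Because marginalization mixes in the fluctuations of all other modes, the
nodes of excited states generally do *not* survive as exact zeros of ρ_j.
Whether an excitation remains qualitatively visible is predicted by the
LOcal COmparison (LOCO) rules: at each nucleus, compare the spatial extent
σ_jk = |d_jk|/√(2ω_k) of each mode's displacement (d_jk is the nucleus-j
block of M^{-1/2}L_k). An excitation of mode k is

* **visible** (rule a) if no other mode displaces the nucleus in the same
  direction with comparable extent,
* **masked** (rule b) if same-direction competitors contribute at least
  twice the excited mode's variance (the closed-form threshold at which a
  transverse Gaussian erases the dip of an excited-state density),
* a **combination** (rule c) if two or more *excited* modes share a
  direction at the nucleus.

## Worked example

No quantum-chemistry input is needed to try the package: analytic fixtures
(a valence-force-field water whose harmonic fundamentals match H₂O, and
spring chains) are built in.

```sh
python examples/water_modes_and_density.py
```

prints

```
vibrational frequencies (cm^-1): [1595. 3657. 3756.]
zero-frequency (trans/rot) modes: 6

state ground (000)
  marginal norms (should all be 1): [1. 1. 1.]
  rho_H at the H equilibrium position: 165.9174 bohr^-3

state bend (010)
  marginal norms (should all be 1): [1. 1. 1.]
  rho_H at the H equilibrium position: 2.7303 bohr^-3

depletion factor at H due to the bend excitation: 60.8x
```

One quantum in the bend carves a near-nodal plane through the hydrogen
density — its value at the H equilibrium position drops 61-fold but stays
strictly positive, because the node exists only in the 9-dimensional
configuration space. `examples/hdo_loco_verdicts.py` shows the isotope
effect: in HDO the stretches localize, and the LOCO verdict table (O-D
stretch visible only at D, O-H stretch only at H, bend at both) matches the
maxima counted in the exactly-marginalized densities.
`examples/oracle_crosscheck.py` validates the closed-form marginals against
literal high-dimensional integration.

## Command line

A thin CLI wraps the library for file-based use:

```sh
nucdens modes geom.xyz hessian.txt          # frequencies + displacements
nucdens compute geom.xyz hessian.txt --state 0,1,0   # per-nucleus densities
nucdens loco geom.xyz hessian.txt --states "1,0,0;0,1,0" --json report.json
nucdens oracle-check                         # analytic-vs-brute-force suite
```

`compute` writes one file per nucleus plus the total, as 2D molecular-plane
cuts (delimited text) or 3D Gaussian cube files. Hessians are plain-text
3N×3N matrices in E_h/bohr² (coordinate order x1 y1 z1 x2 …); a JSON bundle
format carrying geometry, masses and Hessian together is also accepted.
States index vibrational modes in ascending frequency.

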