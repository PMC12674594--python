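# Methods

## Multicomponent reference

The coupled Kohn–Sham problem treats electrons (closed-shell,
spin-restricted) and designated quantum protons (identical same-spin
fermions, one orbital each) in a single product determinant.  The
electronic effective potential contains the classical-nuclear
attraction, the electronic Coulomb and hybrid exchange–correlation
potentials, the attraction to the protonic density and the
electron–proton correlation potential; the protonic effective potential
contains the mass-scaled kinetic term (m_p = 1836.15267343 m_e), the
classical-nuclear *repulsion*, the attraction to the electronic
density, the protonic Coulomb term with exact exchange K^pp, and the
electron–proton correlation potential.  No proton–proton correlation
functional is applied; K^pp alone removes the protonic
self-interaction (exactly, for a single quantum proton).

Quantum protons carry no point charge in any external potential —
their charge lives entirely in the protonic density — and their stored
positions serve only as basis centers.  The electronic basis functions
of the corresponding hydrogen atom are kept on that center.

## Electron–proton correlation

* **epc-17.2** (LDA form): ε = −ρᵉρᵖ / (a − b√(ρᵉρᵖ) + c ρᵉρᵖ) with
  (a, b, c) = (2.35, 2.4, 6.6), overridable via `EPCParams`.  The
  denominator is positive whenever b² < 4ac, which the constructor
  enforces; grid densities below 10⁻¹⁴ are treated as zero before the
  square root and densities below −10⁻¹² raise.
* **ep-MP2**: second-order correlation from simultaneous
  electron+proton single excitations coupled by the electron–proton
  Coulomb operator, evaluated with the converged Kohn–Sham orbitals
  (no orbital optimization).  Closed-shell electrons contribute a spin
  factor 2.  Pure-electronic and pure-protonic singles are omitted, as
  in standard double-hybrid practice of discarding singles; for exact
  Brillouin-satisfying references they vanish identically, and for
  Kohn–Sham references their neglect is part of the model definition.

During the SCF only the epc-17.2 potential is self-consistent and it
enters **scaled by b_epc**, mirroring how double hybrids include the
scaled DFT correlation potential in the Fock operator while the MP2
terms stay strictly post-SCF.  (The alternative — iterating with the
unscaled potential — changes the orbitals and hence E_epc^MP2; the
scaled choice keeps the SCF variational in the assembled
SCF-level energy.)

## SCF protocol

Convergence thresholds: 10⁻⁸ Eh on the total-energy change, 10⁻⁵ a.u.
on the density change and on the orbital-gradient norm of each
species.  DIIS uses up to 10 Fock matrices and starts after the first
iteration.  Each outer iteration runs an electronic subcycle at frozen
protonic density and a protonic subcycle at frozen electronic density
(inner tolerance adapted to 1% of the last outer energy change,
bounded by [0.1·energy_tol, 10⁻⁵]), followed by a *joint* DIIS step
that extrapolates both Fock matrices with a concatenated error vector.
The joint step is essential: pure alternation converges only linearly
in the electron–proton coupling strength, with rates observed near
0.99 on H₂.  The initial guess converges a single-component
calculation with the quantum protons as classical +1 charges, then
diagonalizes the resulting protonic core Hamiltonian.  Degenerate
orbital fills break ties by orbital energy, then by deterministic
index order.

## Integrals, grids, basis sets

One- and two-particle integrals come from a McMurchie–Davidson engine
(Cartesian shells through f, numba-jitted kernels, Boys function via
series + downward recursion below x = 35 and the asymptotic upward
recursion above).  Density fitting uses a shared Coulomb metric over
the union of an even-tempered electronic auxiliary (auto-generated
from the orbital exponents) and the protonic fitting set; the metric
is Jacobi-preconditioned and eigenvalues below 10⁻¹⁰ of the largest
are dropped — with the strongly overlapping even-tempered ladders,
smaller drop thresholds admit numerically polluted directions and
*reduce* fitting accuracy.

Quadrature grids are Becke fuzzy cells with Gauss–Chebyshev radial
points under the rational map (60 radial points at the default level
3; 90 compact points on quantum-proton centers) and product
Gauss–Legendre × uniform-φ angular shells (inner-region pruned).  The
Becke partition uses stiffness 3 for purely electronic grids and 4
when quantum protons are present; the stiffer cell boundary keeps the
tight protonic density out of neighbouring atoms' coarser radial
ladders and is worth roughly two orders of magnitude in the protonic
normalization error.

Electronic basis sets shipped as package data: STO-3G and the 6-31G
family (`*`, `**`, `+`, `++` decorations) for H, He, C, N, O, typed
from the standard published exponents; the H₂/STO-3G integrals
reproduce the classic textbook table values and HF totals (He/STO-3G
−2.8077840 Eh, H₂O/6-31G −75.98397 Eh) to the printed digits.
def2-family sets are *not* redistributed; calculations that quote the
def2-TZVPP protocol therefore run here at 6-31+G** (diffuse functions
on heavy atoms matter for the anionic species).  Protonic bases are
registered by name or built even-tempered; the default orbital
surrogate is 4s4p spanning [2√2, 32] (an X–H stretch of 3000–4000 cm⁻¹
corresponds to harmonic Gaussian exponents m_p·ω/2 ≈ 10–20, so the
ladder brackets the physical range), and the protonic fitting set is
the 10s10p10d10f ladder from 2√2 to 64 — with ten points those
endpoints give exactly ratio √2, i.e. exponents doubling every second
step, which is why the garbled printed lower bound "2 2" is read as
2√2.  Literature protonic sets (PB4-F2, PB6-F) can be registered from
their published exponents via `register_protonic_basis`.

## Electronic functionals

Slater, VWN5, PW92, B88, LYP, PBE (x and c), and P86 (PZ81 local +
gradient correction) are implemented as closed-shell energy densities
ε(ρ, σ); the potentials ∂ε/∂ρ and ∂ε/∂σ are generated symbolically at
first use and lambdified, eliminating hand-derived GGA derivative
algebra as an error source.  Component energies at the He-atom HF
density match literature values (B88 −1.025, LYP −0.0437, PBEx
−1.0136 Eh).  B3LYP uses the VWN5 local correlation variant.  Density
floors: ρ < 10⁻¹² contributes nothing; σ is floored at 10⁻²⁴.

## Dispersion

The dispersion hook accepts pluggable providers keyed by functional
tag; quantum protons enter as hydrogens at their basis centers.  The
default provider is *disabled* (E_disp = 0, reported explicitly in
every breakdown).  A deliberately simple pairwise C6/R⁶ model with
Becke–Johnson-style damping ("c6bj", free-atom C6 coefficients) is
included to exercise the hook; it is a synthetic stand-in, not a
published parameterization, and the shipped proton-affinity
reproductions run without dispersion.  For the small t7/t8 molecules
the pair-count difference between A and AH⁺ puts the neglected
contribution well under 1 kcal/mol.

## Thermochemistry

PA(A) = −ΔE_elec − ΔE_vib + (5/2)RT (single-component route, harmonic
ΔE_vib supplied externally in kcal/mol) or PA(A) = E_A − E_AH⁺ +
(5/2)RT (multicomponent route; the quantum proton's anharmonic
zero-point energy is inside E_AH⁺, and zero-point contributions of the
classical nuclei are taken to cancel between A and AH⁺, so no further
correction is applied).  R is pinned to 1.987204259×10⁻³ kcal/(mol·K);
the default temperature is 298.15 K, the standard state of the
experimental proton affinities, since the (5/2)RT term's temperature
is not otherwise fixed by the benchmark definition.  Unsigned-error
statistics report MUE, RMSD, median (midpoint convention for even
counts; both reference sets have odd sizes), min and max, plus
per-chemical-class breakdowns.

## Admixture optimization

Bayesian optimization over the unit box with a Matérn-5/2 GP
(scikit-learn; amplitude and length-scale by marginal-likelihood
maximization with 5 restarts; observation noise fixed at a 10⁻⁸
jitter since the RMSD objective is deterministic) and plain expected
improvement (ξ = 0).  Budgets: 40 Latin-hypercube presamples + 20
acquisition points in 2-D, 10 + 3 in 1-D (where c_epc = 1 − b_epc).
Acquisition maximization is a dense-grid argmax (2001 points in 1-D,
201² in 2-D) — exact enough on a 1–2-D box and bit-reproducible under
a fixed seed.  Objective values are cached on the point rounded to
10⁻⁶; failed evaluations are recorded and skipped.  Because each new
b_epc changes the SCF (the epc potential is b-scaled), the CLI
optimizer consumes a per-molecule component table (base energy,
E_epc^DFT, E_epc^MP2 computed once) — a frozen-orbital fast mode that
turns the admixture scan into assembly arithmetic; it is an
approximation to full per-point re-SCF and is labelled as such.

## Density analysis

Electronic densities are evaluated on regular voxel grids (0.05 bohr
cubic voxels by default, the default box encloses all basis centers
with a 6 bohr margin).  The single- vs multicomponent difference is
resolved along the X–H bond axis: each voxel joins the slab (width =
voxel spacing) containing its center's projection; d_H = 0 at the
quantum-proton basis center, positive toward the heavy atom.  Slab
decomposition is a reindexing, so slab sums reproduce the 3-D
integral exactly.  Grids round-trip through Gaussian cube files.

## Problem sizes in the shipped tests and reproductions

The test suite runs entirely on generated fixtures: H₂ with one
quantum proton (STO-3G + et-4s4p), NH₄⁺ and a linear H–C–N structure
at the same scale, and a fully hand-set 2×2 two-species model whose
SCF solution is checked against an exhaustive orbital-rotation scan.
The two worked proton-affinity reproductions (NO₂⁻/B3LYP and
NH₃/PBEQIDH) run single-component energies at 6-31+G**, on geometries
optimized at B3LYP/6-31G** in symmetry-internal coordinates with
harmonic frequencies from central-difference B3LYP/6-31G Hessians
(step 0.01 bohr) — the package's own scaled-down realization of the
def2-TZVPP/"tight" protocol the benchmark prescribes.  Passing tests
at this scale demonstrate the correctness of the machinery (integrals,
SCF coupling, assemblies, statistics, optimizer), not basis-set
converged proton affinities: the full PA21 parametrization
additionally needs the deposited geometries and the def2/PB4-F2 basis
data, which are external.

## Known limitations

* Closed-shell electronic references only; no analytic nuclear
  gradients (geometry work is delegated to external engines).
* Cartesian Gaussians throughout (6d/10f); no spherical-harmonic
  transformation.
* The synthetic dispersion model is not D3(BJ); literature-comparable
  dispersion-corrected numbers require an external provider plugged
  into the hook.
* The frozen-orbital admixture scan ignores the orbital relaxation
  with b_epc; full re-SCF per optimizer point is available through the
  library API at proportional cost.
* Protonic orbital bases are uncontracted even-tempered surrogates
  unless literature sets are registered explicitly.
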