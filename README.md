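# neodh — multicomponent double-hybrid density functional theory

`neodh` treats selected protons quantum mechanically, on the same footing
as the electrons: a coupled pair of Kohn–Sham problems (one electronic,
one protonic) is converged self-consistently, and the electron–proton
correlation is described by a tunable admixture of the LDA-type
**epc-17.2** functional and an **MP2-type perturbative term** computed
from the converged Kohn–Sham orbitals — the multicomponent analogue of
electronic double-hybrid functionals.  The package is aimed at method
developers and computational chemists studying nuclear quantum effects
(anharmonic zero-point energy, proton delocalization) in protonation
thermochemistry.

## The model

The total nuclear–electronic orbital (NEO) energy is

    E[ρᵉ, ρᵖ] = E_ext[ρᵉ, ρᵖ] + E_ref[ρᵉ, ρᵖ] + E_exc[ρᵉ] + E_epc[ρᵉ, ρᵖ]

with classical point nuclei creating the external potential, both
Coulomb and kinetic reference terms for each species, an ordinary
electronic exchange–correlation functional, and the electron–proton
correlation E_epc.  Quantum protons are identical same-spin fermions in
a single determinant; their exact exchange K^pp removes protonic
self-interaction (no proton–proton correlation functional is used).

On top of a converged NEO-DFT reference, the double-hybrid assembly for
the B2PLYP-based variant reads

    E = E_ext,ref + (1−a_ex) E_x^DFT + a_ex E_x^HF
        + (1−c_ec) E_c^DFT + c_ec E_c^MP2
        + b_epc E_epc^DFT + c_epc E_epc^MP2

with the published electronic coefficients (a_ex = 0.53, c_ec = 0.27)
kept fixed; DSD-PBEP86- and PBEQIDH-based forms are analogous (the
registry holds every coefficient, `neodh functionals` prints it).  The
electron–proton admixture {b_epc, c_epc} is the tunable pair; the
shipped defaults come from a one-parameter Bayesian optimization
(c_epc = 1 − b_epc) against experimental proton affinities:
0.875/0.125 (NEO-B2PLYP), 0.806/0.194 (NEO-DSD-PBEP86), 0.731/0.269
(NEO-PBEQIDH) — i.e. roughly a 0.8:0.2 DFT:MP2 ratio.

Proton affinities are computed two ways:

* single-component route: PA(A) = −ΔE_elec − ΔE_vib + (5/2)RT, with a
  harmonic vibrational correction from an external frequency
  calculation;
* multicomponent route: PA(A) = E_A − E_AH⁺ + (5/2)RT, where the NEO
  energy of AH⁺ already contains the anharmonic zero-point energy of
  the quantum proton.

The package is self-contained: it carries its own Gaussian-integral
engine (McMurchie–Davidson, numba-jitted), Becke quadrature grids, the
B88/LYP/VWN5/PBE/P86 electronic functionals, the epc-17.2 functional,
density fitting, a Matérn-5/2 Gaussian-process Bayesian optimizer, and
the PA21/test-set reference tables as package data.

## Worked example

Multicomponent proton affinity of ammonia at demonstration scale
(6-31G electronic basis, even-tempered 4s4p protonic basis; the proton
added to form NH₄⁺ is quantized):

```python
from neodh import parse_xyz, RunConfig, run_single_point
from neodh.basis import BasisConfiguration, make_even_tempered
from neodh.thermochem import proton_affinity_neo

cfg = lambda f: RunConfig(functional=f, basis=BasisConfiguration(
    electronic_orbital_basis="6-31g",
    protonic_orbital_basis=make_even_tempered(4, 2*2**0.5, 32.0, ("s", "p"))))

nh3 = parse_xyz(open("nh3.xyz").read())
a = run_single_point(nh3, cfg("b2plyp"))
nh4 = parse_xyz(open("nh4.xyz").read(), quantum_atom_indices=[1],
                net_charge=1)
ah = run_single_point(nh4, cfg("neo-b2plyp"))
print(a.total, ah.total, proton_affinity_neo(a.total, ah.total))
```

prints

```
E(NH3, B2PLYP/6-31G)   = -56.422653 Eh
E(NH4+, NEO-B2PLYP)    = -56.772746 Eh
PA(NH3)                = 221.2 kcal/mol   (experimental: 204.1)
```

The energy difference contains the quantum proton's full vibrational
ground-state energy (here ≈15 kcal/mol) without any frequency
calculation.  At this deliberately small demonstration scale the PA is
overestimated: the unpolarized 6-31G basis inflates the electronic
protonation energy and the compact 4s4p protonic surrogate basis
overbinds the proton.  The NEO-B2PLYP breakdown
(`ah.parts.as_dict()`) shows every assembly slot, e.g.
`e_epc_dft = -0.0331 Eh` and `e_epc_mp2 = -0.0017 Eh`, which enter
with weights 0.875 and 0.125.

The same workflow from the shell:

```
neodh run --xyz nh4.xyz -q 1 --charge 1 --functional neo-b2plyp --basis 6-31g
neodh benchmark --dataset PA21 --energies my_energies.csv
neodh optimize --mode 1d --dataset PA21 --components components.csv --seed 1
```

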