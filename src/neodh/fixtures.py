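"""Deterministic test fixtures: tiny quantum-proton systems and a
fully hand-set two-level model.

Every fixture is solvable in seconds on one CPU and is generated
bit-identically on each call.  ``toy2x2`` carries a hand-set
:class:`~neodh.provider.IntegralBundle` (2 electronic + 2 protonic
basis functions, one electron pair + one proton) whose two-particle
tensors are built from symmetric generator matrices,
(ij|kl) = sum_m A_m[i,j] A_m[k,l], which guarantees permutational
symmetry and positive semidefiniteness of the Coulomb kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisConfiguration, make_even_tempered
from .provider import IntegralBundle, SpeciesIntegrals
from .system import QuantumMolecule, parse_xyz


@dataclass
class Fixture:
    name: str
    molecule: QuantumMolecule | None
    basis: BasisConfiguration | None
    bundle: IntegralBundle | None = None
    notes: dict = field(default_factory=dict)


_H2_XYZ = """2
H2, experimental bond length
H 0.0 0.0 0.0
H 0.0 0.0 0.7414
"""

_NH4_XYZ = """5
NH4+, tetrahedral, r(NH) = 1.021 A
N  0.000000  0.000000  0.000000
H  0.589481  0.589481  0.589481
H -0.589481 -0.589481  0.589481
H -0.589481  0.589481 -0.589481
H  0.589481 -0.589481 -0.589481
"""

_HCN_XYZ = """3
linear H-C-N test structure (r_CH = 1.065, r_CN = 1.153 A)
H 0.0 0.0 0.0
C 0.0 0.0 1.065
N 0.0 0.0 2.218
"""

_SMALL_PROTONIC = make_even_tempered(4, 2 * np.sqrt(2.0), 32.0, ("s", "p"))


def _toy2x2_bundle() -> IntegralBundle:
    """Hand-set two-level/two-level model.  All values are plain
    numbers chosen once; nothing is computed from a geometry."""
    eye = np.eye(2)
    # electronic core Hamiltonian: bound "core" level and a higher one
    h_e = np.array([[-1.30, -0.25],
                    [-0.25, -0.40]])
    # protonic core: kinetic-dominated, mostly repulsive frame
    h_p = np.array([[0.90, -0.10],
                    [-0.10, 1.40]])
    # Coulomb generators (symmetric): eri[i,j,k,l] = sum_m A[i,j]A[k,l]
    A0 = np.array([[0.80, 0.15], [0.15, 0.60]])
    A1 = np.array([[0.10, 0.05], [0.05, 0.30]])
    B0 = np.array([[0.50, 0.05], [0.05, 0.45]])
    B1 = np.array([[0.08, 0.02], [0.02, 0.05]])
    eri_e = np.einsum("ij,kl->ijkl", A0, A0) \
        + np.einsum("ij,kl->ijkl", A1, A1)
    eri_p = np.einsum("ij,kl->ijkl", B0, B0) \
        + np.einsum("ij,kl->ijkl", B1, B1)
    eri_ep = np.einsum("ij,kl->ijkl", A0, B0) \
        + np.einsum("ij,kl->ijkl", A1, B1)
    elec = SpeciesIntegrals(None, eye, 0.5 * h_e, 0.5 * h_e, eri_e)
    prot = SpeciesIntegrals(None, eye, 0.5 * h_p, 0.5 * h_p, eri_p)
    return IntegralBundle(None, elec, prot, eri_ep, e_nuc=0.0,
                          n_elec=2, n_prot=1)


def generate_fixture(name: str) -> Fixture:
    if name == "h2_quantum":
        mol = parse_xyz(_H2_XYZ, quantum_atom_indices=[1])
        basis = BasisConfiguration(electronic_orbital_basis="sto-3g",
                                   protonic_orbital_basis=_SMALL_PROTONIC)
        return Fixture(name, mol, basis,
                       notes={"description": "H2 with the second H "
                              "quantized; 1 classical H, 1 quantum "
                              "proton, charge 0"})
    if name == "nh4_quantum":
        mol = parse_xyz(_NH4_XYZ, quantum_atom_indices=[1], net_charge=1)
        basis = BasisConfiguration(electronic_orbital_basis="sto-3g",
                                   protonic_orbital_basis=_SMALL_PROTONIC)
        return Fixture(name, mol, basis,
                       notes={"description": "NH4+ with one quantum "
                              "proton (10 electrons)"})
    if name == "hcn_like":
        # HCN itself parametrized epc-17.2; this linear X-H structure
        # is a geometry-only stand-in for tests, never a benchmark
        mol = parse_xyz(_HCN_XYZ, quantum_atom_indices=[0])
        basis = BasisConfiguration(electronic_orbital_basis="sto-3g",
                                   protonic_orbital_basis=_SMALL_PROTONIC)
        return Fixture(name, mol, basis,
                       notes={"description": "linear H(C)(N) test "
                              "structure with quantum H"})
    if name == "toy2x2":
        return Fixture(name, None, None, bundle=_toy2x2_bundle(),
                       notes={"description": "hand-set 2x2 model: one "
                              "electron pair + one proton, orthonormal "
                              "bases", "oracle": "exhaustive scan over "
                              "the single orbital-rotation angle of "
                              "each species"})
    raise KeyError(f"unknown fixture {name!r}; known: h2_quantum, "
                   "nh4_quantum, hcn_like, toy2x2")


_TOY_CACHE = None


def toy2x2_energy(theta_e: float, theta_p: float) -> float:
    """Closed-form toy2x2 energy for given orbital-rotation angles:
    the occupied electronic orbital is (cos, sin) and likewise for the
    proton.  Independent oracle for the SCF minimum."""
    global _TOY_CACHE
    if _TOY_CACHE is None:
        _TOY_CACHE = _toy2x2_bundle()
    b = _TOY_CACHE
    ce = np.array([np.cos(theta_e), np.sin(theta_e)])
    cp = np.array([np.cos(theta_p), np.sin(theta_p)])
    h_e = b.elec.T + b.elec.v_ext
    h_p = b.prot.T + b.prot.v_ext
    e = 2.0 * ce @ h_e @ ce
    e += np.einsum("ijkl,i,j,k,l", b.elec.eri, ce, ce, ce, ce)
    e += cp @ h_p @ cp          # single proton: J and K cancel exactly
    e -= 2.0 * np.einsum("ijkl,i,j,k,l", b.eri_ep, ce, ce, cp, cp)
    return float(e)
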