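"""Post-SCF perturbative correlation on converged NEO-DFT orbitals.

Two second-order terms enter the multicomponent double hybrids:

* the closed-shell electronic MP2 energy, resolved into opposite-spin
  and same-spin components (the spin-scaled DSD form needs them
  separately);
* the electron-proton MP2 energy: simultaneous single excitations of
  one electron and one proton coupled by the electron-proton Coulomb
  operator,

      E = sum_{ia,i'a'} 2 |(ia|i'a')|^2
          / (eps_i + eps_i' - eps_a - eps_a')

  (factor 2 from the electronic spin summation; protons are
  distinguishable-spin fermions with singly occupied orbitals, no
  further factor).  Pure-electronic or pure-protonic singles are
  omitted, consistent with standard double-hybrid practice.

Orbitals come straight from the Kohn-Sham reference -- no orbital
optimization is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: number of frozen chemical-core spatial orbitals per element
CORE_ORBITALS = {"H": 0, "He": 0, "Li": 1, "Be": 1, "B": 1, "C": 1,
                 "N": 1, "O": 1, "F": 1, "Ne": 1, "Na": 5, "Mg": 5,
                 "Al": 5, "Si": 5, "P": 5, "S": 5, "Cl": 5, "Ar": 5}


class DegenerateDenominatorError(ZeroDivisionError):
    pass


@dataclass
class OrbitalSet:
    """Occupied/virtual blocks of one species (spatial orbitals)."""
    C_occ: np.ndarray
    C_virt: np.ndarray
    eps_occ: np.ndarray
    eps_virt: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.eps_occ) < -1e-9) \
                or np.any(np.diff(self.eps_virt) < -1e-9):
            raise ValueError("orbital energies must be sorted ascending")

    @property
    def n_occ(self):
        return self.C_occ.shape[1]

    @property
    def n_virt(self):
        return self.C_virt.shape[1]


def orbital_set(state_C, state_eps, n_occ: int, n_frozen: int = 0
                ) -> OrbitalSet:
    return OrbitalSet(state_C[:, n_frozen:n_occ], state_C[:, n_occ:],
                      state_eps[n_frozen:n_occ], state_eps[n_occ:])


def n_frozen_core(system, policy: str = "auto") -> int:
    if policy == "none" or system is None:
        return 0
    if policy != "auto":
        raise ValueError(f"unknown frozen-core policy {policy!r}")
    return sum(CORE_ORBITALS[s] for s, _, _ in system.classical_nuclei)


def _ovov(eri_ao, bra: OrbitalSet, ket: OrbitalSet):
    """(ia|jb) with i,a from bra pairs and j,b from ket pairs."""
    t = np.einsum("pqrs,pi->iqrs", eri_ao, bra.C_occ, optimize=True)
    t = np.einsum("iqrs,qa->iars", t, bra.C_virt, optimize=True)
    t = np.einsum("iars,rj->iajs", t, ket.C_occ, optimize=True)
    return np.einsum("iajs,sb->iajb", t, ket.C_virt, optimize=True)


def _check_denominators(d, what):
    if d.size and np.abs(d).min() < 1e-10:
        bad = np.unravel_index(int(np.argmin(np.abs(d))), d.shape)
        raise DegenerateDenominatorError(
            f"near-degenerate denominator in {what} at orbital quadruple "
            f"{tuple(int(x) for x in bad)}")


def electronic_mp2(elec: OrbitalSet, eri_ao: np.ndarray):
    """Closed-shell MP2 split into (E_os, E_ss), hartree.

    E_os + E_ss equals the conventional unsplit MP2 energy exactly.
    """
    if elec.n_occ == 0 or elec.n_virt == 0:
        return 0.0, 0.0
    ovov = _ovov(eri_ao, elec, elec)
    d = (elec.eps_occ[:, None, None, None]
         + elec.eps_occ[None, None, :, None]
         - elec.eps_virt[None, :, None, None]
         - elec.eps_virt[None, None, None, :])
    _check_denominators(d, "electronic MP2")
    e_os = float(np.sum(ovov ** 2 / d))
    e_ss = float(np.sum(ovov * (ovov - ovov.transpose(0, 3, 2, 1)) / d))
    return e_os, e_ss


def ep_mp2_energy(elec: OrbitalSet, prot: OrbitalSet,
                  eri_ep_ao: np.ndarray) -> float:
    """Electron-proton MP2 correlation energy (hartree, <= 0 for an
    Aufbau reference).  ``eri_ep_ao`` is the bare-repulsion
    (ee|pp) tensor; the attractive interaction sign squares away."""
    if min(elec.n_occ, elec.n_virt, prot.n_occ, prot.n_virt) == 0:
        return 0.0
    t = np.einsum("pqrs,pi->iqrs", eri_ep_ao, elec.C_occ, optimize=True)
    t = np.einsum("iqrs,qa->iars", t, elec.C_virt, optimize=True)
    t = np.einsum("iars,rj->iajs", t, prot.C_occ, optimize=True)
    iajb = np.einsum("iajs,sb->iajb", t, prot.C_virt, optimize=True)
    d = (elec.eps_occ[:, None, None, None]
         + prot.eps_occ[None, None, :, None]
         - elec.eps_virt[None, :, None, None]
         - prot.eps_virt[None, None, None, :])
    _check_denominators(d, "electron-proton MP2")
    return float(2.0 * np.sum(iajb ** 2 / d))


def ep_mp2_energy_df(elec: OrbitalSet, prot: OrbitalSet,
                     j3c_e: np.ndarray, j3c_p: np.ndarray,
                     metric: np.ndarray) -> float:
    """Density-fitted variant of :func:`ep_mp2_energy`: both species'
    pair densities expanded in one shared fitting set."""
    w, U = np.linalg.eigh(metric)
    keep = w > 1e-10
    Mh = U[:, keep] / np.sqrt(w[keep])          # (P, naux')
    Bia = np.einsum("pqP,pi,qa->iaP", j3c_e, elec.C_occ, elec.C_virt,
                    optimize=True) @ Mh
    Bjb = np.einsum("pqP,pi,qa->iaP", j3c_p, prot.C_occ, prot.C_virt,
                    optimize=True) @ Mh
    iajb = np.einsum("iaP,jbP->iajb", Bia, Bjb, optimize=True)
    d = (elec.eps_occ[:, None, None, None]
         + prot.eps_occ[None, None, :, None]
         - elec.eps_virt[None, :, None, None]
         - prot.eps_virt[None, None, None, :])
    _check_denominators(d, "DF electron-proton MP2")
    return float(2.0 * np.sum(iajb ** 2 / d))


def correlate(state, bundle, functional, system=None,
              frozen_core: str = "auto"):
    """Fill the MP2 slots of an EnergyBreakdown from a converged state.

    Returns ``(e_os, e_ss, e_ep)``; components not needed by the
    functional are still computed when the inputs exist (cheap at these
    sizes) so breakdowns are complete.
    """
    nf = n_frozen_core(system if system is not None else bundle.system,
                       frozen_core)
    nocc = int(round(np.sum(state.occ_e) / 2))
    elec = orbital_set(state.C_e, state.eps_e, nocc, nf)
    e_os, e_ss = electronic_mp2(elec, bundle.elec.eri)
    e_ep = None
    if bundle.has_protons and state.C_p is not None:
        nocc_p = int(round(np.sum(state.occ_p)))
        prot = orbital_set(state.C_p, state.eps_p, nocc_p, 0)
        e_ep = ep_mp2_energy(elec, prot, bundle.eri_ep)
    return e_os, e_ss, e_ep
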