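"""Integral provider: everything the SCF and MP2 layers consume.

``build_integrals`` assembles an :class:`IntegralBundle` for a
:class:`~neodh.system.QuantumMolecule`: one-particle matrices for both
species, two-particle repulsion tensors (exact four-index at these
system sizes, plus optional density-fitted three-index tensors), and
the shared quadrature grid with basis amplitudes for both particle
types.

Sign conventions: ``v_ext`` is the full external-potential matrix of
the species including its charge sign -- attractive (negative) for
electrons, repulsive (positive) for protons, both generated by the
*classical* nuclei only.  Two-particle tensors (ab|cd) are bare Coulomb
repulsion integrals; interaction signs are applied by the consumer
(the electron-proton coupling enters with a minus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .basis import (BasisConfiguration, BasisSet, auto_fitting_basis,
                    build_electronic_basis, build_protonic_basis)
from .constants import PROTON_MASS_AU
from .grid import MolecularGrid, grid_for_molecule
from .integrals import (eri_2c, eri_3c, eri_cross, eri_full, eval_basis,
                        nuclear_attraction_operator, overlap_kinetic)

log = logging.getLogger(__name__)


@dataclass
class SpeciesIntegrals:
    basis: BasisSet
    S: np.ndarray
    T: np.ndarray               # kinetic, already mass-scaled
    v_ext: np.ndarray           # signed external potential
    eri: np.ndarray | None      # (ab|cd) four-index
    ao_vals: np.ndarray | None = None    # grid amplitudes
    ao_grads: np.ndarray | None = None
    j3c: np.ndarray | None = None        # (ab|P)
    metric: np.ndarray | None = None     # (P|Q)

    @property
    def nbf(self):
        return self.basis.nbf if self.basis is not None else self.S.shape[0]


@dataclass
class IntegralBundle:
    system: object
    elec: SpeciesIntegrals
    prot: SpeciesIntegrals | None
    eri_ep: np.ndarray | None            # (ee|pp) repulsion
    j3c_ep: np.ndarray | None = None     # (ee|Q_p) against protonic fit
    grid: MolecularGrid | None = None
    e_nuc: float = 0.0
    pruned: int = 0
    n_elec: int | None = None       # overrides system counts (toy bundles)
    n_prot: int | None = None

    @property
    def has_protons(self):
        return self.prot is not None and self.prot.nbf > 0


def build_integrals(system, basis: BasisConfiguration,
                    grid_level: int = 3, with_grid: bool = True,
                    with_df: bool = False) -> IntegralBundle:
    """Assemble all integrals for one system.

    ``with_df`` additionally builds the density-fitted three-index
    tensors (protonic fitting basis for the protonic and mixed blocks).
    """
    ebs = build_electronic_basis(system, basis.electronic_orbital_basis)
    charges = system.classical_charges
    coords = system.classical_coords
    S, T = overlap_kinetic(ebs)
    _check_metric(S, "electronic")
    Vnuc = nuclear_attraction_operator(ebs, charges, coords)
    elec = SpeciesIntegrals(ebs, S, T, -Vnuc, eri_full(ebs))

    prot = None
    eri_ep = None
    j3c_ep = None
    if system.n_quantum_protons > 0:
        pbs = build_protonic_basis(basis.protonic_orbital_basis,
                                   system.quantum_protons)
        Sp, Tp = overlap_kinetic(pbs)
        _check_metric(Sp, "protonic")
        Vp = nuclear_attraction_operator(pbs, charges, coords)
        prot = SpeciesIntegrals(pbs, Sp, Tp / PROTON_MASS_AU, +Vp,
                                eri_full(pbs))
        eri_ep = eri_cross(ebs, pbs)
        if with_df:
            # shared fitting set: protonic even-tempered ladder plus an
            # electronic auto-generated auxiliary, one Coulomb metric
            aux_p = build_protonic_basis(basis.protonic_fitting_basis,
                                         system.quantum_protons)
            aux_e = auto_fitting_basis(ebs)
            aux = BasisSet(aux_e.shells + aux_p.shells)
            prot.j3c = eri_3c(pbs, aux)
            prot.metric = eri_2c(aux)
            j3c_ep = eri_3c(ebs, aux)

    grid = None
    if with_grid:
        grid = grid_for_molecule(system, grid_level)
        vals, grads = eval_basis(ebs, grid.points, deriv=1)
        elec.ao_vals, elec.ao_grads = vals, grads
        if prot is not None:
            prot.ao_vals = eval_basis(pbs, grid.points, deriv=0)

    return IntegralBundle(system, elec, prot, eri_ep, j3c_ep, grid,
                          system.nuclear_repulsion())


def _check_metric(S, label, thresh=1e-7):
    w = np.linalg.eigvalsh(S)
    n_dep = int(np.sum(w < thresh))
    if n_dep:
        log.warning("%s overlap has %d near-dependent directions "
                    "(min eigenvalue %.2e)", label, n_dep, w.min())


def lowdin_x(S: np.ndarray, thresh: float = 1e-9):
    """Canonical orthogonalizer X with near-dependencies pruned."""
    w, U = np.linalg.eigh(S)
    keep = w > thresh
    return U[:, keep] / np.sqrt(w[keep])


def df_eri(j3c: np.ndarray, metric: np.ndarray) -> np.ndarray:
    """Reconstruct a four-index tensor from (ab|P) and (P|Q):
    (ab|cd) ~= (ab|P) (P|Q)^-1 (Q|cd).  Bra and ket may differ; pass
    the ket tensor explicitly via :func:`df_eri_cross` when so."""
    return df_eri_cross(j3c, metric, j3c)


def df_eri_cross(j3c_bra, metric, j3c_ket):
    return np.einsum("abP,PQ,cdQ->abcd", j3c_bra, metric_inverse(metric),
                     j3c_ket, optimize=True)


def metric_inverse(metric: np.ndarray, drop: float = 1e-10) -> np.ndarray:
    """Pseudo-inverse of a Coulomb fitting metric.  Even-tempered
    ladders are near-dependent, so the metric is Jacobi-preconditioned
    before truncating small eigenvalues."""
    d = 1.0 / np.sqrt(np.diag(metric))
    Mp = metric * np.outer(d, d)
    w, U = np.linalg.eigh(Mp)
    keep = w > drop * w.max()
    Minv = (U[:, keep] / w[keep]) @ U[:, keep].T
    return Minv * np.outer(d, d)


def validate_bundle(bundle: IntegralBundle) -> dict:
    """Diagnostics: symmetry defects, metric condition numbers and grid
    self-overlap accuracy.  Never raises -- purely informational."""
    out = {}

    def sym_defect(M):
        return float(np.max(np.abs(M - M.T))) if M is not None else None

    for tag, sp in (("elec", bundle.elec), ("prot", bundle.prot)):
        if sp is None:
            continue
        d = {"sym_defect_S": sym_defect(sp.S),
             "sym_defect_T": sym_defect(sp.T),
             "sym_defect_v": sym_defect(sp.v_ext)}
        w = np.linalg.eigvalsh(sp.S)
        d["overlap_condition"] = float(w.max() / max(w.min(), 1e-300))
        d["overlap_min_eig"] = float(w.min())
        if sp.metric is not None:
            mw = np.linalg.eigvalsh(sp.metric)
            d["metric_condition"] = float(mw.max() / max(mw.min(), 1e-300))
        if sp.ao_vals is not None and bundle.grid is not None:
            gs = np.einsum("p,pi,pi->i", bundle.grid.weights,
                           sp.ao_vals, sp.ao_vals)
            d["grid_self_overlap_max_err"] = float(
                np.max(np.abs(gs - np.diag(sp.S))))
        out[tag] = d
    if bundle.grid is not None:
        out["grid_points"] = int(bundle.grid.size)
        out["grid_negative_weights"] = int(np.sum(bundle.grid.weights <= 0))
    return out
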