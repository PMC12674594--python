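import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import minimize

from neodh.basis import BasisConfiguration
from neodh.fixtures import generate_fixture, toy2x2_energy
from neodh.functionals import get_functional
from neodh.provider import build_integrals, lowdin_x
from neodh.scf import (NEOState, SCFConvergenceError, SCFSettings,
                       build_electronic_fock, build_protonic_fock,
                       diis_update, run_neo_scf, scf_total_energy)
from neodh.system import parse_xyz

H2_XYZ = "2\nh2\nH 0 0 0\nH 0 0 0.7414\n"


def _reference_rhf(bundle, nocc):
    """Independent dense RHF oracle: plain Roothaan iterations with
    heavy damping, no DIIS, no shared code path beyond the integrals."""
    el = bundle.elec
    h = el.T + el.v_ext
    w, U = np.linalg.eigh(el.S)
    X = U / np.sqrt(w)
    def diag(F):
        e, V = np.linalg.eigh(X.T @ F @ X)
        C = X @ V
        return 2.0 * C[:, :nocc] @ C[:, :nocc].T
    D = diag(h)
    for _ in range(500):
        J = np.einsum("pqrs,rs->pq", el.eri, D)
        K = np.einsum("prqs,rs->pq", el.eri, D)
        Dn = 0.5 * D + 0.5 * diag(h + J - 0.5 * K)
        if np.max(np.abs(Dn - D)) < 1e-12:
            D = Dn
            break
        D = Dn
    J = np.einsum("pqrs,rs->pq", el.eri, D)
    K = np.einsum("prqs,rs->pq", el.eri, D)
    return (np.einsum("pq,pq", D, h) + 0.5 * np.einsum("pq,pq", D, J)
            - 0.25 * np.einsum("pq,pq", D, K) + bundle.e_nuc)


class TestDIIS:
    def test_single_entry_identity(self):
        F = np.array([[1.0, 0.2], [0.2, 2.0]])
        out, hist = diis_update([(F, np.array([0.1, -0.1]))], 10)
        assert np.allclose(out, F)

    def test_zero_error_entry(self):
        F = np.diag([1.0, 2.0])
        out, _ = diis_update([(F, np.zeros(2))], 10)
        assert np.allclose(out, F)

    def test_opposite_errors_average(self):
        # e and -e: the Pulay system gives coefficients (1/2, 1/2)
        F1, F2 = np.diag([1.0, 1.0]), np.diag([3.0, 5.0])
        e = np.array([0.3, -0.7])
        out, _ = diis_update([(F1, e), (F2, -e)], 10)
        assert np.allclose(out, 0.5 * (F1 + F2), atol=1e-12)

    def test_history_truncation(self):
        hist = [(np.eye(2) * k, np.array([k, 0.0])) for k in range(1, 15)]
        _, hist2 = diis_update(hist, 10)
        assert len(hist2) == 10
        assert hist2[0][1][0] == 5.0

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SCFSettings(energy_tol=-1)
        with pytest.raises(ValueError):
            SCFSettings(diis_len=0)


class TestSingleComponent:
    def test_h2_matches_independent_rhf_oracle(self):
        mol = parse_xyz(H2_XYZ)
        cfg = BasisConfiguration(electronic_orbital_basis="sto-3g")
        bundle = build_integrals(mol, cfg, with_grid=False)
        st, parts = run_neo_scf(functional=get_functional("hf"),
                                bundle=bundle)
        e = scf_total_energy(parts, get_functional("hf"))
        assert st.converged
        assert e == pytest.approx(_reference_rhf(bundle, 1), abs=1e-8)

    def test_diis_history_length_independence(self):
        mol = parse_xyz(H2_XYZ)
        cfg = BasisConfiguration(electronic_orbital_basis="6-31g")
        bundle = build_integrals(mol, cfg, with_grid=False)
        es = []
        for n in (8, 10, 12):
            _, parts = run_neo_scf(functional=get_functional("hf"),
                                   bundle=bundle,
                                   settings=SCFSettings(diis_len=n))
            es.append(scf_total_energy(parts, get_functional("hf")))
        assert max(es) - min(es) < 1e-7

    def test_nonconvergence_raises_with_log(self):
        mol = parse_xyz(H2_XYZ)
        cfg = BasisConfiguration(electronic_orbital_basis="sto-3g")
        bundle = build_integrals(mol, cfg, with_grid=False)
        with pytest.raises(SCFConvergenceError) as ei:
            run_neo_scf(functional=get_functional("hf"), bundle=bundle,
                        settings=SCFSettings(max_outer=1, max_inner=1,
                                             energy_tol=1e-15,
                                             density_tol=1e-15,
                                             grad_tol=1e-15))
        assert len(ei.value.iteration_log) > 0


class TestToyModel:
    def test_scf_matches_exhaustive_rotation_scan(self, toy2x2):
        st, parts = run_neo_scf(functional=get_functional("hf"),
                                bundle=toy2x2.bundle)
        e_scf = scf_total_energy(parts, get_functional("hf"))
        ths = np.linspace(0, math.pi, 181)
        coarse = min(((toy2x2_energy(a, b), (a, b))
                      for a in ths for b in ths))
        res = minimize(lambda x: toy2x2_energy(*x), coarse[1],
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15})
        assert e_scf == pytest.approx(res.fun, abs=1e-9)

    def test_fock_builders_shape_checks(self, toy2x2):
        st = NEOState(D_e=np.zeros((3, 3)), D_p=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            build_electronic_fock(st, toy2x2.bundle, get_functional("hf"))
        st2 = NEOState(D_e=np.zeros((2, 2)), D_p=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            build_protonic_fock(st2, toy2x2.bundle)


class TestCoupledNEO:
    def test_converged_state_invariants(self, h2_bundle, h2_neo_b3lyp):
        state, parts = h2_neo_b3lyp
        assert state.converged
        assert state.idempotency_defect(h2_bundle.elec.S,
                                        h2_bundle.prot.S) < 1e-8
        # particle counts from density/overlap traces
        ne = np.einsum("pq,pq", state.D_e, h2_bundle.elec.S)
        npr = np.einsum("pq,pq", state.D_p, h2_bundle.prot.S)
        assert ne == pytest.approx(2.0, abs=1e-10)
        assert npr == pytest.approx(1.0, abs=1e-10)

    def test_protonic_density_integrates_on_grid(self, h2_bundle,
                                                 h2_neo_b3lyp):
        state, _ = h2_neo_b3lyp
        ao = h2_bundle.prot.ao_vals
        rho = np.einsum("pi,ij,pj->p", ao, state.D_p, ao, optimize=True)
        assert h2_bundle.grid.weights @ rho == pytest.approx(1.0, abs=1e-6)

    def test_single_proton_exchange_cancels_coulomb(self, h2_bundle,
                                                    h2_neo_b3lyp):
        """One quantum proton is self-interaction free: the J^pp and
        K^pp energies cancel exactly."""
        state, _ = h2_neo_b3lyp
        Dp = state.D_p
        Jp = np.einsum("pqrs,rs->pq", h2_bundle.prot.eri, Dp)
        Kp = np.einsum("prqs,rs->pq", h2_bundle.prot.eri, Dp)
        e_j = 0.5 * np.einsum("pq,pq", Dp, Jp)
        e_k = 0.5 * np.einsum("pq,pq", Dp, Kp)
        assert abs(e_j - e_k) < 1e-12
        # and (J - K) annihilates the occupied protonic orbital
        c = state.C_p[:, 0]
        assert np.max(np.abs((Jp - Kp) @ c)) < 1e-10

    def test_epc_energy_negative(self, h2_neo_b3lyp):
        _, parts = h2_neo_b3lyp
        assert parts.e_epc_dft < 0.0

    def test_rigid_translation_rotation_invariance(self, h2_quantum,
                                                   h2_neo_b3lyp):
        _, parts0 = h2_neo_b3lyp
        f = get_functional("neo-b3lyp")
        e0 = scf_total_energy(parts0, f)
        mol = h2_quantum.molecule.translated([0.7, -0.4, 1.1])
        th = 0.6
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        mol = mol.rotated(R)
        _, parts1 = run_neo_scf(mol, h2_quantum.basis, f)
        assert scf_total_energy(parts1, f) == pytest.approx(e0, abs=1e-8)

    def test_heavier_proton_mass_approaches_clamped_limit(self,
                                                          h2_quantum):
        """Scaling the quantum-proton mass up lowers the NEO energy
        monotonically toward the clamped-nucleus result."""
        f = get_functional("neo-hf")
        bundle = build_integrals(h2_quantum.molecule, h2_quantum.basis,
                                 with_grid=False)
        energies = []
        guess = None
        # adiabatic continuation: each mass starts from the previous
        # solution; the heavy-mass protonic modes are nearly flat, so
        # the density criterion is relaxed for this stress case
        for scale in (1.0, 10.0, 1000.0):
            b = dataclasses.replace(bundle)
            b.prot = dataclasses.replace(bundle.prot)
            b.prot.T = bundle.prot.T / scale
            st, parts = run_neo_scf(
                functional=f, bundle=b, initial_densities=guess,
                settings=SCFSettings(density_tol=1e-4))
            guess = (st.D_e, st.D_p)
            energies.append(scf_total_energy(parts, f))
        assert energies[0] > energies[1] > energies[2]
        # clamped limit: conventional HF with the proton classical
        mol_c = parse_xyz(H2_XYZ)
        cfgc = BasisConfiguration(
            electronic_orbital_basis=h2_quantum.basis
            .electronic_orbital_basis)
        bc = build_integrals(mol_c, cfgc, with_grid=False)
        e_clamped = _reference_rhf(bc, 1)
        assert energies[2] > e_clamped - 1e-6
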