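import itertools

import numpy as np
import pytest

from neodh.mp2 import (DegenerateDenominatorError, OrbitalSet,
                       electronic_mp2, ep_mp2_energy, ep_mp2_energy_df,
                       n_frozen_core, orbital_set)


def _random_orbitals(rng, n, nocc, gap=1.0):
    """Random orthonormal MOs (AO overlap = identity) with a clean
    occupied/virtual gap."""
    Q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    eps = np.sort(rng.uniform(-2.0, -1.0, nocc)).tolist() \
        + np.sort(rng.uniform(gap, gap + 2.0, n - nocc)).tolist()
    eps = np.array(eps)
    return OrbitalSet(Q[:, :nocc], Q[:, nocc:], eps[:nocc], eps[nocc:])


def _random_psd_eri(rng, n, m=None, ngen=4):
    """(ij|kl) built from symmetric generators.  For one species
    (m = None) bra and ket share generators, giving the full
    permutational symmetry and a PSD Coulomb kernel; cross tensors
    (two species) only need pair symmetry within each side."""
    cross = m is not None
    m = n if m is None else m
    out = np.zeros((n, n, m, m))
    for _ in range(ngen):
        A = rng.normal(size=(n, n)); A = 0.5 * (A + A.T)
        if cross:
            B = rng.normal(size=(m, m)); B = 0.5 * (B + B.T)
        else:
            B = A
        out += np.einsum("ij,kl->ijkl", A, B)
    return out / ngen


class TestElectronicMP2:
    def test_zero_integrals(self):
        rng = np.random.default_rng(0)
        orbs = _random_orbitals(rng, 4, 2)
        assert electronic_mp2(orbs, np.zeros((4, 4, 4, 4))) == (0.0, 0.0)

    def test_single_occupied_orbital_has_no_same_spin_pairs(self):
        rng = np.random.default_rng(1)
        orbs = _random_orbitals(rng, 4, 1)
        eri = _random_psd_eri(rng, 4)
        e_os, e_ss = electronic_mp2(orbs, eri)
        assert e_ss == pytest.approx(0.0, abs=1e-14)
        assert e_os < 0.0

    def test_against_spin_orbital_oracle(self):
        """OS/SS partition against an explicit spin-orbital MP2 sum,
        E = 1/4 sum |<ij||ab>|^2 / D split by spin case."""
        rng = np.random.default_rng(2)
        n, nocc = 5, 2
        orbs = _random_orbitals(rng, n, nocc)
        eri = _random_psd_eri(rng, n)
        e_os, e_ss = electronic_mp2(orbs, eri)

        C = np.hstack([orbs.C_occ, orbs.C_virt])
        eps = np.concatenate([orbs.eps_occ, orbs.eps_virt])
        mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", eri, C, C, C, C,
                       optimize=True)
        # spin orbitals: (p, sigma); <pq|rs> = (pr|qs) delta_s...
        nso = 2 * n
        occ = [(i, s) for i in range(nocc) for s in (0, 1)]
        virt = [(a, s) for a in range(nocc, n) for s in (0, 1)]
        e_oracle = {"os": 0.0, "ss": 0.0}
        for (i, si), (j, sj) in itertools.product(occ, occ):
            for (a, sa), (b, sb) in itertools.product(virt, virt):
                # <ij|ab> = (ia|jb) d(si,sa) d(sj,sb)
                dir_ = mo[i, a, j, b] if (si == sa and sj == sb) else 0.0
                exch = mo[i, b, j, a] if (si == sb and sj == sa) else 0.0
                num = (dir_ - exch) ** 2
                if num == 0.0:
                    continue
                den = eps[i] + eps[j] - eps[a] - eps[b]
                e_oracle["ss" if si == sj else "os"] += 0.25 * num / den
        assert e_os == pytest.approx(e_oracle["os"], abs=1e-10)
        assert e_ss == pytest.approx(e_oracle["ss"], abs=1e-10)

    def test_quadratic_scaling_in_coupling(self):
        rng = np.random.default_rng(3)
        orbs = _random_orbitals(rng, 5, 2)
        eri = _random_psd_eri(rng, 5)
        e1 = sum(electronic_mp2(orbs, eri))
        e2 = sum(electronic_mp2(orbs, 2.0 * eri))
        assert e2 == pytest.approx(4.0 * e1, rel=1e-12)

    def test_degenerate_denominator_raises(self):
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        orbs = OrbitalSet(Q[:, :2], Q[:, 2:],
                          np.array([-1.0, -0.5]), np.array([-0.75, 2.0]))
        with pytest.raises(DegenerateDenominatorError):
            electronic_mp2(orbs, _random_psd_eri(rng, 4))


class TestEpMP2:
    def test_zero_mixed_integrals(self):
        rng = np.random.default_rng(5)
        e = _random_orbitals(rng, 3, 1)
        p = _random_orbitals(rng, 3, 1)
        assert ep_mp2_energy(e, p, np.zeros((3, 3, 3, 3))) == 0.0

    def test_single_pair_closed_form(self):
        """One electronic and one protonic excitation channel with
        coupling t: E = 2 t^2 / d."""
        Ce = OrbitalSet(np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]]),
                        np.array([-1.0]), np.array([0.5]))
        Cp = OrbitalSet(np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]]),
                        np.array([-0.2]), np.array([0.9]))
        t = 0.137
        eri = np.zeros((2, 2, 2, 2))
        eri[0, 1, 0, 1] = eri[1, 0, 0, 1] = eri[0, 1, 1, 0] = \
            eri[1, 0, 1, 0] = t
        d = (-1.0) + (-0.2) - 0.5 - 0.9
        assert ep_mp2_energy(Ce, Cp, eri) == pytest.approx(
            2 * t * t / d, abs=1e-14)

    def test_against_determinant_space_oracle(self):
        """Second-order Rayleigh-Schroedinger sum over explicit
        electron spin-orbital x protonic excitation pairs."""
        rng = np.random.default_rng(6)
        ne, np_ = 3, 3
        elec = _random_orbitals(rng, ne, 1)
        prot = _random_orbitals(rng, np_, 1)
        eri = _random_psd_eri(rng, ne, np_)
        e = ep_mp2_energy(elec, prot, eri)

        Ce = np.hstack([elec.C_occ, elec.C_virt])
        Cp = np.hstack([prot.C_occ, prot.C_virt])
        mo = np.einsum("pqrs,pi,qa,rj,sb->iajb", eri, Ce, Ce, Cp, Cp,
                       optimize=True)
        eps_e = np.concatenate([elec.eps_occ, elec.eps_virt])
        eps_p = np.concatenate([prot.eps_occ, prot.eps_virt])
        oracle = 0.0
        # two electrons (alpha, beta) in spatial orbital 0; one proton
        # in orbital 0.  Excited kets: one electron of either spin to a,
        # proton to b.  |<0|W|ket>|^2 = mo[0,a,0,b]^2 per spin channel.
        for spin in range(2):
            for a in range(1, ne):
                for b in range(1, np_):
                    num = mo[0, a, 0, b] ** 2
                    den = (eps_e[0] + eps_p[0] - eps_e[a] - eps_p[b])
                    oracle += num / den
        assert e == pytest.approx(oracle, abs=1e-10)

    def test_invariance_under_degenerate_virtual_rotation(self):
        rng = np.random.default_rng(7)
        ne = 4
        Q, _ = np.linalg.qr(rng.normal(size=(ne, ne)))
        elec = OrbitalSet(Q[:, :1], Q[:, 1:], np.array([-1.2]),
                          np.array([0.7, 0.7, 1.5]))   # degenerate pair
        prot = _random_orbitals(rng, 3, 1)
        eri = _random_psd_eri(rng, ne, 3)
        e0 = ep_mp2_energy(elec, prot, eri)
        th = 0.4
        U = np.eye(3)
        U[:2, :2] = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        elec_rot = OrbitalSet(elec.C_occ, elec.C_virt @ U,
                              elec.eps_occ, elec.eps_virt)
        assert ep_mp2_energy(elec_rot, prot, eri) == pytest.approx(
            e0, abs=1e-10)

    def test_sign_nonpositive_for_aufbau_gaps(self):
        rng = np.random.default_rng(8)
        for k in range(5):
            e = _random_orbitals(rng, 4, 2)
            p = _random_orbitals(rng, 3, 1)
            assert ep_mp2_energy(e, p, _random_psd_eri(rng, 4, 3)) <= 0.0

    def test_df_variant_matches_exact_on_fixture(self, h2_bundle,
                                                 h2_neo_b3lyp):
        state, _ = h2_neo_b3lyp
        elec = orbital_set(state.C_e, state.eps_e, 1)
        prot = orbital_set(state.C_p, state.eps_p, 1)
        e_exact = ep_mp2_energy(elec, prot, h2_bundle.eri_ep)
        e_df = ep_mp2_energy_df(elec, prot, h2_bundle.j3c_ep,
                                h2_bundle.prot.j3c, h2_bundle.prot.metric)
        assert e_df == pytest.approx(e_exact, abs=1e-6)
        assert e_exact < 0.0


class TestFrozenCore:
    def test_counts(self):
        from neodh.system import parse_xyz
        mol = parse_xyz("3\nx\nO 0 0 0\nH 0 0 1\nH 0 1 0\n")
        assert n_frozen_core(mol) == 1
        assert n_frozen_core(mol, "none") == 0
        with pytest.raises(ValueError):
            n_frozen_core(mol, "all")
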