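import math

import numpy as np
import pytest
from scipy.special import erf

from neodh.basis import BasisSet, make_shell
from neodh.density import (DensityGrid, bond_axis_profile,
                           density_on_voxels, read_cube, write_cube)


def _gaussian_grid(alpha, center, lo, n, spacing):
    """Analytic normalized-Gaussian density on a voxel lattice."""
    ax = [lo[k] + spacing * np.arange(n[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    vals = (alpha / math.pi) ** 1.5 * np.exp(-alpha * r2)
    return DensityGrid(np.array(lo, float), spacing, tuple(n), vals)


class TestVoxelDensity:
    def test_normalized_gaussian_integral(self):
        a = 1.0
        bs = BasisSet([make_shell(0, (0, 0, 0), [a / 2], [1.0])])
        D = np.array([[1.0]])      # density = |phi|^2, exponent a
        g = density_on_voxels(D, bs, spacing=0.1, margin=5.0)
        assert g.integral() == pytest.approx(1.0, abs=1e-4)

    def test_values_match_analytic_gaussian(self):
        a = 1.4
        bs = BasisSet([make_shell(0, (0.2, 0.0, -0.1), [a / 2], [1.0])])
        g = density_on_voxels(np.array([[1.0]]), bs, spacing=0.35,
                              margin=3.0)
        pts = g.points()
        rng = np.random.default_rng(0)
        for idx in rng.integers(0, len(pts), 10):
            d = pts[idx] - np.array([0.2, 0.0, -0.1])
            ref = (a / math.pi) ** 1.5 * math.exp(-a * d @ d)
            assert g.values.ravel()[idx] == pytest.approx(ref, abs=1e-10)

    def test_margin_insensitivity_for_compact_density(self):
        bs = BasisSet([make_shell(0, (0, 0, 0), [1.5], [1.0])])
        D = np.array([[1.0]])
        g1 = density_on_voxels(D, bs, spacing=0.25, margin=4.0)
        g2 = density_on_voxels(D, bs, spacing=0.25, margin=6.0)
        assert abs(g1.integral() - g2.integral()) < 1e-6

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            DensityGrid(np.zeros(3), 0.1, (2, 2, 2),
                        np.full((2, 2, 2), -1.0))


class TestBondAxisProfile:
    def test_identical_grids_zero_profile(self):
        g = _gaussian_grid(1.0, [0, 0, 0], [-3, -3, -3], (40, 40, 40),
                           0.15)
        d, prof = bond_axis_profile(g, g, [0, 0, 0], [0, 0, 1.5])
        assert np.all(prof == 0.0)

    def test_slab_decomposition_is_exact(self):
        gA = _gaussian_grid(1.0, [0, 0, 0.2], [-3, -3, -3], (41, 41, 41),
                            0.15)
        gB = _gaussian_grid(1.3, [0, 0, -0.1], [-3, -3, -3], (41, 41, 41),
                            0.15)
        d, prof = bond_axis_profile(gA, gB, [0, 0, 0], [0, 0, 1.0])
        assert prof.sum() == pytest.approx(
            gA.integral() - gB.integral(), abs=1e-12)

    def test_equal_particle_count_gives_zero_net_profile(self):
        gA = _gaussian_grid(1.0, [0, 0, 0.3], [-4, -4, -4], (54, 54, 54),
                            0.15)
        gB = _gaussian_grid(1.0, [0, 0, -0.3], [-4, -4, -4], (54, 54, 54),
                            0.15)
        _, prof = bond_axis_profile(gA, gB, [0, 0, 0], [0, 0, 1.0])
        assert abs(prof.sum()) < 1e-3

    def test_shifted_gaussian_against_1d_integration_oracle(self):
        """Gaussian vs the same Gaussian shifted along the axis: the
        slab profile matches erf-difference slab integrals of the two
        1-D marginals, and changes sign at the midpoint."""
        a, shift, h = 1.0, 0.6, 0.05
        lo = [-4, -4, -4 + 0]
        n = (161, 161, 161)
        gA = _gaussian_grid(a, [0, 0, shift], lo, n, h)
        gB = _gaussian_grid(a, [0, 0, 0.0], lo, n, h)
        d, prof = bond_axis_profile(gA, gB, [0, 0, 0], [0, 0, 1.0])

        def marginal_slab(center, lo_z, hi_z):
            s = math.sqrt(a)
            return 0.5 * (erf(s * (hi_z - center)) - erf(s * (lo_z - center)))

        ref = np.array([marginal_slab(shift, z - h / 2, z + h / 2)
                        - marginal_slab(0.0, z - h / 2, z + h / 2)
                        for z in d])
        assert np.max(np.abs(prof - ref)) < 5e-4
        mid = shift / 2
        assert np.all(prof[(d > mid + 0.1) & (d < shift + 1.0)] > 0)
        assert np.all(prof[(d < mid - 0.1) & (d > -1.0)] < 0)

    def test_rotation_equivariance_exact_for_lattice_rotation(self):
        """A 90-degree rotation maps the voxel lattice onto itself, so
        the profile is exactly invariant."""
        g = _gaussian_grid(1.0, [0.3, 0, 0], [-3, -3, -3], (41, 41, 41),
                           0.15)
        g_rot = _gaussian_grid(1.0, [0, 0, 0.3], [-3, -3, -3],
                               (41, 41, 41), 0.15)
        zero = _gaussian_grid(1.0, [0.9, 0, 0], [-3, -3, -3],
                              (41, 41, 41), 0.15)
        zero_rot = _gaussian_grid(1.0, [0, 0, 0.9], [-3, -3, -3],
                                  (41, 41, 41), 0.15)
        d1, p1 = bond_axis_profile(g, zero, [0.3, 0, 0], [0.9, 0, 0])
        d2, p2 = bond_axis_profile(g_rot, zero_rot, [0, 0, 0.3],
                                   [0, 0, 0.9])
        assert np.allclose(d1, d2, atol=1e-12)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_grid_mismatch_raises(self):
        gA = _gaussian_grid(1.0, [0, 0, 0], [-2, -2, -2], (21, 21, 21),
                            0.2)
        gB = _gaussian_grid(1.0, [0, 0, 0], [-2, -2, -2], (20, 20, 20),
                            0.2)
        with pytest.raises(ValueError):
            bond_axis_profile(gA, gB, [0, 0, 0], [0, 0, 1])


class TestCubeIO:
    def test_roundtrip(self, tmp_path):
        g = _gaussian_grid(2.0, [0, 0, 0], [-1, -1, -1], (12, 13, 14),
                           0.2)
        path = tmp_path / "d.cube"
        write_cube(path, g, [("O", np.zeros(3))])
        g2, atoms = read_cube(path)
        assert g2.shape == g.shape
        assert np.allclose(g2.values, g.values, rtol=1e-4, atol=1e-12)
        assert atoms[0][0] == "O"
        assert g2.particle == "electronic"


class TestNEODensityDifference:
    def test_quantized_proton_depletes_density_at_its_center(
            self, h2_quantum, h2_bundle, h2_neo_b3lyp):
        """Quantizing a proton delocalizes the electron cloud: the
        NEO - single-component profile is negative at the proton
        center, positive toward the bond partner, and conserves
        charge."""
        import numpy as np
        from neodh.basis import (BasisConfiguration,
                                 build_electronic_basis)
        from neodh.functionals import get_functional
        from neodh.provider import build_integrals
        from neodh.scf import run_neo_scf
        from neodh.system import parse_xyz

        state, _ = h2_neo_b3lyp
        mol_c = parse_xyz("2\nh2\nH 0 0 0\nH 0 0 0.7414\n")
        cfg = BasisConfiguration(electronic_orbital_basis="sto-3g")
        bc = build_integrals(mol_c, cfg, with_grid=True)
        st_c, _ = run_neo_scf(functional=get_functional("b3lyp"),
                              bundle=bc)
        box = [(-3.0, 3.0), (-3.0, 3.0), (-3.0, 4.5)]
        g_neo = density_on_voxels(state.D_e, h2_bundle.elec.basis,
                                  box=box, spacing=0.15)
        g_sc = density_on_voxels(st_c.D_e,
                                 build_electronic_basis(mol_c, "sto-3g"),
                                 box=box, spacing=0.15)
        qp = h2_quantum.molecule.quantum_protons[0]
        heavy = np.array(h2_quantum.molecule.classical_nuclei[0][2])
        d, prof = bond_axis_profile(g_neo, g_sc, qp, heavy)
        at_proton = prof[np.argmin(np.abs(d))]
        near_heavy = prof[np.argmin(np.abs(d - 1.4))]
        assert at_proton < 0.0          # depletion at the point charge
        assert near_heavy > 0.0         # excess toward the heavy atom
        assert abs(prof.sum()) < 1e-3   # same electron count
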