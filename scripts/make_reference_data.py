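"""Generate the stored geometry/vibration inputs for the proton-affinity
worked examples.

Geometry optimization and harmonic frequencies are outside the package
proper (the thermochemistry layer consumes their outputs as numbers);
this script fills that external-engine role with the package's own SCF
backend and freezes the results into
``src/neodh/data/reference/pa_reference.json``:

* geometries optimized at B3LYP/6-31G** in symmetry-internal
  coordinates (Nelder-Mead on 1-5 parameters);
* harmonic frequencies from central-difference Cartesian Hessians at
  B3LYP/6-31G (step 0.01 bohr), mass-weighted, six smallest modes
  projected out;
* harmonic vibrational energies E_vib(298.15 K) = sum(h nu/2
  + h nu/(exp(h nu/kT)-1)) in kcal/mol.

Runtime is a few hours on one CPU; progress is checkpointed under
scratch/ so the script can resume.
"""

import json
import math
import os
import sys
import time

import numpy as np
from scipy.optimize import minimize

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from neodh.basis import BasisConfiguration
from neodh.constants import (ANGSTROM_TO_BOHR, ELEMENT_Z, HARTREE_TO_KCAL,
                             R_GAS_KCAL)
from neodh.functionals import get_functional
from neodh.scf import SCFSettings, run_neo_scf, scf_total_energy
from neodh.system import QuantumMolecule

SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")
OUT = os.path.join(os.path.dirname(__file__), "..", "src", "neodh", "data",
                   "reference", "pa_reference.json")

# atomic masses (u)
MASS = {"H": 1.00782503, "N": 14.0030740, "O": 15.9949146}

HARTREE_TO_CM = 219474.6313632
AMU_TO_ME = 1822.888486209
KB_CM = 0.695034800          # cm^-1 / K


def energy(symbols, coords, charge, basis_name, functional="b3lyp",
           level=3):
    nuc = tuple((s, ELEMENT_Z[s], tuple(c)) for s, c in zip(symbols, coords))
    mol = QuantumMolecule(nuc, np.zeros((0, 3)), charge, 1)
    st, parts = run_neo_scf(
        mol, BasisConfiguration(electronic_orbital_basis=basis_name),
        get_functional(functional),
        SCFSettings(energy_tol=1e-9, density_tol=1e-6, grad_tol=1e-6),
        grid_level=level)
    return scf_total_energy(parts, get_functional(functional))


# --- symmetry-parametrized geometries (bohr) -------------------------------

def geo_no2m(p):
    r, th = p
    a = math.radians(th) / 2
    return ["N", "O", "O"], np.array([
        [0, 0, 0],
        [r * math.sin(a), 0, -r * math.cos(a)],
        [-r * math.sin(a), 0, -r * math.cos(a)]])


def geo_hno2(p):
    # trans-HONO, planar: H-O1-N=O2
    roh, rno, rnod, ahon, aono = p
    O1 = np.array([0.0, 0.0, 0.0])
    N = np.array([rno, 0.0, 0.0])
    ah = math.radians(ahon)
    H = O1 + roh * np.array([math.cos(ah), 0.0, math.sin(ah)])
    ao = math.radians(aono)
    # trans: dihedral H-O1-N=O2 is 180 deg (H +z side, O2 -z side)
    O2 = N + rnod * np.array([-math.cos(ao), 0.0, -math.sin(ao)])
    return ["H", "O", "N", "O"], np.array([H, O1, N, O2])


def geo_nh3(p):
    r, th = p     # th = HNH angle in degrees
    # C3v: H's on a cone; cone half-angle from HNH angle
    cos_hnh = math.cos(math.radians(th))
    # unit vectors u_i with u_i.u_j = cos_hnh, symmetric about z
    # u = (sin b cos phi, sin b sin phi, -cos b); cos_hnh = sin^2 b *
    # cos(120) + cos^2 b -> solve for b
    cosb2 = (1 + 2 * cos_hnh) / 3.0
    cosb = math.sqrt(max(cosb2, 0.0))
    sinb = math.sqrt(1 - cosb2)
    sym = ["N"]
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 2 * math.pi * k / 3
        sym.append("H")
        coords.append([r * sinb * math.cos(phi), r * sinb * math.sin(phi),
                       -r * cosb])
    return sym, np.array(coords)


def geo_nh4(p):
    (r,) = p
    t = r / math.sqrt(3.0)
    sym = ["N", "H", "H", "H", "H"]
    coords = np.array([[0, 0, 0], [t, t, t], [-t, -t, t], [-t, t, -t],
                       [t, -t, -t]])
    return sym, coords


SPECIES = {
    "NO2-": dict(geo=geo_no2m, charge=-1,
                 x0=[1.26 * ANGSTROM_TO_BOHR, 117.0]),
    "HNO2": dict(geo=geo_hno2, charge=0,
                 x0=[0.97 * ANGSTROM_TO_BOHR, 1.43 * ANGSTROM_TO_BOHR,
                     1.17 * ANGSTROM_TO_BOHR, 102.0, 110.5]),
    "NH3": dict(geo=geo_nh3, charge=0,
                x0=[1.014 * ANGSTROM_TO_BOHR, 106.7]),
    "NH4+": dict(geo=geo_nh4, charge=1, x0=[1.024 * ANGSTROM_TO_BOHR]),
}

OPT_BASIS = "6-31g**"
HESS_BASIS = "6-31g"
T = 298.15


def optimize_species(name):
    spec = SPECIES[name]
    count = [0]

    def f(p):
        sym, xyz = spec["geo"](p)
        e = energy(sym, xyz, spec["charge"], OPT_BASIS)
        count[0] += 1
        print(f"  [{name}] opt eval {count[0]}: p={np.round(p,5)} "
              f"E={e:.8f}", flush=True)
        return e

    res = minimize(f, spec["x0"], method="Nelder-Mead",
                   options={"xatol": 2e-4, "fatol": 1e-7,
                            "maxfev": 220})
    return res.x, res.fun


def hessian(name, params):
    spec = SPECIES[name]
    sym, xyz0 = spec["geo"](params)
    n = xyz0.size
    h = 0.01

    cachefile = os.path.join(SCRATCH, f"hess_{name.replace('+','p').replace('-','m')}.json")
    cache = {}
    if os.path.exists(cachefile):
        cache = json.load(open(cachefile))

    def e_at(disp):
        key = ",".join(f"{d:.4f}" for d in disp)
        if key not in cache:
            xyz = xyz0 + np.array(disp).reshape(-1, 3)
            cache[key] = energy(sym, xyz, spec["charge"], HESS_BASIS)
            if len(cache) % 20 == 0:
                json.dump(cache, open(cachefile, "w"))
        return cache[key]

    E0 = e_at(np.zeros(n))
    H = np.zeros((n, n))
    t0 = time.time()
    for i in range(n):
        dp = np.zeros(n); dp[i] = h
        dm = np.zeros(n); dm[i] = -h
        H[i, i] = (e_at(dp) - 2 * E0 + e_at(dm)) / h ** 2
        print(f"  [{name}] Hessian diag {i+1}/{n} ({time.time()-t0:.0f}s)",
              flush=True)
    for i in range(n):
        for j in range(i):
            dpp = np.zeros(n); dpp[i] = h; dpp[j] = h
            dpm = np.zeros(n); dpm[i] = h; dpm[j] = -h
            dmp = np.zeros(n); dmp[i] = -h; dmp[j] = h
            dmm = np.zeros(n); dmm[i] = -h; dmm[j] = -h
            H[i, j] = H[j, i] = (e_at(dpp) - e_at(dpm) - e_at(dmp)
                                 + e_at(dmm)) / (4 * h ** 2)
        print(f"  [{name}] Hessian row {i+1}/{n} ({time.time()-t0:.0f}s)",
              flush=True)
    json.dump(cache, open(cachefile, "w"))
    return sym, xyz0, H, E0


def frequencies(sym, H):
    m = np.repeat([MASS[s] * AMU_TO_ME for s in sym], 3)
    Hm = H / np.sqrt(np.outer(m, m))
    w = np.linalg.eigvalsh(Hm)
    # drop the 6 modes closest to zero (translation/rotation; 5 for
    # linear species, but none of these molecules is linear)
    idx = np.argsort(np.abs(w))
    vib = np.sort(w[idx[6:]])
    freq = np.sign(vib) * np.sqrt(np.abs(vib)) * HARTREE_TO_CM
    return freq


def evib_kcal(freqs_cm, T=298.15):
    e = 0.0
    for nu in freqs_cm:
        if nu < 10.0:         # noise-level or imaginary: skip
            continue
        x = nu / (KB_CM * T)
        e += 0.5 * nu + nu / (math.expm1(x))
    # cm^-1 -> kcal/mol
    return e / HARTREE_TO_CM * HARTREE_TO_KCAL


def main():
    os.makedirs(SCRATCH, exist_ok=True)
    out = {}
    if os.path.exists(OUT):
        out = json.load(open(OUT))
    for name in SPECIES:
        if name in out and "freqs_cm" in out[name]:
            print(f"[{name}] already done, skipping")
            continue
        print(f"[{name}] optimizing at B3LYP/{OPT_BASIS}", flush=True)
        params, e_opt = optimize_species(name)
        print(f"[{name}] optimized params: {params}, E={e_opt:.8f}")
        sym, xyz, H, E0 = hessian(name, params)
        freqs = frequencies(sym, H)
        print(f"[{name}] freqs (cm-1): {np.round(freqs,1)}")
        out[name] = {
            "symbols": sym,
            "coords_bohr": xyz.tolist(),
            "charge": SPECIES[name]["charge"],
            "opt_params": list(map(float, params)),
            "e_opt_hartree": e_opt,
            "freqs_cm": [float(f) for f in freqs],
            "evib_298_kcal": evib_kcal(freqs),
            "provenance": {
                "optimization": f"B3LYP/{OPT_BASIS}, Nelder-Mead on "
                                "symmetry-internal parameters, this package",
                "hessian": f"B3LYP/{HESS_BASIS}, central differences "
                           "0.01 bohr, this package",
                "dispersion": "none"},
        }
        os.makedirs(os.path.dirname(OUT), exist_ok=True)
        json.dump(out, open(OUT, "w"), indent=1)
        print(f"[{name}] saved.", flush=True)
    print("all done")


if __name__ == "__main__":
    main()
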