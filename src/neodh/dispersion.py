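"""Dispersion-correction hook.

Long-range dispersion is outside the reach of the (double-)hybrid
functionals' correlation components and is normally restored by an
additive pairwise correction evaluated from the element types and
positions only; quantum protons enter as hydrogen atoms at their
basis-center positions.

Providers are pluggable.  The built-in providers are

* ``"none"`` -- returns 0 (the default; calculations report the
  dispersion slot explicitly so its absence is auditable);
* ``"c6bj"`` -- a deliberately simple synthetic pairwise model,
  -s6 C6_ij / (R^6 + R0_ij^6), using free-atom C6 coefficients and
  Becke-Johnson-style damping radii.  It exercises the hook and gives
  the right order of magnitude, but it is NOT a published
  dispersion parameterization and carries no coordination-number
  dependence; do not use it when comparing against literature
  D3(BJ)-corrected numbers.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# free-atom C6 coefficients (hartree bohr^6) and vdW radii (bohr) from
# standard literature compilations (Chu & Dalgarno-type values)
_FREE_ATOM_C6 = {"H": 6.5, "He": 1.46, "C": 46.6, "N": 24.2, "O": 15.6,
                 "F": 9.5, "Cl": 94.6, "S": 134.0}
_VDW_RADIUS = {"H": 3.1, "He": 2.65, "C": 3.59, "N": 3.34, "O": 3.19,
               "F": 3.04, "Cl": 3.71, "S": 3.86}

#: per-functional global scaling of the synthetic model
_S6 = {"b3lyp": 1.0, "pbe0": 0.8, "b2plyp": 0.6, "dsd-pbep86": 0.5,
       "pbeqidh": 0.6}


class UnknownDispersionTagError(KeyError):
    pass


def _c6bj(atoms, tag: str) -> float:
    base = tag.replace("neo-", "").replace("-2d", "")
    if base not in _S6:
        raise UnknownDispersionTagError(
            f"no dispersion scaling for functional tag {tag!r}")
    s6 = _S6[base]
    e = 0.0
    for (s1, r1), (s2, r2) in itertools.combinations(atoms, 2):
        c6 = math.sqrt(_FREE_ATOM_C6[s1] * _FREE_ATOM_C6[s2])
        r0 = 0.5 * (_VDW_RADIUS[s1] + _VDW_RADIUS[s2])
        R = float(np.linalg.norm(np.asarray(r1) - np.asarray(r2)))
        e -= s6 * c6 / (R ** 6 + r0 ** 6)
    return e


_PROVIDERS = {"none": lambda atoms, tag: 0.0, "c6bj": _c6bj}


def register_provider(name: str, fn):
    """fn(atoms: list[(symbol, xyz_bohr)], functional_tag) -> Eh."""
    _PROVIDERS[name] = fn


def dispersion_energy(system, functional_tag: str,
                      provider: str = "none") -> float:
    """Dispersion energy (hartree) for the given geometry.

    Depends only on element types and positions; quantum protons
    contribute as hydrogens at their basis centers.  A disabled
    provider returns exactly 0; single atoms have no pairs.
    """
    if provider not in _PROVIDERS:
        raise UnknownDispersionTagError(
            f"unknown dispersion provider {provider!r}; "
            f"known: {sorted(_PROVIDERS)}")
    atoms = system.all_atoms()
    if len(atoms) < 2:
        return 0.0
    return float(_PROVIDERS[provider](atoms, functional_tag))
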