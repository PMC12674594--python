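"""Gaussian basis sets for electrons and quantum protons.

Electronic bases are Cartesian contracted Gaussians loaded from the
package's basis library (Pople family).  Protonic bases are specified
either explicitly, as even-tempered geometric progressions, or by a
registered name; protonic basis functions sit on the quantum-proton
basis centers.

Normalization convention: every Cartesian component is individually
normalized.  Contraction coefficients stored in :class:`Shell` are
final primitive weights (library coefficients times primitive norms,
rescaled so the contracted (l,0,0) function has unit self-overlap);
per-component scaling is carried separately in ``BasisSet.comp_norm``.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

L_OF = {"s": 0, "p": 1, "d": 2, "f": 3, "g": 4}
L_NAME = {v: k for k, v in L_OF.items()}


def cart_components(l: int):
    """Cartesian (lx, ly, lz) triples for angular momentum l, in the
    conventional lexicographic order (xx, xy, xz, yy, yz, zz for d)."""
    out = []
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            out.append((lx, ly, l - lx - ly))
    return out


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(l: int, alpha: float) -> float:
    """Norm of a primitive Cartesian Gaussian with lx=l, ly=lz=0."""
    return ((2 * alpha / math.pi) ** 0.75
            * (4 * alpha) ** (l / 2.0)
            / math.sqrt(_double_factorial(2 * l - 1)))


def component_norm_factor(lx: int, ly: int, lz: int) -> float:
    """Scale turning an (l,0,0)-normalized component into a normalized
    general (lx,ly,lz) component."""
    l = lx + ly + lz
    return math.sqrt(_double_factorial(2 * l - 1)
                     / (_double_factorial(2 * lx - 1)
                        * _double_factorial(2 * ly - 1)
                        * _double_factorial(2 * lz - 1)))


@dataclass(frozen=True)
class Shell:
    """One contracted Cartesian Gaussian shell."""
    l: int
    center: tuple
    exps: np.ndarray
    coefs: np.ndarray          # final primitive weights (see module doc)

    @property
    def ncart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def make_shell(l: int, center, exps, coefs, normalize: bool = True) -> Shell:
    exps = np.asarray(exps, dtype=float)
    coefs = np.asarray(coefs, dtype=float)
    if np.any(exps <= 0):
        raise ValueError("Gaussian exponents must be positive")
    if normalize:
        # weights over *unnormalized* primitives, rescaled to unit
        # contracted (l,0,0) self-overlap
        w = coefs * np.array([primitive_norm(l, a) for a in exps])
        norm = w_overlap(exps, w, l)
        coefs = w / math.sqrt(norm)
    return Shell(l, tuple(float(x) for x in center), exps, coefs)


def w_overlap(exps, raw_coefs, l) -> float:
    """Self-overlap of a contracted (l,0,0) Gaussian with raw
    (unnormalized-primitive) coefficients."""
    a = np.asarray(exps, float)
    c = np.asarray(raw_coefs, float)
    aa = a[:, None] + a[None, :]
    # <g_a | g_b> for unnormalized x^l exp(-a r^2):
    # = (pi/aa)^{3/2} * (2l-1)!! / (2*aa)^l
    s = (math.pi / aa) ** 1.5 * _double_factorial(2 * l - 1) / (2 * aa) ** l
    return float(c @ s @ c)


class BasisSet:
    """A list of shells with Cartesian AO bookkeeping."""

    def __init__(self, shells):
        self.shells = list(shells)
        self.first_ao = []
        n = 0
        comp_norm = []
        labels = []
        for sh in self.shells:
            self.first_ao.append(n)
            for (lx, ly, lz) in cart_components(sh.l):
                comp_norm.append(component_norm_factor(lx, ly, lz))
                labels.append((sh.l, lx, ly, lz))
            n += sh.ncart
        self.nbf = n
        self.comp_norm = np.array(comp_norm) if n else np.zeros(0)
        self.labels = labels

    def __len__(self):
        return len(self.shells)

    def max_l(self) -> int:
        return max((sh.l for sh in self.shells), default=0)

    def centers(self) -> np.ndarray:
        return np.array([sh.center for sh in self.shells]).reshape(-1, 3)


# ---------------------------------------------------------------------------
# protonic bases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtonicBasisSpec:
    """Protonic orbital or fitting basis prescription.

    mode ``"explicit"``: ``shells`` is a list of ``(l, [exponents])``.
    mode ``"even_tempered"``: geometric progressions of ``count``
    exponents from ``alpha_min`` to ``alpha_max`` (inclusive) for each
    angular momentum in ``angular_momenta``.
    mode ``"named"``: resolved through :func:`register_protonic_basis`.
    """
    mode: str
    shells: tuple = ()
    count: int = 0
    alpha_min: float = 0.0
    alpha_max: float = 0.0
    angular_momenta: tuple = ()
    name: str = ""

    def __post_init__(self):
        if self.mode not in ("explicit", "even_tempered", "named"):
            raise ValueError(f"unknown protonic basis mode {self.mode!r}")
        if self.mode == "explicit":
            for l, exps in self.shells:
                e = np.asarray(exps, float)
                if np.any(e <= 0):
                    raise ValueError("exponents must be positive")
                if np.any(np.diff(e) <= 0):
                    raise ValueError("exponents must be strictly increasing "
                                     "within a shell")
        if self.mode == "even_tempered":
            if self.count < 2:
                raise ValueError("even-tempered count must be >= 2")
            if not (0 < self.alpha_min < self.alpha_max):
                raise ValueError("need 0 < alpha_min < alpha_max")

    def exponent_table(self):
        """Resolve to a list of (l, exponents) pairs."""
        if self.mode == "named":
            return resolve_protonic_basis(self.name).exponent_table()
        if self.mode == "explicit":
            return [(l, np.asarray(e, float)) for l, e in self.shells]
        r = (self.alpha_max / self.alpha_min) ** (1.0 / (self.count - 1))
        exps = self.alpha_min * r ** np.arange(self.count)
        exps[-1] = self.alpha_max      # guard endpoint rounding
        return [(L_OF[l] if isinstance(l, str) else int(l), exps.copy())
                for l in self.angular_momenta]

    def n_functions(self) -> int:
        return sum(len(e) * (l + 1) * (l + 2) // 2
                   for l, e in self.exponent_table())


def make_even_tempered(count: int, alpha_min: float, alpha_max: float,
                       angular_momenta=("s",)) -> ProtonicBasisSpec:
    """Even-tempered prescription: per shell a geometric sequence of
    ``count`` exponents from ``alpha_min`` to ``alpha_max`` inclusive,
    ratio ``(alpha_max/alpha_min)**(1/(count-1))``."""
    return ProtonicBasisSpec("even_tempered", count=count,
                             alpha_min=float(alpha_min),
                             alpha_max=float(alpha_max),
                             angular_momenta=tuple(angular_momenta))


_PROTONIC_REGISTRY: dict[str, ProtonicBasisSpec] = {}

#: default protonic orbital basis: an even-tempered 4s4p surrogate
#: spanning the exponent range relevant for an X-H stretch ground state
#: (harmonic alpha = m_p*omega/2 ~ 10-20 for 3000-4000 cm^-1 modes).
DEFAULT_PROTONIC_ORBITAL = make_even_tempered(4, 2 * math.sqrt(2), 32.0,
                                              ("s", "p"))
#: protonic density-fitting basis: even-tempered 10s10p10d10f from
#: 2*sqrt(2) to 64 (successive exponents double every two steps).
DEFAULT_PROTONIC_FITTING = make_even_tempered(10, 2 * math.sqrt(2), 64.0,
                                              ("s", "p", "d", "f"))

_PROTONIC_REGISTRY["et-4s4p"] = DEFAULT_PROTONIC_ORBITAL
_PROTONIC_REGISTRY["et-10s10p10d10f"] = DEFAULT_PROTONIC_FITTING
_PROTONIC_REGISTRY["et-8s8p"] = make_even_tempered(8, 2 * math.sqrt(2), 64.0,
                                                   ("s", "p"))


def register_protonic_basis(name: str, spec: ProtonicBasisSpec):
    _PROTONIC_REGISTRY[name] = spec


def resolve_protonic_basis(name: str) -> ProtonicBasisSpec:
    if name in _PROTONIC_REGISTRY:
        return _PROTONIC_REGISTRY[name]
    raise KeyError(
        f"protonic basis {name!r} is not registered. Literature sets such "
        "as PB4-F2/PB6-F are not redistributed with this package; register "
        "their exponents with register_protonic_basis(), or use the "
        "even-tempered surrogates (et-4s4p, et-8s8p).")


def build_protonic_basis(spec: ProtonicBasisSpec,
                         centers: np.ndarray) -> BasisSet:
    shells = []
    for q in np.atleast_2d(centers):
        for l, exps in spec.exponent_table():
            for a in exps:            # protonic bases are uncontracted
                shells.append(make_shell(l, q, [a], [1.0]))
    return BasisSet(shells)


# ---------------------------------------------------------------------------
# electronic bases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisConfiguration:
    """Names/specs of every basis entering a calculation."""
    electronic_orbital_basis: str = "6-31g**"
    electronic_jk_fitting_basis: str = "auto-etb"
    electronic_mp2_fitting_basis: str = "auto-etb"
    protonic_orbital_basis: ProtonicBasisSpec = DEFAULT_PROTONIC_ORBITAL
    protonic_fitting_basis: ProtonicBasisSpec = DEFAULT_PROTONIC_FITTING

    def __post_init__(self):
        for nm in (self.electronic_orbital_basis,
                   self.electronic_jk_fitting_basis,
                   self.electronic_mp2_fitting_basis):
            if not nm:
                raise ValueError("basis names must be non-empty")


def _load_library() -> dict:
    ref = importlib.resources.files("neodh.data") / "basis/pople.json"
    with importlib.resources.as_file(ref) as path:
        return json.loads(path.read_text())


_LIB = None


def _library():
    global _LIB
    if _LIB is None:
        _LIB = _load_library()
    return _LIB


def element_shells(basis_name: str, element: str):
    """Shell templates (l, exps, coefs) for one element of a named
    electronic basis.  Supports the shipped Pople family including the
    ``*``/``**`` polarization and ``+`` diffuse decorations."""
    lib = _library()
    name = basis_name.lower()
    stars = name.count("*")
    plusses = name.count("+")
    base = name.replace("*", "").replace("+", "")
    if base not in lib:
        raise KeyError(f"electronic basis {base!r} not in the shipped "
                       f"library: {sorted(k for k in lib if '-' in k)}")
    if base == "sto-3g" and (stars or plusses):
        raise KeyError("sto-3g has no polarized/diffuse variants here")
    if element not in lib[base]:
        raise KeyError(f"element {element} missing from basis {base!r}")
    out = []
    for sh in lib[base][element]:
        if sh["l"] == "sp":
            out.append((0, sh["exps"], sh["cs"]))
            out.append((1, sh["exps"], sh["cp"]))
        else:
            out.append((L_OF[sh["l"]], sh["exps"], sh["coefs"]))
    if plusses and base == "6-31g":
        # "+": diffuse sp on heavy atoms; "++": also a diffuse s on H
        if element == "H":
            if plusses >= 2:
                out.append((0, [lib["diffuse_s"]["H"]], [1.0]))
        elif element in lib["diffuse_sp"]:
            a = lib["diffuse_sp"][element]
            out.append((0, [a], [1.0]))
            out.append((1, [a], [1.0]))
    if stars >= 1 and element in lib["polarization_d"]:
        out.append((2, [lib["polarization_d"][element]], [1.0]))
    if stars >= 2 and element in lib["polarization_p"]:
        out.append((1, [lib["polarization_p"][element]], [1.0]))
    return out


def build_electronic_basis(mol, basis_name: str) -> BasisSet:
    """Electronic basis over all centers.  Quantum protons keep their
    hydrogen electronic basis functions (the electron cloud still peaks
    there); only the nuclear point charge is removed."""
    shells = []
    for sym, _, pos in mol.classical_nuclei:
        for l, exps, coefs in element_shells(basis_name, sym):
            shells.append(make_shell(l, pos, exps, coefs))
    for q in mol.quantum_protons:
        for l, exps, coefs in element_shells(basis_name, "H"):
            shells.append(make_shell(l, q, exps, coefs))
    return BasisSet(shells)


def auto_fitting_basis(orbital: BasisSet, beta: float = 2.0,
                       max_l: int | None = None) -> BasisSet:
    """Even-tempered auxiliary basis generated from the orbital basis
    (exponent range doubled, progression ratio ``beta``), one
    uncontracted ladder per center and angular momentum up to
    ``2*max_l_orbital`` (capped)."""
    by_center: dict[tuple, dict[int, list[float]]] = {}
    for sh in orbital.shells:
        d = by_center.setdefault(sh.center, {})
        d.setdefault(sh.l, []).extend(float(a) for a in sh.exps)
    shells = []
    for center, ldict in by_center.items():
        lmax_orb = max(ldict)
        lmax_aux = 2 * lmax_orb if max_l is None else min(2 * lmax_orb, max_l)
        all_exps = [a for v in ldict.values() for a in v]
        amin, amax = 2 * min(all_exps), 2 * max(all_exps)
        for l in range(lmax_aux + 1):
            n = max(2, int(math.ceil(math.log(amax / amin) / math.log(beta))))
            # thin out high-l ladders
            n = max(2, n - l)
            r = (amax / amin) ** (1.0 / (n - 1))
            for k in range(n):
                shells.append(make_shell(l, center, [amin * r ** k], [1.0]))
    return BasisSet(shells)
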