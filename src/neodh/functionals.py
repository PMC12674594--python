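"""Functional registry and total-energy assembly.

A :class:`FunctionalParams` record holds every admixture coefficient of
one named (multicomponent) functional; an :class:`EnergyBreakdown`
holds the *unweighted* energy components, so assembling a total energy
is pure arithmetic:

    E = E_ext,ref + x_dft_scale * E_x^DFT + x_hf * E_x^HF
        + c_dft_scale * E_c^DFT + c_os * E_c^MP2,OS + c_ss * E_c^MP2,SS
        + b_epc * E_epc^DFT + c_epc * E_epc^MP2 + E_disp

which reproduces the B2PLYP, DSD and QIDH double-hybrid forms for the
appropriate coefficient choices.  Electronic coefficients are the
published single-component values and are never refitted here; the NEO
variants add the electron-proton admixture {b_epc, c_epc} from the
one-parameter optimization (two-parameter optima are registered under
the ``-2d`` suffix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .epc17 import EPCParams, EPC17_2


@dataclass(frozen=True)
class FunctionalParams:
    name: str
    x_hf: float = 0.0                       # exact-exchange fraction
    x_dft_scale: float = 1.0                # weight of E_x^DFT in the total
    x_dft: tuple = ()                       # ((coef, component), ...)
    c_dft_scale: float = 1.0
    c_dft: tuple = ()
    c_os: float = 0.0                       # opposite-spin MP2 weight
    c_ss: float = 0.0                       # same-spin MP2 weight
    b_epc: float = 0.0                      # epc-17.2 admixture
    c_epc: float = 0.0                      # ep-MP2 admixture
    epc_params: EPCParams = EPC17_2
    dispersion: str = "none"

    def __post_init__(self):
        for f in (self.x_hf, self.c_os, self.c_ss, self.b_epc, self.c_epc):
            if not (-1e-12 <= f <= 1.0 + 1e-12):
                raise ValueError(f"fraction {f} outside [0, 1] in "
                                 f"{self.name}")

    @property
    def is_double_hybrid(self) -> bool:
        return self.c_os != 0.0 or self.c_ss != 0.0

    @property
    def needs_ep_mp2(self) -> bool:
        return self.c_epc != 0.0

    def scf_exchange(self):
        """Composite DFT exchange entering the SCF potential."""
        return tuple((self.x_dft_scale * c, n) for c, n in self.x_dft)

    def scf_correlation(self):
        return tuple((self.c_dft_scale * c, n) for c, n in self.c_dft)

    def override(self, **kw) -> "FunctionalParams":
        """A new record with modified admixtures (registry stays fixed)."""
        return replace(self, name=self.name + "*", **kw)


@dataclass
class EnergyBreakdown:
    """Unweighted energy components of one converged calculation (Eh).

    ``e_ext_ref`` carries the external-potential, kinetic and Coulomb
    reference energy for both species, the classical nuclear repulsion,
    and the protonic exact exchange (the multicomponent reference has
    no proton-proton correlation functional; only K^pp is kept, which
    exactly removes the protonic self-interaction).
    MP2 slots are ``None`` until the perturbative step fills them.
    """
    e_ext_ref: float = 0.0
    e_x_dft: float = 0.0
    e_x_hf: float = 0.0
    e_c_dft: float = 0.0
    e_c_mp2_os: float | None = None
    e_c_mp2_ss: float | None = None
    e_epc_dft: float = 0.0
    e_epc_mp2: float | None = None
    e_disp: float = 0.0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "e_ext_ref", "e_x_dft", "e_x_hf", "e_c_dft", "e_c_mp2_os",
            "e_c_mp2_ss", "e_epc_dft", "e_epc_mp2", "e_disp")}


class MissingComponentError(ValueError):
    pass


def assemble_energy(parts: EnergyBreakdown,
                    params: FunctionalParams) -> float:
    """Exact linear combination of the stored components (hartree)."""
    total = parts.e_ext_ref + parts.e_disp
    total += params.x_dft_scale * parts.e_x_dft
    total += params.x_hf * parts.e_x_hf
    total += params.c_dft_scale * parts.e_c_dft
    if params.c_os or params.c_ss:
        if parts.e_c_mp2_os is None or parts.e_c_mp2_ss is None:
            raise MissingComponentError(
                f"{params.name} needs e_c_mp2_os/e_c_mp2_ss")
        total += params.c_os * parts.e_c_mp2_os
        total += params.c_ss * parts.e_c_mp2_ss
    total += params.b_epc * parts.e_epc_dft
    if params.c_epc:
        if parts.e_epc_mp2 is None:
            raise MissingComponentError(f"{params.name} needs e_epc_mp2")
        total += params.c_epc * parts.e_epc_mp2
    return total


def _registry() -> dict[str, FunctionalParams]:
    lam = 3.0 ** (-1.0 / 3.0)
    reg = {}

    def add(p):
        reg[p.name] = p

    add(FunctionalParams("hf", x_hf=1.0, x_dft=(), c_dft=()))
    add(FunctionalParams("b3lyp",
                         x_hf=0.20,
                         x_dft=((0.08, "slater"), (0.72, "b88")),
                         c_dft=((0.19, "vwn5"), (0.81, "lyp"))))
    add(FunctionalParams("pbe0",
                         x_hf=0.25, x_dft=((0.75, "pbex"),),
                         c_dft=((1.0, "pbec"),)))
    # B2PLYP: a_ex = 0.53, c_ec = 0.27 (G2/97 least-squares fit)
    add(FunctionalParams("b2plyp",
                         x_hf=0.53, x_dft_scale=0.47,
                         x_dft=((1.0, "b88"),),
                         c_dft_scale=0.73, c_dft=((1.0, "lyp"),),
                         c_os=0.27, c_ss=0.27))
    # DSD-PBEP86: c_ex=0.69, c_ec=0.44, c_eco=0.52, c_ecs=0.22
    add(FunctionalParams("dsd-pbep86",
                         x_hf=0.69, x_dft_scale=0.31,
                         x_dft=((1.0, "pbex"),),
                         c_dft_scale=0.44, c_dft=((1.0, "p86"),),
                         c_os=0.52, c_ss=0.22))
    # PBEQIDH: lambda_ex = 3^(-1/3), lambda_ec = 1/3 (adiabatic
    # connection, quadratic interpolation -- no empirical fit)
    add(FunctionalParams("pbeqidh",
                         x_hf=lam, x_dft_scale=1.0 - lam,
                         x_dft=((1.0, "pbex"),),
                         c_dft_scale=2.0 / 3.0, c_dft=((1.0, "pbec"),),
                         c_os=1.0 / 3.0, c_ss=1.0 / 3.0))

    # multicomponent variants: hybrid NEO-DFT uses the full epc-17.2
    neo_admix = {
        "b3lyp": (1.0, 0.0), "pbe0": (1.0, 0.0), "hf": (0.0, 0.0),
        # one-parameter Bayesian optima (defaults)
        "b2plyp": (0.875, 0.125),
        "dsd-pbep86": (0.806, 0.194),
        "pbeqidh": (0.731, 0.269),
    }
    for base, (b, c) in neo_admix.items():
        add(replace(reg[base], name="neo-" + base, b_epc=b, c_epc=c))
    # two-parameter optima, not defaults (the one-parameter constraint
    # c_epc = 1 - b_epc is the physically sounder choice)
    for base, (b, c) in {"b2plyp": (0.660, 0.875),
                         "dsd-pbep86": (0.635, 0.801),
                         "pbeqidh": (0.542, 1.000)}.items():
        add(replace(reg[base], name="neo-" + base + "-2d", b_epc=b, c_epc=c))
    return reg


_REGISTRY = _registry()


def get_functional(name: str) -> FunctionalParams:
    key = name.lower()
    if key not in _REGISTRY:
        raise KeyError(f"unknown functional {name!r}; registry: "
                       f"{sorted(_REGISTRY)}")
    return _REGISTRY[key]


def available_functionals() -> list[str]:
    return sorted(_REGISTRY)
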