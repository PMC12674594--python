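r"""epc-17.2 electron-proton correlation (LDA-type).

The functional couples the electronic and protonic densities through

    E_epc = - \int rho_e rho_p / (a - b sqrt(rho_e rho_p)
                                    + c rho_e rho_p) dr

with the epc-17.2 parameters a = 2.35, b = 2.4, c = 6.6.  The
denominator is positive for all admissible densities (b^2 < 4ac), so
the energy is never positive.  Potentials are the pointwise functional
derivatives with respect to each density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: densities below this are treated as exactly zero before the sqrt
DENSITY_FLOOR = 1e-14
#: most negative grid density tolerated (quadrature noise)
NEG_TOL = -1e-12


@dataclass(frozen=True)
class EPCParams:
    a: float = 2.35
    b: float = 2.4
    c: float = 6.6

    def __post_init__(self):
        if self.b ** 2 >= 4 * self.a * self.c:
            raise ValueError("epc parameters violate b^2 < 4ac; the "
                             "denominator could vanish")


EPC17_2 = EPCParams()


def _clean(rho):
    rho = np.asarray(rho, float)
    if np.any(rho < NEG_TOL):
        raise ValueError(f"negative density encountered (min {rho.min():g})")
    out = np.where(rho < DENSITY_FLOOR, 0.0, rho)
    return out


def epc_energy(rho_e, rho_p, weights, params: EPCParams = EPC17_2) -> float:
    """Quadrature of the epc-17.2 energy density (hartree, <= 0)."""
    rho_e = _clean(rho_e)
    rho_p = _clean(rho_p)
    if rho_e.shape != rho_p.shape:
        raise ValueError("density arrays must have equal length")
    g = rho_e * rho_p
    den = params.a - params.b * np.sqrt(g) + params.c * g
    return float(np.sum(np.asarray(weights) * (-g / den)))


def epc_potentials(rho_e, rho_p, params: EPCParams = EPC17_2):
    """Pointwise (v_e, v_p) = (d eps/d rho_e, d eps/d rho_p).

    With g = rho_e*rho_p and D = a - b sqrt(g) + c g the derivative of
    eps = -g/D with respect to g is -(a - b sqrt(g)/2)/D^2; the chain
    rule gives v_e = rho_p * deps/dg and symmetrically for v_p.
    """
    rho_e = _clean(rho_e)
    rho_p = _clean(rho_p)
    g = rho_e * rho_p
    sq = np.sqrt(g)
    den = params.a - params.b * sq + params.c * g
    dedg = -(params.a - 0.5 * params.b * sq) / den ** 2
    return dedg * rho_p, dedg * rho_e
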