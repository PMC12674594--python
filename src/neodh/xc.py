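"""Electronic exchange-correlation functionals (closed-shell).

Each functional is defined by its energy density per unit volume
eps(rho, sigma) with rho the total density and sigma = |grad rho|^2.
The potentials v_rho = d eps / d rho and v_sigma = d eps / d sigma are
generated symbolically (sympy) at first use and lambdified to numpy,
which keeps the GGA derivative algebra out of hand-written code.

Available: slater, vwn5, pw92, b88 (full exchange, Slater included),
lyp, pbex, pbec, p86 (PZ81 local + Perdew-86 gradient correction).
"""

from __future__ import annotations

import math

import numpy as np

_CACHE: dict = {}

RHO_FLOOR = 1e-12
SIGMA_FLOOR = 1e-24


def _build(name: str):
    import sympy as sp

    rho, sigma = sp.symbols("rho sigma", positive=True)
    pi = sp.pi

    def vwn_like(rs, A, x0, b, c):
        x = sp.sqrt(rs)
        X = x ** 2 + b * x + c
        X0 = x0 ** 2 + b * x0 + c
        Q = sp.sqrt(4 * c - b ** 2)
        at = sp.atan(Q / (2 * x + b))
        return A * (sp.log(x ** 2 / X) + 2 * b / Q * at
                    - b * x0 / X0 * (sp.log((x - x0) ** 2 / X)
                                     + 2 * (b + 2 * x0) / Q * at))

    rs = (3 / (4 * pi * rho)) ** sp.Rational(1, 3)

    if name == "slater":
        Cx = sp.Rational(3, 4) * (3 / pi) ** sp.Rational(1, 3)
        eps = -Cx * rho ** sp.Rational(4, 3)

    elif name == "vwn5":
        ec = vwn_like(rs, 0.0310907, -0.10498, 3.72744, 12.9352)
        eps = rho * ec

    elif name == "pw92":
        A_, a1, b1, b2, b3, b4 = (0.0310907, 0.21370, 7.5957, 3.5876,
                                  1.6382, 0.49294)
        den = 2 * A_ * (b1 * sp.sqrt(rs) + b2 * rs + b3 * rs ** sp.Rational(3, 2)
                        + b4 * rs ** 2)
        ec = -2 * A_ * (1 + a1 * rs) * sp.log(1 + 1 / den)
        eps = rho * ec

    elif name == "b88":
        beta = 0.0042
        rs_half = rho / 2
        xs = sp.sqrt(sigma) / 2 / rs_half ** sp.Rational(4, 3)
        Cxp = sp.Rational(3, 2) * (3 / (4 * pi)) ** sp.Rational(1, 3)
        h = 1 / (1 + 6 * beta * xs * sp.asinh(xs))
        eps = -2 * rs_half ** sp.Rational(4, 3) * (Cxp + beta * xs ** 2 * h)

    elif name == "lyp":
        a, b, c, d = 0.04918, 0.132, 0.2533, 0.349
        CF = sp.Rational(3, 10) * (3 * pi ** 2) ** sp.Rational(2, 3)
        rm13 = rho ** sp.Rational(-1, 3)
        den = 1 + d * rm13
        omega = sp.exp(-c * rm13) * rho ** sp.Rational(-11, 3) / den
        delta = (c + d / den) * rm13
        eps = (-a * rho / den
               - a * b * omega * (CF * rho ** sp.Rational(14, 3)
                                  - (sp.Rational(1, 24)
                                     + sp.Rational(7, 72) * delta)
                                  * rho ** 2 * sigma))

    elif name == "pbex":
        kappa, mu = 0.804, 0.2195149727645171
        Cx = sp.Rational(3, 4) * (3 / pi) ** sp.Rational(1, 3)
        kF = (3 * pi ** 2 * rho) ** sp.Rational(1, 3)
        s2 = sigma / (4 * kF ** 2 * rho ** 2)
        Fx = 1 + kappa - kappa / (1 + mu * s2 / kappa)
        eps = -Cx * rho ** sp.Rational(4, 3) * Fx

    elif name == "pbec":
        beta = 0.06672455060314922
        gamma = (1 - sp.log(2)) / pi ** 2
        A_, a1, b1, b2, b3, b4 = (0.0310907, 0.21370, 7.5957, 3.5876,
                                  1.6382, 0.49294)
        den = 2 * A_ * (b1 * sp.sqrt(rs) + b2 * rs
                        + b3 * rs ** sp.Rational(3, 2) + b4 * rs ** 2)
        ec = -2 * A_ * (1 + a1 * rs) * sp.log(1 + 1 / den)
        kF = (3 * pi ** 2 * rho) ** sp.Rational(1, 3)
        ks = sp.sqrt(4 * kF / pi)
        t2 = sigma / (4 * ks ** 2 * rho ** 2)
        Aa = beta / gamma / (sp.exp(-ec / gamma) - 1)
        H = gamma * sp.log(1 + beta / gamma * t2 * (1 + Aa * t2)
                           / (1 + Aa * t2 + Aa ** 2 * t2 ** 2))
        eps = rho * (ec + H)

    elif name == "p86":
        # PZ81 local part
        ec_hi = (0.0311 * sp.log(rs) - 0.048 + 0.0020 * rs * sp.log(rs)
                 - 0.0116 * rs)                       # rs < 1
        ec_lo = -0.1423 / (1 + 1.0529 * sp.sqrt(rs) + 0.3334 * rs)
        ec = sp.Piecewise((ec_hi, rs < 1), (ec_lo, True))
        # gradient correction, closed shell (d(zeta)=1)
        alpha, beta_, gamma_, delta_ = 0.023266, 7.389e-6, 8.723, 0.472
        Cinf = 0.004235
        C = 0.001667 + (0.002568 + alpha * rs + beta_ * rs ** 2) / (
            1 + gamma_ * rs + delta_ * rs ** 2 + 1e4 * beta_ * rs ** 3)
        Phi = 1.745 * 0.11 * (Cinf / C) * sp.sqrt(sigma) \
            / rho ** sp.Rational(7, 6)
        eps = rho * ec + sp.exp(-Phi) * C * sigma / rho ** sp.Rational(4, 3)

    else:
        raise KeyError(f"unknown functional component {name!r}")

    vrho = sp.diff(eps, rho)
    vsigma = sp.diff(eps, sigma)
    mods = ["numpy"]
    f_eps = sp.lambdify((rho, sigma), eps, mods)
    f_vr = sp.lambdify((rho, sigma), vrho, mods)
    f_vs = sp.lambdify((rho, sigma), vsigma, mods)
    return f_eps, f_vr, f_vs


def is_gga(name: str) -> bool:
    return name in ("b88", "lyp", "pbex", "pbec", "p86")


def eval_xc(name: str, rho: np.ndarray, sigma: np.ndarray | None = None):
    """Energy density and potentials of one functional component.

    Returns ``(eps, vrho, vsigma)`` arrays; ``vsigma`` is zero for LDA
    components.  Densities below ``RHO_FLOOR`` contribute nothing.
    """
    if name not in _CACHE:
        _CACHE[name] = _build(name)
    f_eps, f_vr, f_vs = _CACHE[name]
    rho = np.asarray(rho, float)
    if sigma is None:
        sigma = np.zeros_like(rho)
    sigma = np.asarray(sigma, float)
    mask = rho > RHO_FLOOR
    r = np.where(mask, rho, 1.0)
    s = np.maximum(sigma, SIGMA_FLOOR)
    with np.errstate(all="ignore"):
        eps = np.where(mask, f_eps(r, s), 0.0)
        vr = np.where(mask, f_vr(r, s), 0.0)
        vs = np.where(mask, f_vs(r, s), 0.0)
    return eps, vr, vs


def eval_composite(components, rho, sigma=None):
    """Weighted sum of components given as [(coef, name), ...]."""
    eps = np.zeros_like(np.asarray(rho, float))
    vr = np.zeros_like(eps)
    vs = np.zeros_like(eps)
    for coef, name in components:
        e, r, s = eval_xc(name, rho, sigma)
        eps += coef * e
        vr += coef * r
        vs += coef * s
    return eps, vr, vs
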