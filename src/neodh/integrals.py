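"""Gaussian integrals over contracted Cartesian shells.

McMurchie-Davidson scheme: Hermite expansion coefficients E_t^{ij} for
bra/ket charge distributions and Hermite Coulomb integrals R_{tuv} built
on the Boys function.  The kernels are numba-jitted; drivers loop over
shell pairs/quartets in Python and exploit permutational symmetry.

These routines serve both particle types: a protonic basis is just
another ``BasisSet``.  Two-particle repulsion integrals are in chemists'
notation (ab|cd) = \int a(1)b(1) r12^-1 c(2)d(2).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import BasisSet, Shell, cart_components, component_norm_factor

_SQRT_PI = math.sqrt(math.pi)
_TWO_PI_POW = 2.0 * math.pi ** 2.5


def _comps(l: int) -> np.ndarray:
    return np.array(cart_components(l), dtype=np.int64).reshape(-1, 3)


_COMPS = [_comps(l) for l in range(7)]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _boys(mmax, x, out):
    """Boys function F_m(x) for m = 0..mmax (inclusive)."""
    if x < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if x > 35.0:
        # upward recursion from the asymptotic F0
        ex = math.exp(-x) if x < 700 else 0.0
        out[0] = 0.5 * math.sqrt(math.pi / x)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - ex) / (2.0 * x)
        return
    # series at m = mmax, then downward recursion
    ex = math.exp(-x)
    s = 1.0 / (2 * mmax + 1)
    term = s
    k = 1
    while True:
        term *= 2.0 * x / (2 * mmax + 2 * k + 1)
        s += term
        if term < 1e-17 * s or k > 250:
            break
        k += 1
    out[mmax] = ex * s
    for m in range(mmax, 0, -1):
        out[m - 1] = (2.0 * x * out[m] + ex) / (2 * m - 1)


@njit(cache=True)
def _hermite_E(la, lb, PA, PB, p, K, E):
    """Fill E[i, j, t] for one dimension (t = 0..i+j), premultiplied by
    the Gaussian product prefactor K = exp(-mu*AB^2) in E[0,0,0]."""
    E[:, :, :] = 0.0
    E[0, 0, 0] = K
    o2p = 0.5 / p
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build up in i
                for t in range(i + 1):
                    v = PA * E[i - 1, 0, t]
                    if t > 0:
                        v += o2p * E[i - 1, 0, t - 1]
                    if t + 1 <= i - 1:
                        v += (t + 1) * E[i - 1, 0, t + 1]
                    E[i, 0, t] = v
            else:
                for t in range(i + j + 1):
                    v = PB * E[i, j - 1, t]
                    if t > 0:
                        v += o2p * E[i, j - 1, t - 1]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = v


@njit(cache=True)
def _hermite_R(L, alpha, X, Y, Z, R):
    """Hermite Coulomb integrals R_{tuv} (n = 0 slice) for combined
    order L, via the standard auxiliary-index recursion."""
    r2 = X * X + Y * Y + Z * Z
    F = np.zeros(L + 1)
    _boys(L, alpha * r2, F)
    # Rn[n, t, u, v]
    Rn = np.zeros((L + 1, L + 1, L + 1, L + 1))
    for n in range(L + 1):
        Rn[n, 0, 0, 0] = (-2.0 * alpha) ** n * F[n]
    for total in range(1, L + 1):
        for n in range(L - total + 1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    R[:, :, :] = Rn[0]


@njit(cache=True)
def _pair_overlap_kinetic(la, lb, A, B, expsa, ca, expsb, cb,
                          compa, compb, S, T):
    """Contracted overlap and kinetic blocks for one shell pair."""
    S[:, :] = 0.0
    T[:, :] = 0.0
    ab2 = 0.0
    for d in range(3):
        ab2 += (A[d] - B[d]) ** 2
    # E with lb+2 to reach the shifted kinetic terms
    Ex = np.zeros((la + 1, lb + 3, la + lb + 3))
    Ey = np.zeros((la + 1, lb + 3, la + lb + 3))
    Ez = np.zeros((la + 1, lb + 3, la + lb + 3))
    for ia in range(len(expsa)):
        a = expsa[ia]
        for ib in range(len(expsb)):
            b = expsb[ib]
            p = a + b
            K = math.exp(-a * b / p * ab2)
            cc = ca[ia] * cb[ib]
            if abs(cc) * K < 1e-18:
                continue
            PA = np.empty(3)
            PB = np.empty(3)
            for d in range(3):
                P = (a * A[d] + b * B[d]) / p
                PA[d] = P - A[d]
                PB[d] = P - B[d]
            _hermite_E(la, lb + 2, PA[0], PB[0], p, K, Ex)
            _hermite_E(la, lb + 2, PA[1], PB[1], p, 1.0, Ey)
            _hermite_E(la, lb + 2, PA[2], PB[2], p, 1.0, Ez)
            fac = (math.pi / p) ** 1.5
            for ka in range(compa.shape[0]):
                ax, ay, az = compa[ka, 0], compa[ka, 1], compa[ka, 2]
                for kb in range(compb.shape[0]):
                    bx, by, bz = compb[kb, 0], compb[kb, 1], compb[kb, 2]
                    sx = Ex[ax, bx, 0]
                    sy = Ey[ay, by, 0]
                    sz = Ez[az, bz, 0]
                    S[ka, kb] += cc * fac * sx * sy * sz
                    # 1D kinetic factors w.r.t. the right exponent b
                    tx = -2.0 * b * b * Ex[ax, bx + 2, 0] \
                        + b * (2 * bx + 1) * sx
                    if bx > 1:
                        tx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0]
                    ty = -2.0 * b * b * Ey[ay, by + 2, 0] \
                        + b * (2 * by + 1) * sy
                    if by > 1:
                        ty -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0]
                    tz = -2.0 * b * b * Ez[az, bz + 2, 0] \
                        + b * (2 * bz + 1) * sz
                    if bz > 1:
                        tz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0]
                    T[ka, kb] += cc * fac * (tx * sy * sz + sx * ty * sz
                                             + sx * sy * tz)


@njit(cache=True)
def _pair_nuclear(la, lb, A, B, expsa, ca, expsb, cb, compa, compb,
                  charges, coords, V):
    """Contracted nuclear-attraction-operator block
    sum_A Z_A <a| 1/|r-R_A| |b> (positive; caller applies signs)."""
    V[:, :] = 0.0
    L = la + lb
    ab2 = 0.0
    for d in range(3):
        ab2 += (A[d] - B[d]) ** 2
    Ex = np.zeros((la + 1, lb + 1, L + 1))
    Ey = np.zeros((la + 1, lb + 1, L + 1))
    Ez = np.zeros((la + 1, lb + 1, L + 1))
    R = np.zeros((L + 1, L + 1, L + 1))
    for ia in range(len(expsa)):
        a = expsa[ia]
        for ib in range(len(expsb)):
            b = expsb[ib]
            p = a + b
            K = math.exp(-a * b / p * ab2)
            cc = ca[ia] * cb[ib]
            if abs(cc) * K < 1e-18:
                continue
            Pv = np.empty(3)
            PA = np.empty(3)
            PB = np.empty(3)
            for d in range(3):
                Pv[d] = (a * A[d] + b * B[d]) / p
                PA[d] = Pv[d] - A[d]
                PB[d] = Pv[d] - B[d]
            _hermite_E(la, lb, PA[0], PB[0], p, K, Ex)
            _hermite_E(la, lb, PA[1], PB[1], p, 1.0, Ey)
            _hermite_E(la, lb, PA[2], PB[2], p, 1.0, Ez)
            for ic in range(len(charges)):
                _hermite_R(L, p, Pv[0] - coords[ic, 0],
                           Pv[1] - coords[ic, 1], Pv[2] - coords[ic, 2], R)
                pref = cc * charges[ic] * 2.0 * math.pi / p
                for ka in range(compa.shape[0]):
                    ax, ay, az = compa[ka, 0], compa[ka, 1], compa[ka, 2]
                    for kb in range(compb.shape[0]):
                        bx, by, bz = compb[kb, 0], compb[kb, 1], compb[kb, 2]
                        acc = 0.0
                        for t in range(ax + bx + 1):
                            ex = Ex[ax, bx, t]
                            if ex == 0.0:
                                continue
                            for u in range(ay + by + 1):
                                ey = Ey[ay, by, u]
                                if ey == 0.0:
                                    continue
                                for v in range(az + bz + 1):
                                    ez = Ez[az, bz, v]
                                    if ez != 0.0:
                                        acc += ex * ey * ez * R[t, u, v]
                        V[ka, kb] += pref * acc


@njit(cache=True)
def _quartet_eri(la, lb, lc, ld, A, B, C, D,
                 expsa, ca, expsb, cb, expsc, cc_, expsd, cd,
                 compa, compb, compc, compd, out):
    """Contracted (ab|cd) block for one shell quartet."""
    out[:, :, :, :] = 0.0
    Lb = la + lb
    Lk = lc + ld
    L = Lb + Lk
    ab2 = 0.0
    cd2 = 0.0
    for d in range(3):
        ab2 += (A[d] - B[d]) ** 2
        cd2 += (C[d] - D[d]) ** 2
    E1x = np.zeros((la + 1, lb + 1, Lb + 1))
    E1y = np.zeros((la + 1, lb + 1, Lb + 1))
    E1z = np.zeros((la + 1, lb + 1, Lb + 1))
    E2x = np.zeros((lc + 1, ld + 1, Lk + 1))
    E2y = np.zeros((lc + 1, ld + 1, Lk + 1))
    E2z = np.zeros((lc + 1, ld + 1, Lk + 1))
    R = np.zeros((L + 1, L + 1, L + 1))
    herm_ket = np.zeros((Lk + 1, Lk + 1, Lk + 1))
    for ia in range(len(expsa)):
        a = expsa[ia]
        for ib in range(len(expsb)):
            b = expsb[ib]
            p = a + b
            Kab = math.exp(-a * b / p * ab2)
            cab = ca[ia] * cb[ib]
            if abs(cab) * Kab < 1e-16:
                continue
            Pv = np.empty(3)
            for d in range(3):
                Pv[d] = (a * A[d] + b * B[d]) / p
            _hermite_E(la, lb, Pv[0] - A[0], Pv[0] - B[0], p, Kab, E1x)
            _hermite_E(la, lb, Pv[1] - A[1], Pv[1] - B[1], p, 1.0, E1y)
            _hermite_E(la, lb, Pv[2] - A[2], Pv[2] - B[2], p, 1.0, E1z)
            for ic in range(len(expsc)):
                c = expsc[ic]
                for idd in range(len(expsd)):
                    dd = expsd[idd]
                    q = c + dd
                    if q == 0.0:
                        continue
                    Kcd = 1.0 if cd2 == 0.0 else math.exp(-c * dd / q * cd2)
                    ccd = cc_[ic] * cd[idd]
                    pref = _TWO_PI_POW / (p * q * math.sqrt(p + q))
                    if abs(cab * ccd) * Kab * Kcd * pref < 1e-16:
                        continue
                    Qv = np.empty(3)
                    for d in range(3):
                        Qv[d] = (c * C[d] + dd * D[d]) / q
                    _hermite_E(lc, ld, Qv[0] - C[0], Qv[0] - D[0], q, Kcd,
                               E2x)
                    _hermite_E(lc, ld, Qv[1] - C[1], Qv[1] - D[1], q, 1.0,
                               E2y)
                    _hermite_E(lc, ld, Qv[2] - C[2], Qv[2] - D[2], q, 1.0,
                               E2z)
                    alpha = p * q / (p + q)
                    _hermite_R(L, alpha, Pv[0] - Qv[0], Pv[1] - Qv[1],
                               Pv[2] - Qv[2], R)
                    cfac = cab * ccd * pref
                    for kc in range(compc.shape[0]):
                        cx, cy, cz = compc[kc, 0], compc[kc, 1], compc[kc, 2]
                        for kd in range(compd.shape[0]):
                            dx, dy, dz = (compd[kd, 0], compd[kd, 1],
                                          compd[kd, 2])
                            # pre-contract ket Hermite coefficients
                            for t2 in range(cx + dx + 1):
                                for u2 in range(cy + dy + 1):
                                    for v2 in range(cz + dz + 1):
                                        sgn = 1.0 if (t2 + u2 + v2) % 2 == 0 \
                                            else -1.0
                                        herm_ket[t2, u2, v2] = (
                                            sgn * E2x[cx, dx, t2]
                                            * E2y[cy, dy, u2]
                                            * E2z[cz, dz, v2])
                            for ka in range(compa.shape[0]):
                                ax, ay, az = (compa[ka, 0], compa[ka, 1],
                                              compa[ka, 2])
                                for kb in range(compb.shape[0]):
                                    bx, by, bz = (compb[kb, 0], compb[kb, 1],
                                                  compb[kb, 2])
                                    acc = 0.0
                                    for t in range(ax + bx + 1):
                                        e1 = E1x[ax, bx, t]
                                        if e1 == 0.0:
                                            continue
                                        for u in range(ay + by + 1):
                                            e2 = e1 * E1y[ay, by, u]
                                            if e2 == 0.0:
                                                continue
                                            for v in range(az + bz + 1):
                                                e3 = e2 * E1z[az, bz, v]
                                                if e3 == 0.0:
                                                    continue
                                                s = 0.0
                                                for t2 in range(cx + dx + 1):
                                                    for u2 in range(
                                                            cy + dy + 1):
                                                        for v2 in range(
                                                                cz + dz + 1):
                                                            h = herm_ket[
                                                                t2, u2, v2]
                                                            if h != 0.0:
                                                                s += h * R[
                                                                    t + t2,
                                                                    u + u2,
                                                                    v + v2]
                                                acc += e3 * s
                                    out[ka, kb, kc, kd] += cfac * acc


# ---------------------------------------------------------------------------
# python drivers
# ---------------------------------------------------------------------------

_DUMMY = Shell(0, (0.0, 0.0, 0.0), np.array([0.0]), np.array([1.0]))


def _shell_arrays(sh: Shell):
    return (np.asarray(sh.center, float), np.asarray(sh.exps, float),
            np.asarray(sh.coefs, float))


def overlap_kinetic(bs: BasisSet):
    """(S, T) matrices for one particle type (unit mass kinetic)."""
    n = bs.nbf
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    for i, shi in enumerate(bs.shells):
        Ai, ea, cai = _shell_arrays(shi)
        oi = bs.first_ao[i]
        for j, shj in enumerate(bs.shells):
            if j > i:
                continue
            Bj, eb, cbj = _shell_arrays(shj)
            oj = bs.first_ao[j]
            sblk = np.zeros((shi.ncart, shj.ncart))
            tblk = np.zeros((shi.ncart, shj.ncart))
            _pair_overlap_kinetic(shi.l, shj.l, Ai, Bj, ea, cai, eb, cbj,
                                  _COMPS[shi.l], _COMPS[shj.l], sblk, tblk)
            S[oi:oi + shi.ncart, oj:oj + shj.ncart] = sblk
            T[oi:oi + shi.ncart, oj:oj + shj.ncart] = tblk
            if i != j:
                S[oj:oj + shj.ncart, oi:oi + shi.ncart] = sblk.T
                T[oj:oj + shj.ncart, oi:oi + shi.ncart] = tblk.T
    cn = bs.comp_norm
    S *= cn[:, None] * cn[None, :]
    T *= cn[:, None] * cn[None, :]
    # kinetic is symmetric only up to round-off when built one-sided
    T = 0.5 * (T + T.T)
    return S, T


def nuclear_attraction_operator(bs: BasisSet, charges, coords):
    """Matrix of sum_A Z_A <mu| 1/|r - R_A| |nu> (positive operator)."""
    charges = np.asarray(charges, float)
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = bs.nbf
    V = np.zeros((n, n))
    if len(charges) == 0 or n == 0:
        return V
    for i, shi in enumerate(bs.shells):
        Ai, ea, cai = _shell_arrays(shi)
        oi = bs.first_ao[i]
        for j, shj in enumerate(bs.shells):
            if j > i:
                continue
            Bj, eb, cbj = _shell_arrays(shj)
            oj = bs.first_ao[j]
            blk = np.zeros((shi.ncart, shj.ncart))
            _pair_nuclear(shi.l, shj.l, Ai, Bj, ea, cai, eb, cbj,
                          _COMPS[shi.l], _COMPS[shj.l], charges, coords, blk)
            V[oi:oi + shi.ncart, oj:oj + shj.ncart] = blk
            if i != j:
                V[oj:oj + shj.ncart, oi:oi + shi.ncart] = blk.T
    cn = bs.comp_norm
    V *= cn[:, None] * cn[None, :]
    return 0.5 * (V + V.T)


def _quartet(shi, shj, shk, shl):
    Ai, ea, ca = _shell_arrays(shi)
    Bj, eb, cb = _shell_arrays(shj)
    Ck, ec, cc = _shell_arrays(shk)
    Dl, ed, cd = _shell_arrays(shl)
    out = np.zeros((shi.ncart, shj.ncart, shk.ncart, shl.ncart))
    _quartet_eri(shi.l, shj.l, shk.l, shl.l, Ai, Bj, Ck, Dl,
                 ea, ca, eb, cb, ec, cc, ed, cd,
                 _COMPS[shi.l], _COMPS[shj.l], _COMPS[shk.l], _COMPS[shl.l],
                 out)
    return out


def _schwarz(bs: BasisSet) -> np.ndarray:
    ns = len(bs.shells)
    q = np.zeros((ns, ns))
    for i, shi in enumerate(bs.shells):
        for j in range(i + 1):
            blk = _quartet(shi, bs.shells[j], shi, bs.shells[j])
            m = 0.0
            for a in range(shi.ncart):
                for b in range(bs.shells[j].ncart):
                    m = max(m, abs(blk[a, b, a, b]))
            q[i, j] = q[j, i] = math.sqrt(m)
    return q


def eri_full(bs: BasisSet, screen: float = 1e-13) -> np.ndarray:
    """Full (uv|ls) tensor with 8-fold permutational symmetry."""
    n = bs.nbf
    eri = np.zeros((n, n, n, n))
    qs = _schwarz(bs)
    qmax = qs.max() if qs.size else 0.0
    sh = bs.shells
    off = bs.first_ao
    for i in range(len(sh)):
        for j in range(i + 1):
            if qs[i, j] * qmax < screen:
                continue
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    if qs[i, j] * qs[k, l] < screen:
                        continue
                    blk = _quartet(sh[i], sh[j], sh[k], sh[l])
                    si, sj = slice(off[i], off[i] + sh[i].ncart), \
                        slice(off[j], off[j] + sh[j].ncart)
                    sk, sl = slice(off[k], off[k] + sh[k].ncart), \
                        slice(off[l], off[l] + sh[l].ncart)
                    eri[si, sj, sk, sl] = blk
                    eri[sj, si, sk, sl] = blk.transpose(1, 0, 2, 3)
                    eri[si, sj, sl, sk] = blk.transpose(0, 1, 3, 2)
                    eri[sj, si, sl, sk] = blk.transpose(1, 0, 3, 2)
                    eri[sk, sl, si, sj] = blk.transpose(2, 3, 0, 1)
                    eri[sl, sk, si, sj] = blk.transpose(3, 2, 0, 1)
                    eri[sk, sl, sj, si] = blk.transpose(2, 3, 1, 0)
                    eri[sl, sk, sj, si] = blk.transpose(3, 2, 1, 0)
    cn = bs.comp_norm
    eri *= (cn[:, None, None, None] * cn[None, :, None, None]
            * cn[None, None, :, None] * cn[None, None, None, :])
    return eri


def eri_cross(bra: BasisSet, ket: BasisSet, screen: float = 1e-13):
    """(ab|cd) with a,b from ``bra`` and c,d from ``ket`` (e.g. the
    electron-proton repulsion block).  4-fold symmetry."""
    na, nb = bra.nbf, ket.nbf
    eri = np.zeros((na, na, nb, nb))
    for i, shi in enumerate(bra.shells):
        oi = bra.first_ao[i]
        for j in range(i + 1):
            shj = bra.shells[j]
            oj = bra.first_ao[j]
            for k, shk in enumerate(ket.shells):
                ok = ket.first_ao[k]
                for l in range(k + 1):
                    shl = ket.shells[l]
                    ol = ket.first_ao[l]
                    blk = _quartet(shi, shj, shk, shl)
                    si = slice(oi, oi + shi.ncart)
                    sj = slice(oj, oj + shj.ncart)
                    sk = slice(ok, ok + shk.ncart)
                    sl = slice(ol, ol + shl.ncart)
                    eri[si, sj, sk, sl] = blk
                    eri[sj, si, sk, sl] = blk.transpose(1, 0, 2, 3)
                    eri[si, sj, sl, sk] = blk.transpose(0, 1, 3, 2)
                    eri[sj, si, sl, sk] = blk.transpose(1, 0, 3, 2)
    cna, cnb = bra.comp_norm, ket.comp_norm
    eri *= (cna[:, None, None, None] * cna[None, :, None, None]
            * cnb[None, None, :, None] * cnb[None, None, None, :])
    return eri


def eri_3c(bra: BasisSet, aux: BasisSet) -> np.ndarray:
    """Three-center (ab|P) tensor (ket pair = auxiliary x unit dummy)."""
    na, nx = bra.nbf, aux.nbf
    out = np.zeros((na, na, nx))
    for i, shi in enumerate(bra.shells):
        oi = bra.first_ao[i]
        for j in range(i + 1):
            shj = bra.shells[j]
            oj = bra.first_ao[j]
            for k, shk in enumerate(aux.shells):
                ok = aux.first_ao[k]
                blk = _quartet(shi, shj, shk, _DUMMY)[:, :, :, 0]
                si = slice(oi, oi + shi.ncart)
                sj = slice(oj, oj + shj.ncart)
                sk = slice(ok, ok + shk.ncart)
                out[si, sj, sk] = blk
                if i != j:
                    out[sj, si, sk] = blk.transpose(1, 0, 2)
    out *= (bra.comp_norm[:, None, None] * bra.comp_norm[None, :, None]
            * aux.comp_norm[None, None, :])
    return out


def eri_2c(auxA: BasisSet, auxB: BasisSet | None = None) -> np.ndarray:
    """Two-center Coulomb metric (P|Q)."""
    same = auxB is None
    if same:
        auxB = auxA
    out = np.zeros((auxA.nbf, auxB.nbf))
    for i, shi in enumerate(auxA.shells):
        oi = auxA.first_ao[i]
        for j, shj in enumerate(auxB.shells):
            if same and j > i:
                continue
            oj = auxB.first_ao[j]
            blk = _quartet(shi, _DUMMY, shj, _DUMMY)[:, 0, :, 0]
            out[oi:oi + shi.ncart, oj:oj + shj.ncart] = blk
            if same and i != j:
                out[oj:oj + shj.ncart, oi:oi + shi.ncart] = blk.T
    out *= auxA.comp_norm[:, None] * auxB.comp_norm[None, :]
    return out


# ---------------------------------------------------------------------------
# basis amplitudes on grids (numpy; used by the XC/epc quadrature and
# the voxel density analysis)
# ---------------------------------------------------------------------------

def eval_basis(bs: BasisSet, points: np.ndarray, deriv: int = 0):
    """AO values (and optionally gradients) at ``points`` (npts, 3).

    Returns ``vals`` (npts, nbf) or ``(vals, grads)`` with grads of
    shape (npts, nbf, 3).
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    npts = pts.shape[0]
    vals = np.zeros((npts, bs.nbf))
    grads = np.zeros((npts, bs.nbf, 3)) if deriv else None
    iao = 0
    for sh in bs.shells:
        d = pts - np.asarray(sh.center)
        r2 = np.einsum("pi,pi->p", d, d)
        radial = np.zeros(npts)
        dradial = np.zeros(npts)    # d/d(r2) of radial
        for a, c in zip(sh.exps, sh.coefs):
            e = c * np.exp(-a * r2)
            radial += e
            dradial += -a * e
        for (lx, ly, lz) in cart_components(sh.l):
            mono = (d[:, 0] ** lx) * (d[:, 1] ** ly) * (d[:, 2] ** lz)
            f = component_norm_factor(lx, ly, lz)
            vals[:, iao] = f * mono * radial
            if deriv:
                for k, lk in enumerate((lx, ly, lz)):
                    term = 2.0 * d[:, k] * mono * dradial
                    if lk > 0:
                        pw = [lx, ly, lz]
                        pw[k] -= 1
                        lower = (d[:, 0] ** pw[0]) * (d[:, 1] ** pw[1]) \
                            * (d[:, 2] ** pw[2])
                        term = term + lk * lower * radial
                    grads[:, iao, k] = f * term
            iao += 1
    if deriv:
        return vals, grads
    return vals
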