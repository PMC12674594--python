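"""Coupled electron-proton Kohn-Sham SCF.

Two Fock operators -- electronic and protonic -- are converged in
alternating species subcycles inside an outer loop.  The electronic
Fock carries kinetic energy, classical-nuclear attraction, electronic
Coulomb, the hybrid exchange-correlation potential, the attraction to
the protonic density and the (b_epc-scaled) electron-side epc-17.2
potential.  The protonic Fock carries the mass-scaled kinetic energy,
classical-nuclear *repulsion*, attraction to the electronic density,
protonic Coulomb J^pp with exact exchange K^pp (protons are identical
same-spin fermions in one determinant; no proton-proton correlation
functional is used) and the proton-side epc potential.

Convergence protocol: energy difference below 1e-8 Eh, density change
and orbital-gradient norm below 1e-5 a.u. for both species, with DIIS
(Pulay) extrapolation over up to 10 Fock matrices starting after the
first iteration.  The MP2-type terms are strictly post-SCF; only the
epc-17.2 potential (scaled by b_epc) is self-consistent, mirroring how
double hybrids treat the scaled DFT correlation potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .epc17 import epc_energy, epc_potentials
from .functionals import EnergyBreakdown, FunctionalParams
from .provider import IntegralBundle, build_integrals, lowdin_x
from .xc import eval_composite

log = logging.getLogger(__name__)


class SCFConvergenceError(RuntimeError):
    def __init__(self, msg, iteration_log=None):
        super().__init__(msg)
        self.iteration_log = iteration_log or []


@dataclass
class SCFSettings:
    energy_tol: float = 1e-8        # Eh
    density_tol: float = 1e-5       # a.u.
    grad_tol: float = 1e-5          # a.u.
    diis_len: int = 10
    diis_start: int = 1             # DIIS initiated after this iteration
    max_outer: int = 100
    max_inner: int = 30
    initial_guess: str = "auto"     # auto | core

    def __post_init__(self):
        if min(self.energy_tol, self.density_tol, self.grad_tol) <= 0:
            raise ValueError("thresholds must be positive")
        if self.diis_len < 1:
            raise ValueError("DIIS history length must be >= 1")


@dataclass
class NEOState:
    C_e: np.ndarray = None
    eps_e: np.ndarray = None
    occ_e: np.ndarray = None
    D_e: np.ndarray = None
    C_p: np.ndarray | None = None
    eps_p: np.ndarray | None = None
    occ_p: np.ndarray | None = None
    D_p: np.ndarray | None = None
    iteration_log: list = field(default_factory=list)
    converged: bool = False

    def idempotency_defect(self, S_e, S_p=None) -> float:
        d = np.max(np.abs(self.D_e @ S_e @ self.D_e - 2.0 * self.D_e))
        if self.D_p is not None and S_p is not None and self.D_p.size:
            d = max(d, float(np.max(np.abs(
                self.D_p @ S_p @ self.D_p - self.D_p))))
        return float(d)


# ---------------------------------------------------------------------------
# DIIS
# ---------------------------------------------------------------------------

def _diis_coefficients(errors):
    """Pulay coefficients (sum to 1) for a list of error vectors, or
    ``None`` when the linear system is singular."""
    n = len(errors)
    B = np.empty((n + 1, n + 1))
    B[-1, :] = -1.0
    B[:, -1] = -1.0
    B[-1, -1] = 0.0
    for i in range(n):
        for j in range(i + 1):
            B[i, j] = B[j, i] = float(np.vdot(errors[i], errors[j]))
    rhs = np.zeros(n + 1)
    rhs[-1] = -1.0
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > 1e14:
        return None
    try:
        coeff = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(coeff)):
        return None
    return coeff


def diis_update(history, max_len: int = 10):
    """Pulay least-squares extrapolation over (Fock, error) pairs.

    Returns ``(F_extrapolated, truncated_history)``.  Falls back to the
    most recent Fock when the DIIS system is singular.
    """
    history = list(history)[-max_len:]
    if len(history) == 1:
        return history[0][0].copy(), history
    coeff = _diis_coefficients([e for _, e in history])
    if coeff is None:
        return history[-1][0].copy(), history
    F = np.zeros_like(history[0][0])
    for ci, (Fi, _) in zip(coeff, history):
        F += ci * Fi
    return F, history


def _diag(F, X, nocc, occ_val):
    e, V = np.linalg.eigh(X.T @ F @ X)
    C = X @ V
    occ = np.zeros(C.shape[1])
    occ[:nocc] = occ_val
    D = (C[:, :nocc] * occ_val) @ C[:, :nocc].T
    return C, e, occ, D


# ---------------------------------------------------------------------------
# Fock builders
# ---------------------------------------------------------------------------

def _grid_density(ao, D, grads=None):
    t = ao @ D
    rho = np.einsum("pi,pi->p", t, ao)
    if grads is None:
        return rho, None, None
    grho = 2.0 * np.einsum("pi,pik->pk", t, grads)
    sigma = np.einsum("pk,pk->p", grho, grho)
    return rho, grho, sigma


def _xc_contribution(bundle, components, rho, grho, sigma):
    """(E_xc, V_xc) of a composite on the bundle grid."""
    w = bundle.grid.weights
    ao = bundle.elec.ao_vals
    grads = bundle.elec.ao_grads
    eps, vr, vs = eval_composite(components, rho, sigma)
    E = float(w @ eps)
    V = ao.T @ (ao * (w * vr)[:, None])
    for k in range(3):
        M = grads[:, :, k].T @ (ao * (2.0 * w * vs * grho[:, k])[:, None])
        V += M + M.T
    return E, 0.5 * (V + V.T)


def _epc_matrices(bundle, rho_e, rho_p, params):
    w = bundle.grid.weights
    v_e, v_p = epc_potentials(rho_e, rho_p, params)
    ao_e = bundle.elec.ao_vals
    ao_p = bundle.prot.ao_vals
    V_e = ao_e.T @ (ao_e * (w * v_e)[:, None])
    V_p = ao_p.T @ (ao_p * (w * v_p)[:, None])
    E = epc_energy(rho_e, rho_p, w, params)
    return E, V_e, V_p


def build_electronic_fock(state: NEOState, bundle: IntegralBundle,
                          functional: FunctionalParams,
                          epc_scale: float | None = None) -> np.ndarray:
    """Electronic Fock matrix at the state's densities (spec Eq. form:
    kinetic + external + Coulomb + hybrid XC + proton attraction +
    scaled epc potential)."""
    if epc_scale is None:
        epc_scale = functional.b_epc
    F, *_ = _electronic_fock_pieces(state.D_e, state.D_p, bundle,
                                    functional, epc_scale)
    return F


def _electronic_fock_pieces(D_e, D_p, bundle, functional, epc_scale):
    el = bundle.elec
    if D_e.shape != el.S.shape:
        raise ValueError("electronic density dimension mismatch")
    h = el.T + el.v_ext
    J = np.einsum("pqrs,rs->pq", el.eri, D_e, optimize=True)
    F = h + J
    K = None
    if functional.x_hf:
        K = np.einsum("prqs,rs->pq", el.eri, D_e, optimize=True)
        F -= 0.5 * functional.x_hf * K
    E_x_dft = E_c_dft = 0.0
    rho_e = grho = sigma = None
    if bundle.grid is not None and (functional.x_dft or functional.c_dft):
        rho_e, grho, sigma = _grid_density(el.ao_vals, D_e, el.ao_grads)
        E_x_dft, Vx = _xc_contribution(bundle, functional.x_dft,
                                       rho_e, grho, sigma)
        F += functional.x_dft_scale * Vx
        if functional.c_dft:
            E_c_dft, Vc = _xc_contribution(bundle, functional.c_dft,
                                           rho_e, grho, sigma)
            F += functional.c_dft_scale * Vc
    E_epc = 0.0
    if (bundle.has_protons and D_p is not None and D_p.size
            and bundle.grid is not None and epc_scale):
        if rho_e is None:
            rho_e, _, _ = _grid_density(el.ao_vals, D_e)
        rho_p, _, _ = _grid_density(bundle.prot.ao_vals, D_p)
        E_epc, V_e, _ = _epc_matrices(bundle, rho_e, rho_p,
                                      functional.epc_params)
        F += epc_scale * V_e
    if bundle.has_protons and D_p is not None and D_p.size:
        F -= np.einsum("pqrs,rs->pq", bundle.eri_ep, D_p, optimize=True)
    return F, J, K, E_x_dft, E_c_dft, E_epc


def build_protonic_fock(state: NEOState, bundle: IntegralBundle,
                        epc_scale: float = 1.0,
                        functional: FunctionalParams | None = None
                        ) -> np.ndarray:
    F, *_ = _protonic_fock_pieces(state.D_e, state.D_p, bundle,
                                  functional, epc_scale)
    return F


def _protonic_fock_pieces(D_e, D_p, bundle, functional, epc_scale):
    pr = bundle.prot
    if D_p.shape != pr.S.shape:
        raise ValueError("protonic density dimension mismatch")
    h = pr.T + pr.v_ext
    Jp = np.einsum("pqrs,rs->pq", pr.eri, D_p, optimize=True)
    Kp = np.einsum("prqs,rs->pq", pr.eri, D_p, optimize=True)
    F = h + Jp - Kp
    if D_e is not None and D_e.size:
        F -= np.einsum("pqrs,pq->rs", bundle.eri_ep, D_e, optimize=True)
    if bundle.grid is not None and epc_scale and D_e is not None:
        params = functional.epc_params if functional else None
        from .epc17 import EPC17_2
        rho_e, _, _ = _grid_density(bundle.elec.ao_vals, D_e)
        rho_p, _, _ = _grid_density(pr.ao_vals, D_p)
        _, _, V_p = _epc_matrices(bundle, rho_e, rho_p, params or EPC17_2)
        F += epc_scale * V_p
    return F, Jp, Kp


# ---------------------------------------------------------------------------
# total energy
# ---------------------------------------------------------------------------

def _energies(D_e, D_p, bundle, functional, epc_scale):
    """All energy components at the given densities.  Returns
    (E_scf_total, EnergyBreakdown with MP2 slots unset)."""
    el = bundle.elec
    h_e = el.T + el.v_ext
    J = np.einsum("pqrs,rs->pq", el.eri, D_e, optimize=True)
    e1 = float(np.einsum("pq,pq", D_e, h_e))
    ej = 0.5 * float(np.einsum("pq,pq", D_e, J))
    K = np.einsum("prqs,rs->pq", el.eri, D_e, optimize=True)
    e_x_hf = -0.25 * float(np.einsum("pq,pq", D_e, K))
    e_ext_ref = bundle.e_nuc + e1 + ej
    e_x_dft = e_c_dft = e_epc = 0.0
    rho_e = grho = sigma = None
    if bundle.grid is not None and (functional.x_dft or functional.c_dft):
        rho_e, grho, sigma = _grid_density(el.ao_vals, D_e, el.ao_grads)
        from .xc import eval_composite as _ec
        w = bundle.grid.weights
        if functional.x_dft:
            eps, _, _ = _ec(functional.x_dft, rho_e, sigma)
            e_x_dft = float(w @ eps)
        if functional.c_dft:
            eps, _, _ = _ec(functional.c_dft, rho_e, sigma)
            e_c_dft = float(w @ eps)
    if bundle.has_protons and D_p is not None and D_p.size:
        pr = bundle.prot
        h_p = pr.T + pr.v_ext
        Jp = np.einsum("pqrs,rs->pq", pr.eri, D_p, optimize=True)
        Kp = np.einsum("prqs,rs->pq", pr.eri, D_p, optimize=True)
        e_ext_ref += float(np.einsum("pq,pq", D_p, h_p))
        e_ext_ref += 0.5 * float(np.einsum("pq,pq", D_p, Jp))
        e_ext_ref -= 0.5 * float(np.einsum("pq,pq", D_p, Kp))
        e_ext_ref -= float(np.einsum("pqrs,pq,rs", bundle.eri_ep,
                                     D_e, D_p, optimize=True))
        if bundle.grid is not None:
            if rho_e is None:
                rho_e, _, _ = _grid_density(el.ao_vals, D_e)
            rho_p, _, _ = _grid_density(pr.ao_vals, D_p)
            e_epc = epc_energy(rho_e, rho_p, bundle.grid.weights,
                               functional.epc_params)
    parts = EnergyBreakdown(e_ext_ref=e_ext_ref, e_x_dft=e_x_dft,
                            e_x_hf=e_x_hf, e_c_dft=e_c_dft,
                            e_epc_dft=e_epc)
    e_scf = (e_ext_ref + functional.x_dft_scale * e_x_dft
             + functional.x_hf * e_x_hf
             + functional.c_dft_scale * e_c_dft + epc_scale * e_epc)
    return e_scf, parts


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _species_subcycle(D, D_other, bundle, functional, epc_scale, species,
                      X, nocc, occ_val, settings, tol_e, history):
    """Converge one species at fixed density of the other; returns the
    updated (C, eps, occ, D, grad_norm, history)."""
    S = bundle.elec.S if species == "e" else bundle.prot.S
    e_prev = None
    C = eps = occ = None
    grad = np.inf
    for it in range(settings.max_inner):
        if species == "e":
            F, J, K, ex, ec, eepc = _electronic_fock_pieces(
                D, D_other, bundle, functional, epc_scale)
        else:
            F, Jp, Kp = _protonic_fock_pieces(
                D_other, D, bundle, functional, epc_scale)
        err = X.T @ (F @ D @ S - S @ D @ F) @ X
        grad = float(np.max(np.abs(err))) if err.size else 0.0
        history.append((F, err))
        if len(history) > settings.diis_start:
            F, history[:] = diis_update(history, settings.diis_len)
        C, eps, occ, D = _diag(F, X, nocc, occ_val)
        # inner convergence on the species electronic energy proxy
        e_now = float(np.einsum("pq,pq", D, F))
        if e_prev is not None and abs(e_now - e_prev) < tol_e \
                and grad < settings.grad_tol * 10:
            e_prev = e_now
            break
        e_prev = e_now
    return C, eps, occ, D, grad, history


def run_neo_scf(system=None, basis=None, functional: FunctionalParams = None,
                settings: SCFSettings | None = None,
                bundle: IntegralBundle | None = None, grid_level: int = 3,
                epc_scale: float | None = None,
                initial_densities=None):
    """Converge the (multicomponent) SCF; returns (NEOState,
    EnergyBreakdown).

    Either pass ``system`` + ``basis`` (a :class:`BasisConfiguration`)
    or a prebuilt ``bundle``.  With zero quantum protons this is a
    conventional restricted Kohn-Sham calculation.  ``epc_scale``
    defaults to the functional's b_epc (the epc potential enters the
    SCF with its admixture weight; the MP2-type terms never do).
    """
    settings = settings or SCFSettings()
    if functional is None:
        raise ValueError("functional required")
    if bundle is None:
        needs_grid = bool(functional.x_dft or functional.c_dft
                          or (functional.b_epc
                              and system.n_quantum_protons))
        bundle = build_integrals(system, basis, grid_level=grid_level,
                                 with_grid=needs_grid)
    sys_ = bundle.system
    if sys_ is not None and sys_.multiplicity != 1:
        raise NotImplementedError("only closed-shell electronic references")
    if epc_scale is None:
        epc_scale = functional.b_epc
    if bundle.n_elec is not None:
        n_elec = bundle.n_elec
    elif sys_ is not None:
        n_elec = sys_.n_electrons
    else:
        raise ValueError("bundle without system needs n_elec")
    if n_elec % 2:
        raise NotImplementedError("odd electron count (open shell)")
    nocc_e = n_elec // 2
    X_e = lowdin_x(bundle.elec.S)

    if not bundle.has_protons:
        state, e_tot, parts = _converge_single(bundle, functional, settings,
                                               X_e, nocc_e)
        return state, parts

    n_p = bundle.n_prot if bundle.n_prot is not None \
        else sys_.n_quantum_protons
    X_p = lowdin_x(bundle.prot.S)

    # --- initial guess ---------------------------------------------------
    if initial_densities is not None:
        D_e, D_p = initial_densities
    else:
        D_e = _initial_electronic_density(bundle, functional, settings,
                                          X_e, nocc_e)
        F_p0 = bundle.prot.T + bundle.prot.v_ext \
            - np.einsum("pqrs,pq->rs", bundle.eri_ep, D_e, optimize=True)
        _, _, _, D_p = _diag(F_p0, X_p, n_p, 1.0)

    log_rows = []
    e_prev = None
    joint_hist = []       # (F_e, F_p, concatenated error) across outers
    state = NEOState()
    dE = 1.0
    for it in range(settings.max_outer):
        inner_tol = max(0.1 * settings.energy_tol,
                        min(1e-5, 0.01 * abs(dE)))
        D_e_old, D_p_old = D_e, D_p
        # species subcycles at the partner's frozen density
        (state.C_e, state.eps_e, state.occ_e, D_e, _,
         _) = _species_subcycle(D_e, D_p, bundle, functional,
                                epc_scale, "e", X_e, nocc_e, 2.0,
                                settings, inner_tol, [])
        (state.C_p, state.eps_p, state.occ_p, D_p, _,
         _) = _species_subcycle(D_p, D_e, bundle, functional,
                                epc_scale, "p", X_p, n_p, 1.0,
                                settings, inner_tol, [])
        # joint acceleration: extrapolate both Fock matrices together so
        # the slow electron-proton alternation mode is also damped
        F_e, *_ = _electronic_fock_pieces(D_e, D_p, bundle, functional,
                                          epc_scale)
        F_p, *_ = _protonic_fock_pieces(D_e, D_p, bundle, functional,
                                        epc_scale)
        err_e = X_e.T @ (F_e @ D_e @ bundle.elec.S
                         - bundle.elec.S @ D_e @ F_e) @ X_e
        err_p = X_p.T @ (F_p @ D_p @ bundle.prot.S
                         - bundle.prot.S @ D_p @ F_p) @ X_p
        grad_e = float(np.max(np.abs(err_e)))
        grad_p = float(np.max(np.abs(err_p)))
        joint_hist.append((F_e, F_p,
                           np.concatenate([err_e.ravel(), err_p.ravel()])))
        joint_hist = joint_hist[-settings.diis_len:]
        if it >= settings.diis_start and len(joint_hist) > 1:
            coeff = _diis_coefficients([e for _, _, e in joint_hist])
            if coeff is not None:
                F_e = sum(c * F for c, (F, _, _) in zip(coeff, joint_hist))
                F_p = sum(c * F for c, (_, F, _) in zip(coeff, joint_hist))
        state.C_e, state.eps_e, state.occ_e, D_e = _diag(F_e, X_e,
                                                         nocc_e, 2.0)
        state.C_p, state.eps_p, state.occ_p, D_p = _diag(F_p, X_p,
                                                         n_p, 1.0)
        e_tot, parts = _energies(D_e, D_p, bundle, functional, epc_scale)
        dD = max(float(np.max(np.abs(D_e - D_e_old))),
                 float(np.max(np.abs(D_p - D_p_old))))
        dE = (e_tot - e_prev) if e_prev is not None else 1.0
        log_rows.append({"iter": it, "energy": e_tot, "dE": dE,
                         "dD": dD, "grad_e": grad_e, "grad_p": grad_p})
        log.info("NEO outer %2d  E=%.10f dE=%.2e dD=%.2e g_e=%.2e g_p=%.2e",
                 it, e_tot, dE, dD, grad_e, grad_p)
        if (e_prev is not None and abs(dE) < settings.energy_tol
                and dD < settings.density_tol
                and max(grad_e, grad_p) < settings.grad_tol):
            state.D_e, state.D_p = D_e, D_p
            state.iteration_log = log_rows
            state.converged = True
            return state, parts
        e_prev = e_tot
    raise SCFConvergenceError(
        f"NEO-SCF not converged in {settings.max_outer} outer iterations",
        log_rows)


def _initial_electronic_density(bundle, functional, settings, X_e, nocc_e):
    """Single-component guess: quantum protons put back as classical +1
    charges, converged loosely, then removed."""
    if settings.initial_guess == "core" or bundle.system is None \
            or bundle.grid is None:
        h = bundle.elec.T + bundle.elec.v_ext
        _, _, _, D = _diag(h, X_e, nocc_e, 2.0)
        return D
    from .integrals import nuclear_attraction_operator
    qp = bundle.system.quantum_protons
    V_qp = -nuclear_attraction_operator(bundle.elec.basis,
                                        np.ones(len(qp)), qp)
    guess_settings = SCFSettings(energy_tol=1e-6, density_tol=1e-4,
                                 grad_tol=1e-4, diis_len=settings.diis_len,
                                 max_inner=60)
    state, _, _ = _converge_single(bundle, functional, guess_settings,
                                   X_e, nocc_e, v_extra=V_qp)
    return state.D_e


def _converge_single(bundle, functional, settings, X_e, nocc_e,
                     v_extra=None):
    """Plain electronic SCF loop (no quantum protons, or guess stage)."""
    el = bundle.elec
    h = el.T + el.v_ext + (v_extra if v_extra is not None else 0.0)
    _, _, _, D = _diag(h, X_e, nocc_e, 2.0)
    hist = []
    e_prev = None
    log_rows = []
    patched = _PatchedBundle(bundle, v_extra) if v_extra is not None \
        else bundle
    h_eff = patched.elec.T + patched.elec.v_ext
    for it in range(settings.max_outer if v_extra is None
                    else settings.max_inner):
        F, J, K, ex, ec, _ = _electronic_fock_pieces(
            D, None, patched, functional, 0.0)
        err = X_e.T @ (F @ D @ el.S - el.S @ D @ F) @ X_e
        grad = float(np.max(np.abs(err)))
        # energy from the pieces already at hand (K skipped for pure
        # functionals; the HF-exchange term is then zero anyway)
        e_tot = (patched.e_nuc + float(np.einsum("pq,pq", D, h_eff))
                 + 0.5 * float(np.einsum("pq,pq", D, J))
                 + functional.x_dft_scale * ex
                 + functional.c_dft_scale * ec)
        if K is not None:
            e_tot -= 0.25 * functional.x_hf * float(
                np.einsum("pq,pq", D, K))
        hist.append((F, err))
        if len(hist) > settings.diis_start:
            F, hist = diis_update(hist, settings.diis_len)
        C, eps, occ, D_new = _diag(F, X_e, nocc_e, 2.0)
        dD = float(np.max(np.abs(D_new - D)))
        dE = (e_tot - e_prev) if e_prev is not None else 1.0
        log_rows.append({"iter": it, "energy": e_tot, "dE": dE, "dD": dD,
                         "grad_e": grad, "grad_p": 0.0})
        D = D_new
        if (e_prev is not None and abs(dE) < settings.energy_tol
                and dD < settings.density_tol
                and grad < settings.grad_tol):
            state = NEOState(C_e=C, eps_e=eps, occ_e=occ, D_e=D,
                             iteration_log=log_rows, converged=True)
            e_tot, parts = _energies(D, None, patched, functional, 0.0)
            return state, e_tot, parts
        e_prev = e_tot
    raise SCFConvergenceError("electronic SCF not converged", log_rows)


class _PatchedBundle:
    """Bundle view with an extra external potential (guess stage)."""

    def __init__(self, bundle, v_extra):
        self._b = bundle
        from .provider import SpeciesIntegrals
        el = bundle.elec
        self.elec = SpeciesIntegrals(el.basis, el.S, el.T,
                                     el.v_ext + v_extra, el.eri,
                                     el.ao_vals, el.ao_grads)
        qp = bundle.system.quantum_protons
        z = bundle.system.classical_charges
        r = bundle.system.classical_coords
        extra = 0.0
        for q in qp:
            for zi, ri in zip(z, r):
                extra += zi / np.linalg.norm(q - ri)
        for i in range(len(qp)):
            for j in range(i):
                extra += 1.0 / np.linalg.norm(qp[i] - qp[j])
        self.e_nuc = bundle.e_nuc + extra
        self.grid = bundle.grid
        self.prot = None
        self.eri_ep = None
        self.has_protons = False
        self.system = bundle.system


def scf_total_energy(parts: EnergyBreakdown,
                     functional: FunctionalParams) -> float:
    """SCF-level total (MP2 slots excluded): the b_epc=1/c_epc=0 limit
    of the assembled energy when the functional is a plain hybrid."""
    e = (parts.e_ext_ref + functional.x_dft_scale * parts.e_x_dft
         + functional.x_hf * parts.e_x_hf
         + functional.c_dft_scale * parts.e_c_dft
         + functional.b_epc * parts.e_epc_dft)
    return e
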