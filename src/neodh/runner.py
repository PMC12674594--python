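"""High-level single-point driver: SCF + post-SCF terms + assembly."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .basis import BasisConfiguration
from .dispersion import dispersion_energy
from .functionals import (EnergyBreakdown, FunctionalParams, assemble_energy,
                          get_functional)
from .mp2 import correlate
from .provider import build_integrals
from .scf import NEOState, SCFSettings, run_neo_scf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    functional: str = "neo-b2plyp"
    basis: BasisConfiguration = field(default_factory=BasisConfiguration)
    grid_level: int = 3
    scf: SCFSettings = field(default_factory=SCFSettings)
    dispersion_provider: str = "none"
    frozen_core: str = "auto"
    temperature: float = 298.15
    seed: int = 0

    def resolved(self) -> dict:
        """Fully-resolved echo of every setting (emitted with results
        so a run is reproducible from its output alone)."""
        f = get_functional(self.functional)
        return {
            "functional": self.functional,
            "coefficients": {
                "x_hf": f.x_hf, "x_dft_scale": f.x_dft_scale,
                "c_dft_scale": f.c_dft_scale, "c_os": f.c_os,
                "c_ss": f.c_ss, "b_epc": f.b_epc, "c_epc": f.c_epc},
            "electronic_basis": self.basis.electronic_orbital_basis,
            "protonic_basis": str(self.basis.protonic_orbital_basis),
            "grid_level": self.grid_level,
            "scf": {"energy_tol": self.scf.energy_tol,
                    "density_tol": self.scf.density_tol,
                    "grad_tol": self.scf.grad_tol,
                    "diis_len": self.scf.diis_len,
                    "diis_start": self.scf.diis_start},
            "dispersion_provider": self.dispersion_provider,
            "frozen_core": self.frozen_core,
            "temperature": self.temperature,
            "seed": self.seed,
        }


@dataclass
class SinglePointResult:
    total: float
    parts: EnergyBreakdown
    state: NEOState
    functional: FunctionalParams
    config_echo: dict

    def as_record(self) -> dict:
        rec = {"total_hartree": self.total,
               "converged": self.state.converged,
               "components": self.parts.as_dict(),
               "iterations": self.state.iteration_log,
               "config": self.config_echo}
        return rec


def run_single_point(mol, config: RunConfig | None = None,
                     functional: str | FunctionalParams | None = None,
                     bundle=None) -> SinglePointResult:
    """End-to-end energy: converge the (NEO-)SCF, add the perturbative
    and dispersion terms the functional requests, assemble the total."""
    config = config or RunConfig()
    if functional is None:
        f = get_functional(config.functional)
    elif isinstance(functional, str):
        f = get_functional(functional)
    else:
        f = functional
    if bundle is None:
        needs_grid = bool(f.x_dft or f.c_dft
                          or (f.b_epc and mol.n_quantum_protons))
        bundle = build_integrals(mol, config.basis,
                                 grid_level=config.grid_level,
                                 with_grid=needs_grid)
    state, parts = run_neo_scf(functional=f, settings=config.scf,
                               bundle=bundle)
    if f.is_double_hybrid or (f.needs_ep_mp2 and bundle.has_protons):
        e_os, e_ss, e_ep = correlate(state, bundle, f, mol,
                                     config.frozen_core)
        parts.e_c_mp2_os, parts.e_c_mp2_ss = e_os, e_ss
        parts.e_epc_mp2 = e_ep
    elif bundle.has_protons:
        parts.e_epc_mp2 = 0.0
    if parts.e_c_mp2_os is None and not f.is_double_hybrid:
        parts.e_c_mp2_os = parts.e_c_mp2_ss = 0.0
    if parts.e_epc_mp2 is None:
        parts.e_epc_mp2 = 0.0
    parts.e_disp = dispersion_energy(mol, f.name,
                                     config.dispersion_provider) \
        if mol is not None else 0.0
    total = assemble_energy(parts, f)
    log.info("single point %s: E = %.10f Eh (converged=%s)", f.name,
             total, state.converged)
    return SinglePointResult(total, parts, state, f, config.resolved())
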