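"""Proton-affinity thermochemistry and benchmark statistics.

The proton affinity is the negative protonation enthalpy,
PA = -dH = -dE + RT.  In the ideal-gas picture the translational
energy change on losing the free proton is -(3/2)RT, rotational
changes cancel, so

    single-component route:  PA(A) = -dE_elec - dE_vib + (5/2) RT
    multicomponent route:    PA(A) = E_A - E_AH+ + (5/2) RT

where the NEO energy of AH+ already contains the anharmonic zero-point
energy of the quantum proton, and zero-point contributions of the
classical nuclei predominantly cancel between A and AH+ (no further
correction is applied).  dE_vib is the harmonic vibrational-energy
change from an external frequency calculation, supplied as a number in
kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HARTREE_TO_KCAL, R_GAS_KCAL, T_STANDARD


@dataclass(frozen=True)
class ThermoConstants:
    R: float = R_GAS_KCAL          # kcal mol^-1 K^-1
    T: float = T_STANDARD          # K


@dataclass(frozen=True)
class PAResult:
    label: str
    pa_calc: float                 # kcal/mol
    pa_exp: float                  # kcal/mol
    route: str                     # "neo" | "sc"

    @property
    def unsigned_error(self) -> float:
        return abs(self.pa_calc - self.pa_exp)


def proton_affinity_neo(E_A: float, E_AH_neo: float,
                        T: float = T_STANDARD) -> float:
    """PA from a single-component energy of A (hartree) and a NEO
    energy of AH+ with the added proton quantized (hartree)."""
    return (E_A - E_AH_neo) * HARTREE_TO_KCAL + 2.5 * R_GAS_KCAL * T


def proton_affinity_sc(E_A: float, E_AH: float, dE_vib: float,
                       T: float = T_STANDARD) -> float:
    """Single-component PA; ``dE_vib`` (kcal/mol) is the change in
    harmonic vibrational energy (ZPE + thermal) upon protonation."""
    return (-(E_AH - E_A) * HARTREE_TO_KCAL - dE_vib
            + 2.5 * R_GAS_KCAL * T)


@dataclass
class DatasetSummary:
    mue: float
    rmsd: float
    median: float
    min: float
    max: float
    n: int

    def as_dict(self):
        return {"mue": self.mue, "rmsd": self.rmsd, "median": self.median,
                "min": self.min, "max": self.max, "n": self.n}


def summarize_errors(errors) -> DatasetSummary:
    e = np.abs(np.asarray(list(errors), float))
    return DatasetSummary(mue=float(e.mean()),
                          rmsd=float(np.sqrt(np.mean(e ** 2))),
                          median=float(np.median(e)),
                          min=float(e.min()), max=float(e.max()),
                          n=len(e))


def evaluate_dataset(entries, computed: dict, route: str = "sc"):
    """Score computed PAs (kcal/mol, keyed by dataset label) against a
    reference table; returns (list of PAResult, DatasetSummary)."""
    missing = [e.label for e in entries if e.label not in computed]
    if missing:
        raise KeyError(f"no computed PA for labels: {missing}")
    results = [PAResult(e.label, float(computed[e.label]), e.pa_exp_kcal,
                        route) for e in entries]
    summary = summarize_errors([r.unsigned_error for r in results])
    return results, summary


def per_class_summary(entries, computed: dict, route: str = "sc") -> dict:
    out = {}
    for klass in sorted({e.klass for e in entries}):
        sub = [e for e in entries if e.klass == klass]
        _, s = evaluate_dataset(sub, computed, route)
        out[klass] = s
    return out
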