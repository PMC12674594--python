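"""Molecular data model for multicomponent calculations.

A :class:`QuantumMolecule` separates the nuclei into *classical* point
charges (which create the external potential) and *quantum protons*,
which are treated as fermions with their own orbital basis.  A quantum
proton carries no point charge in the external potential -- its +1
charge lives entirely in the protonic density -- and its stored position
only serves as the protonic basis center.

The module also ships the proton-affinity reference tables (the PA23
parametrization set and the 9-molecule test set) as package data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, ELEMENT_Z


class XYZParseError(ValueError):
    """Malformed XYZ input."""


class ValidationError(ValueError):
    """Inconsistent molecular specification."""


@dataclass(frozen=True)
class QuantumMolecule:
    """Classical point nuclei plus designated quantum protons.

    Attributes
    ----------
    classical_nuclei:
        list of ``(symbol, Z, xyz_bohr)`` tuples.
    quantum_protons:
        ``(N_p, 3)`` array of protonic basis-center positions in bohr.
    net_charge:
        total molecular charge (classical nuclei + quantum protons -
        electrons).
    multiplicity:
        electronic spin multiplicity (only 1 is supported by the SCF).
    """

    classical_nuclei: tuple
    quantum_protons: np.ndarray
    net_charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        qp = np.atleast_2d(np.asarray(self.quantum_protons, dtype=float))
        if qp.size == 0:
            qp = np.zeros((0, 3))
        object.__setattr__(self, "quantum_protons", qp)
        if self.n_electrons < 0:
            raise ValidationError("negative electron count")
        # classical nuclei and quantum protons must be disjoint centers
        for _, _, pos in self.classical_nuclei:
            for q in qp:
                if np.linalg.norm(np.asarray(pos) - q) < 1e-6:
                    raise ValidationError(
                        "quantum proton coincides with a classical nucleus")

    @property
    def n_quantum_protons(self) -> int:
        return len(self.quantum_protons)

    @property
    def n_electrons(self) -> int:
        zsum = sum(z for _, z, _ in self.classical_nuclei)
        return int(zsum) + self.n_quantum_protons - self.net_charge

    @property
    def classical_charges(self) -> np.ndarray:
        return np.array([z for _, z, _ in self.classical_nuclei], dtype=float)

    @property
    def classical_coords(self) -> np.ndarray:
        if not self.classical_nuclei:
            return np.zeros((0, 3))
        return np.array([p for _, _, p in self.classical_nuclei], dtype=float)

    def nuclear_repulsion(self) -> float:
        """Coulomb repulsion among *classical* nuclei only (hartree).

        Quantum-proton interactions with the classical frame and among
        themselves are carried by the protonic Hamiltonian.
        """
        z = self.classical_charges
        r = self.classical_coords
        e = 0.0
        for i in range(len(z)):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    def all_atoms(self):
        """All atoms (classical + quantum protons as H) for dispersion
        and geometry purposes: list of (symbol, xyz_bohr)."""
        out = [(s, np.asarray(p, float)) for s, _, p in self.classical_nuclei]
        out += [("H", q) for q in self.quantum_protons]
        return out

    def translated(self, shift) -> "QuantumMolecule":
        shift = np.asarray(shift, float)
        nuc = tuple((s, z, tuple(np.asarray(p) + shift))
                    for s, z, p in self.classical_nuclei)
        return QuantumMolecule(nuc, self.quantum_protons + shift,
                               self.net_charge, self.multiplicity)

    def rotated(self, rot) -> "QuantumMolecule":
        rot = np.asarray(rot, float)
        nuc = tuple((s, z, tuple(rot @ np.asarray(p)))
                    for s, z, p in self.classical_nuclei)
        return QuantumMolecule(nuc, self.quantum_protons @ rot.T,
                               self.net_charge, self.multiplicity)


def parse_xyz(text: str, quantum_atom_indices=(), net_charge: int = 0,
              multiplicity: int = 1) -> QuantumMolecule:
    """Parse standard XYZ text (angstrom) into a :class:`QuantumMolecule`.

    ``quantum_atom_indices`` are 0-based indices into the atom list;
    each must refer to a hydrogen line, which becomes a quantum proton
    (its coordinates turn into the protonic basis center).
    """
    lines = [ln for ln in text.strip().splitlines()]
    if len(lines) < 2:
        raise XYZParseError("XYZ needs a count line and a comment line")
    try:
        natom = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZParseError(f"bad atom-count line: {lines[0]!r}") from exc
    body = lines[2:2 + natom]
    if len(body) != natom:
        raise XYZParseError(f"expected {natom} atom lines, got {len(body)}")
    qidx = set(int(i) for i in quantum_atom_indices)
    if qidx and (min(qidx) < 0 or max(qidx) >= natom):
        raise ValidationError("quantum atom index out of range")
    classical, protons = [], []
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZParseError(f"bad atom line: {ln!r}")
        sym = parts[0].capitalize()
        if sym not in ELEMENT_Z:
            raise XYZParseError(f"unknown element {parts[0]!r}")
        try:
            xyz = np.array([float(x) for x in parts[1:4]]) * ANGSTROM_TO_BOHR
        except ValueError as exc:
            raise XYZParseError(f"bad coordinates in line: {ln!r}") from exc
        if i in qidx:
            if sym != "H":
                raise ValidationError(
                    f"quantum atom index {i} refers to {sym}, not H")
            protons.append(xyz)
        else:
            classical.append((sym, ELEMENT_Z[sym], tuple(xyz)))
    return QuantumMolecule(tuple(classical),
                           np.array(protons) if protons else np.zeros((0, 3)),
                           net_charge, multiplicity)


def to_xyz(mol: QuantumMolecule, comment: str = "") -> str:
    """Serialize back to XYZ (angstrom); quantum protons are written as H
    after the classical atoms."""
    rows = []
    for s, _, p in mol.classical_nuclei:
        x, y, z = np.asarray(p) * BOHR_TO_ANGSTROM
        rows.append(f"{s:2s} {x:20.12f} {y:20.12f} {z:20.12f}")
    for q in mol.quantum_protons:
        x, y, z = q * BOHR_TO_ANGSTROM
        rows.append(f"H  {x:20.12f} {y:20.12f} {z:20.12f}")
    n = len(rows)
    return f"{n}\n{comment}\n" + "\n".join(rows) + "\n"


@dataclass(frozen=True)
class PADatasetEntry:
    label: str
    formula: str
    klass: str
    pa_exp_kcal: float

    def __post_init__(self):
        if self.pa_exp_kcal <= 0:
            raise ValidationError("experimental PA must be positive")


_DATASET_FILES = {"PA21": "pa23.csv", "PA23": "pa23.csv",
                  "test": "test_set.csv"}


def load_dataset(name: str) -> list[PADatasetEntry]:
    """Load a proton-affinity reference table.

    ``"PA21"`` returns the first 21 molecules of the PA23 set (the
    anions 22/CN- and 23/HS- are excluded: 22-23 would need rotational
    symmetry corrections); ``"PA23"`` returns all 23; ``"test"`` returns
    the 9-molecule biocatalysis-motivated test set.
    """
    if name not in _DATASET_FILES:
        raise KeyError(f"unknown dataset {name!r}; known: PA21, PA23, test")
    ref = importlib.resources.files("neodh.data") / _DATASET_FILES[name]
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"label": str})
    entries = [PADatasetEntry(r.label, r.formula, r.klass, float(r.pa_exp_kcal))
               for r in df.itertuples()]
    labels = [e.label for e in entries]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate labels in dataset")
    if name == "PA21":
        entries = entries[:21]
    return entries
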