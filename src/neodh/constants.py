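"""Physical constants and unit conversions.

All internal quantities are in Hartree atomic units (bohr, hartree,
electron mass).  kcal/mol, kJ/mol and angstrom appear only at I/O
boundaries; the conversion factors below are the single source of truth.
"""

# CODATA-2018 based conversions
HARTREE_TO_KCAL = 627.5094740631       # 1 Eh in kcal/mol
HARTREE_TO_KJ = 2625.4996394799        # 1 Eh in kJ/mol
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: proton mass in electron masses (CODATA 2018)
PROTON_MASS_AU = 1836.15267343

#: gas constant in kcal mol^-1 K^-1
R_GAS_KCAL = 1.987204259e-3

#: default thermochemistry temperature (K)
T_STANDARD = 298.15

# element symbol -> nuclear charge (extend as bases are added)
ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}
Z_ELEMENT = {z: s for s, z in ELEMENT_Z.items()}

# Bragg-Slater radii in angstrom, used for grid scaling and Becke
# partition size adjustment (H set to 0.35 A, Becke's choice)
BRAGG_ANGSTROM = {
    "H": 0.35, "He": 0.31, "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70,
    "N": 0.65, "O": 0.60, "F": 0.50, "Ne": 0.38, "Na": 1.80, "Mg": 1.50,
    "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00, "Cl": 1.00, "Ar": 0.71,
}


def bragg_radius_bohr(symbol: str) -> float:
    return BRAGG_ANGSTROM[symbol] * ANGSTROM_TO_BOHR
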