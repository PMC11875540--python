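"""Physical constants and unit conversions.

Internal units throughout the analytical engines: energies in kT, lengths in
units of the virtual peptide bond length ``b`` (default 3.8 Angstrom).
Conversions to molar / mg/ml happen only at module boundaries.
"""

from __future__ import annotations

import math

# CODATA-2018 values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
GAS_CONSTANT_CAL = 1.98720425864083  # cal / (mol K)
KCAL_PER_MOL_PER_KT = GAS_CONSTANT_CAL / 1000.0  # kcal/mol per kT per kelvin

BOND_LENGTH_A = 3.8  # virtual peptide bond length b, Angstrom

# residue masses (Da), i.e. amino acid minus one water
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153
PHOSPHO_MASS = 79.9799  # HPO3 added by phosphorylation


def bjerrum_length_A(T: float, epsilon_r: float) -> float:
    """Bjerrum length e^2/(4 pi eps0 eps_r kB T) in Angstrom."""
    if T <= 0 or epsilon_r <= 0:
        raise ValueError("temperature and permittivity must be positive")
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * epsilon_r * BOLTZMANN * T
    )
    return lb_m * 1e10


def molar_to_per_b3(c_molar: float, b_A: float = BOND_LENGTH_A) -> float:
    """Convert molar concentration to particles per b^3."""
    per_L = c_molar * AVOGADRO
    b3_L = (b_A * 1e-10) ** 3 * 1e3  # m^3 -> L
    return per_L * b3_L


def per_b3_to_molar(rho: float, b_A: float = BOND_LENGTH_A) -> float:
    b3_L = (b_A * 1e-10) ** 3 * 1e3
    return rho / (b3_L * AVOGADRO)
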