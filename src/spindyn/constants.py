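"""Physical constants and element tables used across the package.

Values are CODATA-2018 where applicable. Gyromagnetic ratios are in
rad s^-1 T^-1; the gas constant in J mol^-1 K^-1.
"""

import math

#: molar gas constant, J mol^-1 K^-1
R_GAS = 8.314462618

#: reduced Planck constant, J s
HBAR = 1.054571817e-34

#: mu_0 / 4 pi, T^2 m^3 J^-1
MU0_OVER_4PI = 1.0e-7

#: gyromagnetic ratio of 1H, rad s^-1 T^-1
GAMMA_H = 267.52218744e6

#: gyromagnetic ratio of 13C, rad s^-1 T^-1
GAMMA_C = 67.2828e6

#: default 13C Larmor frequency at 11.7 T, MHz
NU_C_DEFAULT_MHZ = 125.7

#: default 1H Larmor frequency consistent with NU_C via the gamma ratio, MHz
NU_H_DEFAULT_MHZ = NU_C_DEFAULT_MHZ * GAMMA_H / GAMMA_C

#: exact magic-angle cosine, the Lee-Goldburg scaling factor
MAGIC_COS = 1.0 / math.sqrt(3.0)

#: Bondi van der Waals radii, Angstrom
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

VDW_RADII_SETS = {"bondi": BONDI_RADII}

#: standard atomic weights, g mol^-1 (IUPAC 2021, abridged)
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
}

#: molar mass of simvastatin C25H38O5, g mol^-1
SIMVASTATIN_MOLAR_MASS = 25 * ATOMIC_MASSES["C"] + 38 * ATOMIC_MASSES["H"] + 5 * ATOMIC_MASSES["O"]


def molar_mass(formula: dict[str, int]) -> float:
    """Molar mass in g/mol from an element->count mapping."""
    try:
        return sum(ATOMIC_MASSES[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - trivial
        raise KeyError(f"no atomic mass tabulated for element {exc}") from None
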