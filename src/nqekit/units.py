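"""Unit system and physical constants.

Internal unit system: length in Å, mass in amu, time in fs, angles in
radians. The derived internal energy unit is amu·Å²·fs⁻² ; energies at all
public interfaces are kcal·mol⁻¹ and angles are degrees.

Constants are derived from CODATA 2018 values.
"""

from __future__ import annotations

# CODATA 2018
AVOGADRO = 6.02214076e23          # mol^-1 (exact)
BOLTZMANN_J = 1.380649e-23        # J/K (exact)
HBAR_JS = 1.054571817e-34         # J*s
AMU_KG = 1.66053906660e-27        # kg
CAL_J = 4.184                     # J per thermochemical calorie (exact)

# 1 kcal/mol in joules
_KCALMOL_J = 1000.0 * CAL_J / AVOGADRO

#: Boltzmann constant, kcal mol^-1 K^-1
KB = BOLTZMANN_J / _KCALMOL_J

#: hbar in (kcal/mol)*fs
HBAR = HBAR_JS / _KCALMOL_J * 1.0e15

#: 1 internal energy unit (amu Å² fs⁻²) in kcal/mol
INT_TO_KCAL = AMU_KG * 1.0e10 / _KCALMOL_J

#: 1 kcal/mol in internal energy units
KCAL_TO_INT = 1.0 / INT_TO_KCAL

#: Boltzmann constant in internal units (amu Å² fs⁻² K⁻¹)
KB_INT = KB * KCAL_TO_INT

#: hbar in internal units (amu Å² fs⁻¹)
HBAR_INT = HBAR * KCAL_TO_INT

#: Coulomb constant in kcal mol^-1 Å e^-2
COULOMB = 332.06371

#: conversion cm^-1 -> kcal/mol (E = h c nu~), for reporting vibrational scales
WAVENUMBER_TO_KCAL = 6.62607015e-34 * 2.99792458e10 / _KCALMOL_J

#: standard atomic masses, amu
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "He": 4.002602,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403,
    "Ne": 20.1797, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "X": 1.0,  # generic dummy particle
}

ATOMIC_NUMBERS = {
    "X": 0, "H": 1, "D": 1, "He": 2, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "S": 16, "Cl": 17, "Ar": 18,
}

NUMBERS_TO_SYMBOLS = {
    0: "X", 1: "H", 2: "He", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 16: "S", 17: "Cl", 18: "Ar",
}


def thermal_energy(T: float) -> float:
    """kB*T in kcal/mol.

    At room temperature (300 K) this is ~0.6 kcal/mol, the energy scale
    against which torsional barriers are judged.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return KB * T


def mass_of(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no tabulated mass for element {symbol!r}") from None
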