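"""Physical constants and per-element parameter tables.

All internal arithmetic is done in Hartree atomic units (Bohr, Hartree,
elementary charge).  File I/O and restraint specifications use Å and
kcal/mol, converted at the boundary.
"""

from __future__ import annotations

import math

# CODATA 2014 value, the convention of the fragment-method code lineage.
ANGSTROM_PER_BOHR = 0.52917721067
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

KCAL_PER_HARTREE = 627.509474
HARTREE_PER_KCAL = 1.0 / KCAL_PER_HARTREE

# Bondi van der Waals radii, Å.  Used for the unitless relative pair
# distance R_IJ = min_ab r_ab / (R_a + R_b) that drives the dimer cutoff.
VDW_RADII_ANGSTROM: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27,
    "Mg": 1.73,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "K": 2.75,
    "Ar": 1.88,
    "Br": 1.85,
    "I": 1.98,
}
VDW_DEFAULT_ANGSTROM = 1.70

KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Fe Zn Br I".split()
)

# Rigid reference water used by fixtures and by the mock-potential bond
# table: r(OH) = 0.9572 Å, HOH angle 104.52 deg (gas-phase experimental).
WATER_OH_ANGSTROM = 0.9572
WATER_HOH_DEGREES = 104.52
WATER_HH_ANGSTROM = 2.0 * WATER_OH_ANGSTROM * math.sin(
    math.radians(WATER_HOH_DEGREES) / 2.0
)


def vdw_radius(element: str) -> float:
    """Bondi radius in Å, with a generic fallback for unparametrized elements."""
    return VDW_RADII_ANGSTROM.get(element, VDW_DEFAULT_ANGSTROM)
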