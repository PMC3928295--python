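"""System geometry container and geometric observables.

Coordinates are stored in Bohr.  Constructors and accessors that talk to
the outside world (XYZ/PDB files, restraint targets, reaction coordinates)
work in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, KNOWN_ELEMENTS

#: Two atoms closer than this (Bohr) are considered unphysical overlap.
MIN_INTERATOMIC_BOHR = 0.1


class GeometryError(ValueError):
    """Raised when a geometry violates a structural invariant."""


@dataclass(frozen=True)
class SystemGeometry:
    """Elements and Cartesian coordinates of the full molecular system.

    The single mutable state of a calculation is a succession of these
    immutable snapshots: optimizers return new instances via
    :meth:`with_coords`.

    Parameters
    ----------
    elements
        Element symbols, one per atom.
    coords
        ``(n_atoms, 3)`` array in Bohr.
    """

    elements: tuple[str, ...]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (n, 3), got {coords.shape}")
        if len(self.elements) != coords.shape[0] or coords.shape[0] < 1:
            raise GeometryError(
                f"{len(self.elements)} element symbols for {coords.shape[0]} coordinates"
            )
        unknown = set(self.elements) - KNOWN_ELEMENTS
        if unknown:
            raise GeometryError(f"unknown element symbols: {sorted(unknown)}")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        if coords.shape[0] > 1:
            diff = coords[:, None, :] - coords[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, np.inf)
            dmin = dist.min()
            if dmin < MIN_INTERATOMIC_BOHR:
                i, j = np.unravel_index(np.argmin(dist), dist.shape)
                raise GeometryError(
                    f"atoms {i} and {j} are {dmin:.4f} Bohr apart (< {MIN_INTERATOMIC_BOHR})"
                )

    @property
    def atom_count(self) -> int:
        return len(self.elements)

    @classmethod
    def from_angstrom(cls, elements, coords_angstrom) -> "SystemGeometry":
        coords = np.asarray(coords_angstrom, dtype=float) * BOHR_PER_ANGSTROM
        return cls(tuple(elements), coords)

    def coords_angstrom(self) -> np.ndarray:
        return self.coords * ANGSTROM_PER_BOHR

    def with_coords(self, coords_bohr) -> "SystemGeometry":
        """New snapshot with the same elements and replaced coordinates (Bohr)."""
        return SystemGeometry(self.elements, np.array(coords_bohr, dtype=float))

    def distance(self, i: int, j: int) -> float:
        """Interatomic distance in Bohr."""
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def distance_angstrom(self, i: int, j: int) -> float:
        return self.distance(i, j) * ANGSTROM_PER_BOHR


def reaction_coordinate(
    geometry: SystemGeometry,
    breaking_pair: tuple[int, int],
    forming_pair: tuple[int, int],
) -> float:
    """Signed reaction coordinate R = r(breaking) − r(forming), in Å.

    The convention follows adiabatic mapping of bond-rearrangement
    reactions: R is negative on the reactant side (breaking bond still
    short), positive on the product side.
    """
    atoms = (*breaking_pair, *forming_pair)
    if len(set(atoms)) != 4:
        raise ValueError(f"reaction coordinate needs 4 distinct atoms, got {atoms}")
    n = geometry.atom_count
    if any(not (0 <= a < n) for a in atoms):
        raise IndexError(f"atom index out of range for {n}-atom system: {atoms}")
    return geometry.distance_angstrom(*breaking_pair) - geometry.distance_angstrom(
        *forming_pair
    )
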