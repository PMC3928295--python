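"""Fragmentation and frozen/polarizable/active domain partitioning.

A system is split into disjoint fragments (whole molecules or capped
residues; severed covalent bonds are not supported).  Fragments are then
grouped into three domains for frozen-domain-and-dimers (FDD) runs:

``F``  frozen — geometry and electronic records fixed after first evaluation;
``b``  polarizable buffer — frozen geometry, participates in polarization;
``A``  active — atoms optimized; contains the single high-level fragment H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SystemGeometry
from .constants import BOHR_PER_ANGSTROM, ANGSTROM_PER_BOHR


class PartitionError(ValueError):
    """Fragment groups overlap, leave gaps, or break a domain invariant."""


@dataclass(frozen=True)
class Fragment:
    """A set of atoms treated as one quantum-mechanical unit."""

    id: int
    atom_indices: tuple[int, ...]
    charge: int = 0
    multiplicity: int = 1
    basis_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices", tuple(self.atom_indices))
        if not self.atom_indices:
            raise PartitionError(f"fragment {self.id} has no atoms")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise PartitionError(f"fragment {self.id} repeats atom indices")
        if self.multiplicity != 1:
            raise PartitionError(
                "only closed-shell fragments (multiplicity 1) are supported"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass(frozen=True)
class FragmentSet:
    """Validated partition of all atoms into fragments."""

    fragments: tuple[Fragment, ...]
    n_atoms: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments", tuple(self.fragments))
        seen: set[int] = set()
        for frag in self.fragments:
            for a in frag.atom_indices:
                if not (0 <= a < self.n_atoms):
                    raise IndexError(
                        f"fragment {frag.id}: atom index {a} out of range [0, {self.n_atoms})"
                    )
                if a in seen:
                    raise PartitionError(
                        f"atom {a} belongs to more than one fragment"
                    )
                seen.add(a)
        if len(seen) != self.n_atoms:
            missing = sorted(set(range(self.n_atoms)) - seen)
            raise PartitionError(f"atoms not covered by any fragment: {missing[:10]}")

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def __getitem__(self, fragment_id: int) -> Fragment:
        for frag in self.fragments:
            if frag.id == fragment_id:
                return frag
        raise KeyError(f"no fragment with id {fragment_id}")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(f.id for f in self.fragments)

    def total_charge(self) -> int:
        return sum(f.charge for f in self.fragments)


@dataclass(frozen=True)
class DomainPartition:
    """FDD assignment of fragments to frozen (F), buffer (b), active (A)."""

    frozen: frozenset[int]
    polarizable: frozenset[int]
    active: frozenset[int]
    high_level: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "frozen", frozenset(self.frozen))
        object.__setattr__(self, "polarizable", frozenset(self.polarizable))
        object.__setattr__(self, "active", frozenset(self.active))
        if not self.active:
            raise PartitionError("active domain must be non-empty")
        for x, y in (
            (self.frozen, self.polarizable),
            (self.frozen, self.active),
            (self.polarizable, self.active),
        ):
            if x & y:
                raise PartitionError(f"domains overlap on fragments {sorted(x & y)}")
        if self.high_level not in self.active:
            raise PartitionError(
                f"high-level fragment {self.high_level} is not in the active domain"
            )

    @property
    def all_ids(self) -> frozenset[int]:
        return self.frozen | self.polarizable | self.active

    def domain_of(self, fragment_id: int) -> str:
        if fragment_id in self.active:
            return "A"
        if fragment_id in self.polarizable:
            return "b"
        if fragment_id in self.frozen:
            return "F"
        raise KeyError(f"fragment {fragment_id} not in any domain")

    def validate_against(self, fragments: FragmentSet) -> None:
        if self.all_ids != set(fragments.ids):
            raise PartitionError(
                "domain partition does not cover the fragment id set exactly"
            )

    def active_atoms(self, fragments: FragmentSet) -> tuple[int, ...]:
        out: list[int] = []
        for fid in sorted(self.active):
            out.extend(fragments[fid].atom_indices)
        return tuple(sorted(out))


def build_fragments(
    geometry: SystemGeometry,
    fragment_spec: list[tuple[list[int] | tuple[int, ...], int]],
    basis_label: str = "",
) -> FragmentSet:
    """Build a validated FragmentSet from (atom_indices, charge) groups.

    Groups must exactly partition ``range(geometry.atom_count)``; overlaps
    and gaps raise :class:`PartitionError`.
    """
    frags = [
        Fragment(
            id=i,
            atom_indices=tuple(atoms),
            charge=int(charge),
            basis_label=basis_label,
        )
        for i, (atoms, charge) in enumerate(fragment_spec)
    ]
    return FragmentSet(tuple(frags), geometry.atom_count)


def min_fragment_distance_angstrom(
    geometry: SystemGeometry, frag_a: Fragment, frag_b: Fragment
) -> float:
    """Minimum interatomic distance between two fragments, Å."""
    ca = geometry.coords[list(frag_a.atom_indices)]
    cb = geometry.coords[list(frag_b.atom_indices)]
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    return float(d.min()) * ANGSTROM_PER_BOHR


def assign_domains(
    fragments: FragmentSet,
    geometry: SystemGeometry,
    center_fragment: int,
    active_radius: float,
    buffer_radius: float,
) -> DomainPartition:
    """Distance-based domain assignment around a center fragment.

    A fragment joins the active domain A when any of its atoms lies within
    ``active_radius`` Å of any atom of the center fragment (all atoms are
    considered, not only heavy atoms).  The polarizable buffer b then
    collects the remaining fragments within ``buffer_radius`` of *any
    active fragment* — the buffer surrounds the active layer, not just its
    center.  Everything else is frozen.  The center fragment itself
    becomes the high-level fragment H.
    """
    if not (buffer_radius >= active_radius >= 0.0):
        raise ValueError(
            f"need buffer_radius >= active_radius >= 0, got {buffer_radius} < {active_radius}"
        )
    center = fragments[center_fragment]
    active, buffer_, frozen = {center_fragment}, set(), set()
    for frag in fragments:
        if frag.id == center_fragment:
            continue
        if min_fragment_distance_angstrom(geometry, center, frag) <= active_radius:
            active.add(frag.id)
    for frag in fragments:
        if frag.id in active:
            continue
        d = min(
            min_fragment_distance_angstrom(geometry, fragments[a], frag)
            for a in active
        )
        if d <= buffer_radius:
            buffer_.add(frag.id)
        else:
            frozen.add(frag.id)
    return DomainPartition(
        frozen=frozenset(frozen),
        polarizable=frozenset(buffer_),
        active=frozenset(active),
        high_level=center_fragment,
    )
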