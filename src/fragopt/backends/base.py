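"""Backend contract: record types, cache keys, and the plug-in registry."""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np

from ..fragments import Fragment
from ..geometry import SystemGeometry

CHARGE_SUM_TOL = 1e-6


class Level(str, Enum):
    RHF = "RHF"
    MP2 = "MP2"


class BackendError(RuntimeError):
    """Engine failure, carrying the fragment/pair identity it occurred on."""

    def __init__(self, message: str, fragment_ids: tuple[int, ...] = (), level: str = ""):
        super().__init__(message)
        self.fragment_ids = fragment_ids
        self.level = level


def geometry_key(
    geometry: SystemGeometry,
    atom_indices: tuple[int, ...],
    level: str,
    basis_label: str,
) -> str:
    """Content hash of (coordinates rounded to 1e-10 Bohr, level, basis).

    This key defines frozen-domain reuse: a cached record is valid exactly
    when the atoms it was computed for have not moved.
    """
    coords = geometry.coords[list(atom_indices)]
    rounded = np.round(coords, 10)
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(rounded).tobytes())
    h.update(repr(atom_indices).encode())
    h.update(level.encode())
    h.update(basis_label.encode())
    return h.hexdigest()


@dataclass(frozen=True)
class FragmentRecord:
    """Cached result of one monomer calculation.

    ``energy`` is the total energy at the requested level; for MP2 records
    ``correlation_energy`` holds the (non-positive) correlation part and
    ``correlation_gradient`` its nuclear gradient on the fragment's atoms.
    """

    fragment_id: int
    level: Level
    basis_label: str
    energy: float
    correlation_energy: float
    gradient: np.ndarray = field(repr=False)
    correlation_gradient: np.ndarray | None = field(repr=False)
    charges: np.ndarray = field(repr=False)
    polarizabilities: np.ndarray = field(repr=False)
    geometry_key: str

    def validate(self, fragment: Fragment) -> None:
        n = fragment.n_atoms
        if self.gradient.shape != (n, 3):
            raise BackendError(
                f"gradient shape {self.gradient.shape} for {n}-atom fragment",
                (self.fragment_id,),
            )
        if abs(float(self.charges.sum()) - fragment.charge) > CHARGE_SUM_TOL:
            raise BackendError(
                f"charges sum to {self.charges.sum():.8f}, expected {fragment.charge}",
                (self.fragment_id,),
            )
        if self.level == Level.MP2 and self.correlation_energy > 0.0:
            raise BackendError(
                f"positive MP2 correlation energy {self.correlation_energy}",
                (self.fragment_id,),
                level="MP2",
            )


@dataclass(frozen=True)
class DimerRecord:
    """Cached QM pair interaction: ΔE_IJ = E_IJ − E⁰_I − E⁰_J and its gradient.

    ``gradient_I``/``gradient_J`` are the interaction-gradient contributions
    on the atoms of each member, ordered as in the fragment definitions.
    """

    pair: tuple[int, int]
    interaction_energy: float
    gradient_I: np.ndarray = field(repr=False)
    gradient_J: np.ndarray = field(repr=False)
    geometry_key: str


class Backend(ABC):
    """Contract every electronic-structure engine adapter must satisfy."""

    name: str = "abstract"

    @abstractmethod
    def compute_monomer(
        self,
        geometry: SystemGeometry,
        fragment: Fragment,
        level: Level,
        basis_label: str,
    ) -> FragmentRecord:
        """Gas-phase (unembedded) energy, gradient, charges, polarizabilities."""

    @abstractmethod
    def compute_dimer(
        self,
        geometry: SystemGeometry,
        frag_i: Fragment,
        frag_j: Fragment,
        level: Level,
        basis_labels: tuple[str, str],
    ) -> DimerRecord:
        """Pair interaction energy and gradient contributions."""


_REGISTRY: dict[str, Callable[[], Backend]] = {}


def register_backend(name: str, factory: Callable[[], Backend]) -> None:
    _REGISTRY[name] = factory


def get_backend(name: str) -> Backend:
    if name == "pyscf" and name not in _REGISTRY:
        from . import pyscf_adapter  # noqa: F401  (self-registers)
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise BackendError(
            f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory()
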