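"""Deterministic closed-form mock electronic-structure backend.

The mock potential plays the role of an SCF/MP2 engine in tests and in
desk-scale demonstrations.  Its functional form is chosen so that the
framework's structural claims can be checked exactly:

* intra-fragment: harmonic terms on every atom pair (per-element-pair
  reference lengths and force constants), plus optional *coordinate terms*
  — 1-D potentials on linear combinations of interatomic distances, used
  by the toy-reaction fixture to embed a double well along a reaction
  coordinate;
* inter-fragment: Lennard-Jones plus Coulomb over fixed per-element
  charges.  Being strictly pairwise in the atoms, the inter-fragment part
  makes the two-body fragment expansion *exact*, which is what the
  supersystem oracle exploits;
* mock "MP2 correlation": an intra-fragment −C₆/r⁶ sum scaled by a
  per-basis factor — smooth, strictly negative, and basis-dependent like
  the real thing.

Energies are Hartree, lengths Bohr throughout.  All parameters are plain
data on :class:`MockParams`, so a hand evaluation of the documented
formulas is always possible as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..constants import BOHR_PER_ANGSTROM, WATER_HH_ANGSTROM, WATER_OH_ANGSTROM, vdw_radius
from ..fragments import Fragment, FragmentSet
from ..geometry import SystemGeometry
from .base import Backend, DimerRecord, FragmentRecord, Level, geometry_key

# --------------------------------------------------------------------------
# parameter tables (atomic units unless noted)

_ELEMENT_CHARGE = {"O": -0.66, "H": 0.33, "C": 0.22, "N": -0.45, "S": -0.20}
_ELEMENT_ALPHA = {"H": 1.5, "C": 6.0, "N": 4.5, "O": 3.5, "S": 9.0}  # Bohr^3
_ELEMENT_LJ_EPS = {"H": 2.0e-4, "C": 4.0e-4, "N": 4.5e-4, "O": 5.0e-4}  # Hartree
# Dispersion-like coefficients for the mock correlation term, Hartree·Bohr^6.
# Kept small so that every bonded pair remains a stable minimum of the
# harmonic + correlation sum: stability needs 42·C6_ab/r0^8 < k_ab, and the
# values below satisfy that with an order of magnitude to spare.
DEFAULT_C6 = {"H": 0.06, "C": 0.40, "N": 0.30, "O": 0.24}
_ELEMENT_C6 = DEFAULT_C6

# (force constant Hartree/Bohr^2, reference length Bohr); key = sorted pair.
# The O-H / H-H entries reproduce the rigid reference water exactly, so a
# fixture water sits at the mock minimum.
_BOND_TABLE = {
    ("H", "O"): (0.50, WATER_OH_ANGSTROM * BOHR_PER_ANGSTROM),
    ("H", "H"): (0.10, WATER_HH_ANGSTROM * BOHR_PER_ANGSTROM),
    ("C", "C"): (0.40, 2.91),
    ("C", "O"): (0.45, 2.69),
    ("C", "H"): (0.35, 2.06),
    ("C", "N"): (0.42, 2.78),
    ("H", "N"): (0.48, 1.92),
}
_BOND_DEFAULT = (0.25, 2.80)

_BASIS_SCALE = {"6-31G(d)": 1.0, "cc-pVDZ": 1.1, "cc-pVTZ": 1.2, "STO-3G": 0.8}


@dataclass(frozen=True)
class CoordinateTerm:
    """1-D potential on q = Σ c_k · r(i_k, j_k) over intra-fragment pairs.

    kind "harmonic": V = ½ k (q − q0)²            params = (k, q0)
    kind "quartic":  V = a((q − q0)² − b²)² + c(q − q0)   params = (a, b, q0, c)

    The quartic form is a tilted double well with minima near q0 ± b and a
    barrier near q0; the tilt c makes the reaction exothermic.
    """

    pairs: tuple[tuple[int, int, float], ...]
    kind: str
    params: tuple[float, ...]

    def value_and_derivative(self, q: float) -> tuple[float, float]:
        if self.kind == "harmonic":
            k, q0 = self.params
            d = q - q0
            return 0.5 * k * d * d, k * d
        if self.kind == "quartic":
            a, b, q0, c = self.params
            d = q - q0
            w = d * d - b * b
            return a * w * w + c * d, 4.0 * a * w * d + c
        raise ValueError(f"unknown coordinate-term kind {self.kind!r}")

    @property
    def atoms(self) -> frozenset[int]:
        return frozenset(a for i, j, _ in self.pairs for a in (i, j))


@dataclass(frozen=True)
class MockParams:
    """All numbers defining the mock potential, overridable per instance."""

    element_charge: dict = field(default_factory=lambda: dict(_ELEMENT_CHARGE))
    element_alpha: dict = field(default_factory=lambda: dict(_ELEMENT_ALPHA))
    element_lj_eps: dict = field(default_factory=lambda: dict(_ELEMENT_LJ_EPS))
    element_c6: dict = field(default_factory=lambda: dict(_ELEMENT_C6))
    bond_table: dict = field(default_factory=lambda: dict(_BOND_TABLE))
    bond_default: tuple[float, float] = _BOND_DEFAULT
    basis_scale: dict = field(default_factory=lambda: dict(_BASIS_SCALE))
    lj_sigma_scale: float = 0.85  # sigma_ab = scale · (RvdW_a + RvdW_b)
    correlation_enabled: bool = True
    #: atoms whose intra-fragment pairs skip the default harmonic terms
    #: (their physics is supplied via coordinate_terms instead)
    harmonic_exclude_atoms: frozenset[int] = frozenset()
    coordinate_terms: tuple[CoordinateTerm, ...] = ()

    def charge(self, element: str) -> float:
        return self.element_charge.get(element, 0.0)

    def alpha(self, element: str) -> float:
        return self.element_alpha.get(element, 3.0)

    def lj_eps(self, element: str) -> float:
        return self.element_lj_eps.get(element, 3.0e-4)

    def c6(self, element: str) -> float:
        return self.element_c6.get(element, 0.3)

    def bond(self, el_a: str, el_b: str) -> tuple[float, float]:
        return self.bond_table.get(tuple(sorted((el_a, el_b))), self.bond_default)

    def scale_for_basis(self, basis_label: str) -> float:
        return self.basis_scale.get(basis_label, 1.0)


class MockBackend(Backend):
    """Closed-form potential satisfying the full backend contract."""

    name = "mock"

    def __init__(self, params: MockParams | None = None):
        self.params = params if params is not None else MockParams()

    # -- contract ----------------------------------------------------------

    def compute_monomer(
        self,
        geometry: SystemGeometry,
        fragment: Fragment,
        level: Level,
        basis_label: str,
    ) -> FragmentRecord:
        atoms = fragment.atom_indices
        e_rhf, g_rhf = self._intra_rhf(geometry, atoms)
        e_corr, g_corr = 0.0, np.zeros((len(atoms), 3))
        if level == Level.MP2:
            e_corr, g_corr = self._intra_correlation(geometry, atoms, basis_label)
        energy = e_rhf + e_corr
        gradient = g_rhf + g_corr
        return FragmentRecord(
            fragment_id=fragment.id,
            level=level,
            basis_label=basis_label,
            energy=energy,
            correlation_energy=e_corr,
            gradient=gradient,
            correlation_gradient=g_corr if level == Level.MP2 else None,
            charges=self.fragment_charges(geometry, fragment),
            polarizabilities=np.array(
                [self.params.alpha(geometry.elements[a]) for a in atoms]
            ),
            geometry_key=geometry_key(geometry, atoms, level.value, basis_label),
        )

    def compute_dimer(
        self,
        geometry: SystemGeometry,
        frag_i: Fragment,
        frag_j: Fragment,
        level: Level,
        basis_labels: tuple[str, str],
    ) -> DimerRecord:
        if frag_i.id == frag_j.id:
            raise ValueError("dimer requires two distinct fragments")
        # canonical orientation: record(I,J) ≡ record(J,I)
        if frag_i.id > frag_j.id:
            frag_i, frag_j = frag_j, frag_i
            basis_labels = (basis_labels[1], basis_labels[0])
        # The mock supersystem energy of a dimer is intra(I)+intra(J)+inter,
        # so ΔE_IJ = E_IJ − E⁰_I − E⁰_J reduces to the inter-fragment terms,
        # evaluated here directly.  The interaction carries no correlation
        # part: the hybrid correction is monomer-only by construction.
        e, g_i, g_j = self._inter(geometry, frag_i, frag_j)
        atoms = frag_i.atom_indices + frag_j.atom_indices
        key = geometry_key(
            geometry, atoms, level.value, "|".join(basis_labels)
        )
        return DimerRecord(
            pair=(frag_i.id, frag_j.id),
            interaction_energy=e,
            gradient_I=g_i,
            gradient_J=g_j,
            geometry_key=key,
        )

    # -- documented closed forms -------------------------------------------

    def fragment_charges(
        self, geometry: SystemGeometry, fragment: Fragment
    ) -> np.ndarray:
        """Per-element charges, shifted uniformly to sum to the net charge."""
        q = np.array(
            [self.params.charge(geometry.elements[a]) for a in fragment.atom_indices]
        )
        q += (fragment.charge - q.sum()) / len(q)
        return q

    def _intra_rhf(
        self, geometry: SystemGeometry, atoms: tuple[int, ...]
    ) -> tuple[float, np.ndarray]:
        p = self.params
        coords = geometry.coords
        energy = 0.0
        grad = np.zeros((len(atoms), 3))
        pos = {a: k for k, a in enumerate(atoms)}
        for ii in range(len(atoms)):
            for jj in range(ii + 1, len(atoms)):
                a, b = atoms[ii], atoms[jj]
                if a in p.harmonic_exclude_atoms and b in p.harmonic_exclude_atoms:
                    continue
                k_f, r0 = p.bond(geometry.elements[a], geometry.elements[b])
                d = coords[a] - coords[b]
                r = float(np.linalg.norm(d))
                energy += 0.5 * k_f * (r - r0) ** 2
                dedr = k_f * (r - r0)
                u = d / r
                grad[ii] += dedr * u
                grad[jj] -= dedr * u
        atom_set = frozenset(atoms)
        for term in p.coordinate_terms:
            if not term.atoms <= atom_set:
                continue
            q = 0.0
            for i, j, coef in term.pairs:
                q += coef * float(np.linalg.norm(coords[i] - coords[j]))
            v, dvdq = term.value_and_derivative(q)
            energy += v
            for i, j, coef in term.pairs:
                d = coords[i] - coords[j]
                u = d / float(np.linalg.norm(d))
                grad[pos[i]] += dvdq * coef * u
                grad[pos[j]] -= dvdq * coef * u
        return energy, grad

    def _intra_correlation(
        self, geometry: SystemGeometry, atoms: tuple[int, ...], basis_label: str
    ) -> tuple[float, np.ndarray]:
        p = self.params
        if not p.correlation_enabled:
            return 0.0, np.zeros((len(atoms), 3))
        scale = p.scale_for_basis(basis_label)
        coords = geometry.coords
        energy = 0.0
        grad = np.zeros((len(atoms), 3))
        for ii in range(len(atoms)):
            for jj in range(ii + 1, len(atoms)):
                a, b = atoms[ii], atoms[jj]
                c6 = scale * np.sqrt(
                    p.c6(geometry.elements[a]) * p.c6(geometry.elements[b])
                )
                d = coords[a] - coords[b]
                r = float(np.linalg.norm(d))
                energy -= c6 / r**6
                dedr = 6.0 * c6 / r**7
                u = d / r
                grad[ii] += dedr * u
                grad[jj] -= dedr * u
        return energy, grad

    def _inter(
        self, geometry: SystemGeometry, frag_i: Fragment, frag_j: Fragment
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """LJ + Coulomb between two fragments' atoms; strictly pairwise."""
        p = self.params
        coords = geometry.coords
        q_i = self.fragment_charges(geometry, frag_i)
        q_j = self.fragment_charges(geometry, frag_j)
        energy = 0.0
        g_i = np.zeros((frag_i.n_atoms, 3))
        g_j = np.zeros((frag_j.n_atoms, 3))
        for ii, a in enumerate(frag_i.atom_indices):
            el_a = geometry.elements[a]
            for jj, b in enumerate(frag_j.atom_indices):
                el_b = geometry.elements[b]
                d = coords[a] - coords[b]
                r = float(np.linalg.norm(d))
                qq = q_i[ii] * q_j[jj]
                eps = np.sqrt(p.lj_eps(el_a) * p.lj_eps(el_b))
                sigma = p.lj_sigma_scale * (vdw_radius(el_a) + vdw_radius(el_b)) * BOHR_PER_ANGSTROM
                s6 = (sigma / r) ** 6
                energy += qq / r + 4.0 * eps * (s6 * s6 - s6)
                dedr = -qq / r**2 + 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
                u = d / r
                g_i[ii] += dedr * u
                g_j[jj] -= dedr * u
        return energy, g_i, g_j

    def supersystem_energy(
        self,
        geometry: SystemGeometry,
        fragments: FragmentSet,
        level: Level = Level.RHF,
        basis_label: str = "",
    ) -> float:
        """Direct whole-system evaluation, the exactness oracle.

        Sums every intra-fragment term and every inter-fragment atom pair
        in one pass, independently of the monomer/dimer assembly.
        """
        total = 0.0
        frags = list(fragments)
        for frag in frags:
            e, _ = self._intra_rhf(geometry, frag.atom_indices)
            total += e
            if level == Level.MP2:
                ec, _ = self._intra_correlation(geometry, frag.atom_indices, basis_label)
                total += ec
        for i in range(len(frags)):
            for j in range(i + 1, len(frags)):
                e, _, _ = self._inter(geometry, frags[i], frags[j])
                total += e
        return total

    def with_correlation_disabled(self) -> "MockBackend":
        return MockBackend(replace(self.params, correlation_enabled=False))


from .base import register_backend  # noqa: E402

register_backend("mock", MockBackend)
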