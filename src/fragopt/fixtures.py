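"""Deterministic synthetic systems for tests and demonstrations.

Three families:

* rigid water chains/clusters (one fragment per molecule), optionally with
  seeded random perturbations — the workhorse for energy/gradient checks;
* a four-atom "substrate" whose mock potential embeds a tilted double well
  along the difference of a breaking and a forming bond length, with
  spectator waters in the buffer and frozen domains — a desk-scale
  stand-in for an enzyme-catalysed bond rearrangement, with a fully
  analytic 1-D reference for the scan oracle.

All randomness flows through one documented 64-bit generator seeded in
the fixture spec; identical specs give bitwise identical geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .backends.mock import DEFAULT_C6, CoordinateTerm, MockBackend, MockParams
from .config import RunConfig
from .constants import (
    ANGSTROM_PER_BOHR,
    BOHR_PER_ANGSTROM,
    HARTREE_PER_KCAL,
    KCAL_PER_HARTREE,
    WATER_HOH_DEGREES,
    WATER_OH_ANGSTROM,
)
from .fragments import DomainPartition, FragmentSet, build_fragments
from .geometry import SystemGeometry


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # water_chain | water_cluster | toy_reaction
    n_fragments: int = 3
    spacing: float = 3.0  # Å
    seed: int = 0
    perturbation_amplitude: float = 0.0  # Å

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise ValueError("need at least one fragment")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def _water_template_angstrom() -> np.ndarray:
    """O at the origin, H's symmetric about +y: the rigid reference water."""
    r = WATER_OH_ANGSTROM
    half = math.radians(WATER_HOH_DEGREES) / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [r * math.sin(half), r * math.cos(half), 0.0],
            [-r * math.sin(half), r * math.cos(half), 0.0],
        ]
    )


def make_water_chain(
    n: int, spacing: float = 3.0, seed: int = 0, perturbation: float = 0.0
) -> tuple[SystemGeometry, FragmentSet]:
    """n rigid waters along x, O–O distance = ``spacing`` Å, one fragment each."""
    if n < 1:
        raise ValueError("need at least one water")
    template = _water_template_angstrom()
    coords = np.vstack([template + np.array([i * spacing, 0.0, 0.0]) for i in range(n)])
    rng = np.random.default_rng(seed)
    if perturbation > 0:
        coords = coords + rng.uniform(-perturbation, perturbation, size=coords.shape)
    elements = ["O", "H", "H"] * n
    geometry = SystemGeometry.from_angstrom(elements, coords)
    fragments = build_fragments(
        geometry, [(list(range(3 * i, 3 * i + 3)), 0) for i in range(n)]
    )
    return geometry, fragments


def make_water_cluster(
    n: int, spacing: float = 3.0, seed: int = 0, perturbation: float = 0.0
) -> tuple[SystemGeometry, FragmentSet]:
    """n rigid waters on a cubic grid of pitch ``spacing`` Å."""
    if n < 1:
        raise ValueError("need at least one water")
    side = math.ceil(n ** (1.0 / 3.0))
    template = _water_template_angstrom()
    offsets = []
    for i in range(n):
        ix, rem = divmod(i, side * side)
        iy, iz = divmod(rem, side)
        offsets.append(np.array([ix, iy, iz], dtype=float) * spacing)
    coords = np.vstack([template + off for off in offsets])
    rng = np.random.default_rng(seed)
    if perturbation > 0:
        coords = coords + rng.uniform(-perturbation, perturbation, size=coords.shape)
    elements = ["O", "H", "H"] * n
    geometry = SystemGeometry.from_angstrom(elements, coords)
    fragments = build_fragments(
        geometry, [(list(range(3 * i, 3 * i + 3)), 0) for i in range(n)]
    )
    return geometry, fragments


# --------------------------------------------------------------------------
# toy reaction


# Substrate potential, atomic units.  q1 = r1 + r2 is held near S by a stiff
# harmonic; the reaction lives in q2 = r1 − r2 as a tilted quartic double
# well; three auxiliary difference coordinates keep the chain straight and
# vanish identically on the collinear path, so the substrate energy along
# the scan is an exactly known 1-D function.
_TOY_S = 7.0  # Bohr, r1 + r2 on the path
_TOY_SCAFFOLD = 2.8  # Bohr, central C–C bond
_TOY_K_SUM = 1.0  # Hartree/Bohr^2
_TOY_K_STRAIGHT = 0.3
_TOY_K_SCAFFOLD = 0.5
_TOY_A = 0.016  # quartic prefactor, Hartree/Bohr^4
_TOY_B = 1.2  # well half-separation, Bohr
_TOY_TILT = -0.002  # Hartree/Bohr, makes the reaction exothermic
# The toy uses the backend's default mock-correlation C6 table; the values
# are small enough that the correlated substrate stays effectively on the
# 1-D path (induced relaxations far below the scan oracle's tolerance).
_TOY_C6 = dict(DEFAULT_C6)
# The substrate elements (N, C) carry no mock charge, polarizability or
# LJ well in the toy: the substrate is electrostatically inert, so the
# spectator waters exert no force on it and its energy along the scan is
# exactly the documented 1-D function.  (A real enzyme anchors its
# substrate through many contacts; a 4-atom toy has no such scaffold, so
# decoupling is the honest way to keep an analytic reference.)
_TOY_CHARGE = {"O": -0.66, "H": 0.33, "C": 0.0, "N": 0.0}
_TOY_ALPHA = {"O": 3.5, "H": 1.5, "C": 0.0, "N": 0.0}
_TOY_LJ_EPS = {"O": 5.0e-4, "H": 2.0e-4, "C": 0.0, "N": 0.0}


@dataclass(frozen=True)
class ToyReference:
    """Analytic 1-D reference of the toy reaction.

    ``barrier``/``reaction_energy`` come from a fine grid over the path
    energy E(R); the ``restrained_*`` values are the corresponding
    quantities predicted for a scan with harmonic restraints of effective
    stiffness k_R = k_r/2 along R — the documented restraint-stiffness
    bias is their difference.  ``bias_bound_kcal`` adds a fixed 0.3
    kcal/mol allowance for the (far) spectator fragments and residual
    off-path relaxation.
    """

    barrier: float  # Hartree
    reaction_energy: float  # Hartree
    ts_coordinate_bohr: float
    reactant_coordinate_bohr: float
    product_coordinate_bohr: float
    restrained_barrier: float  # Hartree
    restrained_reaction_energy: float  # Hartree
    bias_bound_kcal: float
    grid_r: np.ndarray = field(repr=False, default=None)
    grid_e: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class ToyReaction:
    geometry: SystemGeometry
    fragments: FragmentSet
    partition: DomainPartition
    backend: MockBackend
    config: RunConfig
    breaking_pair: tuple[int, int]
    forming_pair: tuple[int, int]
    scan_targets: tuple[tuple[float, float], ...]  # Å
    reference: ToyReference


def _toy_path_energy(r_values: np.ndarray, mp2_scale: float) -> np.ndarray:
    """Substrate energy along the collinear path, Hartree.

    On the path r1 = (S+R)/2, r2 = (S−R)/2, all harmonic terms vanish and
    the energy is the tilted quartic plus the (scaled) −C6/r⁶ correlation
    over the six substrate pairs, whose distances are functions of R only.
    """
    r = np.asarray(r_values, dtype=float)
    w = _TOY_A * (r**2 - _TOY_B**2) ** 2 + _TOY_TILT * r
    r1 = (_TOY_S + r) / 2.0
    r2 = (_TOY_S - r) / 2.0
    c_nc = math.sqrt(_TOY_C6["N"] * _TOY_C6["C"])
    c_cc = _TOY_C6["C"]
    pair_dists_c6 = [
        (r1, c_nc),                      # N—C1 (breaking)
        (r2, c_cc),                      # C3—C4 (forming)
        (np.full_like(r, _TOY_SCAFFOLD), c_cc),  # C1—C3
        (r1 + _TOY_SCAFFOLD, c_nc),      # N—C3
        (r2 + _TOY_SCAFFOLD, c_cc),      # C1—C4
        (np.full_like(r, _TOY_S + _TOY_SCAFFOLD), c_nc),  # N—C4
    ]
    corr = np.zeros_like(r)
    for dist, c6 in pair_dists_c6:
        corr -= mp2_scale * c6 / dist**6
    return w + corr


def _toy_reference(
    scan_r_bohr: np.ndarray, k_restraint_kcal: float, mp2_scale: float
) -> ToyReference:
    grid = np.linspace(-1.8, 1.8, 14401)
    energy = _toy_path_energy(grid, mp2_scale)
    mid = len(grid) // 2
    i_react = int(np.argmin(energy[:mid]))
    i_prod = mid + int(np.argmin(energy[mid:]))
    i_ts = i_react + int(np.argmax(energy[i_react:i_prod]))
    barrier = float(energy[i_ts] - energy[i_react])
    reaction = float(energy[i_prod] - energy[i_react])

    # restrained-scan prediction: each target samples the minimum of
    # E(R) + ½ k_R (R − R_t)², k_R = k_r / 2
    k_r_au = k_restraint_kcal * HARTREE_PER_KCAL * ANGSTROM_PER_BOHR**2
    k_eff = k_r_au / 2.0
    sampled = []
    for rt in scan_r_bohr:
        total = energy + 0.5 * k_eff * (grid - rt) ** 2
        sampled.append(float(energy[int(np.argmin(total))]))
    sampled = np.array(sampled)
    restrained_barrier = float(sampled.max() - sampled[0])
    restrained_reaction = float(sampled[-1] - sampled[0])
    bias = abs(restrained_barrier - barrier) + abs(restrained_reaction - reaction)
    return ToyReference(
        barrier=barrier,
        reaction_energy=reaction,
        ts_coordinate_bohr=float(grid[i_ts]),
        reactant_coordinate_bohr=float(grid[i_react]),
        product_coordinate_bohr=float(grid[i_prod]),
        restrained_barrier=restrained_barrier,
        restrained_reaction_energy=restrained_reaction,
        bias_bound_kcal=bias * KCAL_PER_HARTREE + 0.3,
        grid_r=grid,
        grid_e=energy,
    )


def make_toy_reaction(seed: int = 0, n_scan: int = 21) -> ToyReaction:
    """Four-atom double-well substrate with two spectator waters (b and F).

    Substrate atoms (fragment 0, the high-level fragment): N(0)—C(1)—C(2)—C(3)
    collinear along x; the breaking bond is N–C(1), the forming bond C(3)–C(2).
    One water sits 12 Å above the substrate (buffer domain), another 16 Å
    above (frozen domain).
    """
    r_react = -_TOY_B  # start in the reactant well
    r1 = (_TOY_S + r_react) / 2.0
    r2 = (_TOY_S - r_react) / 2.0
    x_c1 = r1
    x_c3 = r1 + _TOY_SCAFFOLD
    x_c4 = r1 + _TOY_SCAFFOLD + r2
    substrate_bohr = np.array(
        [
            [0.0, 0.0, 0.0],
            [x_c1, 0.0, 0.0],
            [x_c3, 0.0, 0.0],
            [x_c4, 0.0, 0.0],
        ]
    )
    template = _water_template_angstrom() * BOHR_PER_ANGSTROM
    x_mid = 0.5 * x_c4
    water_b = template + np.array([x_mid, 12.0 * BOHR_PER_ANGSTROM, 0.0])
    water_f = template + np.array([x_mid, 16.0 * BOHR_PER_ANGSTROM, 0.0])
    coords = np.vstack([substrate_bohr, water_b, water_f])
    elements = ["N", "C", "C", "C", "O", "H", "H", "O", "H", "H"]
    geometry = SystemGeometry(tuple(elements), coords)
    fragments = build_fragments(
        geometry, [([0, 1, 2, 3], 0), ([4, 5, 6], 0), ([7, 8, 9], 0)]
    )
    partition = DomainPartition(
        frozen=frozenset({2}),
        polarizable=frozenset({1}),
        active=frozenset({0}),
        high_level=0,
    )
    terms = (
        CoordinateTerm(((0, 1, 1.0), (3, 2, 1.0)), "harmonic", (_TOY_K_SUM, _TOY_S)),
        CoordinateTerm(
            ((0, 1, 1.0), (3, 2, -1.0)),
            "quartic",
            (_TOY_A, _TOY_B, 0.0, _TOY_TILT),
        ),
        CoordinateTerm(((1, 2, 1.0),), "harmonic", (_TOY_K_SCAFFOLD, _TOY_SCAFFOLD)),
        # straightness terms, identically zero on the collinear path
        CoordinateTerm(
            ((0, 2, 1.0), (0, 1, -1.0)), "harmonic", (_TOY_K_STRAIGHT, _TOY_SCAFFOLD)
        ),
        CoordinateTerm(
            ((1, 3, 1.0), (2, 3, -1.0)), "harmonic", (_TOY_K_STRAIGHT, _TOY_SCAFFOLD)
        ),
        CoordinateTerm(
            ((0, 3, 1.0), (0, 1, -1.0), (2, 3, -1.0)),
            "harmonic",
            (_TOY_K_STRAIGHT, _TOY_SCAFFOLD),
        ),
    )
    params = MockParams(
        element_charge=dict(_TOY_CHARGE),
        element_alpha=dict(_TOY_ALPHA),
        element_lj_eps=dict(_TOY_LJ_EPS),
        element_c6=dict(_TOY_C6),
        harmonic_exclude_atoms=frozenset({0, 1, 2, 3}),
        coordinate_terms=terms,
    )
    backend = MockBackend(params)
    config = RunConfig(
        backend="mock",
        mp2_basis="cc-pVDZ",
        hybrid_mp2=True,
        dimer_cutoff=1.5,
        polarization_enabled=True,
        fdd_enabled=True,
        gradient_tolerance=1.0e-5,
        max_opt_steps=300,
        restraint_force_constant=500.0,
        random_seed=seed,
    )
    scan_r = np.linspace(-1.4, 1.4, n_scan)
    targets = tuple(
        (
            float((_TOY_S + r) / 2.0 * ANGSTROM_PER_BOHR),
            float((_TOY_S - r) / 2.0 * ANGSTROM_PER_BOHR),
        )
        for r in scan_r
    )
    mp2_scale = params.scale_for_basis(config.mp2_basis)
    reference = _toy_reference(scan_r, config.restraint_force_constant, mp2_scale)
    return ToyReaction(
        geometry=geometry,
        fragments=fragments,
        partition=partition,
        backend=backend,
        config=config,
        breaking_pair=(0, 1),
        forming_pair=(3, 2),
        scan_targets=targets,
        reference=reference,
    )


def make(spec: FixtureSpec):
    """Dispatch a FixtureSpec to the corresponding generator."""
    if spec.kind == "water_chain":
        return make_water_chain(
            spec.n_fragments, spec.spacing, spec.seed, spec.perturbation_amplitude
        )
    if spec.kind == "water_cluster":
        return make_water_cluster(
            spec.n_fragments, spec.spacing, spec.seed, spec.perturbation_amplitude
        )
    if spec.kind == "toy_reaction":
        return make_toy_reaction(spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
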