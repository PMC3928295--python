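"""Analytic gradient assembly on active-domain atoms.

Only atoms of fragments in the active domain A move during optimization,
so the reported gradient is the derivative of the assembled total energy
with respect to those coordinates, zero-masked everywhere else.  Terms:

* monomer gradients of A fragments (frozen/buffer monomers do not depend
  on A coordinates);
* QM dimer interaction gradients for pairs with at least one member in A;
* minus the classical pair-polarization gradient for those pairs;
* far-pair Coulomb gradients for pairs touching A;
* the Hellmann–Feynman gradient of the system-wide induction energy;
* for hybrid runs, the MP2 correlation gradient on fragment H's atoms.

Charges and polarizabilities are fixed parameters of the run (frozen
densities), so the gradient is exact for the implemented energy — the
correctness criterion is agreement with central finite differences of
that energy, which :func:`numerical_gradient` provides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .backends import Backend, Level, get_backend
from .config import RunConfig
from .energy import FDDCache, _domain_pair_label, select_qm_pairs
from .fragments import DomainPartition, FragmentSet
from .geometry import SystemGeometry
from .polarization import (
    build_sites,
    far_pair_gradient,
    polarization_gradient,
    pol_energy_pair,
    static_field,
    solve_induced_dipoles,
)


@dataclass(frozen=True)
class GradientReport:
    """Per-atom force constants of one gradient evaluation, Hartree/Bohr."""

    gradient: np.ndarray = field(repr=False)  # (n_atoms, 3), zero outside A
    terms: dict = field(repr=False)  # name -> (n_atoms, 3), each zero-masked
    mp2_term: np.ndarray = field(repr=False)  # (n_atoms, 3)
    max_component: float = 0.0
    active_atoms: tuple[int, ...] = ()


def _mask(array: np.ndarray, active_atoms: Iterable[int]) -> np.ndarray:
    out = np.zeros_like(array)
    idx = list(active_atoms)
    out[idx] = array[idx]
    return out


def efmo_gradient(
    geometry: SystemGeometry,
    fragments: FragmentSet,
    partition: DomainPartition,
    config: RunConfig,
    cache: FDDCache | None = None,
    backend: Backend | None = None,
    hybrid: bool = False,
) -> GradientReport:
    """Gradient of the assembled total energy on active-domain atoms."""
    partition.validate_against(fragments)
    backend = backend if backend is not None else get_backend(config.backend)
    cache = cache if cache is not None else FDDCache()
    use_cache = config.fdd_enabled
    ids = sorted(partition.all_ids)
    h = partition.high_level
    n = geometry.atom_count
    active_atoms = partition.active_atoms(fragments)

    def basis_of(fid: int) -> str:
        return config.basis_for(fid, h) if hybrid else config.rhf_basis

    # monomer records (charges/polarizabilities needed system-wide)
    records = {
        fid: cache.get_monomer(
            backend,
            geometry,
            fragments,
            fid,
            Level.RHF,
            basis_of(fid),
            partition.domain_of(fid),
            use_cache,
        )
        for fid in ids
    }

    terms: dict[str, np.ndarray] = {}

    g_mono = np.zeros((n, 3))
    for fid in sorted(partition.active):
        frag = fragments[fid]
        g_mono[list(frag.atom_indices)] += records[fid].gradient
    terms["monomer"] = g_mono

    qm_pairs = select_qm_pairs(fragments, geometry, partition, config.dimer_cutoff)
    g_dimer = np.zeros((n, 3))
    g_pair_pol = np.zeros((n, 3))
    for pair in sorted(qm_pairs):
        i, j = pair
        if i not in partition.active and j not in partition.active:
            continue
        dimer = cache.get_dimer(
            backend,
            geometry,
            fragments,
            pair,
            Level.RHF,
            (basis_of(i), basis_of(j)),
            _domain_pair_label(partition, i, j),
            use_cache,
        )
        g_dimer[list(fragments[i].atom_indices)] += dimer.gradient_I
        g_dimer[list(fragments[j].atom_indices)] += dimer.gradient_J
        if config.polarization_enabled:
            sites = build_sites((i, j), fragments, records, geometry)
            state = pol_energy_pair(i, j, fragments, records, geometry, config.pol)
            g_pair_pol -= polarization_gradient(sites, state, n, config.pol)
    terms["qm_dimer"] = g_dimer
    if config.polarization_enabled:
        terms["pair_pol_correction"] = g_pair_pol

    g_far = np.zeros((n, 3))
    all_pairs = {
        (ids[a], ids[b]) for a in range(len(ids)) for b in range(a + 1, len(ids))
    }
    for pair in sorted(all_pairs - qm_pairs):
        i, j = pair
        if i not in partition.active and j not in partition.active:
            continue
        g_far += far_pair_gradient(i, j, fragments, records, geometry)
    terms["far_pair"] = g_far

    if config.polarization_enabled:
        span_ids = (
            ids
            if config.pol.span == "all"
            else sorted(partition.active | partition.polarizable)
        )
        sites = build_sites(span_ids, fragments, records, geometry)
        if len(set(sites.fragment_ids.tolist())) >= 2:
            f_static = static_field(sites)
            state = solve_induced_dipoles(sites, f_static, config.pol)
            terms["total_pol"] = polarization_gradient(sites, state, n, config.pol)
        else:
            terms["total_pol"] = np.zeros((n, 3))

    mp2_term = np.zeros((n, 3))
    if hybrid and config.hybrid_mp2:
        h_rec = cache.get_monomer(
            backend,
            geometry,
            fragments,
            h,
            Level.MP2,
            config.mp2_basis,
            partition.domain_of(h),
            use_cache,
        )
        if h_rec.correlation_gradient is not None:
            mp2_term[list(fragments[h].atom_indices)] += h_rec.correlation_gradient
        terms["mp2_correlation"] = mp2_term

    terms = {name: _mask(g, active_atoms) for name, g in terms.items()}
    mp2_term = _mask(mp2_term, active_atoms)
    total = np.zeros((n, 3))
    for g in terms.values():
        total += g
    max_component = float(np.max(np.abs(total))) if n else 0.0
    return GradientReport(
        gradient=total,
        terms=terms,
        mp2_term=mp2_term,
        max_component=max_component,
        active_atoms=active_atoms,
    )


def hybrid_gradient(
    geometry: SystemGeometry,
    fragments: FragmentSet,
    partition: DomainPartition,
    config: RunConfig,
    cache: FDDCache | None = None,
    backend: Backend | None = None,
) -> GradientReport:
    """RHF gradient plus the MP2 correlation gradient on H's atoms only."""
    return efmo_gradient(
        geometry, fragments, partition, config, cache, backend, hybrid=True
    )


def numerical_gradient(
    energy_fn: Callable[[SystemGeometry], float],
    geometry: SystemGeometry,
    atoms: Iterable[int],
    step: float = 1.0e-4,
) -> np.ndarray:
    """Central finite differences of ``energy_fn`` over the given atoms.

    Returns an ``(n_atoms, 3)`` array that is zero for atoms not listed.
    ``step`` is in Bohr.
    """
    if step <= 0:
        raise ValueError("finite-difference step must be positive")
    grad = np.zeros_like(geometry.coords)
    for a in atoms:
        for x in range(3):
            plus = geometry.coords.copy()
            plus[a, x] += step
            minus = geometry.coords.copy()
            minus[a, x] -= step
            e_plus = energy_fn(geometry.with_coords(plus))
            e_minus = energy_fn(geometry.with_coords(minus))
            grad[a, x] = (e_plus - e_minus) / (2.0 * step)
    return grad
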