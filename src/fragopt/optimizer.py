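"""Restrained geometry optimization and adiabatic reaction-path mapping.

Only the coordinates of active-domain atoms are optimization variables;
frozen and buffer atoms are never touched.  Reaction paths are traced by
a sequence of restrained optimizations: harmonic distance restraints pull
the breaking and forming bonds toward scanned targets, each point
starting from the previous converged geometry (adiabatic mapping).

The minimizer is a Cartesian quasi-Newton (BFGS) loop with an Armijo
backtracking line search, which guarantees a non-increasing energy along
accepted steps and makes the convergence test (max or RMS gradient
component, restraint forces included) explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .backends import Backend, get_backend
from .config import RunConfig
from .constants import (
    ANGSTROM_PER_BOHR,
    BOHR_PER_ANGSTROM,
    HARTREE_PER_KCAL,
    KCAL_PER_HARTREE,
)
from .energy import EnergyReport, FDDCache, efmo_hybrid_energy, efmo_total_energy
from .fragments import DomainPartition, FragmentSet
from .geometry import SystemGeometry, reaction_coordinate
from .gradients import efmo_gradient, hybrid_gradient

logger = logging.getLogger("fragopt.optimizer")


@dataclass(frozen=True)
class Restraint:
    """Harmonic distance restraint ½ k (r − r₀)².

    ``target_distance`` in Å, ``force_constant`` in kcal·mol⁻¹·Å⁻²
    (converted to atomic units internally).
    """

    atom_pair: tuple[int, int]
    target_distance: float
    force_constant: float

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("restraint force constant must be non-negative")
        if self.target_distance <= 0:
            raise ValueError("restraint target distance must be positive")
        if self.atom_pair[0] == self.atom_pair[1]:
            raise ValueError("restraint needs two distinct atoms")


def restraint_energy_gradient(
    geometry: SystemGeometry, restraints: Sequence[Restraint]
) -> tuple[float, np.ndarray]:
    """Total restraint energy (Hartree) and gradient (Hartree/Bohr)."""
    energy = 0.0
    grad = np.zeros_like(geometry.coords)
    for res in restraints:
        i, j = res.atom_pair
        d = geometry.coords[i] - geometry.coords[j]
        r = float(np.linalg.norm(d))
        if r < 1e-10:
            raise ZeroDivisionError(
                f"restrained atoms {i}, {j} coincide; distance undefined"
            )
        k_au = res.force_constant * HARTREE_PER_KCAL * ANGSTROM_PER_BOHR**2
        r0 = res.target_distance * BOHR_PER_ANGSTROM
        energy += 0.5 * k_au * (r - r0) ** 2
        dedr = k_au * (r - r0)
        u = d / r
        grad[i] += dedr * u
        grad[j] -= dedr * u
    return energy, grad


@dataclass(frozen=True)
class PathPoint:
    """One converged (or abandoned) point of an adiabatic scan."""

    scan_index: int
    restraints: tuple[Restraint, ...]
    geometry: SystemGeometry
    reaction_coordinate: float | None
    energy_report: EnergyReport
    restraint_energy: float
    n_steps: int
    converged: bool
    step_log: pd.DataFrame = field(repr=False, default=None)


class BarrierSummary(NamedTuple):
    """Barrier = max(E) − E(first); reaction energy = E(last) − E(first)."""

    barrier: float  # kcal/mol
    reaction_energy: float  # kcal/mol
    ts_reaction_coordinate: float | None  # Å, at the path maximum


def _convergence_measure(grad_active: np.ndarray, metric: str) -> float:
    if metric == "rms":
        return float(np.sqrt(np.mean(grad_active**2)))
    return float(np.max(np.abs(grad_active)))


def optimize(
    geometry: SystemGeometry,
    fragments: FragmentSet,
    partition: DomainPartition,
    restraints: Sequence[Restraint],
    config: RunConfig,
    cache: FDDCache | None = None,
    backend: Backend | None = None,
    scan_index: int = 0,
    reaction_pairs: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> PathPoint:
    """Minimize the (hybrid) total energy plus restraints over A-domain atoms.

    Non-convergence within ``config.max_opt_steps`` returns a PathPoint
    with ``converged=False`` rather than raising.
    """
    partition.validate_against(fragments)
    backend = backend if backend is not None else get_backend(config.backend)
    cache = cache if cache is not None else FDDCache()
    active_atoms = list(partition.active_atoms(fragments))
    energy_fn = efmo_hybrid_energy if config.hybrid_mp2 else efmo_total_energy
    grad_fn = hybrid_gradient if config.hybrid_mp2 else efmo_gradient

    base_coords = geometry.coords.copy()

    def geom_of(x: np.ndarray) -> SystemGeometry:
        coords = base_coords.copy()
        coords[active_atoms] = x.reshape(-1, 3)
        return geometry.with_coords(coords)

    def evaluate(x: np.ndarray) -> tuple[float, np.ndarray, EnergyReport, float]:
        g = geom_of(x)
        report = energy_fn(g, fragments, partition, config, cache, backend)
        grad_report = grad_fn(g, fragments, partition, config, cache, backend)
        e_res, g_res = restraint_energy_gradient(g, restraints)
        grad = (grad_report.gradient + g_res)[active_atoms].ravel()
        return report.total + e_res, grad, report, e_res

    x = base_coords[active_atoms].ravel().copy()
    e, g, report, e_res = evaluate(x)
    n_var = len(x)
    h_inv = np.eye(n_var)
    log_rows = [
        {
            "step": 0,
            "energy_hartree": e,
            "max_gradient": float(np.max(np.abs(g))) if n_var else 0.0,
            "cache_hits": sum(cache.monomer_hits.values()),
        }
    ]
    metric = config.convergence_metric
    tol = config.gradient_tolerance
    converged = _convergence_measure(g, metric) <= tol if n_var else True
    steps = 0
    while not converged and steps < config.max_opt_steps:
        p = -h_inv @ g
        if float(p @ g) >= 0.0:  # safeguard: reset to steepest descent
            h_inv = np.eye(n_var)
            p = -g
        alpha = 1.0
        accepted = False
        for _ in range(40):
            x_new = x + alpha * p
            try:
                e_new, g_new, report_new, e_res_new = evaluate(x_new)
            except Exception:
                alpha *= 0.5
                continue
            if e_new <= e + 1.0e-4 * alpha * float(g @ p):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            logger.warning("line search failed at step %d", steps + 1)
            break
        s = x_new - x
        y = g_new - g
        sy = float(s @ y)
        if sy > 1e-12:
            rho = 1.0 / sy
            i_mat = np.eye(n_var)
            v = i_mat - rho * np.outer(s, y)
            h_inv = v @ h_inv @ v.T + rho * np.outer(s, s)
        x, e, g, report, e_res = x_new, e_new, g_new, report_new, e_res_new
        steps += 1
        measure = _convergence_measure(g, metric)
        log_rows.append(
            {
                "step": steps,
                "energy_hartree": e,
                "max_gradient": float(np.max(np.abs(g))),
                "cache_hits": sum(cache.monomer_hits.values()),
            }
        )
        logger.info(
            "step %d  E=%.10f Ha  |g|max=%.3e Ha/Bohr  cache_hits=%d",
            steps,
            e,
            log_rows[-1]["max_gradient"],
            log_rows[-1]["cache_hits"],
        )
        converged = measure <= tol

    final_geometry = geom_of(x)
    rc = (
        reaction_coordinate(final_geometry, *reaction_pairs)
        if reaction_pairs is not None
        else None
    )
    return PathPoint(
        scan_index=scan_index,
        restraints=tuple(restraints),
        geometry=final_geometry,
        reaction_coordinate=rc,
        energy_report=report,
        restraint_energy=e_res,
        n_steps=steps,
        converged=converged,
        step_log=pd.DataFrame(log_rows),
    )


def scan_reaction_path(
    geometry: SystemGeometry,
    fragments: FragmentSet,
    partition: DomainPartition,
    scan_targets: Sequence[tuple[float, float]],
    config: RunConfig,
    breaking_pair: tuple[int, int],
    forming_pair: tuple[int, int],
    cache: FDDCache | None = None,
    backend: Backend | None = None,
) -> list[PathPoint]:
    """Adiabatic mapping: one restrained optimization per target pair.

    ``scan_targets`` holds (r₁, r₂) target distances in Å for the breaking
    and forming bonds.  Each point starts from the previous converged
    geometry.  Unconverged points are flagged but the scan continues.
    """
    if not scan_targets:
        raise ValueError("scan requires at least one target pair")
    backend = backend if backend is not None else get_backend(config.backend)
    cache = cache if cache is not None else FDDCache()
    points: list[PathPoint] = []
    current = geometry
    for idx, (r1, r2) in enumerate(scan_targets):
        restraints = (
            Restraint(breaking_pair, r1, config.restraint_force_constant),
            Restraint(forming_pair, r2, config.restraint_force_constant),
        )
        point = optimize(
            current,
            fragments,
            partition,
            restraints,
            config,
            cache,
            backend,
            scan_index=idx,
            reaction_pairs=(breaking_pair, forming_pair),
        )
        if not point.converged:
            logger.warning("scan point %d did not converge", idx)
        points.append(point)
        current = point.geometry
    return points


def path_table(points: Sequence[PathPoint]) -> pd.DataFrame:
    """Tabular view of a scan: one row per point, energies relative in kcal/mol."""
    e0 = points[0].energy_report.total
    rows = []
    for p in points:
        r1 = p.restraints[0].target_distance if p.restraints else float("nan")
        r2 = (
            p.restraints[1].target_distance
            if len(p.restraints) > 1
            else float("nan")
        )
        rows.append(
            {
                "scan_index": p.scan_index,
                "r1_target": r1,
                "r2_target": r2,
                "reaction_coordinate_A": p.reaction_coordinate,
                "E_total_Hartree": p.energy_report.total,
                "dE_kcal_mol": (p.energy_report.total - e0) * KCAL_PER_HARTREE,
                "n_steps": p.n_steps,
                "converged": p.converged,
            }
        )
    return pd.DataFrame(rows)


def barrier_and_reaction_energy(points: Sequence[PathPoint]) -> BarrierSummary:
    """Barrier and reaction energy of a path, kcal/mol, plus the TS coordinate."""
    if len(points) < 2:
        raise ValueError("need at least two path points")
    energies = np.array([p.energy_report.total for p in points])
    i_max = int(np.argmax(energies))
    barrier = float((energies[i_max] - energies[0]) * KCAL_PER_HARTREE)
    reaction = float((energies[-1] - energies[0]) * KCAL_PER_HARTREE)
    return BarrierSummary(
        barrier=barrier,
        reaction_energy=reaction,
        ts_reaction_coordinate=points[i_max].reaction_coordinate,
    )
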