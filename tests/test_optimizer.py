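"""Restraints, restrained optimization, and adiabatic-mapping scans."""

import numpy as np
import pandas as pd
import pytest

from fragopt.backends import MockBackend
from fragopt.backends.mock import MockParams
from fragopt.config import RunConfig
from fragopt.constants import (
    ANGSTROM_PER_BOHR,
    BOHR_PER_ANGSTROM,
    HARTREE_PER_KCAL,
    KCAL_PER_HARTREE,
)
from fragopt.energy import EnergyReport, FDDCache
from fragopt.fixtures import make_water_chain
from fragopt.fragments import DomainPartition, build_fragments
from fragopt.geometry import SystemGeometry
from fragopt.gradients import numerical_gradient
from fragopt.optimizer import (
    PathPoint,
    Restraint,
    barrier_and_reaction_energy,
    optimize,
    path_table,
    restraint_energy_gradient,
    scan_reaction_path,
)


def _fake_point(idx, energy_hartree, rc=None):
    report = EnergyReport.assemble({0: energy_hartree}, {}, 0.0, 0.0, {}, "RHF")
    geometry = SystemGeometry(("C",), np.array([[float(idx), 0.0, 0.0]]))
    return PathPoint(
        scan_index=idx,
        restraints=(),
        geometry=geometry,
        reaction_coordinate=rc,
        energy_report=report,
        restraint_energy=0.0,
        n_steps=0,
        converged=True,
    )


class TestRestraints:
    def test_zero_at_target(self):
        g = SystemGeometry.from_angstrom(["C", "C"], [[0, 0, 0], [2.0, 0, 0]])
        e, grad = restraint_energy_gradient(g, [Restraint((0, 1), 2.0, 500.0)])
        assert e == pytest.approx(0.0, abs=1e-15)
        assert np.max(np.abs(grad)) == pytest.approx(0.0, abs=1e-12)

    def test_half_k_delta_squared(self):
        # k = 500 kcal/mol/A^2 stretched by 0.1 A stores 2.5 kcal/mol
        g = SystemGeometry.from_angstrom(["C", "C"], [[0, 0, 0], [2.1, 0, 0]])
        e, _ = restraint_energy_gradient(g, [Restraint((0, 1), 2.0, 500.0)])
        assert e == pytest.approx(2.5 * HARTREE_PER_KCAL, rel=1e-10)

    def test_additivity_over_disjoint_pairs(self):
        g = SystemGeometry.from_angstrom(
            ["C", "C", "C", "C"], [[0, 0, 0], [2.1, 0, 0], [0, 5, 0], [1.9, 5, 0]]
        )
        r1, r2 = Restraint((0, 1), 2.0, 500.0), Restraint((2, 3), 2.0, 300.0)
        e1, g1 = restraint_energy_gradient(g, [r1])
        e2, g2 = restraint_energy_gradient(g, [r2])
        e12, g12 = restraint_energy_gradient(g, [r1, r2])
        assert e12 == pytest.approx(e1 + e2, rel=1e-14)
        assert np.allclose(g12, g1 + g2, atol=1e-16)

    def test_gradient_matches_finite_difference(self):
        g = SystemGeometry.from_angstrom(["C", "C"], [[0.1, 0.2, -0.3], [1.8, 0.7, 0.4]])
        res = [Restraint((0, 1), 2.0, 500.0)]
        _, grad = restraint_energy_gradient(g, res)
        num = numerical_gradient(
            lambda geom: restraint_energy_gradient(geom, res)[0], g, [0, 1], 1e-5
        )
        assert np.max(np.abs(grad - num)) < 1e-8

    def test_invalid_restraints_rejected(self):
        with pytest.raises(ValueError):
            Restraint((0, 0), 2.0, 500.0)
        with pytest.raises(ValueError):
            Restraint((0, 1), -1.0, 500.0)
        with pytest.raises(ValueError):
            Restraint((0, 1), 2.0, -5.0)


class TestOptimize:
    def _diatomic(self):
        # one harmonic mock bond; correlation disabled so the energy is
        # exactly the single harmonic term
        backend = MockBackend(MockParams(correlation_enabled=False))
        k_b, r0 = backend.params.bond("O", "H")
        g = SystemGeometry(("O", "H"), np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]))
        fragments = build_fragments(g, [([0, 1], 0)])
        part = DomainPartition(frozenset(), frozenset(), frozenset({0}), 0)
        return backend, k_b, r0, g, fragments, part

    def test_already_converged_takes_no_steps(self):
        backend, _, _, g, fragments, part = self._diatomic()
        cfg = RunConfig(hybrid_mp2=False, gradient_tolerance=1e-6)
        point = optimize(g, fragments, part, [], cfg, FDDCache(), backend)
        assert point.converged and point.n_steps == 0
        assert np.array_equal(point.geometry.coords, g.coords)

    def test_two_harmonic_closed_form(self):
        # mock bond (k_b, L) + restraint (k_r, T): stationary length is the
        # stiffness-weighted mean (k_b L + k_r T)/(k_b + k_r)
        backend, k_b, r0, g, fragments, part = self._diatomic()
        target_bohr = r0 + 0.5
        restraint = Restraint(
            (0, 1),
            target_bohr * ANGSTROM_PER_BOHR,
            500.0,
        )
        k_r = 500.0 * HARTREE_PER_KCAL * ANGSTROM_PER_BOHR**2
        expected = (k_b * r0 + k_r * target_bohr) / (k_b + k_r)
        cfg = RunConfig(hybrid_mp2=False, gradient_tolerance=1e-8, max_opt_steps=100)
        point = optimize(g, fragments, part, [restraint], cfg, FDDCache(), backend)
        assert point.converged
        assert point.geometry.distance(0, 1) == pytest.approx(expected, abs=1e-6)

    def test_restraint_residual_bound(self):
        # at convergence the distance misses its target by at most
        # |dE_unrestrained/dr| / k_r
        backend, k_b, r0, g, fragments, part = self._diatomic()
        target_bohr = r0 + 0.5
        restraint = Restraint((0, 1), target_bohr * ANGSTROM_PER_BOHR, 500.0)
        cfg = RunConfig(hybrid_mp2=False, gradient_tolerance=1e-8, max_opt_steps=100)
        point = optimize(g, fragments, part, [restraint], cfg, FDDCache(), backend)
        r = point.geometry.distance(0, 1)
        k_r = 500.0 * HARTREE_PER_KCAL * ANGSTROM_PER_BOHR**2
        force_unrestrained = abs(k_b * (r - r0))
        assert abs(r - target_bohr) <= force_unrestrained / k_r + 1e-8

    def test_unconverged_returns_flag_not_exception(self):
        # C-C mock bond (k = 0.4): one steepest-descent step cannot land on
        # the minimum, so a 1-step budget must come back unconverged
        backend = MockBackend(MockParams(correlation_enabled=False))
        _, r0 = backend.params.bond("C", "C")
        g = SystemGeometry(("C", "C"), np.array([[0.0, 0.0, 0.0], [r0 + 1.0, 0.0, 0.0]]))
        fragments = build_fragments(g, [([0, 1], 0)])
        part = DomainPartition(frozenset(), frozenset(), frozenset({0}), 0)
        cfg = RunConfig(hybrid_mp2=False, gradient_tolerance=1e-10, max_opt_steps=1)
        point = optimize(g, fragments, part, [], cfg, FDDCache(), backend)
        assert not point.converged
        assert point.n_steps == 1

    def test_frozen_atoms_bitwise_unchanged(self, toy):
        restraints = [
            Restraint(toy.breaking_pair, toy.scan_targets[0][0], 500.0),
            Restraint(toy.forming_pair, toy.scan_targets[0][1], 500.0),
        ]
        point = optimize(
            toy.geometry, toy.fragments, toy.partition, restraints, toy.config,
            FDDCache(), toy.backend,
        )
        frozen_atoms = [
            a
            for fid in toy.partition.frozen | toy.partition.polarizable
            for a in toy.fragments[fid].atom_indices
        ]
        assert np.array_equal(
            point.geometry.coords[frozen_atoms], toy.geometry.coords[frozen_atoms]
        )
        assert point.converged

    def test_energy_non_increasing_along_accepted_steps(self, toy):
        restraints = [
            Restraint(toy.breaking_pair, toy.scan_targets[2][0], 500.0),
            Restraint(toy.forming_pair, toy.scan_targets[2][1], 500.0),
        ]
        point = optimize(
            toy.geometry, toy.fragments, toy.partition, restraints, toy.config,
            FDDCache(), toy.backend,
        )
        energies = point.step_log["energy_hartree"].to_numpy()
        assert np.all(np.diff(energies) <= 1e-15)


class TestScan:
    def test_single_target_equals_optimize(self, toy):
        pts = scan_reaction_path(
            toy.geometry, toy.fragments, toy.partition, toy.scan_targets[:1],
            toy.config, toy.breaking_pair, toy.forming_pair, FDDCache(), toy.backend,
        )
        assert len(pts) == 1
        single = optimize(
            toy.geometry, toy.fragments, toy.partition,
            [
                Restraint(toy.breaking_pair, toy.scan_targets[0][0], 500.0),
                Restraint(toy.forming_pair, toy.scan_targets[0][1], 500.0),
            ],
            toy.config, FDDCache(), toy.backend,
            reaction_pairs=(toy.breaking_pair, toy.forming_pair),
        )
        assert pts[0].energy_report.total == pytest.approx(
            single.energy_report.total, abs=1e-12
        )

    def test_recovers_analytic_barrier_within_bias_bound(self, toy):
        pts = scan_reaction_path(
            toy.geometry, toy.fragments, toy.partition, toy.scan_targets,
            toy.config, toy.breaking_pair, toy.forming_pair, FDDCache(), toy.backend,
        )
        assert all(p.converged for p in pts)
        summary = barrier_and_reaction_energy(pts)
        ref = toy.reference
        assert summary.barrier == pytest.approx(
            ref.barrier * KCAL_PER_HARTREE, abs=ref.bias_bound_kcal
        )
        assert summary.reaction_energy == pytest.approx(
            ref.reaction_energy * KCAL_PER_HARTREE, abs=ref.bias_bound_kcal
        )
        # reaction coordinate sign convention: reactant negative, product positive
        assert pts[0].reaction_coordinate < 0 < pts[-1].reaction_coordinate

    def test_matches_restrained_one_dimensional_prediction(self, toy):
        # sharper than the bias bound: the scan should land on the 1-D
        # restrained-minimum prediction almost exactly
        pts = scan_reaction_path(
            toy.geometry, toy.fragments, toy.partition, toy.scan_targets,
            toy.config, toy.breaking_pair, toy.forming_pair, FDDCache(), toy.backend,
        )
        summary = barrier_and_reaction_energy(pts)
        ref = toy.reference
        assert summary.barrier == pytest.approx(
            ref.restrained_barrier * KCAL_PER_HARTREE, abs=0.05
        )
        assert summary.reaction_energy == pytest.approx(
            ref.restrained_reaction_energy * KCAL_PER_HARTREE, abs=0.05
        )

    def test_determinism(self, toy):
        tables = []
        for _ in range(2):
            pts = scan_reaction_path(
                toy.geometry, toy.fragments, toy.partition, toy.scan_targets[:5],
                toy.config, toy.breaking_pair, toy.forming_pair, FDDCache(), toy.backend,
            )
            tables.append(path_table(pts))
        pd.testing.assert_frame_equal(tables[0], tables[1])

    def test_reverse_scan_reproduces_endpoint_energies(self, toy):
        fwd = scan_reaction_path(
            toy.geometry, toy.fragments, toy.partition, toy.scan_targets,
            toy.config, toy.breaking_pair, toy.forming_pair, FDDCache(), toy.backend,
        )
        rev = scan_reaction_path(
            fwd[-1].geometry, toy.fragments, toy.partition,
            tuple(reversed(toy.scan_targets)),
            toy.config, toy.breaking_pair, toy.forming_pair, FDDCache(), toy.backend,
        )
        assert rev[-1].energy_report.total == pytest.approx(
            fwd[0].energy_report.total, abs=1e-6
        )
        assert rev[0].energy_report.total == pytest.approx(
            fwd[-1].energy_report.total, abs=1e-6
        )

    def test_empty_target_list_rejected(self, toy):
        with pytest.raises(ValueError):
            scan_reaction_path(
                toy.geometry, toy.fragments, toy.partition, [], toy.config,
                toy.breaking_pair, toy.forming_pair,
            )


class TestBarrierArithmetic:
    def test_hand_written_path(self):
        pts = [
            _fake_point(0, 0.0, rc=-0.6),
            _fake_point(1, 5.0 * HARTREE_PER_KCAL, rc=-0.1),
            _fake_point(2, 3.0 * HARTREE_PER_KCAL, rc=0.6),
        ]
        s = barrier_and_reaction_energy(pts)
        assert s.barrier == pytest.approx(5.0, rel=1e-12)
        assert s.reaction_energy == pytest.approx(3.0, rel=1e-12)
        assert s.ts_reaction_coordinate == pytest.approx(-0.1)

    def test_monotonically_decreasing_path(self):
        pts = [_fake_point(i, -i * HARTREE_PER_KCAL) for i in range(4)]
        s = barrier_and_reaction_energy(pts)
        assert s.barrier == 0.0
        assert s.reaction_energy == pytest.approx(-3.0, rel=1e-12)

    def test_short_path_rejected(self):
        with pytest.raises(ValueError):
            barrier_and_reaction_energy([_fake_point(0, 0.0)])
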