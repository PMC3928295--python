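"""Two-body energy assembly, hybrid additivity, and FDD cache semantics."""

import numpy as np
import pytest

from fragopt.backends import Level, MockBackend
from fragopt.config import RunConfig
from fragopt.energy import (
    FDDCache,
    efmo_hybrid_energy,
    efmo_total_energy,
    fdd_cache_audit,
    relative_pair_distance,
    select_qm_pairs,
)
from fragopt.constants import vdw_radius
from fragopt.fixtures import make_water_chain
from fragopt.fragments import DomainPartition, build_fragments
from fragopt.geometry import SystemGeometry


def _all_active(n):
    return DomainPartition(frozenset(), frozenset(), frozenset(range(n)), 0)


def _cfg(**kw):
    defaults = dict(
        dimer_cutoff=1.5, polarization_enabled=True, hybrid_mp2=True, mp2_basis="cc-pVDZ"
    )
    defaults.update(kw)
    return RunConfig(**defaults)


class TestPairSelection:
    def test_close_waters_selected(self, mock_backend):
        geometry, fragments = make_water_chain(2, spacing=2.8)
        part = _all_active(2)
        # independent evaluation of the vdW-scaled relative distance
        coords = geometry.coords_angstrom()
        rel = min(
            np.linalg.norm(coords[a] - coords[b])
            / (vdw_radius(geometry.elements[a]) + vdw_radius(geometry.elements[b]))
            for a in range(3)
            for b in range(3, 6)
        )
        assert relative_pair_distance(geometry, fragments, 0, 1) == pytest.approx(rel)
        assert rel < 1.5
        assert select_qm_pairs(fragments, geometry, part, 1.5) == {(0, 1)}

    def test_tiny_cutoff_excludes_pair(self):
        geometry, fragments = make_water_chain(2, spacing=2.8)
        assert select_qm_pairs(fragments, geometry, _all_active(2), 1e-9) == set()

    def test_frozen_pairs_dropped_from_recompute_set(self):
        geometry, fragments = make_water_chain(3, spacing=2.8)
        part = DomainPartition(frozenset({1, 2}), frozenset(), frozenset({0}), 0)
        full = select_qm_pairs(fragments, geometry, part, 1.5)
        fresh = select_qm_pairs(fragments, geometry, part, 1.5, exclude_frozen_pairs=True)
        assert (1, 2) in full
        assert (1, 2) not in fresh
        assert fresh == full - {(1, 2)}


class TestTotalEnergy:
    def test_single_fragment_total_is_monomer(self, mock_backend):
        geometry, fragments = make_water_chain(1, seed=1, perturbation=0.1)
        part = DomainPartition(frozenset(), frozenset(), frozenset({0}), 0)
        rep = efmo_total_energy(geometry, fragments, part, _cfg(), FDDCache(), mock_backend)
        e0 = mock_backend.compute_monomer(geometry, fragments[0], Level.RHF, "6-31G(d)").energy
        assert rep.total == e0
        assert rep.qm_dimer_sum == 0.0 and rep.total_classical_pol == 0.0

    @pytest.mark.parametrize("n", [2, 3])
    def test_two_body_exactness(self, n, mock_backend):
        # the mock inter-fragment potential is strictly pairwise, so the
        # expansion with infinite cutoff and no polarization is exact
        geometry, fragments = make_water_chain(n, seed=n, perturbation=0.1)
        cfg = _cfg(dimer_cutoff=1e9, polarization_enabled=False, hybrid_mp2=False)
        rep = efmo_total_energy(geometry, fragments, _all_active(n), cfg, FDDCache(), mock_backend)
        supersystem = mock_backend.supersystem_energy(geometry, fragments)
        assert rep.total == pytest.approx(supersystem, abs=1e-12)

    def test_report_identity(self, water3, water3_config, mock_backend):
        geometry, fragments, part = water3
        rep = efmo_hybrid_energy(geometry, fragments, part, water3_config, FDDCache(), mock_backend)
        recomputed = (
            rep.monomer_sum
            + rep.qm_dimer_sum
            + rep.pair_pol_correction
            + rep.far_pair_sum
            + rep.total_classical_pol
            + rep.mp2_correction
        )
        assert rep.total == recomputed
        table = rep.to_table()
        assert table[table.term == "total"].hartree.iloc[0] == rep.total

    def test_size_consistency(self, mock_backend):
        geometry, fragments = make_water_chain(2, seed=21, perturbation=0.1)
        coords_far = np.vstack(
            [geometry.coords, geometry.coords + np.array([1000.0 / 0.52917721067, 0, 0])]
        )
        doubled = SystemGeometry.from_angstrom(
            list(geometry.elements) * 2, coords_far * 0.52917721067
        )
        frags2 = build_fragments(
            doubled, [([0, 1, 2], 0), ([3, 4, 5], 0), ([6, 7, 8], 0), ([9, 10, 11], 0)]
        )
        cfg = _cfg(hybrid_mp2=False)
        e1 = efmo_total_energy(geometry, fragments, _all_active(2), cfg, FDDCache(), mock_backend).total
        e2 = efmo_total_energy(doubled, frags2, _all_active(4), cfg, FDDCache(), mock_backend).total
        assert e2 == pytest.approx(2 * e1, abs=1e-8)

    def test_far_pairs_migrate_into_qm_sum(self, mock_backend):
        geometry, fragments = make_water_chain(3, spacing=4.5)
        part = _all_active(3)
        small = efmo_total_energy(
            geometry, fragments, part, _cfg(dimer_cutoff=1.2, hybrid_mp2=False), FDDCache(), mock_backend
        )
        large = efmo_total_energy(
            geometry, fragments, part, _cfg(dimer_cutoff=1e9, hybrid_mp2=False), FDDCache(), mock_backend
        )
        assert small.far_pair_sum != 0.0
        assert large.far_pair_sum == 0.0
        assert len(large.pair_terms) == 3

    def test_domain_decomposition_buckets(self, mock_backend):
        geometry, fragments = make_water_chain(4, spacing=2.9)
        part = DomainPartition(frozenset({3}), frozenset({2}), frozenset({0, 1}), 0)
        rep = efmo_total_energy(geometry, fragments, part, _cfg(hybrid_mp2=False), FDDCache(), mock_backend)
        d = rep.domain_decomposition
        assert {"A_internal", "b_internal", "F_internal", "Ab_interaction"} <= set(d)
        bucket_sum = sum(v for k, v in d.items() if k != "pol_total")
        assert bucket_sum == pytest.approx(
            rep.monomer_sum + rep.qm_dimer_sum + rep.pair_pol_correction + rep.far_pair_sum,
            abs=1e-12,
        )


class TestHybrid:
    def test_additivity_is_bitwise(self, water3, water3_config, mock_backend):
        geometry, fragments, part = water3
        hyb = efmo_hybrid_energy(geometry, fragments, part, water3_config, FDDCache(), mock_backend)
        rhf = efmo_total_energy(geometry, fragments, part, water3_config, FDDCache(), mock_backend)
        # strict additivity: the hybrid total is bitwise the RHF total plus
        # E_corr(H), and no other stored term changes
        assert hyb.total == rhf.total + hyb.mp2_correction
        assert hyb.monomer_sum == rhf.monomer_sum
        assert hyb.qm_dimer_sum == rhf.qm_dimer_sum
        assert hyb.total_classical_pol == rhf.total_classical_pol
        assert hyb.mp2_correction < 0

    def test_correction_follows_high_level_fragment(self, water3, water3_config, mock_backend):
        geometry, fragments, _ = water3
        for h in range(3):
            part = DomainPartition(frozenset(), frozenset(), frozenset({0, 1, 2}), h)
            rep = efmo_hybrid_energy(geometry, fragments, part, water3_config, FDDCache(), mock_backend)
            expected = mock_backend.compute_monomer(
                geometry, fragments[h], Level.MP2, "cc-pVDZ"
            ).correlation_energy
            assert rep.mp2_correction == expected

    def test_disabled_correlation_collapses_to_rhf(self, water3, water3_config):
        geometry, fragments, part = water3
        backend = MockBackend().with_correlation_disabled()
        hyb = efmo_hybrid_energy(geometry, fragments, part, water3_config, FDDCache(), backend)
        rhf = efmo_total_energy(geometry, fragments, part, water3_config, FDDCache(), backend)
        assert hyb.total == rhf.total


class TestFDDCache:
    def _two_step(self, fdd_enabled):
        geometry, fragments = make_water_chain(4, spacing=2.9, seed=8, perturbation=0.05)
        part = DomainPartition(frozenset({3}), frozenset({2}), frozenset({0, 1}), 0)
        cfg = _cfg(fdd_enabled=fdd_enabled, hybrid_mp2=False)
        backend = MockBackend()
        cache = FDDCache()
        efmo_total_energy(geometry, fragments, part, cfg, cache, backend)
        # move only active-domain atoms, as an optimizer step would
        coords = geometry.coords.copy()
        coords[list(fragments[0].atom_indices)] += 0.02
        efmo_total_energy(geometry.with_coords(coords), fragments, part, cfg, cache, backend)
        return cache

    def test_frozen_monomers_computed_once(self):
        cache = self._two_step(fdd_enabled=True)
        assert cache.monomer_computes[3] == 1
        assert cache.monomer_computes[2] == 1
        assert cache.monomer_computes[0] == 2  # A fragment moved

    def test_disabling_fdd_recomputes_everything(self):
        cache = self._two_step(fdd_enabled=False)
        assert cache.monomer_computes[3] == 2
        assert cache.monomer_computes[2] == 2

    def test_moving_active_atom_invalidates_only_that_fragment(self):
        cache = self._two_step(fdd_enabled=True)
        # fragment 1 (also active) did not move: cache key unchanged
        assert cache.monomer_computes[1] == 1
        assert cache.monomer_hits[1] >= 1

    def test_fdd_and_nofdd_totals_bitwise_identical(self, water3, mock_backend):
        geometry, fragments, part = water3
        on = efmo_hybrid_energy(geometry, fragments, part, _cfg(fdd_enabled=True), FDDCache(), mock_backend)
        off = efmo_hybrid_energy(geometry, fragments, part, _cfg(fdd_enabled=False), FDDCache(), mock_backend)
        assert on.total == off.total

    def test_audit_reports_domains(self):
        cache = self._two_step(fdd_enabled=True)
        audit = fdd_cache_audit(cache)
        by_domain = audit.monomer_computes_by_domain()
        assert by_domain["F"] == [1]
        assert by_domain["b"] == [1]
        assert set(audit.monomer_table.columns) == {"fragment", "domain", "computes", "hits"}


class TestCachePersistence:
    def test_hdf5_round_trip_and_warm_start(self, tmp_path, water3, water3_config, mock_backend):
        geometry, fragments, part = water3
        cache = FDDCache()
        first = efmo_hybrid_energy(geometry, fragments, part, water3_config, cache, mock_backend)
        store = tmp_path / "cache.h5"
        cache.save(store)
        warm = FDDCache.load(store)
        assert set(warm.monomers) == set(cache.monomers)
        key = next(iter(cache.monomers))
        assert warm.monomers[key].energy == cache.monomers[key].energy
        assert np.array_equal(warm.monomers[key].gradient, cache.monomers[key].gradient)
        # warm-started evaluation: same total, zero fresh monomer computes
        second = efmo_hybrid_energy(geometry, fragments, part, water3_config, warm, mock_backend)
        assert second.total == first.total
        assert sum(warm.monomer_computes.values()) == 0
        assert sum(warm.monomer_hits.values()) > 0


class TestPolarizationSpan:
    def test_span_switch_changes_frozen_contribution(self, mock_backend):
        geometry, fragments = make_water_chain(3, spacing=2.9)
        part = DomainPartition(frozenset({2}), frozenset({1}), frozenset({0}), 0)
        all_span = efmo_total_energy(
            geometry, fragments, part,
            _cfg(hybrid_mp2=False, pol={"span": "all"}), FDDCache(), mock_backend,
        )
        ab_span = efmo_total_energy(
            geometry, fragments, part,
            _cfg(hybrid_mp2=False, pol={"span": "active_buffer"}), FDDCache(), mock_backend,
        )
        assert all_span.total_classical_pol != ab_span.total_classical_pol
        assert all_span.total_classical_pol < 0
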