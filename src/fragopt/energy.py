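"""Two-body fragment energy assembly with frozen-domain caching.

The total energy of the expansion is

    E = Σ_I E⁰_I
      + Σ_{QM pairs}  (ΔE_IJ − E_pol,IJ)
      + Σ_{far pairs} E^elec_IJ
      + E_pol^tot
      (+ E_corr(H) for hybrid RHF:MP2 runs),

where a pair is "QM" when its vdW-scaled relative distance is within the
dimer cutoff and "far" otherwise.  The classical pair-polarization term
E_pol,IJ is subtracted from each QM dimer because the dimer calculation
already contains the mutual polarization of the pair.

Frozen-domain-and-dimers (FDD) reuse is content-addressed: every record
is keyed by the coordinates it was computed from, so fragments whose
atoms never move (domains F and b) are computed exactly once per run and
served from cache afterwards.  Disabling FDD simply bypasses the cache;
the assembled numbers are bitwise identical either way.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backends import Backend, DimerRecord, FragmentRecord, Level, geometry_key, get_backend
from .config import RunConfig
from .constants import ANGSTROM_PER_BOHR, KCAL_PER_HARTREE, vdw_radius
from .fragments import DomainPartition, FragmentSet
from .geometry import SystemGeometry
from .polarization import (
    far_pair_electrostatics,
    pol_energy_pair,
    pol_energy_total,
)

# --------------------------------------------------------------------------
# FDD cache


@dataclass
class FDDCache:
    """Content-addressed store of monomer and dimer records.

    ``monomer_computes``/``dimer_computes`` count actual backend calls per
    fragment / pair; ``*_hits`` count cache service.  Domains are recorded
    at compute time so the audit can report per-domain statistics.
    """

    monomers: dict = field(default_factory=dict)
    dimers: dict = field(default_factory=dict)
    monomer_computes: Counter = field(default_factory=Counter)
    monomer_hits: Counter = field(default_factory=Counter)
    dimer_computes: Counter = field(default_factory=Counter)
    dimer_hits: Counter = field(default_factory=Counter)
    monomer_domain: dict = field(default_factory=dict)
    dimer_domain: dict = field(default_factory=dict)

    def get_monomer(
        self,
        backend: Backend,
        geometry: SystemGeometry,
        fragments: FragmentSet,
        fragment_id: int,
        level: Level,
        basis_label: str,
        domain: str,
        use_cache: bool,
    ) -> FragmentRecord:
        frag = fragments[fragment_id]
        key = geometry_key(geometry, frag.atom_indices, level.value, basis_label)
        if use_cache and key in self.monomers:
            self.monomer_hits[fragment_id] += 1
            return self.monomers[key]
        record = backend.compute_monomer(geometry, frag, level, basis_label)
        record.validate(frag)
        self.monomers[key] = record
        self.monomer_computes[fragment_id] += 1
        self.monomer_domain[fragment_id] = domain
        return record

    def save(self, path) -> None:
        """Persist monomer/dimer records to an HDF5 keyed store."""
        import h5py

        with h5py.File(path, "w") as f:
            for key, rec in self.monomers.items():
                g = f.create_group(f"monomers/{key}")
                g.attrs["fragment_id"] = rec.fragment_id
                g.attrs["level"] = rec.level.value
                g.attrs["basis_label"] = rec.basis_label
                g.attrs["energy"] = rec.energy
                g.attrs["correlation_energy"] = rec.correlation_energy
                g["gradient"] = rec.gradient
                g["charges"] = rec.charges
                g["polarizabilities"] = rec.polarizabilities
                if rec.correlation_gradient is not None:
                    g["correlation_gradient"] = rec.correlation_gradient
            for key, rec in self.dimers.items():
                g = f.create_group(f"dimers/{key}")
                g.attrs["pair"] = rec.pair
                g.attrs["interaction_energy"] = rec.interaction_energy
                g["gradient_I"] = rec.gradient_I
                g["gradient_J"] = rec.gradient_J

    @classmethod
    def load(cls, path) -> "FDDCache":
        """Restore a cache written by :meth:`save` (counters start fresh)."""
        import h5py
        import numpy as np

        cache = cls()
        with h5py.File(path, "r") as f:
            for key, g in f.get("monomers", {}).items():
                cache.monomers[key] = FragmentRecord(
                    fragment_id=int(g.attrs["fragment_id"]),
                    level=Level(g.attrs["level"]),
                    basis_label=str(g.attrs["basis_label"]),
                    energy=float(g.attrs["energy"]),
                    correlation_energy=float(g.attrs["correlation_energy"]),
                    gradient=np.array(g["gradient"]),
                    correlation_gradient=(
                        np.array(g["correlation_gradient"])
                        if "correlation_gradient" in g
                        else None
                    ),
                    charges=np.array(g["charges"]),
                    polarizabilities=np.array(g["polarizabilities"]),
                    geometry_key=key,
                )
            for key, g in f.get("dimers", {}).items():
                cache.dimers[key] = DimerRecord(
                    pair=tuple(int(v) for v in g.attrs["pair"]),
                    interaction_energy=float(g.attrs["interaction_energy"]),
                    gradient_I=np.array(g["gradient_I"]),
                    gradient_J=np.array(g["gradient_J"]),
                    geometry_key=key,
                )
        return cache

    def get_dimer(
        self,
        backend: Backend,
        geometry: SystemGeometry,
        fragments: FragmentSet,
        pair: tuple[int, int],
        level: Level,
        basis_labels: tuple[str, str],
        domain_pair: str,
        use_cache: bool,
    ) -> DimerRecord:
        i, j = sorted(pair)
        fa, fb = fragments[i], fragments[j]
        key = geometry_key(
            geometry,
            fa.atom_indices + fb.atom_indices,
            level.value,
            "|".join(basis_labels),
        )
        if use_cache and key in self.dimers:
            self.dimer_hits[(i, j)] += 1
            return self.dimers[key]
        record = backend.compute_dimer(geometry, fa, fb, level, basis_labels)
        self.dimers[key] = record
        self.dimer_computes[(i, j)] += 1
        self.dimer_domain[(i, j)] = domain_pair
        return record


@dataclass(frozen=True)
class CacheAudit:
    """Per-fragment / per-pair computation and hit counts, tagged by domain."""

    monomer_table: pd.DataFrame
    dimer_table: pd.DataFrame

    def monomer_computes_by_domain(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for _, row in self.monomer_table.iterrows():
            out.setdefault(row["domain"], []).append(int(row["computes"]))
        return out


def fdd_cache_audit(cache: FDDCache) -> CacheAudit:
    """Summarize how often each monomer and dimer was actually computed."""
    mono = pd.DataFrame(
        [
            {
                "fragment": fid,
                "domain": cache.monomer_domain.get(fid, "?"),
                "computes": cache.monomer_computes[fid],
                "hits": cache.monomer_hits[fid],
            }
            for fid in sorted(cache.monomer_computes)
        ]
    )
    dim = pd.DataFrame(
        [
            {
                "pair": pair,
                "domain_pair": cache.dimer_domain.get(pair, "?"),
                "computes": cache.dimer_computes[pair],
                "hits": cache.dimer_hits[pair],
            }
            for pair in sorted(cache.dimer_computes)
        ]
    )
    return CacheAudit(monomer_table=mono, dimer_table=dim)


# --------------------------------------------------------------------------
# pair selection


def relative_pair_distance(
    geometry: SystemGeometry, fragments: FragmentSet, frag_i: int, frag_j: int
) -> float:
    """Unitless vdW-scaled distance R_IJ = min_ab r_ab / (R_a + R_b)."""
    fa, fb = fragments[frag_i], fragments[frag_j]
    ca = geometry.coords[list(fa.atom_indices)] * ANGSTROM_PER_BOHR
    cb = geometry.coords[list(fb.atom_indices)] * ANGSTROM_PER_BOHR
    ra = np.array([vdw_radius(geometry.elements[a]) for a in fa.atom_indices])
    rb = np.array([vdw_radius(geometry.elements[b]) for b in fb.atom_indices])
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    scaled = dist / (ra[:, None] + rb[None, :])
    return float(scaled.min())


def select_qm_pairs(
    fragments: FragmentSet,
    geometry: SystemGeometry,
    partition: DomainPartition,
    cutoff: float,
    exclude_frozen_pairs: bool = False,
) -> set[tuple[int, int]]:
    """Fragment pairs treated quantum mechanically (within the cutoff).

    With ``exclude_frozen_pairs=True`` the set is filtered to the pairs
    that may need a fresh computation this step: pairs lying entirely in
    the frozen domain are dropped (their records never change and are
    served from cache after the first evaluation).
    """
    if cutoff <= 0:
        raise ValueError("dimer cutoff must be positive")
    ids = sorted(partition.all_ids)
    out: set[tuple[int, int]] = set()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            if exclude_frozen_pairs and i in partition.frozen and j in partition.frozen:
                continue
            if relative_pair_distance(geometry, fragments, i, j) <= cutoff:
                out.add((i, j))
    return out


# --------------------------------------------------------------------------
# energy report


@dataclass(frozen=True)
class EnergyReport:
    """Term-by-term decomposition of one total-energy evaluation (Hartree).

    ``total`` is the exact floating-point sum of the stored terms, formed
    once at construction and never recomputed.
    """

    monomer_sum: float
    qm_dimer_sum: float
    pair_pol_correction: float
    far_pair_sum: float
    total_classical_pol: float
    mp2_correction: float
    total: float
    monomer_terms: dict[int, float]
    pair_terms: dict[tuple[int, int], dict[str, float]]
    domain_decomposition: dict[str, float]
    level: str

    @classmethod
    def assemble(
        cls,
        monomer_terms: dict[int, float],
        pair_terms: dict[tuple[int, int], dict[str, float]],
        total_classical_pol: float,
        mp2_correction: float,
        domain_decomposition: dict[str, float],
        level: str,
    ) -> "EnergyReport":
        monomer_sum = sum(monomer_terms.values())
        qm_dimer_sum = sum(t.get("delta_e", 0.0) for t in pair_terms.values())
        pair_pol = sum(t.get("pair_pol_correction", 0.0) for t in pair_terms.values())
        far_sum = sum(t.get("far_elec", 0.0) for t in pair_terms.values())
        # the MP2 correction is added last, onto a subtotal that is bitwise
        # the corresponding pure-RHF total: the hybrid energy is strictly
        # rhf_total + E_corr(H), with no other term perturbed
        subtotal = (
            monomer_sum + qm_dimer_sum + pair_pol + far_sum + total_classical_pol
        )
        total = subtotal + mp2_correction
        return cls(
            monomer_sum=monomer_sum,
            qm_dimer_sum=qm_dimer_sum,
            pair_pol_correction=pair_pol,
            far_pair_sum=far_sum,
            total_classical_pol=total_classical_pol,
            mp2_correction=mp2_correction,
            total=total,
            monomer_terms=dict(monomer_terms),
            pair_terms={k: dict(v) for k, v in pair_terms.items()},
            domain_decomposition=dict(domain_decomposition),
            level=level,
        )

    def to_table(self) -> pd.DataFrame:
        """One row per term, in Hartree and kcal/mol."""
        rows = []
        for fid, e in sorted(self.monomer_terms.items()):
            rows.append(("monomer", str(fid), e))
        for pair, terms in sorted(self.pair_terms.items()):
            for name, e in terms.items():
                rows.append((name, f"{pair[0]}-{pair[1]}", e))
        rows.append(("total_classical_pol", "all", self.total_classical_pol))
        if self.mp2_correction:
            rows.append(("mp2_correction", "H", self.mp2_correction))
        rows.append(("total", "all", self.total))
        df = pd.DataFrame(rows, columns=["term", "fragments", "hartree"])
        df["kcal_mol"] = df["hartree"] * KCAL_PER_HARTREE
        return df

    def to_text(self) -> str:
        df = self.to_table()
        lines = [f"Energy decomposition ({self.level})"]
        for _, row in df.iterrows():
            lines.append(
                f"  {row['term']:>22s} {row['fragments']:>8s} "
                f"{row['hartree']: .10e} Ha  {row['kcal_mol']: .6f} kcal/mol"
            )
        return "\n".join(lines)


# --------------------------------------------------------------------------
# assembly


def _domain_pair_label(partition: DomainPartition, i: int, j: int) -> str:
    da, db = sorted((partition.domain_of(i), partition.domain_of(j)))
    return f"{da}{db}"


def efmo_total_energy(
    geometry: SystemGeometry,
    fragments: FragmentSet,
    partition: DomainPartition,
    config: RunConfig,
    cache: FDDCache | None = None,
    backend: Backend | None = None,
) -> EnergyReport:
    """Assemble the two-body total energy at the RHF level (no hybrid term)."""
    report, _ = _assemble(
        geometry, fragments, partition, config, cache, backend, hybrid=False
    )
    return report


def efmo_hybrid_energy(
    geometry: SystemGeometry,
    fragments: FragmentSet,
    partition: DomainPartition,
    config: RunConfig,
    cache: FDDCache | None = None,
    backend: Backend | None = None,
) -> EnergyReport:
    """Hybrid RHF:MP2 total: the RHF assembly plus E_corr of fragment H.

    The correction is strictly additive — every other term is identical to
    the RHF report at the same geometry.
    """
    report, _ = _assemble(
        geometry, fragments, partition, config, cache, backend, hybrid=True
    )
    return report


def _assemble(
    geometry: SystemGeometry,
    fragments: FragmentSet,
    partition: DomainPartition,
    config: RunConfig,
    cache: FDDCache | None,
    backend: Backend | None,
    hybrid: bool,
) -> tuple[EnergyReport, dict]:
    """Shared energy assembly; returns the report and the working records."""
    partition.validate_against(fragments)
    backend = backend if backend is not None else get_backend(config.backend)
    cache = cache if cache is not None else FDDCache()
    use_cache = config.fdd_enabled
    ids = sorted(partition.all_ids)
    h = partition.high_level

    monomer_records: dict[int, FragmentRecord] = {}
    monomer_terms: dict[int, float] = {}
    for fid in ids:
        basis = config.basis_for(fid, h) if hybrid else config.rhf_basis
        rec = cache.get_monomer(
            backend,
            geometry,
            fragments,
            fid,
            Level.RHF,
            basis,
            partition.domain_of(fid),
            use_cache,
        )
        monomer_records[fid] = rec
        monomer_terms[fid] = rec.energy

    qm_pairs = select_qm_pairs(fragments, geometry, partition, config.dimer_cutoff)
    pair_terms: dict[tuple[int, int], dict[str, float]] = {}
    decomposition: Counter = Counter()
    for fid in ids:
        decomposition[f"{partition.domain_of(fid)}_internal"] += monomer_terms[fid]

    for pair in sorted(qm_pairs):
        i, j = pair
        basis_labels = (
            (config.basis_for(i, h), config.basis_for(j, h))
            if hybrid
            else (config.rhf_basis, config.rhf_basis)
        )
        label = _domain_pair_label(partition, i, j)
        dimer = cache.get_dimer(
            backend, geometry, fragments, pair, Level.RHF, basis_labels, label, use_cache
        )
        terms = {"delta_e": dimer.interaction_energy}
        if config.polarization_enabled:
            pair_state = pol_energy_pair(
                i, j, fragments, monomer_records, geometry, config.pol
            )
            terms["pair_pol_correction"] = -pair_state.energy
        pair_terms[pair] = terms
        bucket = (
            f"{label[0]}{label[1]}_internal" if label[0] == label[1] else f"{label}_interaction"
        )
        decomposition[bucket] += sum(terms.values())

    all_pairs = {
        (ids[a], ids[b])
        for a in range(len(ids))
        for b in range(a + 1, len(ids))
    }
    for pair in sorted(all_pairs - qm_pairs):
        i, j = pair
        e_far = far_pair_electrostatics(i, j, fragments, monomer_records, geometry)
        pair_terms[pair] = {"far_elec": e_far}
        label = _domain_pair_label(partition, i, j)
        bucket = (
            f"{label[0]}{label[1]}_internal" if label[0] == label[1] else f"{label}_interaction"
        )
        decomposition[bucket] += e_far

    total_pol = 0.0
    if config.polarization_enabled:
        span_ids = (
            ids
            if config.pol.span == "all"
            else sorted(partition.active | partition.polarizable)
        )
        state = pol_energy_total(
            span_ids, fragments, monomer_records, geometry, config.pol
        )
        total_pol = state.energy
        decomposition["pol_total"] = total_pol

    mp2_correction = 0.0
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
        mp2_correction = h_rec.correlation_energy
        monomer_records[("mp2", h)] = h_rec

    # normalize internal-bucket names: AA_internal -> A_internal etc.
    decomp = {}
    for key, val in decomposition.items():
        name = key
        if len(key) > 2 and key[0] == key[1] and key.endswith("_internal"):
            name = key[1:]
        decomp[name] = decomp.get(name, 0.0) + val

    report = EnergyReport.assemble(
        monomer_terms=monomer_terms,
        pair_terms=pair_terms,
        total_classical_pol=total_pol,
        mp2_correction=mp2_correction,
        domain_decomposition=decomp,
        level="RHF:MP2" if hybrid and config.hybrid_mp2 else "RHF",
    )
    return report, monomer_records
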