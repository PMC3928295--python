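"""Real-engine adapter backed by pyscf (optional dependency).

Satisfies the same :class:`~fragopt.backends.base.Backend` contract as the
mock backend: RHF/MP2 monomer energies and analytic gradients, Mulliken
atom-centered charges, and fixed per-element isotropic polarizabilities
(pyscf does not expose distributed atomic polarizabilities; the values
reuse the mock table, which is an explicit modelling choice, not an
ab-initio quantity).

The import of pyscf is deferred so the rest of the package works without
it; constructing the adapter raises a clear error when pyscf is missing.
"""

from __future__ import annotations

import numpy as np

from ..constants import ANGSTROM_PER_BOHR
from ..fragments import Fragment
from ..geometry import SystemGeometry
from .base import Backend, BackendError, DimerRecord, FragmentRecord, Level, geometry_key
from .mock import MockParams


class PyscfBackend(Backend):
    name = "pyscf"

    def __init__(self) -> None:
        try:
            from pyscf import gto, scf  # noqa: F401
        except ImportError as exc:  # pragma: no cover - exercised only with pyscf
            raise BackendError(
                "backend 'pyscf' requires the pyscf package to be installed"
            ) from exc
        self._alpha = MockParams().element_alpha

    # pragma: no cover - requires pyscf, exercised manually
    def _build_mol(self, geometry: SystemGeometry, atoms, charge, basis):
        from pyscf import gto

        coords = geometry.coords_angstrom()
        atom_spec = [
            (geometry.elements[a], tuple(coords[a])) for a in atoms
        ]
        return gto.M(atom=atom_spec, charge=charge, spin=0, basis=basis, unit="Angstrom")

    def _energy_gradient(self, mol, level: Level):
        from pyscf import mp, scf

        mf = scf.RHF(mol).run()
        if not mf.converged:
            raise BackendError("SCF did not converge")
        if level == Level.RHF:
            grad = mf.nuc_grad_method().kernel()
            return float(mf.e_tot), 0.0, grad, None, mf
        post = mp.MP2(mf).run()
        grad = post.nuc_grad_method().kernel()
        grad_rhf = mf.nuc_grad_method().kernel()
        return (
            float(post.e_tot),
            float(post.e_corr),
            grad,
            grad - grad_rhf,
            mf,
        )

    def compute_monomer(self, geometry, fragment, level, basis_label):
        mol = self._build_mol(geometry, fragment.atom_indices, fragment.charge, basis_label)
        try:
            energy, e_corr, grad, g_corr, mf = self._energy_gradient(mol, level)
        except BackendError as exc:
            raise BackendError(str(exc), (fragment.id,), level.value) from exc
        from pyscf.scf import hf

        pop = hf.mulliken_pop(mol, mf.make_rdm1(), verbose=0)[1]
        alphas = np.array(
            [self._alpha.get(geometry.elements[a], 3.0) for a in fragment.atom_indices]
        )
        return FragmentRecord(
            fragment_id=fragment.id,
            level=level,
            basis_label=basis_label,
            energy=energy,
            correlation_energy=e_corr,
            gradient=np.asarray(grad),
            correlation_gradient=None if g_corr is None else np.asarray(g_corr),
            charges=np.asarray(pop),
            polarizabilities=alphas,
            geometry_key=geometry_key(
                geometry, fragment.atom_indices, level.value, basis_label
            ),
        )

    def compute_dimer(self, geometry, frag_i, frag_j, level, basis_labels):
        if frag_i.id > frag_j.id:
            frag_i, frag_j = frag_j, frag_i
            basis_labels = (basis_labels[1], basis_labels[0])
        rec_i = self.compute_monomer(geometry, frag_i, level, basis_labels[0])
        rec_j = self.compute_monomer(geometry, frag_j, level, basis_labels[1])
        atoms = frag_i.atom_indices + frag_j.atom_indices
        basis = {}
        coords = geometry.coords_angstrom()
        atom_spec = []
        for k, a in enumerate(atoms):
            label = f"{geometry.elements[a]}@{k}"
            atom_spec.append((label, tuple(coords[a])))
            basis[label] = basis_labels[0] if k < frag_i.n_atoms else basis_labels[1]
        from pyscf import gto

        mol = gto.M(
            atom=atom_spec,
            charge=frag_i.charge + frag_j.charge,
            spin=0,
            basis=basis,
            unit="Angstrom",
        )
        try:
            energy, _, grad, _, _ = self._energy_gradient(mol, level)
        except BackendError as exc:
            raise BackendError(str(exc), (frag_i.id, frag_j.id), level.value) from exc
        ni = frag_i.n_atoms
        return DimerRecord(
            pair=(frag_i.id, frag_j.id),
            interaction_energy=energy - rec_i.energy - rec_j.energy,
            gradient_I=np.asarray(grad)[:ni] - rec_i.gradient,
            gradient_J=np.asarray(grad)[ni:] - rec_j.gradient,
            geometry_key=geometry_key(
                geometry, atoms, level.value, "|".join(basis_labels)
            ),
        )


from .base import register_backend  # noqa: E402

register_backend("pyscf", PyscfBackend)
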