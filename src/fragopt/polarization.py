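"""Classical many-body polarization over atom-centered point polarizabilities.

Each atom of every fragment carries an isotropic polarizability α_i and a
fixed partial charge q_i (both supplied by the backend).  Induced dipoles
solve the mutual-induction fixed point

    μ_i = α_i ( F_i^static + Σ_{j ≠ i, inter-fragment} T_ij μ_j ),

where F_i^static is the field at site i from the *other* fragments'
charges and T_ij the dipole field tensor.  Intra-fragment coupling and
intra-fragment static fields are excluded: a fragment's internal response
is already contained in its quantum-mechanical monomer energy.

The total induction energy is E_pol = −½ Σ_i μ_i · F_i^static, which at
the fixed point equals the variational minimum of
E(μ) = ½ μᵀ(α⁻¹ − T)μ − μᵀF.  Because the energy is stationary in μ, its
nuclear gradient needs only the explicit position dependence of F and T
(Hellmann–Feynman), which :func:`polarization_gradient` assembles
analytically.

All quantities are in Hartree atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PolarizationConfig
from .fragments import Fragment, FragmentSet
from .geometry import SystemGeometry

_SINGULAR_R = 1e-8


class PolarizationError(RuntimeError):
    """Solver non-convergence; carries the last residual."""

    def __init__(self, message: str, residual: float = float("nan")):
        super().__init__(message)
        self.residual = residual


class SingularityError(ValueError):
    """Coincident inter-fragment interaction sites."""


@dataclass(frozen=True)
class PolarSites:
    """Flattened per-site arrays for a subset of fragments."""

    positions: np.ndarray  # (n, 3) Bohr
    charges: np.ndarray  # (n,) e
    alphas: np.ndarray  # (n,) Bohr^3
    fragment_ids: np.ndarray  # (n,) int
    atom_indices: tuple[int, ...]  # global atom index per site

    @property
    def n_sites(self) -> int:
        return len(self.atom_indices)


@dataclass(frozen=True)
class PolarizationState:
    induced_dipoles: np.ndarray = field(repr=False)  # (n, 3) a.u.
    static_field: np.ndarray = field(repr=False)  # (n, 3) a.u.
    converged: bool = True
    iterations: int = 0
    energy: float = 0.0  # Hartree


def build_sites(
    fragment_ids,
    fragments: FragmentSet,
    records: dict,
    geometry: SystemGeometry,
) -> PolarSites:
    """Collect positions/charges/polarizabilities for the given fragments.

    ``records`` maps fragment id -> FragmentRecord (charges and
    polarizabilities are read from there).
    """
    pos, q, al, fid, atoms = [], [], [], [], []
    for f in sorted(fragment_ids):
        frag: Fragment = fragments[f]
        rec = records[f]
        for k, a in enumerate(frag.atom_indices):
            pos.append(geometry.coords[a])
            q.append(rec.charges[k])
            al.append(rec.polarizabilities[k])
            fid.append(f)
            atoms.append(a)
    return PolarSites(
        positions=np.array(pos, dtype=float).reshape(-1, 3),
        charges=np.array(q, dtype=float),
        alphas=np.array(al, dtype=float),
        fragment_ids=np.array(fid, dtype=int),
        atom_indices=tuple(atoms),
    )


# --------------------------------------------------------------------------
# fields and tensors


def _pair_geometry(sites: PolarSites) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Displacements d_ij = r_i − r_j, distances, and inter-fragment mask."""
    d = sites.positions[:, None, :] - sites.positions[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    inter = sites.fragment_ids[:, None] != sites.fragment_ids[None, :]
    if np.any((r < _SINGULAR_R) & inter):
        i, j = np.argwhere((r < _SINGULAR_R) & inter)[0]
        raise SingularityError(
            f"inter-fragment sites {sites.atom_indices[i]} and "
            f"{sites.atom_indices[j]} coincide"
        )
    return d, r, inter


def static_field(sites: PolarSites) -> np.ndarray:
    """Field at each site from all other fragments' point charges, a.u."""
    d, r, inter = _pair_geometry(sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r3 = np.where(inter, 1.0 / np.where(inter, r, 1.0) ** 3, 0.0)
    return np.einsum("j,ij,ijx->ix", sites.charges, inv_r3, d)


def _thole_factors(
    r: np.ndarray, alphas: np.ndarray, a: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential (Thole) damping factors λ3, λ5 and ds/dr for the tensor."""
    aa = np.sqrt(np.outer(alphas, alphas))
    aa = np.where(aa > 0, aa, 1.0)
    s = a * r**3 / aa
    es = np.exp(-s)
    lam3 = 1.0 - es
    lam5 = 1.0 - (1.0 + s) * es
    return lam3, lam5, s


def dipole_tensor(
    sites: PolarSites, pol_config: PolarizationConfig | None = None
) -> np.ndarray:
    """(n, n, 3, 3) dipole field tensor, zero on intra-fragment blocks."""
    cfg = pol_config or PolarizationConfig()
    d, r, inter = _pair_geometry(sites)
    rs = np.where(inter, r, 1.0)
    lam3 = np.ones_like(r)
    lam5 = np.ones_like(r)
    if cfg.damping == "thole":
        lam3, lam5, _ = _thole_factors(r, sites.alphas, cfg.thole_a)
    eye = np.eye(3)
    t = (
        3.0 * lam5[..., None, None] * d[..., :, None] * d[..., None, :] / rs[..., None, None] ** 5
        - lam3[..., None, None] * eye / rs[..., None, None] ** 3
    )
    t[~inter] = 0.0
    return t


# --------------------------------------------------------------------------
# solvers


def solve_induced_dipoles(
    sites: PolarSites,
    static_field_vectors: np.ndarray,
    pol_config: PolarizationConfig | None = None,
) -> PolarizationState:
    """Self-consistent induced dipoles and the induction energy.

    The Jacobi iteration is the production path; the dense linear solve
    (``solver="dense"``) inverts (α⁻¹ − T) directly and serves as the
    independent oracle.  Sites with α = 0 carry no dipole.
    """
    cfg = pol_config or PolarizationConfig()
    n = sites.n_sites
    f = np.asarray(static_field_vectors, dtype=float).reshape(n, 3)
    if n == 0 or np.all(sites.alphas == 0.0):
        return PolarizationState(
            induced_dipoles=np.zeros((n, 3)),
            static_field=f,
            converged=True,
            iterations=0,
            energy=0.0,
        )
    t = dipole_tensor(sites, cfg)
    alphas = sites.alphas
    if cfg.solver == "dense":
        mu = _dense_solve(alphas, t, f)
        iterations = 0
    else:
        mu = np.zeros((n, 3))
        iterations = 0
        for iterations in range(1, cfg.max_iter + 1):
            coupled = np.einsum("ijxy,jy->ix", t, mu)
            mu_new = alphas[:, None] * (f + coupled)
            mu_new[alphas == 0.0] = 0.0
            delta = float(np.max(np.abs(mu_new - mu)))
            mu = mu_new
            if delta < cfg.tolerance:
                break
        else:  # pragma: no cover - defensive
            pass
        if delta >= cfg.tolerance:
            raise PolarizationError(
                f"induced dipoles not converged in {cfg.max_iter} iterations "
                f"(residual {delta:.3e})",
                residual=delta,
            )
    energy = -0.5 * float(np.sum(mu * f))
    return PolarizationState(
        induced_dipoles=mu,
        static_field=f,
        converged=True,
        iterations=iterations,
        energy=energy,
    )


def _dense_solve(alphas: np.ndarray, t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Solve (α⁻¹ − T) μ = F restricted to polarizable sites."""
    n = len(alphas)
    live = np.flatnonzero(alphas > 0.0)
    m = len(live)
    if m == 0:
        return np.zeros((n, 3))
    b = np.zeros((3 * m, 3 * m))
    for p, i in enumerate(live):
        b[3 * p : 3 * p + 3, 3 * p : 3 * p + 3] = np.eye(3) / alphas[i]
        for q, j in enumerate(live):
            if i != j:
                b[3 * p : 3 * p + 3, 3 * q : 3 * q + 3] -= t[i, j]
    mu_live = np.linalg.solve(b, f[live].ravel()).reshape(m, 3)
    mu = np.zeros((n, 3))
    mu[live] = mu_live
    return mu


# --------------------------------------------------------------------------
# energies


def pol_energy_total(
    fragment_ids,
    fragments: FragmentSet,
    records: dict,
    geometry: SystemGeometry,
    pol_config: PolarizationConfig | None = None,
) -> PolarizationState:
    """System-wide self-consistent induction energy E_pol^tot."""
    sites = build_sites(fragment_ids, fragments, records, geometry)
    if len(set(sites.fragment_ids.tolist())) < 2:
        return PolarizationState(
            induced_dipoles=np.zeros((sites.n_sites, 3)),
            static_field=np.zeros((sites.n_sites, 3)),
            converged=True,
            iterations=0,
            energy=0.0,
        )
    f = static_field(sites)
    return solve_induced_dipoles(sites, f, pol_config)


def pol_energy_pair(
    frag_i: int,
    frag_j: int,
    fragments: FragmentSet,
    records: dict,
    geometry: SystemGeometry,
    pol_config: PolarizationConfig | None = None,
) -> PolarizationState:
    """Two-body induction energy E_pol,IJ of the isolated pair {I, J}."""
    if frag_i == frag_j:
        raise ValueError("pair polarization requires two distinct fragments")
    return pol_energy_total((frag_i, frag_j), fragments, records, geometry, pol_config)


def far_pair_electrostatics(
    frag_i: int,
    frag_j: int,
    fragments: FragmentSet,
    records: dict,
    geometry: SystemGeometry,
) -> float:
    """Classical Coulomb interaction of two fragments' atom charges, Hartree."""
    fa, fb = fragments[frag_i], fragments[frag_j]
    qa, qb = records[frag_i].charges, records[frag_j].charges
    ca = geometry.coords[list(fa.atom_indices)]
    cb = geometry.coords[list(fb.atom_indices)]
    r = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    if np.any(r < _SINGULAR_R):
        raise SingularityError(
            f"fragments {frag_i} and {frag_j} have coincident atoms"
        )
    return float(np.einsum("a,b,ab->", qa, qb, 1.0 / r))


def far_pair_gradient(
    frag_i: int,
    frag_j: int,
    fragments: FragmentSet,
    records: dict,
    geometry: SystemGeometry,
) -> np.ndarray:
    """Gradient of the far-pair Coulomb term, (n_atoms_total, 3)."""
    fa, fb = fragments[frag_i], fragments[frag_j]
    qa, qb = records[frag_i].charges, records[frag_j].charges
    grad = np.zeros_like(geometry.coords)
    for ii, a in enumerate(fa.atom_indices):
        for jj, b in enumerate(fb.atom_indices):
            d = geometry.coords[a] - geometry.coords[b]
            r = float(np.linalg.norm(d))
            g = -qa[ii] * qb[jj] / r**3 * d
            grad[a] += g
            grad[b] -= g
    return grad


# --------------------------------------------------------------------------
# analytic gradient of the induction energy


def polarization_gradient(
    sites: PolarSites,
    state: PolarizationState,
    n_atoms_total: int,
    pol_config: PolarizationConfig | None = None,
) -> np.ndarray:
    """Nuclear gradient of E_pol, scattered to global atoms, Hartree/Bohr.

    With μ converged, dE/dx = −Σ_i μ_i·∂F_i/∂x − ½ Σ_{i≠j} μ_i·(∂T_ij/∂x)·μ_j
    (charges are fixed parameters of the run, so they contribute no
    response terms).
    """
    cfg = pol_config or PolarizationConfig()
    mu = state.induced_dipoles
    grad = np.zeros((n_atoms_total, 3))
    n = sites.n_sites
    if n == 0 or not np.any(mu):
        return grad
    pos = sites.positions
    fid = sites.fragment_ids
    atom_of = sites.atom_indices
    use_thole = cfg.damping == "thole"

    # field term: F_i gets q_j d/r^3 from every charge j on another fragment
    for i in range(n):
        for j in range(n):
            if fid[i] == fid[j]:
                continue
            d = pos[i] - pos[j]
            r = float(np.linalg.norm(d))
            t = _bare_t(d, r)
            # ∂F_i/∂r_i = −q_j T(d); ∂F_i/∂r_j = +q_j T(d)
            g = sites.charges[j] * (t @ mu[i])
            grad[atom_of[i]] += g
            grad[atom_of[j]] -= g

    # tensor term over unordered inter-fragment pairs
    for i in range(n):
        for j in range(i + 1, n):
            if fid[i] == fid[j]:
                continue
            d = pos[i] - pos[j]
            r = float(np.linalg.norm(d))
            g = _tensor_term_gradient(
                d, r, mu[i], mu[j], sites.alphas[i], sites.alphas[j],
                cfg.thole_a if use_thole else None,
            )
            # −½ Σ_{i≠j} doubles over ordered pairs → factor −1 per unordered pair
            grad[atom_of[i]] -= g
            grad[atom_of[j]] += g
    return grad


def _bare_t(d: np.ndarray, r: float) -> np.ndarray:
    return 3.0 * np.outer(d, d) / r**5 - np.eye(3) / r**3


def _tensor_term_gradient(
    d: np.ndarray,
    r: float,
    u: np.ndarray,
    v: np.ndarray,
    alpha_i: float,
    alpha_j: float,
    thole_a: float | None,
) -> np.ndarray:
    """∂/∂d of uᵀ T(d) v, including Thole damping factors when enabled."""
    ud = float(u @ d)
    vd = float(v @ d)
    uv = float(u @ v)
    if thole_a is None:
        lam3 = lam5 = 1.0
        dlam3 = dlam5 = 0.0
    else:
        aa = np.sqrt(alpha_i * alpha_j) if alpha_i * alpha_j > 0 else 1.0
        s = thole_a * r**3 / aa
        es = np.exp(-s)
        lam3 = 1.0 - es
        lam5 = 1.0 - (1.0 + s) * es
        dsdr = 3.0 * s / r
        dlam3 = es * dsdr
        dlam5 = s * es * dsdr
    g = (
        3.0 * lam5 * (u * vd + v * ud) / r**5
        - 15.0 * lam5 * ud * vd * d / r**7
        + 3.0 * lam3 * uv * d / r**5
    )
    if thole_a is not None:
        unit = d / r
        g += (3.0 * ud * vd / r**5 * dlam5 - uv / r**3 * dlam3) * unit
    return g
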