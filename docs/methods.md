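# Methods

This note documents the model implemented by fragopt, the choices made
where the design was genuinely open, and what the shipped test systems do
and do not show about real calculations.

## Energy model

The total energy is a two-body fragment expansion

E = Σ_I E⁰_I + Σ_{near pairs} (ΔE_IJ − E_pol,IJ) + Σ_{far pairs} E^elec_IJ + E_pol^tot (+ E_corr(H)),

with all internal arithmetic in Hartree atomic units (lengths in Bohr);
file I/O, restraints and reaction coordinates use Å (1 Bohr =
0.52917721067 Å), and rendered tables also give kcal/mol (627.509474
kcal/mol per Hartree).

**Pair classification.** A pair is computed quantum mechanically when its
unitless relative distance R_IJ = min over atom pairs of r_ab/(R_a + R_b),
with Bondi van der Waals radii, is at most the dimer cutoff (default
1.5).  This vdW-scaled definition is the convention of the fragment
molecular orbital code lineage; the cutoff is dimensionless by
construction.  Far pairs interact through the Coulomb energy of their
atom-centered partial charges only — no distributed dipoles or
quadrupoles.  That truncation is deliberate and isolated: the backend
contract supplies charges per atom, and a higher multipole order could be
added behind the same interface without touching the assembly.

**Monomers are unembedded.** Fragment calculations see no embedding
potential; many-body polarization is restored classically (below).  This
makes monomer and dimer records pure functions of their own coordinates,
which is what permits content-addressed caching.

## Classical polarization

Every atom carries an isotropic polarizability α_i and a fixed charge
q_i, both supplied by the backend.  Induced dipoles solve

μ_i = α_i (F_i^static + Σ_{j≠i} T_ij μ_j),

where F_i^static collects fields from *other* fragments' charges and the
dipole tensor T couples only inter-fragment site pairs.  Intra-fragment
fields and couplings are excluded because a fragment's internal response
is already inside its quantum monomer energy.  E_pol = −½ Σ μ_i·F_i^static;
the pair term E_pol,IJ is the same functional restricted to the isolated
pair {I, J}.

Numerics: Jacobi iteration (tolerance 1e-10 a.u. on the dipole change,
200 iterations max) is the production solver; a dense solve of
(α⁻¹ − T)μ = F is kept as the independent oracle, and the two agree to
better than 1e-10 Hartree on the test systems.  Divergence (possible when
α r⁻³ ≳ 1 for close site pairs) raises an error carrying the last
residual rather than returning garbage.  No short-range damping is
applied by default; Thole-style exponential damping of the dipole–dipole
coupling (a = 0.39) is available behind `pol.damping: thole` and is
covered by the gradient consistency tests.  During frozen-domain runs
E_pol^tot spans all fragments by default; `pol.span: active_buffer`
restricts it to b ∪ A, and both paths are tested.

One property worth stating precisely: the total induction energy is *not*
the sum of isolated pair energies, and this discrepancy does not vanish
even if the dipole–dipole coupling T is switched off — with T = 0,
E_pol^tot = −½ Σ α_i |Σ_J F_i^(J)|² retains field cross terms F^(J)·F^(K)
that the pair sum lacks.  Equality holds only for two fragments.  The
tests assert the two-fragment identity and the three-fragment inequality.

## Hybrid RHF:MP2

The hybrid energy is formed by adding the MP2 correlation energy of the
single high-level fragment H, computed in H's own basis, onto the RHF
expansion in which H's monomer and dimers also use H's basis and all
other fragments use the RHF basis.  The correction is strictly additive:
the implementation forms the RHF subtotal first and adds E_corr(H) as the
final floating-point operation, so `hybrid_total == rhf_total + E_corr(H)`
holds bitwise and the gradient difference lives exactly on H's atoms.

## Gradients

Only active-domain atoms are optimization variables, so the gradient
report is the derivative of the assembled energy with respect to those
coordinates, zero-masked elsewhere.  Charges and polarizabilities of all
fragments are constants of the run (frozen densities); consequently the
polarization gradient needs only the explicit position dependence of the
static fields and dipole tensors, evaluated at the converged dipoles
(Hellmann–Feynman, since the induction energy is variational in μ).  The
resulting gradient is exact *for the implemented energy*; its correctness
criterion throughout is agreement with central finite differences of that
energy (step 1e-4 Bohr, tolerance 1e-7 Hartree/Bohr on the mock backend),
not parity with any external code.

## Frozen domains and caching

Every monomer/dimer record is keyed by a hash of its atoms' coordinates
(rounded to 1e-10 Bohr), the level, and the basis label.  Since F- and
b-domain atoms never move, their records are computed on the first
evaluation and served from cache forever after — the "computed exactly
once" contract is an emergent property of content addressing, and the
audit table (computes/hits per fragment and pair, tagged by domain)
verifies it.  Disabling the frozen-domain mode simply bypasses the cache;
assembled totals are bitwise identical either way.  Pairs wholly inside F
remain part of the energy (they contribute a constant) but are excluded
from the per-step recomputation set.

## Optimizer and adiabatic mapping

Restrained minimization uses Cartesian BFGS with an Armijo backtracking
line search over the active-domain coordinates; accepted steps never
increase the objective, and convergence tests the max (default) or RMS
gradient component *including* restraint forces against the tolerance
(default 1e-4 Hartree/Bohr).  Harmonic distance restraints ½k(r − r₀)²
use k in kcal·mol⁻¹·Å⁻² (default 500) — the dimensionally coherent
reading of a distance-restraint force constant.  Non-convergence within
the step budget returns a flagged result, not an exception, and a scan
continues past flagged points.  Scans are deterministic: no stochastic
elements enter unless a perturbation option seeded by `random_seed` is
explicitly enabled.

## The mock backend

The mock potential is the package's oracle, not a stand-in approximation
of any particular molecule.  Its parts:

* intra-fragment: harmonic terms on every atom pair, with per-element-pair
  force constants and reference lengths (the O–H/H–H entries make the
  rigid reference water an exact minimum); optional *coordinate terms* —
  1-D potentials on linear combinations of interatomic distances — for
  building engineered surfaces;
* inter-fragment: Lennard-Jones (σ from scaled vdW radii, ε from a
  per-element table) plus Coulomb over fixed per-element charges, shifted
  uniformly per fragment so they sum exactly to the fragment charge;
* mock correlation: −C₆ab/r⁶ over intra-fragment pairs, scaled by a
  per-basis factor (6-31G(d) 1.0, cc-pVDZ 1.1, cc-pVTZ 1.2), so E_corr is
  smooth, strictly negative and basis-dependent.

The C₆ values are deliberately small: a bonded pair is a stable minimum
of the harmonic + correlation sum only if 42·C₆/r₀⁸ < k, and the shipped
table satisfies that with an order of magnitude to spare.  (Larger
dispersion coefficients make the mock MP2 surface collapse under
optimization — a model artifact, not a property of the framework.)

Because the inter-fragment part is strictly pairwise in the atoms, the
two-body expansion with infinite cutoff and polarization off reproduces
the directly evaluated supersystem energy to machine precision; that is
the exactness oracle.  Real electronic structure is not pairwise, so this
is a property of the test harness, not a claim about chemistry.

## The toy reaction and its analytic reference

The scan fixture is a four-atom collinear substrate N(0)—C(1)—C(2)—C(3)
whose potential is built from coordinate terms in r₁ = r(N,C1) (breaking)
and r₂ = r(C3,C2) (forming): a stiff harmonic holds q₁ = r₁ + r₂ at S =
7 Bohr, a tilted quartic a((q₂)² − b²)² + c·q₂ (a = 0.016 Ha/Bohr⁴, b =
1.2 Bohr, c = −0.002 Ha/Bohr) puts a double well along q₂ = r₁ − r₂, a
harmonic fixes the central C–C scaffold, and three difference-coordinate
harmonics that vanish identically on the collinear path keep the chain
straight.  On the scan manifold (q₁ = S, scaffold at its reference) every
substrate pair distance is a function of R = q₂ alone, so the substrate
energy along the path — including its mock correlation — is an exactly
known 1-D function E(R).

Two spectator waters sit 12 Å (buffer domain) and 16 Å (frozen domain)
above the substrate.  The substrate's elements carry no mock charge,
polarizability, or LJ well, so the spectators exert no force on it: a
real enzyme anchors its substrate through many contacts, and a four-atom
toy has no such scaffold, so decoupling is the honest way to keep the
1-D reference rigorous while the spectators still exercise the
polarization, dimer and caching machinery among themselves.

**Restraint bias.**  Restraining r₁ and r₂ with force constant k_r acts
along R with effective stiffness k_R = k_r/2.  Each scan point therefore
samples E at the minimizer of E(R) + ½k_R(R − R_target)², slightly
downhill of the target — so the recovered barrier systematically
*underestimates* the analytic one.  The fixture computes this restrained
prediction on a fine grid from the same E(R); the scan reproduces it to
~5·10⁻⁵ kcal/mol, and the documented bias bound used in the tests is the
|prediction − analytic| gap plus a fixed 0.3 kcal/mol allowance for
residual off-path relaxation.  At k_r = 500 kcal·mol⁻¹·Å⁻² and a 21-point
grid over R ∈ [−1.4, 1.4] Bohr the bound is ≈1.16 kcal/mol against an
analytic barrier of 19.51 kcal/mol.

## What the fixtures do and do not show

The synthetic systems validate the *framework*: assembly identities,
gradient consistency, caching semantics, restraint bias, domain
bookkeeping.  They do not emulate real charge transfer, exchange
repulsion, anisotropic polarizabilities, conformational flexibility, or
covalent fragment boundaries (fragmentations that sever bonds are
unsupported by design).  Passing tests therefore certify that the
machinery computes its defined model exactly — not that the mock model
approximates any specific chemical system.

## Problem sizes and defaults

The shipped tests and the acceptance script use 1–10-water chains and
clusters (3–30 atoms), 12-site polarization systems, and the 10-atom toy
reaction scanned over 21 restrained optimizations — sizes chosen so that
every check runs against closed-form or dense-linear-algebra oracles.
Key defaults: dimer cutoff 1.5 (vdW-scaled), gradient tolerance 1e-4
Hartree/Bohr (1e-5 for the toy scan, whose analytic comparison deserves
the tighter setting), restraint force constant 500 kcal·mol⁻¹·Å⁻², Jacobi
tolerance 1e-10 a.u., finite-difference step 1e-4 Bohr.

## Known limitations

* Gradient response terms of frozen charges are exactly zero here because
  backend charges are geometry-independent; a real backend with
  geometry-dependent charges would make the neglected response terms an
  approximation (consistent with frozen densities, but worth restating).
* The far-pair interaction is charge–charge only.
* The pyscf adapter is functional but not exercised by the test suite,
  which is mock-backend only.
* Cartesian BFGS is adequate for the shipped systems; internal-coordinate
  optimization for stiff macromolecular cases is out of scope.
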