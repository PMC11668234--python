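# Methods

This note records the model, the conventions that had to be fixed, the
numerical choices, and what the built-in fixtures do and do not demonstrate.

## Energy model

The environment is a set of classical sites carrying fixed multipoles up to
quadrupoles and isotropic dipole polarizabilities (the induced-point-dipole
family of polarizable force fields, of which AMOEBA is the canonical member).
The coupled QM/MM energy is assembled from four terms plus a Lagrangian
coupling term:

* `E_self = 1/2 Σ_{k≠l} s^m_{kl} Σ_{LL'} M^L_k T^{LL'}_{kl} M^{L'}_l`, the
  screened self-interaction of the fixed multipoles, with the generalized
  Coulomb kernel `T^{LL'} = ∂^L/∂r_k^L ∂^{L'}/∂r_l^{L'} (1/|r_k − r_l|)`
  (derivatives with respect to `r_k` applied first — the sign convention is
  fixed once and enforced by finite-difference tests, because multipole sign
  conventions are a classic source of drift).
* `E_ele`, the QM–MM Coulomb term: multipoles against nuclei and density
  point charges, unscreened and undamped.
* `E_pol = −1/2 ⟨μ^d, E(qm) + E^p(M)⟩`, with the two induced-dipole sets
  solving `T μ^{d/p} = E(qm) + E^{d/p}(M)`.  The asymmetric pairing (direct
  dipoles contracted with the polarization field) is the defining form, not
  an error; the Lagrangian term `1/2⟨μ^p, Tμ^d − E − E^d⟩` restores
  variationality and vanishes at the solution.
* `E_qm`, the internal energy reported by the density provider.

The dipole set that acts back on the QM density — in the embedding operator
and in the gradient — is the average `(μ^d + μ^p)/2`.

## Conventions fixed here

* **Units.** Atomic units internally (bohr, hartree, e); Ångström at the
  file boundary (conversion factor 0.52917721092 Å/bohr); eV only in
  excitation output.
* **Quadrupoles.** Traceless Cartesian, stored packed (xx, xy, xz, yy, yz,
  zz), energy contraction `Θ : T` with *no* extra 1/2 or 1/3 factor.  Any
  internally consistent choice is acceptable as long as parameters,
  potentials, fields and gradients share it; fixture parameters are generated
  in this convention.
* **Screening.** Three factor sets over bond separations 1-2 … 1-5: `m`
  (self-energy, default 0, 0, 0.4, 0.8), `d` (direct field, default
  0, 0, 1, 1), `p` (polarization field and dipole–dipole coupling, default
  group based: 0 within a polarization group, 1 across).  Pairs more than
  four bonds apart are never screened.  Polarization groups default to the
  connected components of the bond graph.  All of this is configuration in
  the parameter file; the defaults follow common AMOEBA practice.
* **Dipole–dipole coupling inside T** carries the p-kind screening; the d/p
  distinction enters only through the source fields, so both equations share
  one matrix.

## Thole damping

Between two polarizable sites the kernel is built from `λ(u)/r` with
`u = r/(α_k α_l)^{1/6}` and the exponential damping family
`λ_3 = 1 − e^{−a u³}`, `λ_5 = 1 − (1 + v)e^{−v}`,
`λ_7 = 1 − (1 + v + 3v²/5)e^{−v}`,
`λ_9 = 1 − (1 + v + 18v²/35 + 9v³/35)e^{−v}` with `v = a u³`.  The potential-
level function `λ_1 = 1 − e^{−v} + a^{1/3} u Γ(2/3, v)` is included so the
damped tensors are literally the derivative ladder of `λ_1(u)/r`; tests
verify this by finite differences.  The pair width is `a = min(a_k, a_l)`
with the conventional default `a = 0.39`; setting a site's factor to zero
disables damping for its pairs exactly.  Damping applies only to
polarization-related kernels (source fields at polarizable sites, the
dipole–dipole coupling); the static self-energy and all QM–MM interactions
are undamped.  Fields from QM point charges are likewise undamped by
default — the density is a point discretization, not a diffuse charge, and
QM–MM polarization damping conventions vary between codes; the choice is
deliberate and localized in `qm_field_at_polarizable_sites`.

## Kernel evaluation

All interaction tensors come from one construction: the n-th Cartesian
derivative of a radial kernel is a sum over Kronecker-delta/position-vector
index pairings weighted by the radial ladder `g_k = ((1/r) d/dr)^k f(r)`.
For `f = 1/r`, `g_k = (−1)^k (2k−1)!!/r^{2k+1}`; damping multiplies `g_k` by
`λ_{2k+1}`.  Orders up to five are needed (quadrupole–quadrupole gradients);
damped kernels are implemented through order four (the damped tensors never
need order five because polarization gradients are QM-side and the QM sources
are point charges).  No fast summation is attempted: the double loops are
O(N²) and fine at the intended scale (tens to hundreds of sites).

## The model QM and the coupling loop

A real electronic-structure engine enters through a three-method contract:
report state labels, return the density (point charges at declared sites)
under a given external potential, and report the internal energy of a state
at a given density.  The built-in `ModelQM` implements it linearly:
`q = q⁰ + K V` with `K` symmetric, negative semidefinite, zero row sums
(graph-Laplacian construction, so charge is conserved identically and
polarization can only lower the energy).  Its internal energy is the
reorganization cost `1/2 δqᵀ(−K)⁺δq`, which makes `q = q⁰ + K V` the
*variational* response — the coupled fixed point is then a genuine stationary
point of the total energy, which is what validates the explicit-only gradient
and is exploited by the finite-difference tests.

The SCF loop alternates: embedding potential at the density sites (static
multipoles + average induced dipoles) → density response → QM field at the
polarizable sites → dipole solve.  Convergence requires the energy change
below `tol_E` (default 1e-9 hartree) and the max-norm dipole and charge
changes below `tol_mu` (default 1e-7); a first pass in which neither dipoles
nor charges move is accepted immediately (purely static problem).  Plain
fixed-point iteration with optional linear mixing (default 1.0; 0.5 is
adequate for stiff response matrices); no extrapolation between cycles —
each dipole solve starts from the previous solution.  For the linear model
the fixed point is unique, and tests confirm independence of the starting
guess and agreement with a monolithic dense solve of the joint
dipole+charge system to 1e-8.

Dipole solves use dense Cholesky below 600 scalar unknowns and Jacobi-
preconditioned conjugate gradients above (relative residual 1e-8, max 200
iterations); the matrix assembly checks positive definiteness and names the
closest polarizable pair when conditioning fails.

## Gradients and optimization

Only explicit derivatives are evaluated.  The electrostatic gradient of a QM
atom is `Z_α ∇φ(r_α)` plus the rigid-follow contribution of its density
sites (each density point rides with a declared host atom; a real provider
would supply its own integral derivatives instead).  The polarization
gradient contracts `(μ^d + μ^p)` with the derivative of the QM point-charge
field — the extra `μ^p` half relative to the energy is the explicit
derivative of the Lagrangian coupling term.  MM-side gradients of the
self-energy and the QM–MM term (with frame-fixed multipoles) plus analytic
site torques (`μ × E` and the quadrupole commutator) are implemented to make
the translation/rotation conservation checks possible, even though the
optimizer freezes the environment.

Geometry optimization is BFGS over the unfrozen QM Cartesian coordinates
(scipy's implementation with Wolfe line search — chosen over a hand-rolled
backtracking scheme for robustness; accepted iterates are non-increasing in
energy), convergence at max |g| ≤ 4.5e-4 hartree/bohr by default.  All MM
sites are frozen by construction; individual QM components can be frozen
with a mask, and harmonic dihedral restraints (analytic gradient,
finite-difference validated) stand in for frozen-dihedral protocols.

## State-specific correction

At the converged state-averaged environment, for each state X the dipoles
are re-solved with that state's density and
`E_corr^X = E_elepol(γ^X, μ(γ^X)) − E_elepol(γ^X, μ(γ̄))`, where `E_elepol`
is the sum of the QM–MM electrostatic and polarization terms with the
indicated density/dipoles; the corrected excitation is
`ΔE_SS = ΔE_SA + E_corr^F − E_corr^I`.  The electrostatic part cancels in
the difference when the densities are fixed point sets; it is computed
anyway, following the defining expression.  The correction solves use the
same screening and damping settings as the state-averaged solve.  Each
`E_corr^X ≤ 0` (re-relaxation is variational), and the correction vanishes
identically when a state's density equals the average.  For the model QM,
the state-averaged "state" is the equal-weight mean of the state base
charges, and the model's ΔE_SA is defined as the difference of the per-state
energies (internal + electrostatic + polarization) under the frozen
state-averaged embedding.

## Fixtures: what they emulate and what they do not

The generators produce seeded, minimum-separation (1.5 bohr) geometries:
random multipolar chains ("molecules" of 2–4 bonded sites, |q| ≤ 0.5 e,
polarizabilities 0.5–3 bohr³), water-like rigid trimers with textbook point
charges and polarizabilities (O 5.65, H 3.35 bohr³, Thole 0.39), and a
coupled model-QM case (three nuclei with on-atom density charges, a 0.3 e
intramolecular charge-transfer difference between two states, response
scale 0.2 e²/hartree, placed 9 bohr from a six-site MM cluster).  These
exercise every equation at realistic magnitudes, but they are *not* protein
environments: no bonded or van-der-Waals terms, no link atoms, no periodic
boundary conditions, no real electronic structure.  Passing tests establish
the correctness of the coupling machinery — kernels, solvers, fixed points,
gradients — not the accuracy of any force field for a real system.

## Numerical choices and degenerate inputs

* Tolerances: SCF 1e-9/1e-7 (energy/max-norm) by default, tightened to
  1e-13/1e-11 in gradient tests so finite-difference noise stays below the
  1e-6 hartree/bohr comparison threshold (central differences, step 1e-4
  bohr; Richardson extrapolation available).
* Coincident points: undamped kernels raise a singularity error naming the
  pair; damped kernels are finite by construction at short range but still
  reject exactly zero separation.
* Systems with no polarizable sites (or no density sites) short-circuit the
  corresponding terms to zero rather than assembling empty operators.
* Fixture generation is rejection sampling with a deterministic generator;
  unsatisfiable packing raises after a bounded number of attempts.
* Problem sizes: the test suite and the acceptance script run clusters of
  5–50 polarizable sites and a 3-atom model QM region — large enough for
  every code path (screened/unscreened, damped/undamped, CG/dense), small
  enough that the whole suite runs in well under a minute.

## Known limitations

* Fixed multipoles live in the global frame: there is no local-frame
  definition or multipole rotation with molecular orientation, so MM
  torques/forces are meaningful for validation, not for MM dynamics.
* The point-charge density contract cannot represent penetration effects or
  continuous densities; integral derivatives are the provider's job.
* No Ewald/PME, cutoffs, or fast multipole summation; O(N²) throughout.
* The CASSCF-side machinery (orbital optimization, CI, state averaging
  itself) is outside the scope of the density-provider contract.
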