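# polembed

Polarizable-embedding QM/MM machinery at desk scale: AMOEBA-style multipole
electrostatics, dual-set induced point dipoles with Thole damping, a
self-consistent coupling loop against a pluggable QM density provider,
analytical geometrical gradients with a frozen-environment optimizer, and the
a-posteriori state-specific correction to state-averaged excitation energies.

## Who this is for

Developers and students of polarizable QM/MM methods who need every coupling
equation of an induced-point-dipole embedding — energies, fields, dipole
solvers, gradients, the mutual-polarization loop — as small, tested,
importable pieces, without dragging in an electronic-structure code.  The QM
side is a *contract* (potentials in, point-charge density and internal energy
out); a built-in linear-response model QM makes the full coupled problem
exercisable and exactly checkable against dense linear algebra.

## The model

The total energy of a QM region embedded in a classical polarizable
environment is assembled from a Lagrangian

```
L = E_QM(density) + E_self(M) + E_ele(density, M) + E_pol
      + 1/2 <mu_p, T mu_d - E(qm) - E_d(M)>
```

* **E_self** — self-interaction of the fixed multipoles `M^L` (charges,
  dipoles, traceless Cartesian quadrupoles), `1/2 Σ_{k≠l} s^m_{kl} Σ_{LL'}
  M^L_k T^{LL'}_{kl} M^{L'}_l`, with the generalized Coulomb kernel
  `T^{LL'} = ∂^L_k ∂^{L'}_l (1/|r_k − r_l|)` and per-pair screening factors
  `s^m` by bond separation.
* **E_ele** — unscreened Coulomb coupling of the multipoles to the QM nuclei
  and the (point-charge discretized) electron density.
* **E_pol = −1/2 ⟨mu_d, E(qm) + E_p(M)⟩** — induced-dipole relaxation.  Two
  dipole sets `mu_d`, `mu_p` solve `T mu = E(qm) + E_{d/p}(M)`, sharing one
  symmetric positive-definite matrix `T` (diagonal `α_k^{-1} I`, off-diagonal
  Thole-damped dipole tensors); they differ only through the screening of the
  multipole source fields (`s^d` by bond order, `s^p` by polarization group).
  Thole's exponential damping `λ_3 = 1 − exp(−a u³)`, `u = r/(α_k α_l)^{1/6}`
  keeps mutual induction finite at short range.
* The last term vanishes at stationarity and makes all geometry derivatives
  *explicit*: the electrostatic gradient follows from the kernel derivatives,
  the polarization gradient is `−1/2 Σ_k (mu_d + mu_p)_k · ∂E_k(qm)/∂r`.
* For excitations computed in a state-averaged scheme the environment
  responds to the averaged density; a state-specific correction
  `E_corr^X = E_elepol(γ^X, μ(γ^X)) − E_elepol(γ^X, μ(γ̄))` per state gives
  `ΔE_SS = ΔE_SA + (E_corr^F − E_corr^I)`.

Internal units are atomic (bohr, hartree, e); files use Ångström and
excitation output eV.

## Worked example

```sh
python examples/03_scf_embedding.py
```

```
converged in 4 iterations
  E_self          : +0.0675864543 hartree
  E_electrostatic : -0.0305622520 hartree
  E_polarization  : -0.0026882029 hartree
  E_qm_internal   : +0.0528174193 hartree
  E_total         : +0.0871534187 hartree
  Lagrangian penalty: -2.42e-19 hartree
```

A six-site multipolar MM cluster is coupled to the built-in model QM (three
nuclei with responding density charges).  The loop alternates density
response and dipole solution; four iterations reach stationarity, the
penalty term collapses to round-off, and the per-term decomposition sums
exactly to the total.  The other examples cover multipole electrostatics
(`01`), induced dipoles and Thole damping (`02`), gradient validation and
frozen-environment optimization (`04`), and state-specific excitation
corrections (`05`).

A thin CLI wraps the same library calls:

```sh
polembed fixture --kind model_qm_case --n 6 --seed 5 --outdir case
polembed energy   --geometry case/mm.xyz --params case/params.json --qm case/qm.json
polembed gradient --geometry case/mm.xyz --params case/params.json --qm case/qm.json --check-fd
polembed excite   --geometry case/mm.xyz --params case/params.json --qm case/qm.json
```

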