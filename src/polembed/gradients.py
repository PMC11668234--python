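"""Analytical geometrical gradients of the embedding terms, a universal
finite-difference validator, and a frozen-environment geometry optimizer.

Only *explicit* position derivatives are needed: at the coupled fixed point
the Lagrangian is stationary in the induced dipoles and (for the built-in
model QM) in the density charges, so the response terms drop out.  The
polarization gradient contracts the *sum* mu^d + mu^p with the derivative of
the QM field — the extra mu^p half relative to the energy expression is the
explicit derivative of the Lagrangian coupling term, which vanishes in value
but not in gradient.

Density points ride rigidly with their host atoms under differentiation; a
real QM provider would instead supply its own integral-derivative terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .electrostatics import potential_and_field_at_points, source_potential_derivs
from .embedding import (
    DensityProvider,
    EmbeddingState,
    QMRegion,
    scf_loop,
    total_energy,
)
from .mmsystem import MMSystem, QMDensity, screening_matrix

__all__ = [
    "GradientReport",
    "DihedralRestraint",
    "OptimizationResult",
    "grad_electrostatic",
    "grad_polarization",
    "qm_gradients",
    "mm_gradient_self_energy",
    "mm_gradient_electrostatic",
    "mm_torques",
    "validate_fd",
    "optimize_qm",
]


@dataclass(frozen=True)
class GradientReport:
    """Per-atom gradients (hartree/bohr) split by energy term."""

    electrostatic: np.ndarray  # (A, 3)
    polarization: np.ndarray
    qm_internal: np.ndarray
    max_fd_deviation: float | None = None

    @property
    def total(self) -> np.ndarray:
        return self.electrostatic + self.polarization + self.qm_internal


def grad_electrostatic(system: MMSystem, density: QMDensity, region: QMRegion) -> np.ndarray:
    """d E_ele / d r_alpha for each QM atom (static multipoles only).

    The nuclear term is Z_alpha grad(phi) at the nucleus; density charges
    contribute through their host atoms (rigid-follow map).
    """
    if len(density.density_charges) and region.n_sites != len(density.density_charges):
        raise ValueError("density sites present but region map does not match")
    grads = np.zeros((region.n_atoms, 3))
    if region.n_atoms:
        _, e_nuc, _ = potential_and_field_at_points(system, density.nuclei_positions)
        grads -= density.nuclear_charges[:, None] * e_nuc  # grad(phi) = -E
    if region.n_sites:
        _, e_dens, _ = potential_and_field_at_points(system, density.density_positions)
        np.add.at(grads, region.site_atoms, -density.density_charges[:, None] * e_dens)
    return grads


def _qm_charge_points(density: QMDensity, region: QMRegion):
    """(positions, charges, host-atom index) for every QM point charge."""
    pos = density.all_positions
    q = density.all_charges
    atoms = np.concatenate(
        [np.arange(region.n_atoms), region.site_atoms]
    )
    return pos, q, atoms


def grad_polarization(
    system: MMSystem, dipoles, density: QMDensity, region: QMRegion
) -> np.ndarray:
    """-1/2 sum_k (mu^d + mu^p)_k . dE_k(qm)/dr_alpha for each QM atom.

    Dipoles are held fixed (explicit derivative only) — valid only at the
    converged fixed point, where the implicit response terms vanish by
    stationarity.
    """
    grads = np.zeros((region.n_atoms, 3))
    pol = system.polarizable_indices
    if len(pol) == 0:
        return grads
    mu_sum = dipoles.mu_d + dipoles.mu_p
    pos, q, atoms = _qm_charge_points(density, region)
    for i, k in enumerate(pol):
        rk = system.positions[k]
        for c in range(len(q)):
            x = rk - pos[c]
            r = np.linalg.norm(x)
            # dE_k/dr_c = q_c grad grad (1/r) = q_c (3 x x^T - r^2 I)/r^5
            hess = q[c] * (3.0 * np.outer(x, x) - r**2 * np.eye(3)) / r**5
            grads[atoms[c]] -= 0.5 * (mu_sum[i] @ hess)
    return grads


def qm_gradients(
    system: MMSystem, region: QMRegion, state: EmbeddingState
) -> GradientReport:
    """Per-atom analytic gradient of the converged total energy."""
    if not state.converged:
        raise RuntimeError("gradients require a converged embedding state")
    g_ele = grad_electrostatic(system, state.density, region)
    g_pol = grad_polarization(system, state.dipoles, state.density, region)
    return GradientReport(
        electrostatic=g_ele,
        polarization=g_pol,
        qm_internal=np.zeros_like(g_ele),
    )


def _site_potential_derivs(system: MMSystem, k: int, n_max: int,
                           kind: str = "m", density: QMDensity | None = None):
    """Screened derivatives of the potential at MM site k from the other MM
    multipoles (``kind`` screening) plus, optionally, the QM point charges
    (unscreened)."""
    s = screening_matrix(system, kind)
    pos, q, mu, th = (
        system.positions,
        system.charges,
        system.dipoles,
        system.quadrupoles,
    )
    acc = [np.zeros((3,) * n) if n else 0.0 for n in range(n_max + 1)]
    for l in range(system.n_sites):
        if l == k or s[k, l] == 0.0:
            continue
        v = source_potential_derivs(
            pos[k] - pos[l], q[l], mu[l], th[l], n_max, context=f"sites {k},{l}"
        )
        for n in range(n_max + 1):
            acc[n] = acc[n] + s[k, l] * v[n]
    if density is not None:
        cpos, cq = density.all_positions, density.all_charges
        for c in range(len(cq)):
            v = source_potential_derivs(
                pos[k] - cpos[c], cq[c], np.zeros(3), np.zeros((3, 3)), n_max,
                context=f"MM site {k} / QM point {c}",
            )
            for n in range(n_max + 1):
                acc[n] = acc[n] + v[n]
    return acc


def mm_gradient_self_energy(system: MMSystem) -> np.ndarray:
    """d E_self / d r_k for every MM site (multipoles frame-fixed)."""
    grads = np.zeros((system.n_sites, 3))
    q, mu, th = system.charges, system.dipoles, system.quadrupoles
    for k in range(system.n_sites):
        v = _site_potential_derivs(system, k, 3, kind="m")
        grads[k] = (
            q[k] * v[1]
            + np.tensordot(v[2], mu[k], axes=([0], [0]))
            + np.tensordot(v[3], th[k], axes=([0, 1], [0, 1]))
        )
    return grads


def mm_gradient_electrostatic(system: MMSystem, density: QMDensity) -> np.ndarray:
    """d E_ele / d r_k for every MM site (QM charges as fixed sources)."""
    grads = np.zeros((system.n_sites, 3))
    q, mu, th = system.charges, system.dipoles, system.quadrupoles
    cpos, cq = density.all_positions, density.all_charges
    for k in range(system.n_sites):
        acc = [np.zeros((3,) * n) if n else 0.0 for n in range(4)]
        for c in range(len(cq)):
            v = source_potential_derivs(
                system.positions[k] - cpos[c], cq[c], np.zeros(3), np.zeros((3, 3)), 3,
                context=f"MM site {k} / QM point {c}",
            )
            for n in range(4):
                acc[n] = acc[n] + v[n]
        grads[k] = (
            q[k] * acc[1]
            + np.tensordot(acc[2], mu[k], axes=([0], [0]))
            + np.tensordot(acc[3], th[k], axes=([0, 1], [0, 1]))
        )
    return grads


def mm_torques(system: MMSystem, density: QMDensity | None = None) -> np.ndarray:
    """Torque on each MM site's fixed multipoles (self-energy sources with
    m-screening, plus unscreened QM charges when a density is given).

    tau = mu x E + quadrupole commutator term; together with the interaction
    forces these make the net torque of an isolated system vanish.
    """
    taus = np.zeros((system.n_sites, 3))
    for k in range(system.n_sites):
        v = _site_potential_derivs(system, k, 2, kind="m", density=density)
        e_loc = -np.asarray(v[1])
        taus[k] = np.cross(system.dipoles[k], e_loc)
        th, v2 = system.quadrupoles[k], np.asarray(v[2])
        c = th @ v2 - v2 @ th
        taus[k] += -np.array([c[1, 2] - c[2, 1], c[2, 0] - c[0, 2], c[0, 1] - c[1, 0]])
    return taus


def validate_fd(
    energy_fn,
    coords: np.ndarray,
    gradient: np.ndarray,
    step: float = 1e-3,
    richardson: bool = False,
):
    """Central-difference check of an analytic gradient.

    Returns (max deviation, finite-difference gradient).  With ``richardson``
    the two-step Richardson extrapolation (4 D(h/2) - D(h))/3 is used.
    """
    coords = np.asarray(coords, dtype=float)
    flat = coords.ravel().copy()
    grad = np.asarray(gradient, dtype=float).ravel()
    fd = np.zeros_like(flat)

    def central(h, i):
        x = flat.copy()
        x[i] += h
        ep = energy_fn(x.reshape(coords.shape))
        x[i] -= 2 * h
        em = energy_fn(x.reshape(coords.shape))
        for e, sgn in ((ep, +h), (em, -h)):
            if not np.isfinite(e):
                raise FloatingPointError(
                    f"non-finite energy at coordinate {i} displaced by {sgn:+.2e}"
                )
        return (ep - em) / (2 * h)

    for i in range(len(flat)):
        d = central(step, i)
        if richardson:
            d = (4.0 * central(step / 2, i) - d) / 3.0
        fd[i] = d
    dev = float(np.max(np.abs(fd - grad), initial=0.0))
    return dev, fd.reshape(coords.shape)


@dataclass(frozen=True)
class DihedralRestraint:
    """Harmonic restraint 1/2 k (phi - phi0)^2 on a proper dihedral.

    ``atoms`` are four QM atom indices; ``target`` in radians; ``force_k`` in
    hartree/rad^2.  The angle difference is wrapped to (-pi, pi].
    """

    atoms: tuple
    target: float
    force_k: float

    def angle(self, positions: np.ndarray) -> float:
        p0, p1, p2, p3 = (positions[a] for a in self.atoms)
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        return float(np.arctan2(m1 @ n2, n1 @ n2))

    def energy_and_gradient(self, positions: np.ndarray):
        p0, p1, p2, p3 = (positions[a] for a in self.atoms)
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        phi = float(np.arctan2(np.cross(n1, b2 / nb2) @ n2, n1 @ n2))
        dphi = (phi - self.target + np.pi) % (2 * np.pi) - np.pi
        energy = 0.5 * self.force_k * dphi**2

        g0 = nb2 / (n1 @ n1) * n1
        g3 = -nb2 / (n2 @ n2) * n2
        c1 = (b1 @ b2) / nb2**2
        c3 = (b3 @ b2) / nb2**2
        g1 = -(1.0 + c1) * g0 + c3 * g3
        g2 = c1 * g0 - (1.0 + c3) * g3
        grad = np.zeros_like(positions)
        pref = self.force_k * dphi
        for a, g in zip(self.atoms, (g0, g1, g2, g3)):
            grad[a] += pref * g
        return energy, grad


@dataclass
class OptimizationResult:
    """Trajectory and diagnostics of a frozen-environment minimization."""

    positions: np.ndarray  # final QM atom positions (A, 3)
    trajectory: list  # accepted geometries, (A, 3) each
    energies: list
    gradient_norms: list
    converged: bool
    n_steps: int
    final_state: EmbeddingState | None = None


class OptimizerError(RuntimeError):
    pass


def optimize_qm(
    system: MMSystem,
    provider: DensityProvider,
    initial_positions: np.ndarray | None = None,
    frozen_mask: np.ndarray | None = None,
    restraints: tuple = (),
    state_label: str = "SA",
    gtol: float = 4.5e-4,
    max_steps: int = 200,
    scf_kwargs: dict | None = None,
) -> OptimizationResult:
    """Minimize the total energy over the unfrozen QM coordinates (BFGS).

    All MM sites are frozen by construction (they are not variables);
    ``frozen_mask`` additionally freezes individual QM Cartesian components
    (boolean, shape (A, 3)).  Convergence when max |g| <= ``gtol``
    hartree/bohr on the free coordinates.
    """
    region = provider.region
    x_full = (
        region.atom_positions.copy()
        if initial_positions is None
        else np.asarray(initial_positions, dtype=float).reshape(-1, 3).copy()
    )
    mask = (
        np.zeros_like(x_full, dtype=bool)
        if frozen_mask is None
        else np.asarray(frozen_mask, dtype=bool).reshape(x_full.shape)
    )
    free = ~mask.ravel()
    scf_kwargs = dict(scf_kwargs or {})

    cache = {}

    def embed(positions):
        key = positions.tobytes()
        if key not in cache:
            cache.clear()  # keep only the current geometry
            cache[key] = scf_loop(
                system, provider, state_label=state_label,
                atom_positions=positions, **scf_kwargs,
            )
        return cache[key]

    def unpack(xfree):
        pos = x_full.copy()
        pos.ravel()[free] = xfree
        return pos

    def fun(xfree):
        pos = unpack(xfree)
        state = embed(pos)
        e = total_energy(state)
        g = qm_gradients(system, region, state).total
        for r in restraints:
            er, gr = r.energy_and_gradient(pos)
            e += er
            g = g + gr
        return e, g.ravel()[free]

    trajectory, energies, gnorms = [], [], []

    def record(xfree):
        pos = unpack(xfree)
        e, g = fun(xfree)
        trajectory.append(pos)
        energies.append(e)
        gnorms.append(float(np.max(np.abs(g), initial=0.0)))

    x0 = x_full.ravel()[free]
    record(x0)
    res = minimize(
        fun,
        x0,
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_steps, "norm": np.inf},
        callback=record,
    )
    final_pos = unpack(res.x)
    converged = bool(np.max(np.abs(res.jac), initial=0.0) <= gtol)
    if not converged:
        raise OptimizerError(
            f"optimizer stopped without convergence after {res.nit} steps "
            f"(max |g| = {np.max(np.abs(res.jac)):.3e}; {res.message})"
        )
    return OptimizationResult(
        positions=final_pos,
        trajectory=trajectory,
        energies=energies,
        gradient_norms=gnorms,
        converged=converged,
        n_steps=int(res.nit),
        final_state=embed(final_pos),
    )
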