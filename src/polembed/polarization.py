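"""Induced-dipole equations: assemble T, solve for mu^d / mu^p, energies.

The polarization unknowns satisfy the two linear systems

    T mu^d = E(qm) + E^d(M)      T mu^p = E(qm) + E^p(M)

sharing one symmetric positive-definite matrix T whose diagonal blocks are
alpha_k^{-1} I and whose off-diagonal blocks are the Thole-damped dipole
interaction tensors (p-kind screening).  The two right-hand sides differ only
through the screening of the multipole source fields, which is why AMOEBA
carries two dipole sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.sparse.linalg import LinearOperator, cg

from .electrostatics import (
    FieldSet,
    _kernel_tensors,
    multipole_field,
    pair_damping,
)
from .mmsystem import MMSystem, screening_matrix

__all__ = [
    "InducedDipoles",
    "ConvergenceError",
    "ConditioningError",
    "assemble_T",
    "solve_dipoles",
    "polarization_energy",
    "lagrangian_penalty",
]

#: switch from dense factorization to CG above this many scalar unknowns
DENSE_LIMIT = 600


class ConvergenceError(RuntimeError):
    """Iterative dipole solver failed to reach the requested residual."""

    def __init__(self, message, residual_trace=None):
        super().__init__(message)
        self.residual_trace = residual_trace


class ConditioningError(RuntimeError):
    """Polarization matrix is (near-)singular."""


@dataclass(frozen=True)
class InducedDipoles:
    """The two converged induced-dipole sets over the polarizable sites."""

    mu_d: np.ndarray  # (N_pol, 3), e*bohr
    mu_p: np.ndarray
    residual_norms: tuple = (0.0, 0.0)
    iterations: tuple = (0, 0)

    def __post_init__(self):
        d = np.asarray(self.mu_d, dtype=float).reshape(-1, 3)
        p = np.asarray(self.mu_p, dtype=float).reshape(-1, 3)
        if d.shape != p.shape:
            raise ValueError("mu_d and mu_p must have matching shapes")
        object.__setattr__(self, "mu_d", d)
        object.__setattr__(self, "mu_p", p)

    @property
    def average(self) -> np.ndarray:
        """(mu_d + mu_p)/2 — the set that couples back to the QM density."""
        return 0.5 * (self.mu_d + self.mu_p)


def dipole_interaction_block(system: MMSystem, k: int, l: int) -> np.ndarray:
    """Damped T^11 block between polarizable sites k and l (3x3)."""
    alpha, a = system.polarizabilities, system.thole_factors
    damping = pair_damping(alpha[k], alpha[l], a[k], a[l])
    x = system.positions[k] - system.positions[l]
    t = _kernel_tensors(x, 2, damping, context=f"sites {k},{l}")
    return -t[2]  # T^{11} = (-1)^{L'=1} grad^2 f


def assemble_T(system: MMSystem, check_conditioning: bool = True) -> np.ndarray:
    """Polarization matrix T (3N_pol x 3N_pol), symmetric positive definite.

    Diagonal blocks alpha_k^{-1} I; off-diagonal blocks s^p_{kl} T^11_{kl}
    with Thole damping.
    """
    pol = system.polarizable_indices
    n = len(pol)
    if n == 0:
        raise ValueError("system has no polarizable sites")
    alpha = system.polarizabilities
    if np.any(alpha[pol] <= 0):
        raise ValueError("polarizable sites must have alpha > 0")
    sp = screening_matrix(system, "p")
    T = np.zeros((3 * n, 3 * n))
    for i, k in enumerate(pol):
        T[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = np.eye(3) / alpha[k]
        for j in range(i + 1, n):
            l = pol[j]
            if sp[k, l] == 0.0:
                continue
            block = sp[k, l] * dipole_interaction_block(system, k, l)
            T[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            T[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block.T
    if check_conditioning:
        w = eigh(T, eigvals_only=True, subset_by_index=[0, 0])
        if w[0] < 1e-10:
            k, l = _closest_polarizable_pair(system)
            raise ConditioningError(
                f"polarization matrix near-singular (min eigenvalue {w[0]:.3e}); "
                f"closest polarizable pair: sites {k} and {l}"
            )
    return T


def _closest_polarizable_pair(system):
    pol = system.polarizable_indices
    best, pair = np.inf, (None, None)
    for i, k in enumerate(pol):
        for l in pol[i + 1 :]:
            d = np.linalg.norm(system.positions[k] - system.positions[l])
            if d < best:
                best, pair = d, (int(k), int(l))
    return pair


def _as_field_array(field, n_pol):
    if field is None:
        return np.zeros((n_pol, 3))
    if isinstance(field, FieldSet):
        field = field.at_sites
    field = np.asarray(field, dtype=float).reshape(-1, 3)
    if len(field) != n_pol:
        raise ValueError("field must supply one vector per polarizable site")
    if not np.all(np.isfinite(field)):
        raise ValueError("non-finite external field")
    return field


def _solve_one(T, rhs, solver, cg_tol, max_iter, x0, alpha_diag):
    b = rhs.ravel()
    if solver == "dense":
        c = cho_factor(T)
        x = cho_solve(c, b)
        res = np.linalg.norm(T @ x - b)
        return x.reshape(-1, 3), res, 0
    # conjugate gradient with Jacobi (inverse-diagonal = alpha) preconditioner
    M = LinearOperator(T.shape, matvec=lambda v: alpha_diag * v)
    trace = []
    x, info = cg(
        T,
        b,
        x0=None if x0 is None else x0.ravel(),
        rtol=cg_tol,
        atol=0.0,
        maxiter=max_iter,
        M=M,
        callback=lambda xk: trace.append(np.linalg.norm(T @ xk - b)),
    )
    if info != 0:
        raise ConvergenceError(
            f"CG failed to converge within {max_iter} iterations "
            f"(last residual {trace[-1] if trace else np.nan:.3e})",
            residual_trace=trace,
        )
    return x.reshape(-1, 3), np.linalg.norm(T @ x - b), len(trace)


def solve_dipoles(
    system: MMSystem,
    qm_field=None,
    solver: str = "auto",
    cg_tol: float = 1e-8,
    max_iter: int = 200,
    guess: InducedDipoles | None = None,
    T: np.ndarray | None = None,
) -> InducedDipoles:
    """Solve the two polarization equations for mu^d and mu^p.

    Parameters
    ----------
    qm_field
        Field of the QM charge distribution at the polarizable sites
        (FieldSet or (N_pol, 3) array); zero when omitted.
    solver
        "dense", "cg", or "auto" (dense below 600 unknowns).
    guess
        Previous dipoles, used as the CG starting point.
    T
        Pre-assembled polarization matrix (avoids reassembly inside SCF loops).
    """
    pol = system.polarizable_indices
    n = len(pol)
    eqm = _as_field_array(qm_field, n)
    if T is None:
        T = assemble_T(system)
    if solver == "auto":
        solver = "dense" if T.shape[0] <= DENSE_LIMIT else "cg"
    if solver not in ("dense", "cg"):
        raise ValueError(f"unknown solver {solver!r}")
    alpha_diag = np.repeat(system.polarizabilities[pol], 3)

    rhs_d = eqm + multipole_field(system, "d").at_sites
    rhs_p = eqm + multipole_field(system, "p").at_sites
    mu_d, res_d, it_d = _solve_one(
        T, rhs_d, solver, cg_tol, max_iter,
        None if guess is None else guess.mu_d, alpha_diag,
    )
    mu_p, res_p, it_p = _solve_one(
        T, rhs_p, solver, cg_tol, max_iter,
        None if guess is None else guess.mu_p, alpha_diag,
    )
    return InducedDipoles(
        mu_d=mu_d, mu_p=mu_p, residual_norms=(res_d, res_p), iterations=(it_d, it_p)
    )


def polarization_energy(system: MMSystem, dipoles: InducedDipoles, qm_field=None) -> float:
    """E_pol = -1/2 <mu^d, E(qm) + E^p(M)> in hartree.

    The direct dipoles are contracted with the *polarization* source field —
    the asymmetry is the printed definition, not an error.
    """
    n = system.n_polarizable
    if dipoles.mu_d.shape != (n, 3):
        raise ValueError("dipole shape does not match polarizable-site count")
    eqm = _as_field_array(qm_field, n)
    ep = multipole_field(system, "p").at_sites
    return -0.5 * float(np.sum(dipoles.mu_d * (eqm + ep)))


def lagrangian_penalty(
    system: MMSystem,
    dipoles: InducedDipoles,
    qm_field=None,
    T: np.ndarray | None = None,
) -> float:
    """Lagrangian coupling term 1/2 <mu^p, T mu^d - E(qm) - E^d(M)>.

    Vanishes (to solver tolerance) at converged mu^d; away from the solution
    it grows linearly in the dipole error, which makes it a cheap stationarity
    diagnostic.
    """
    n = system.n_polarizable
    eqm = _as_field_array(qm_field, n)
    if T is None:
        T = assemble_T(system)
    rhs_d = (eqm + multipole_field(system, "d").at_sites).ravel()
    resid = T @ dipoles.mu_d.ravel() - rhs_d
    return 0.5 * float(dipoles.mu_p.ravel() @ resid)
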