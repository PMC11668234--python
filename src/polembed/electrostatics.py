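"""Interaction kernels, multipole potentials/fields, and the MM self-energy.

The generalized Coulomb kernel is the Cartesian derivative tensor

    T^{LL'}(r_k, r_l) = d^L/dr_k^L d^L'/dr_l^L' 1/|r_k - r_l|,

with derivatives with respect to r_k applied first, then r_l.  Since the
kernel depends only on x = r_k - r_l this reduces to (-1)^{L'} grad_x^{L+L'}
(1/|x|).  The damped variant replaces 1/r by lambda(u)/r with the Thole
exponential damping, u = r/(alpha_k alpha_l)^{1/6}; each inverse-power term in
the derivative ladder then acquires its own screening function lambda_3,
lambda_5, ... so the damped tensors stay exact derivatives of the damped
potential and remain finite as r -> 0 (no polarization catastrophe).

Multipole contraction convention (fixed package-wide): pair energies are the
full contraction sum_{LL'} M^L_k . T^{LL'} . M^{L'}_l with traceless Cartesian
quadrupoles and no extra 1/3 (or 1/2) normalization factor; potentials,
fields, gradients and the fixture parameters all share this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import gammaincc

from .mmsystem import MMSystem, screening_matrix

__all__ = [
    "FieldSet",
    "TholeDamping",
    "SingularityError",
    "coulomb_kernel",
    "damped_kernel",
    "self_energy",
    "multipole_field",
    "potential_and_field_at_points",
    "source_potential_derivs",
    "pair_damping",
]

_GAMMA_2_3 = gamma_fn(2.0 / 3.0)

#: odd double factorials (2k-1)!! for k = 0..5
_DFACT = np.array([1.0, 1.0, 3.0, 15.0, 105.0, 945.0])


class SingularityError(ValueError):
    """Raised when an undamped kernel is evaluated at coincident points."""


@dataclass(frozen=True)
class FieldSet:
    """Electric field vectors at the polarizable MM sites.

    ``kind`` records provenance: "direct" and "polarization" are the two
    multipole source fields (they differ only through screening), "qm" is the
    field of the QM charge distribution.
    """

    at_sites: np.ndarray  # (N_pol, 3), hartree/(e*bohr)
    kind: str

    def __post_init__(self):
        arr = np.asarray(self.at_sites, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite entries in {self.kind} field")
        object.__setattr__(self, "at_sites", arr)


@dataclass(frozen=True)
class TholeDamping:
    """Pair damping spec: width parameter ``a`` and length scale ``s``.

    ``s = (alpha_k alpha_l)^{1/6}`` so that u = r/s; ``a = 0`` disables
    damping exactly.
    """

    a: float
    s: float


def pair_damping(alpha_k, alpha_l, thole_k, thole_l) -> TholeDamping | None:
    """Damping spec for a site pair, or None when damping does not apply.

    Damping applies only between two polarizable sites (both alpha > 0) with
    nonzero Thole factors; the pair width is min(a_k, a_l).
    """
    if alpha_k <= 0 or alpha_l <= 0:
        return None
    a = min(thole_k, thole_l)
    if a == 0:
        return None
    return TholeDamping(a=a, s=(alpha_k * alpha_l) ** (1.0 / 6.0))


def _thole_lambdas(r: float, damping: TholeDamping, max_order: int) -> np.ndarray:
    """Screening functions lambda_1, lambda_3, ..., lambda_{2*max_order+1}.

    These are derivative-consistent: lambda_{2k+3} follows from lambda_{2k+1}
    through (1/r d/dr), so the damped g_k below are literally the derivative
    ladder of lambda_1(u)/r.
    """
    u = r / damping.s
    v = damping.a * u**3
    ev = np.exp(-v)
    lam = np.empty(max_order + 1)
    # lambda_1 = 1 - e^-v + a^{1/3} u Gamma(2/3, v); gammaincc is regularized
    lam[0] = 1.0 - ev + damping.a ** (1.0 / 3.0) * u * gammaincc(2.0 / 3.0, v) * _GAMMA_2_3
    if max_order >= 1:
        lam[1] = 1.0 - ev
    if max_order >= 2:
        lam[2] = 1.0 - (1.0 + v) * ev
    if max_order >= 3:
        lam[3] = 1.0 - (1.0 + v + 0.6 * v**2) * ev
    if max_order >= 4:
        lam[4] = 1.0 - (1.0 + v + (18.0 / 35.0) * v**2 + (9.0 / 35.0) * v**3) * ev
    if max_order >= 5:
        raise NotImplementedError("damped kernels implemented up to 4th derivatives")
    return lam


def _radial_g(r: float, max_order: int, damping: TholeDamping | None) -> np.ndarray:
    """g_k = ((1/r) d/dr)^k applied to the (possibly damped) 1/r, k=0..max."""
    k = np.arange(max_order + 1)
    g = (-1.0) ** k * _DFACT[k] / r ** (2 * k + 1)
    if damping is not None:
        g = g * _thole_lambdas(r, damping, max_order)
    return g


def _perfect_matchings(elems):
    if not elems:
        yield []
        return
    first = elems[0]
    for j in range(1, len(elems)):
        rest = elems[1:j] + elems[j + 1 :]
        for m in _perfect_matchings(rest):
            yield [(first, elems[j])] + m


@lru_cache(maxsize=None)
def _pairings(n: int):
    """All ways to pick m disjoint index pairs out of n positions, m=0..n//2.

    Returns tuples (pairs, singles) driving the tensor construction
    grad^n f = sum over pairings g_{n-m} * prod delta * prod x.
    """
    out = []
    idx = tuple(range(n))
    for m in range(n // 2 + 1):
        for paired in combinations(idx, 2 * m):
            singles = tuple(i for i in idx if i not in paired)
            for match in _perfect_matchings(list(paired)):
                out.append((tuple(match), singles))
    return tuple(out)


_LETTERS = "abcdef"
_I3 = np.eye(3)


def _deriv_tensor(x: np.ndarray, n: int, g: np.ndarray) -> np.ndarray | float:
    """n-th Cartesian derivative tensor of the radial kernel at x.

    grad^n f(|x|) = sum over delta/x pairings of the indices, each weighted by
    g_{n - #pairs}.
    """
    if n == 0:
        return float(g[0])
    T = np.zeros((3,) * n)
    for pairs, singles in _pairings(n):
        m = len(pairs)
        subs, ops = [], []
        for (i, j) in pairs:
            ops.append(_I3)
            subs.append(_LETTERS[i] + _LETTERS[j])
        for i in singles:
            ops.append(x)
            subs.append(_LETTERS[i])
        term = np.einsum(",".join(subs) + "->" + _LETTERS[:n], *ops)
        T += g[n - m] * term
    return T


def _kernel_tensors(
    x: np.ndarray, max_order: int, damping: TholeDamping | None, context: str = ""
):
    """List of grad^n f for n = 0..max_order; f = 1/r or damped."""
    r = float(np.linalg.norm(x))
    if r == 0.0:
        raise SingularityError(
            f"coincident points{(': ' + context) if context else ''}"
        )
    g = _radial_g(r, max_order, damping)
    return [_deriv_tensor(x, n, g) for n in range(max_order + 1)]


def coulomb_kernel(r_k, r_l, L: int, Lp: int):
    """Undamped generalized Coulomb kernel T^{LL'}(r_k, r_l).

    Rank L+L' Cartesian tensor (scalar for L=L'=0); the first L indices belong
    to derivatives with respect to r_k, the last L' to r_l.
    """
    _check_ranks(L, Lp)
    x = np.asarray(r_k, dtype=float) - np.asarray(r_l, dtype=float)
    t = _kernel_tensors(x, L + Lp, None, context=f"pair at {r_k} / {r_l}")
    return (-1.0) ** Lp * t[L + Lp]


def damped_kernel(r_k, r_l, L: int, Lp: int, alpha_k: float, alpha_l: float, thole: float):
    """Thole-damped kernel T^{LL'} built from lambda(u)/r.

    ``thole`` is the pair damping parameter a (use min of the two site
    factors); u = r/(alpha_k alpha_l)^{1/6}.  With a = 0 the undamped kernel
    is returned exactly.  All tensor elements stay finite as r -> 0 when
    damping is active.
    """
    _check_ranks(L, Lp)
    if thole == 0:
        return coulomb_kernel(r_k, r_l, L, Lp)
    if alpha_k <= 0 or alpha_l <= 0:
        raise ValueError("damping requires positive polarizabilities on both sites")
    damping = TholeDamping(a=thole, s=(alpha_k * alpha_l) ** (1.0 / 6.0))
    x = np.asarray(r_k, dtype=float) - np.asarray(r_l, dtype=float)
    t = _kernel_tensors(x, L + Lp, damping, context=f"pair at {r_k} / {r_l}")
    return (-1.0) ** Lp * t[L + Lp]


def _check_ranks(L, Lp):
    if L not in (0, 1, 2) or Lp not in (0, 1, 2):
        raise ValueError("multipole ranks must be in {0, 1, 2}")


def source_potential_derivs(
    x: np.ndarray,
    q: float,
    mu: np.ndarray,
    theta: np.ndarray,
    n_max: int,
    damping: TholeDamping | None = None,
    context: str = "",
):
    """Derivatives (orders 0..n_max) w.r.t. the observation point of the
    potential generated by a multipole source.

    ``x`` is observation minus source position.  Element n of the returned
    list is the rank-n tensor d^n phi / d r_obs^n; in particular the field is
    -result[1] and the field gradient -result[2].
    """
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    has_mu = np.any(mu != 0.0)
    has_theta = np.any(theta != 0.0)
    top = n_max + (2 if has_theta else (1 if has_mu else 0))
    t = _kernel_tensors(np.asarray(x, dtype=float), top, damping, context=context)
    out = []
    for n in range(n_max + 1):
        v = q * t[n]
        if has_mu:
            # dipole: (-1)^1 grad^{n+1} f . mu, contracted over the last index
            v = v - np.tensordot(t[n + 1], mu, axes=([-1], [0]))
        if has_theta:
            v = v + np.tensordot(t[n + 2], theta, axes=([-2, -1], [0, 1]))
        out.append(v)
    return out


def self_energy(system: MMSystem, return_pairs: bool = False):
    """Multipole self-interaction energy of the MM distribution (hartree).

    E_self = 1/2 sum_{k != l} s^m_{kl} sum_{LL'} M^L_k T^{LL'}_{kl} M^{L'}_l
    with undamped kernels.  Optionally returns the per-pair breakdown as a
    dict {(k, l): energy} over ordered pairs k < l.
    """
    s = screening_matrix(system, "m")
    pos, q, mu, th = (
        system.positions,
        system.charges,
        system.dipoles,
        system.quadrupoles,
    )
    total = 0.0
    pairs = {}
    n = system.n_sites
    for k in range(n):
        for l in range(k + 1, n):
            if s[k, l] == 0.0:
                continue
            v = source_potential_derivs(
                pos[k] - pos[l], q[l], mu[l], th[l], 2, context=f"sites {k},{l}"
            )
            e = s[k, l] * (
                q[k] * v[0]
                + mu[k] @ v[1]
                + float(np.tensordot(th[k], v[2], axes=([0, 1], [0, 1])))
            )
            total += e
            if return_pairs:
                pairs[(k, l)] = e
    return (total, pairs) if return_pairs else total


def multipole_field(system: MMSystem, kind: str) -> FieldSet:
    """Field of the fixed multipoles at every polarizable site.

    E_k = -sum_l s^{kind}_{kl} T^{1L}_{kl} M^L_l with Thole damping applied to
    every polarizable-polarizable pair (the fields drive induced dipoles).
    ``kind`` is "d" (direct) or "p" (polarization); they differ only through
    the screening factors.
    """
    if kind not in ("d", "p"):
        raise ValueError("multipole field kind must be 'd' or 'p'")
    s = screening_matrix(system, kind)
    pol = system.polarizable_indices
    pos, q, mu, th = (
        system.positions,
        system.charges,
        system.dipoles,
        system.quadrupoles,
    )
    alpha, a = system.polarizabilities, system.thole_factors
    fields = np.zeros((len(pol), 3))
    for i, k in enumerate(pol):
        acc = np.zeros(3)
        for l in range(system.n_sites):
            if l == k or s[k, l] == 0.0:
                continue
            damping = pair_damping(alpha[k], alpha[l], a[k], a[l])
            v = source_potential_derivs(
                pos[k] - pos[l], q[l], mu[l], th[l], 1, damping=damping,
                context=f"sites {k},{l}",
            )
            acc -= s[k, l] * v[1]
        fields[i] = acc
    return FieldSet(at_sites=fields, kind="direct" if kind == "d" else "polarization")


def potential_and_field_at_points(
    system: MMSystem,
    points: np.ndarray,
    dipoles: np.ndarray | None = None,
):
    """Potential, field and field gradient of the MM distribution at points.

    QM-MM interactions carry no screening and no damping, so the static
    multipole contribution is the bare Coulomb one.  When ``dipoles`` is given
    (one induced dipole per polarizable site) its contribution is added, also
    undamped.

    Returns
    -------
    (potentials, fields, field_gradients)
        Shapes (P,), (P, 3), (P, 3, 3); fields are -grad(phi) and field
        gradients -grad(grad(phi)).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    pos, q, mu, th = (
        system.positions,
        system.charges,
        system.dipoles.copy(),
        system.quadrupoles,
    )
    if dipoles is not None:
        dipoles = np.asarray(dipoles, dtype=float).reshape(-1, 3)
        pol = system.polarizable_indices
        if len(dipoles) != len(pol):
            raise ValueError("one induced dipole per polarizable site required")
        mu[pol] += dipoles
    phi = np.zeros(len(points))
    field = np.zeros((len(points), 3))
    grad = np.zeros((len(points), 3, 3))
    for p, rp in enumerate(points):
        for l in range(system.n_sites):
            v = source_potential_derivs(
                rp - pos[l], q[l], mu[l], th[l], 2,
                context=f"point {p} / MM site {l}",
            )
            phi[p] += v[0]
            field[p] -= v[1]
            grad[p] -= v[2]
    return phi, field, grad
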