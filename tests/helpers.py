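"""Independent oracles used by the tests.

Everything here is written from closed-form textbook expressions (explicit
charge/dipole/quadrupole field formulas, published Thole screening functions,
a monolithic dense solve of the coupled dipole+charge equations) and must not
call into the package's tensor machinery, so that agreement is a genuine
cross-check rather than a tautology.
"""

import dataclasses

import numpy as np

from polembed.mmsystem import build_system, pack_quadrupole, unpack_quadrupole
from polembed.mmsystem import screening_matrix


def thole_lams(r, a, s):
    """Published Thole exponential screening functions lambda_3,5,7."""
    v = a * (r / s) ** 3
    ev = np.exp(-v)
    return 1 - ev, 1 - (1 + v) * ev, 1 - (1 + v + 0.6 * v**2) * ev


def pair_damp_params(system, k, l):
    ak, al = system.polarizabilities[k], system.polarizabilities[l]
    tk, tl = system.thole_factors[k], system.thole_factors[l]
    if ak <= 0 or al <= 0 or min(tk, tl) == 0:
        return None
    return min(tk, tl), (ak * al) ** (1.0 / 6.0)


def field_from_site(x, q, mu, theta, damp=None):
    """Closed-form (possibly Thole-damped) field at x from a multipole source
    at the origin, in the package's traceless full-contraction convention."""
    r = np.linalg.norm(x)
    l3 = l5 = l7 = 1.0
    if damp is not None:
        l3, l5, l7 = thole_lams(r, *damp)
    e = l3 * q * x / r**3
    e += l5 * 3 * (mu @ x) * x / r**5 - l3 * mu / r**3
    e += -l5 * 6 * (theta @ x) / r**5 + l7 * 15 * (x @ theta @ x) * x / r**7
    return e


def brute_multipole_field(system, kind):
    """Double-loop screened multipole field at the polarizable sites."""
    s = screening_matrix(system, kind)
    pol = system.polarizable_indices
    out = np.zeros((len(pol), 3))
    for i, k in enumerate(pol):
        for l in range(system.n_sites):
            if l == k:
                continue
            x = system.positions[k] - system.positions[l]
            out[i] += s[k, l] * field_from_site(
                x,
                system.charges[l],
                system.dipoles[l],
                system.quadrupoles[l],
                damp=pair_damp_params(system, k, l),
            )
    return out


def brute_T(system):
    """Double-loop polarization matrix from the closed-form dipole tensor."""
    pol = system.polarizable_indices
    n = len(pol)
    sp = screening_matrix(system, "p")
    T = np.zeros((3 * n, 3 * n))
    for i, k in enumerate(pol):
        T[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = (
            np.eye(3) / system.polarizabilities[k]
        )
        for j, l in enumerate(pol):
            if j == i:
                continue
            x = system.positions[k] - system.positions[l]
            r = np.linalg.norm(x)
            damp = pair_damp_params(system, k, l)
            l3 = l5 = 1.0
            if damp is not None:
                l3, l5, _ = thole_lams(r, *damp)
            block = l3 * np.eye(3) / r**3 - l5 * 3 * np.outer(x, x) / r**5
            T[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = sp[k, l] * block
    return T


def qm_coupling_matrices(system, region):
    """A: field at pol sites per unit density charge; D: potential at density
    sites per unit dipole component; f_nuc: nuclear field at pol sites."""
    pol = system.polarizable_indices
    n = len(pol)
    dens = region.density_positions()
    m = len(dens)
    A = np.zeros((3 * n, m))
    D = np.zeros((m, 3 * n))
    f_nuc = np.zeros(3 * n)
    for i, k in enumerate(pol):
        rk = system.positions[k]
        for j in range(m):
            x = rk - dens[j]
            r = np.linalg.norm(x)
            A[3 * i : 3 * i + 3, j] = x / r**3
            D[j, 3 * i : 3 * i + 3] = -x / r**3  # potential at j from dipole at k
        for a in range(region.n_atoms):
            x = rk - region.atom_positions[a]
            f_nuc[3 * i : 3 * i + 3] += (
                region.nuclear_charges[a] * x / np.linalg.norm(x) ** 3
            )
    return A, D, f_nuc


def monolithic_fixed_point(system, model, label):
    """Dense solve of the coupled (mu_d, mu_p, dq) linear system."""
    from polembed.electrostatics import multipole_field, potential_and_field_at_points

    region = model.region
    pol = system.polarizable_indices
    n, m = len(pol), region.n_sites
    T = brute_T(system)
    A, D, f_nuc = qm_coupling_matrices(system, region)
    K = model.response
    q0 = model.base_charges[label]
    dens = region.density_positions()
    phi_stat, _, _ = potential_and_field_at_points(system, dens)
    e_d = multipole_field(system, "d").at_sites.ravel()
    e_p = multipole_field(system, "p").at_sites.ravel()

    nn = 3 * n
    M = np.zeros((2 * nn + m, 2 * nn + m))
    rhs = np.zeros(2 * nn + m)
    M[:nn, :nn] = T
    M[:nn, 2 * nn :] = -A
    rhs[:nn] = f_nuc + A @ q0 + e_d
    M[nn : 2 * nn, nn : 2 * nn] = T
    M[nn : 2 * nn, 2 * nn :] = -A
    rhs[nn : 2 * nn] = f_nuc + A @ q0 + e_p
    M[2 * nn :, :nn] = -0.5 * K @ D
    M[2 * nn :, nn : 2 * nn] = -0.5 * K @ D
    M[2 * nn :, 2 * nn :] = np.eye(m)
    rhs[2 * nn :] = K @ phi_stat
    sol = np.linalg.solve(M, rhs)
    mu_d = sol[:nn].reshape(n, 3)
    mu_p = sol[nn : 2 * nn].reshape(n, 3)
    charges = q0 + sol[2 * nn :]
    return mu_d, mu_p, charges


def rotate_system(system, R):
    """Rigidly rotate positions and multipole components."""
    sites = []
    for s in system.sites:
        th = unpack_quadrupole(s.quadrupole)
        sites.append(
            dataclasses.replace(
                s,
                position=R @ s.position,
                dipole=R @ s.dipole,
                quadrupole=pack_quadrupole(R @ th @ R.T),
            )
        )
    return build_system(sites, system.bonds, system.rules,
                        groups=list(system.group_ids))


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
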