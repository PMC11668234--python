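"""Mutual polarization: the two induced-dipole sets and Thole damping.

Solves the coupled dipole equations on a water-like trimer and shows the
polarization energy and the stationarity diagnostic.
"""

import numpy as np

from polembed import (
    assemble_T,
    damped_kernel,
    coulomb_kernel,
    lagrangian_penalty,
    polarization_energy,
    solve_dipoles,
)
from polembed.fixtures import make_water_like_cluster

cluster = make_water_like_cluster(3, seed=7)
T = assemble_T(cluster)
print(f"polarization matrix: {T.shape[0]} unknowns, "
      f"min eigenvalue {np.linalg.eigvalsh(T).min():.4f} (positive definite)")

dip = solve_dipoles(cluster)
e_pol = polarization_energy(cluster, dip)
pen = lagrangian_penalty(cluster, dip)
print(f"largest induced dipole |mu_d|: {np.linalg.norm(dip.mu_d, axis=1).max():.5f} e bohr")
print(f"polarization energy          : {e_pol:+.8f} hartree")
print(f"Lagrangian penalty           : {pen:+.2e} hartree (vanishes at stationarity)")
print("mu_d and mu_p differ only through the screening of their source")
print("fields.  For this water parameterization the d table and the")
print("group-based p rule remove exactly the same intramolecular pairs, so")
print("the two sets coincide — the equal-screening identity in action:")
print(f"max |mu_d - mu_p|            : {np.abs(dip.mu_d - dip.mu_p).max():.2e} e bohr")

# Thole damping keeps the dipole interaction finite at short range
r = 0.3
t_bare = coulomb_kernel([0, 0, 0], [r, 0, 0], 1, 1)
t_damp = damped_kernel([0, 0, 0], [r, 0, 0], 1, 1, 1.0, 1.0, 0.39)
print(f"dipole kernel norm at r={r} bohr: bare {np.linalg.norm(t_bare):.1f}, "
      f"damped {np.linalg.norm(t_damp):.3f}")
print("Damping removes the short-range divergence that would otherwise make")
print("mutual polarization blow up (the polarization catastrophe).")
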