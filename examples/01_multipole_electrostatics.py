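"""Fixed-multipole electrostatics: self-energy, fields, potentials.

Builds two tiny analytic systems and a random multipolar cluster, then prints
interaction energies against their closed forms.
"""

import numpy as np

from polembed import MMSite, build_system, self_energy, potential_and_field_at_points
from polembed.fixtures import make_random_cluster

# opposite unit charges 2 bohr apart: E = q1 q2 / r = -0.5 hartree
pair = build_system(
    [MMSite(index=0, position=[0, 0, 0], charge=1.0),
     MMSite(index=1, position=[2, 0, 0], charge=-1.0)]
)
print(f"charge pair energy      : {self_energy(pair):+.10f} hartree (exact -0.5)")

# collinear head-to-tail unit dipoles at 3 bohr: E = -2 mu^2 / r^3 = -2/27
dipoles = build_system(
    [MMSite(index=0, position=[0, 0, 0], dipole=[0, 0, 1.0]),
     MMSite(index=1, position=[0, 0, 3.0], dipole=[0, 0, 1.0])]
)
print(f"collinear dipole energy : {self_energy(dipoles):+.10f} hartree (exact {-2/27:+.10f})")

# a screened, bonded random cluster with charges, dipoles and quadrupoles
cluster = make_random_cluster(8, seed=42)
e = self_energy(cluster)
phi, field, grad = potential_and_field_at_points(cluster, [[12.0, 0.0, 0.0]])
print(f"8-site cluster self-energy        : {e:+.8f} hartree")
print(f"potential 12 bohr from the cluster: {phi[0]:+.8f} hartree/e")
print(f"field magnitude there             : {np.linalg.norm(field[0]):.3e} hartree/(e bohr)")
print("The self-energy sums all screened pair interactions of the fixed")
print("multipoles; the potential/field values are what a QM region embedded")
print("at that point would feel.")
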