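"""Unit conventions.

Everything in memory is in Hartree atomic units: lengths in bohr, energies in
hartree, charges in units of the elementary charge, dipoles in e*bohr,
quadrupoles in e*bohr^2, polarizabilities in bohr^3, fields in hartree/(e*bohr).
Angstrom appears only at the I/O boundary (XYZ files) and eV only in
excitation-energy output.
"""

ANGSTROM_PER_BOHR = 0.52917721092
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR
EV_PER_HARTREE = 27.211386245988


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def hartree_to_ev(x):
    return x * EV_PER_HARTREE
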