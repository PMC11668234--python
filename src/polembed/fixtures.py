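"""Deterministic fixture generation for tests, examples and the CLI.

Every generator is seeded and produces geometries with a guaranteed minimum
inter-site separation (1.5 bohr by default) so that undamped kernels stay
well away from their singularities.  ``model_qm_case`` additionally emits two
electronic-state densities and their equal-weight average for exercising the
state-specific correction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .embedding import ModelQM, QMRegion, with_state_average
from .mmsystem import MMSite, MMSystem, ScreeningRules, build_system, traceless_quadrupole
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "GenerationError",
    "make_dimer",
    "make_random_cluster",
    "make_water_like_cluster",
    "make_model_qm_case",
    "generate_fixture",
]

MIN_SEPARATION = 1.5  # bohr

#: AMOEBA-flavoured water parameters (charges in e, alphas in bohr^3)
_WATER_Q = {"O": -0.834, "H": 0.417}
_WATER_ALPHA = {"O": 0.837 * BOHR_PER_ANGSTROM**3, "H": 0.496 * BOHR_PER_ANGSTROM**3}
_OH = 0.9572 * BOHR_PER_ANGSTROM
_HOH = np.deg2rad(104.52)


class GenerationError(RuntimeError):
    """Packing or constraint failure during fixture generation."""


def make_dimer(separation: float = 3.0, q=(1.0, -1.0), alpha=(1.0, 1.0),
               thole: float = 0.39) -> MMSystem:
    """Two unbonded sites on the x axis — the minimal interaction fixture."""
    sites = [
        MMSite(index=0, position=[0.0, 0.0, 0.0], charge=q[0],
               polarizability=alpha[0], thole_factor=thole),
        MMSite(index=1, position=[separation, 0.0, 0.0], charge=q[1],
               polarizability=alpha[1], thole_factor=thole),
    ]
    return build_system(sites, bonds=(), rules=ScreeningRules())


def _pack_positions(rng, n, box, min_sep, max_tries=20000):
    pts = []
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(-box / 2, box / 2, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n} sites with separation {min_sep} "
                f"in a box of {box} bohr"
            )
    return np.array(pts)


def make_random_cluster(
    n: int,
    seed: int,
    min_sep: float = MIN_SEPARATION,
    polarizable_fraction: float = 1.0,
    with_multipoles: bool = True,
    rules: ScreeningRules | None = None,
) -> MMSystem:
    """Random multipolar cluster: sites in chains of 2-4 bonded neighbours.

    Charges, dipoles and traceless quadrupoles are drawn small (|q| <= 0.5 e)
    so interaction energies stay O(0.1) hartree; polarizabilities in
    [0.5, 3] bohr^3, Thole factor 0.39.
    """
    if n < 1:
        raise GenerationError("need at least one site")
    rng = np.random.default_rng(seed)
    box = max(6.0, 2.2 * min_sep * n ** (1 / 3) * 2)
    pos = _pack_positions(rng, n, box, min_sep)
    sites = []
    for i in range(n):
        quad = np.zeros(6)
        dip = np.zeros(3)
        if with_multipoles:
            raw = 0.2 * rng.standard_normal((3, 3))
            quad = traceless_quadrupole(0.5 * (raw + raw.T))
            dip = 0.2 * rng.standard_normal(3)
        polarizable = rng.random() < polarizable_fraction
        sites.append(
            MMSite(
                index=i,
                position=pos[i],
                charge=float(rng.uniform(-0.5, 0.5)),
                dipole=dip,
                quadrupole=quad,
                polarizability=float(rng.uniform(0.5, 3.0)) if polarizable else 0.0,
                thole_factor=0.39,
            )
        )
    # chain bonds within consecutive blocks of 2-4 sites ("molecules")
    bonds = []
    i = 0
    while i < n:
        block = min(int(rng.integers(2, 5)), n - i)
        for j in range(i, i + block - 1):
            bonds.append((j, j + 1))
        i += block
    return build_system(sites, bonds, rules if rules is not None else ScreeningRules())


def _water_geometry():
    h1 = np.array([_OH * np.sin(_HOH / 2), _OH * np.cos(_HOH / 2), 0.0])
    h2 = np.array([-_OH * np.sin(_HOH / 2), _OH * np.cos(_HOH / 2), 0.0])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def _random_rotation(rng):
    # QR of a Gaussian matrix with sign fix: Haar-uniform rotation
    m = rng.standard_normal((3, 3))
    qmat, r = np.linalg.qr(m)
    qmat *= np.sign(np.diag(r))
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] *= -1
    return qmat


def make_water_like_cluster(
    n_waters: int,
    seed: int,
    min_sep: float = 2.5,
    rules: ScreeningRules | None = None,
) -> MMSystem:
    """Cluster of rigid water-like molecules with polarizable O and H sites.

    Each molecule carries point charges (O -0.834, H +0.417), a small fixed
    dipole on the oxygen, isotropic polarizabilities and Thole factor 0.39;
    p-screening is group based, so mutual induction acts only between
    molecules.
    """
    if n_waters < 1:
        raise GenerationError("need at least one molecule")
    rng = np.random.default_rng(seed)
    centers = _pack_positions(rng, n_waters, box=max(8.0, 7.0 * n_waters ** (1 / 3)),
                              min_sep=max(min_sep, 5.0))
    template = _water_geometry()
    sites, bonds = [], []
    for m, c in enumerate(centers):
        rot = _random_rotation(rng)
        geom = template @ rot.T + c
        o_index = len(sites)
        for a, el in enumerate("OHH"):
            sites.append(
                MMSite(
                    index=o_index + a,
                    position=geom[a],
                    charge=_WATER_Q[el[0]],
                    dipole=(0.1 * rot @ np.array([0.0, 1.0, 0.0]))
                    if el == "O"
                    else np.zeros(3),
                    polarizability=_WATER_ALPHA[el[0]],
                    thole_factor=0.39,
                )
            )
        bonds += [(o_index, o_index + 1), (o_index, o_index + 2)]
    return build_system(sites, bonds, rules if rules is not None else ScreeningRules())


def make_model_qm_case(
    seed: int,
    n_mm: int = 6,
    n_qm_atoms: int = 3,
    response_scale: float = 0.2,
    qm_offset: float = 9.0,
):
    """Coupled MM cluster + linear-response model QM with two states.

    The MM cluster sits ``qm_offset`` bohr away from the QM triangle.  The QM
    region carries one density site per atom; the two electronic states
    differ by an intramolecular charge shift (same total charge), the
    state-averaged density is their equal-weight mean, and the response
    matrix is a scaled graph-Laplacian (symmetric, negative semidefinite,
    zero row sums).

    Returns (system, model) where ``model`` has states S0, S1 and SA.
    """
    rng = np.random.default_rng(seed)
    system = make_random_cluster(n_mm, seed=int(rng.integers(2**31)))
    shifted = system.positions + np.array([qm_offset, 0.0, 0.0])
    system = system.with_positions(shifted)

    # QM atoms: near-regular polygon around origin, slight jitter
    angles = 2 * np.pi * np.arange(n_qm_atoms) / n_qm_atoms
    atoms = np.stack(
        [2.0 * np.cos(angles), 2.0 * np.sin(angles), np.zeros(n_qm_atoms)], axis=1
    )
    atoms += 0.1 * rng.standard_normal(atoms.shape)
    nuclear_charges = np.ones(n_qm_atoms)
    region = QMRegion(
        atom_positions=atoms,
        nuclear_charges=nuclear_charges,
        site_atoms=np.arange(n_qm_atoms),
        site_offsets=np.zeros((n_qm_atoms, 3)),
    )
    # neutral states; S1 shifts charge along the ring
    q0 = -np.ones(n_qm_atoms)
    shift = 0.3 * (np.roll(np.eye(n_qm_atoms)[0], 1) - np.eye(n_qm_atoms)[0])
    q1 = q0 + shift
    # path-graph Laplacian response
    lap = np.zeros((n_qm_atoms, n_qm_atoms))
    for i in range(n_qm_atoms - 1):
        lap[i, i] += 1
        lap[i + 1, i + 1] += 1
        lap[i, i + 1] -= 1
        lap[i + 1, i] -= 1
    model = ModelQM(
        region=region,
        base_charges={"S0": q0, "S1": q1},
        response=-response_scale * lap,
        base_energies={"S0": 0.0, "S1": 0.1},
    )
    return system, with_state_average(model, ("S0", "S1"))


def generate_fixture(kind: str, n: int, seed: int, outdir) -> dict:
    """Write a fixture to disk; returns the mapping of artifact names to paths.

    Kinds: ``dimer_scan``, ``random_cluster``, ``water_like_cluster``,
    ``model_qm_case``.  Output is deterministic in (kind, n, seed):
    regenerating with the same arguments yields byte-identical files.
    """
    from .io import write_params, write_qm_spec, write_xyz

    if n < 1:
        raise GenerationError("n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def emit_system(system, elements=None):
        elements = elements or ["X"] * system.n_sites
        paths["geometry"] = str(outdir / "mm.xyz")
        paths["parameters"] = str(outdir / "params.json")
        write_xyz(paths["geometry"], elements, system.positions,
                  comment=f"{kind} n={n} seed={seed}")
        write_params(paths["parameters"], system)
        return system

    if kind == "dimer_scan":
        system = emit_system(make_dimer(separation=3.0))
        radii = list(np.linspace(0.5, 10.0, max(n, 2)))
        scan_path = outdir / "scan_radii.json"
        scan_path.write_text(
            "[" + ", ".join(f"{r:.6f}" for r in radii) + "]\n"
        )
        paths["scan_radii"] = str(scan_path)
    elif kind == "random_cluster":
        emit_system(make_random_cluster(n, seed), elements=["C"] * n)
    elif kind == "water_like_cluster":
        system = make_water_like_cluster(n, seed)
        emit_system(system, elements=["O", "H", "H"] * n)
    elif kind == "model_qm_case":
        system, model = make_model_qm_case(seed, n_mm=max(n, 2))
        emit_system(system, elements=["C"] * system.n_sites)
        paths["qm_spec"] = str(outdir / "qm.json")
        write_qm_spec(paths["qm_spec"], model)
    else:
        raise GenerationError(f"unknown fixture kind {kind!r}")
    meta = outdir / "meta.json"
    meta.write_text(
        f'{{"kind": "{kind}", "n": {n}, "seed": {seed}}}\n'
    )
    paths["meta"] = str(meta)
    return paths
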