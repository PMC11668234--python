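"""Readers and writers: XYZ geometries, JSON parameter/topology files, the QM
region specification, run configuration (JSON/TOML), CSV traces and optional
HDF5 debug dumps.

Disk units are Angstrom; everything returned to callers is in bohr.  Readers
reject malformed input (unknown keys, wrong shapes) rather than coercing it.
"""

from __future__ import annotations

import csv
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embedding import FixedDensityProvider, ModelQM, QMRegion
from .mmsystem import MMSite, MMSystem, ScreeningRules, ValidationError, build_system
from .units import angstrom_to_bohr, bohr_to_angstrom

__all__ = [
    "ParseError",
    "RunConfig",
    "read_xyz",
    "write_xyz",
    "write_trajectory_xyz",
    "read_params",
    "write_params",
    "load_system",
    "read_qm_spec",
    "write_qm_spec",
    "load_config",
    "write_optimization_csv",
    "dump_debug_h5",
]

PARAMS_SCHEMA_VERSION = 1
QM_SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Malformed input file; the message carries the location."""


def read_xyz(path):
    """Read a standard XYZ file.

    Returns (elements, coordinates in bohr of shape (N, 3), comment).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"{path}:1: expected atom count, got {lines[0]!r}") from None
    if len(lines) < count + 2:
        raise ParseError(
            f"{path}: header declares {count} atoms but only "
            f"{max(0, len(lines) - 2)} coordinate lines follow"
        )
    comment = lines[1] if len(lines) > 1 else ""
    elements, coords = [], []
    for i in range(count):
        ln = 3 + i
        parts = lines[2 + i].split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise ParseError(f"{path}:{ln}: non-numeric coordinate") from None
    return elements, angstrom_to_bohr(np.array(coords)), comment


def _format_xyz_frame(elements, coords_bohr, comment=""):
    coords = bohr_to_angstrom(np.asarray(coords_bohr, dtype=float).reshape(-1, 3))
    if len(elements) != len(coords):
        raise ValueError("element and coordinate counts differ")
    out = [str(len(elements)), str(comment).replace("\n", " ")]
    for el, (x, y, z) in zip(elements, coords):
        out.append(f"{el:<4s} {x: .10f} {y: .10f} {z: .10f}")
    return "\n".join(out) + "\n"


def write_xyz(path, elements, coords_bohr, comment=""):
    """Write one XYZ frame (coordinates in bohr, written in Angstrom)."""
    Path(path).write_text(_format_xyz_frame(elements, coords_bohr, comment))


def write_trajectory_xyz(path, elements, frames, comments=None):
    """Write a multi-frame XYZ trajectory."""
    text = "".join(
        _format_xyz_frame(
            elements, f, comments[i] if comments else f"frame {i}"
        )
        for i, f in enumerate(frames)
    )
    Path(path).write_text(text)


_SITE_KEYS = {"charge", "dipole", "quadrupole", "polarizability", "thole", "group"}
_TOP_KEYS = {"schema_version", "sites", "bonds", "screening"}
_SCREEN_KEYS = {"m", "d", "p", "group_based_p"}


def read_params(path):
    """Read the JSON parameter/topology file.

    Returns (site_params, bonds, rules) where ``site_params`` is a list of
    dicts ready to combine with geometry through :func:`load_system`.
    Unknown keys are rejected with the offending JSON pointer.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON ({e})") from None
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be an object")
    version = doc.get("schema_version")
    if version != PARAMS_SCHEMA_VERSION:
        raise ParseError(
            f"{path}:/schema_version: expected {PARAMS_SCHEMA_VERSION}, got {version!r}"
        )
    for key in doc:
        if key not in _TOP_KEYS:
            raise ParseError(f"{path}:/{key}: unknown key")
    sites = doc.get("sites", [])
    out_sites = []
    for i, s in enumerate(sites):
        for key in s:
            if key not in _SITE_KEYS:
                raise ParseError(f"{path}:/sites/{i}/{key}: unknown key")
        entry = {
            "charge": float(s.get("charge", 0.0)),
            "dipole": np.asarray(s.get("dipole", [0, 0, 0]), dtype=float),
            "quadrupole": np.asarray(s.get("quadrupole", [0] * 6), dtype=float),
            "polarizability": float(s.get("polarizability", 0.0)),
            "thole": float(s.get("thole", 0.39)),
            "group": int(s.get("group", 0)),
        }
        if entry["polarizability"] < 0:
            raise ParseError(f"{path}:/sites/{i}/polarizability: must be >= 0")
        if entry["dipole"].shape != (3,):
            raise ParseError(f"{path}:/sites/{i}/dipole: must have 3 components")
        if entry["quadrupole"].shape != (6,):
            raise ParseError(
                f"{path}:/sites/{i}/quadrupole: must have 6 packed components"
            )
        out_sites.append(entry)
    bonds = []
    for i, b in enumerate(doc.get("bonds", [])):
        if len(b) != 2:
            raise ParseError(f"{path}:/bonds/{i}: must be an index pair")
        bonds.append((int(b[0]), int(b[1])))
    sc = doc.get("screening", {})
    for key in sc:
        if key not in _SCREEN_KEYS:
            raise ParseError(f"{path}:/screening/{key}: unknown key")
    defaults = ScreeningRules()
    try:
        rules = ScreeningRules(
            mutual_m=np.asarray(sc.get("m", defaults.mutual_m), dtype=float),
            direct_d=np.asarray(sc.get("d", defaults.direct_d), dtype=float),
            polarization_p=np.asarray(
                sc.get("p", defaults.polarization_p), dtype=float
            ),
            group_based_p=bool(sc.get("group_based_p", defaults.group_based_p)),
        )
    except ValidationError as e:
        raise ParseError(f"{path}:/screening: {e}") from None
    return out_sites, bonds, rules


def write_params(path, system: MMSystem):
    """Write the parameter/topology JSON for an existing system."""
    doc = {
        "schema_version": PARAMS_SCHEMA_VERSION,
        "sites": [
            {
                "charge": s.charge,
                "dipole": list(map(float, s.dipole)),
                "quadrupole": list(map(float, s.quadrupole)),
                "polarizability": s.polarizability,
                "thole": s.thole_factor,
                "group": s.group_id,
            }
            for s in system.sites
        ],
        "bonds": [list(b) for b in system.bonds],
        "screening": {
            "m": list(map(float, system.rules.mutual_m)),
            "d": list(map(float, system.rules.direct_d)),
            "p": list(map(float, system.rules.polarization_p)),
            "group_based_p": system.rules.group_based_p,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_system(xyz_path, params_path) -> MMSystem:
    """Combine an XYZ geometry with a parameter file into an MMSystem."""
    _, coords, _ = read_xyz(xyz_path)
    site_params, bonds, rules = read_params(params_path)
    if len(site_params) != len(coords):
        raise ParseError(
            f"{params_path}: {len(site_params)} parameter entries but "
            f"{len(coords)} atoms in {xyz_path}"
        )
    sites = [
        MMSite(
            index=i,
            position=coords[i],
            charge=p["charge"],
            dipole=p["dipole"],
            quadrupole=p["quadrupole"],
            polarizability=p["polarizability"],
            thole_factor=p["thole"],
            group_id=p["group"],
        )
        for i, p in enumerate(site_params)
    ]
    explicit_groups = any(p["group"] != 0 for p in site_params)
    return build_system(
        sites, bonds, rules,
        groups=[p["group"] for p in site_params] if explicit_groups else None,
    )


_QM_TOP_KEYS = {"schema_version", "nuclei", "density_sites", "states", "response"}


def read_qm_spec(path):
    """Read the QM-region JSON: nuclei, density sites, per-state charges.

    Positions and offsets on disk are Angstrom.  Returns a ModelQM when a
    response matrix is present, otherwise a FixedDensityProvider.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON ({e})") from None
    version = doc.get("schema_version")
    if version != QM_SCHEMA_VERSION:
        raise ParseError(
            f"{path}:/schema_version: expected {QM_SCHEMA_VERSION}, got {version!r}"
        )
    for key in doc:
        if key not in _QM_TOP_KEYS:
            raise ParseError(f"{path}:/{key}: unknown key")
    nuclei = doc.get("nuclei", [])
    positions = angstrom_to_bohr(
        np.array([n["position"] for n in nuclei], dtype=float).reshape(-1, 3)
    )
    charges = np.array([n["charge"] for n in nuclei], dtype=float)
    dsites = doc.get("density_sites", [])
    region = QMRegion(
        atom_positions=positions,
        nuclear_charges=charges,
        site_atoms=np.array([d["atom"] for d in dsites], dtype=int),
        site_offsets=angstrom_to_bohr(
            np.array([d.get("offset", [0, 0, 0]) for d in dsites], dtype=float)
        ).reshape(-1, 3),
    )
    states = doc.get("states", {})
    base_charges = {
        lab: np.asarray(st["charges"], dtype=float) for lab, st in states.items()
    }
    base_energies = {lab: float(st.get("energy", 0.0)) for lab, st in states.items()}
    if "response" in doc:
        return ModelQM(
            region=region,
            base_charges=base_charges,
            response=np.asarray(doc["response"], dtype=float),
            base_energies=base_energies,
        )
    return FixedDensityProvider(region=region, charges=base_charges, energies=base_energies)


def write_qm_spec(path, provider):
    """Write a ModelQM / FixedDensityProvider back to the JSON schema."""
    region = provider.region
    charges = (
        provider.base_charges if isinstance(provider, ModelQM) else provider.charges
    )
    energies = (
        provider.base_energies if isinstance(provider, ModelQM) else provider.energies
    )
    doc = {
        "schema_version": QM_SCHEMA_VERSION,
        "nuclei": [
            {
                "position": list(map(float, bohr_to_angstrom(p))),
                "charge": float(z),
            }
            for p, z in zip(region.atom_positions, region.nuclear_charges)
        ],
        "density_sites": [
            {
                "atom": int(a),
                "offset": list(map(float, bohr_to_angstrom(o))),
            }
            for a, o in zip(region.site_atoms, region.site_offsets)
        ],
        "states": {
            lab: {
                "charges": list(map(float, q)),
                "energy": float(energies.get(lab, 0.0)),
            }
            for lab, q in charges.items()
        },
    }
    if isinstance(provider, ModelQM):
        doc["response"] = [list(map(float, row)) for row in provider.response]
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


@dataclass
class RunConfig:
    """Run configuration (paths, tolerances, solver and damping choices)."""

    geometry: str | None = None
    parameters: str | None = None
    qm_spec: str | None = None
    tol_e: float = 1e-9
    tol_mu: float = 1e-7
    cg_tol: float = 1e-8
    solver: str = "auto"
    mixing: float = 1.0
    seed: int = 0
    output_dir: str = "."
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("tol_e", "tol_mu", "cg_tol"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def load_config(path) -> RunConfig:
    """Load a RunConfig from JSON or TOML (by file extension)."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    else:
        with open(path) as fh:
            doc = json.load(fh)
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extras"}
    kwargs = {k: v for k, v in doc.items() if k in known}
    extras = {k: v for k, v in doc.items() if k not in known}
    return RunConfig(**kwargs, extras=extras)


def write_optimization_csv(path, result):
    """Per-step energies and gradient norms of an optimization run."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "energy_hartree", "max_gradient_hartree_per_bohr"])
        for i, (e, g) in enumerate(zip(result.energies, result.gradient_norms)):
            w.writerow([i, f"{e:.12f}", f"{g:.3e}"])


def dump_debug_h5(path, **arrays):
    """Optional HDF5 dump of intermediate arrays (T matrix, fields, dipoles)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))
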