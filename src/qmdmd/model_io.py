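"""Structure data model and readers/writers.

The central container is :class:`MolecularSystem`: a flat list of annotated
atoms, a bond table with reference lengths, and a role map assigning atoms to
the chemically meaningful groups the pipeline cares about (``metal``,
``substrate``, ``cofactor``, ``water``, ``site_residues``).

Atom ids are 0-based and equal to the atom's index in ``atoms``; every module
in the package relies on this so that positions can live in plain ``(N, 3)``
arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO
from scipy.spatial import cKDTree

from .constants import (METAL_ELEMENTS, atomic_mass, covalent_radius)

ROLE_LABELS = ("metal", "substrate", "cofactor", "water", "site_residues")

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class FormatError(ValueError):
    """A file could not be interpreted in the expected format."""


@dataclass
class AtomRecord:
    """One atom: identity, placement and bookkeeping flags."""

    atom_id: int
    element: str
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    mass: float
    frozen: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.atom_id}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: non-finite position")
        if not self.mass > 0:
            raise ValueError(f"atom {self.atom_id}: mass must be positive")

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


class BondTable:
    """Unordered atom-id pairs with reference lengths (Å)."""

    def __init__(self):
        self._bonds: dict[tuple[int, int], float] = {}
        self._adj: dict[int, set[int]] = {}

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def add(self, i: int, j: int, length: float) -> None:
        if i == j:
            raise ValueError(f"self-bond on atom {i}")
        if not (0.5 < length < 3.0):
            raise ValueError(f"bond {i}-{j}: reference length {length:.3f} Å "
                             "outside (0.5, 3.0)")
        self._bonds[self._key(i, j)] = float(length)
        self._adj.setdefault(i, set()).add(j)
        self._adj.setdefault(j, set()).add(i)

    def __contains__(self, pair) -> bool:
        return self._key(*pair) in self._bonds

    def __len__(self) -> int:
        return len(self._bonds)

    def length(self, i: int, j: int) -> float:
        return self._bonds[self._key(i, j)]

    def pairs(self):
        """Iterate (i, j, reference_length) with i < j, sorted."""
        for (i, j) in sorted(self._bonds):
            yield i, j, self._bonds[(i, j)]

    def neighbors(self, i: int) -> set[int]:
        return set(self._adj.get(i, ()))

    def copy(self) -> "BondTable":
        out = BondTable()
        out._bonds = dict(self._bonds)
        out._adj = {k: set(v) for k, v in self._adj.items()}
        return out


@dataclass
class MolecularSystem:
    """Annotated atoms + bonds + role map; the full simulated object."""

    atoms: list[AtomRecord]
    bonds: BondTable
    roles: dict[str, set[int]] = field(default_factory=dict)
    backend_params: object | None = None  # SurrogateParams, attached by builders
    # reference 1-3 distances (angle analogs) at the topology's rest geometry
    angle_refs: dict | None = None
    # packing-cage references: (i, j) -> rest distance, emulating the dense
    # environment a real protein frame provides around mobile atoms
    packing_refs: dict | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if ids != list(range(len(self.atoms))):
            raise ValueError("atom_ids must be unique and equal to list indices")
        n = len(self.atoms)
        for role, members in self.roles.items():
            bad = [i for i in members if not (0 <= i < n)]
            if bad:
                raise ValueError(f"role {role!r} references missing atoms {bad}")
        metal = self.roles.get("metal", set())
        if metal and len(metal) != 1:
            raise ValueError(f"exactly one metal atom expected, got {len(metal)}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (self.n_atoms, 3):
            raise ValueError("position array shape mismatch")
        for a, p in zip(self.atoms, pos):
            a.position = p.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def frozen_mask(self) -> np.ndarray:
        return np.array([a.frozen for a in self.atoms], dtype=bool)

    @property
    def metal_id(self) -> int:
        (m,) = self.roles["metal"]
        return m

    def heavy_atoms(self) -> list[int]:
        return [a.atom_id for a in self.atoms if a.element.upper() != "H"]

    def find_atoms(self, atom_name: str, role: str | None = None,
                   residue_id: int | None = None) -> list[int]:
        pool = range(self.n_atoms) if role is None else sorted(self.roles.get(role, ()))
        out = []
        for i in pool:
            a = self.atoms[i]
            if a.atom_name == atom_name and (residue_id is None or
                                             a.residue_id == residue_id):
                out.append(i)
        return out

    def compute_angle_refs(self) -> None:
        """Record current 1-3 distances as the rest-geometry references."""
        refs = {}
        pos = self.positions
        for j in range(self.n_atoms):
            nb = sorted(self.bonds.neighbors(j))
            for a in range(len(nb)):
                for c in range(a + 1, len(nb)):
                    pair = (nb[a], nb[c])
                    refs[pair] = float(np.linalg.norm(pos[pair[0]] - pos[pair[1]]))
        self.angle_refs = refs

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            atoms=[a.copy() for a in self.atoms],
            bonds=self.bonds.copy(),
            roles={k: set(v) for k, v in self.roles.items()},
            backend_params=self.backend_params,
            angle_refs=dict(self.angle_refs) if self.angle_refs else None,
            packing_refs=dict(self.packing_refs) if self.packing_refs else None,
        )


# ---------------------------------------------------------------------------
# bond inference


def infer_bonds(atoms: list[AtomRecord], tolerance: float = 0.15) -> BondTable:
    """Distance-based bonds: d < (1+tolerance)·(sum of covalent radii).

    Metals are never auto-bonded: their coordination is role-declared.
    """
    bonds = BondTable()
    if not atoms:
        return bonds
    pos = np.array([a.position for a in atoms])
    radii = np.array([covalent_radius(a.element) for a in atoms])
    is_metal = np.array([a.element.upper() in METAL_ELEMENTS for a in atoms])
    cutoff = (1.0 + tolerance) * 2.0 * radii.max()
    tree = cKDTree(pos)
    for i, j in sorted(tree.query_pairs(cutoff)):
        if is_metal[i] or is_metal[j]:
            continue
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d < (1.0 + tolerance) * (radii[i] + radii[j]) and 0.5 < d < 3.0:
            bonds.add(atoms[i].atom_id, atoms[j].atom_id, d)
    return bonds


# ---------------------------------------------------------------------------
# PDB reading / writing (wwPDB v3.3 columns via Biopython)


def _system_from_model(model, bond_tolerance: float) -> MolecularSystem:
    atoms: list[AtomRecord] = []
    seen_altloc = False
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.get_altloc() not in (" ", "", "A"):
                    seen_altloc = True
                    continue  # first altloc wins
                element = (atom.element or "").strip()
                if not element:
                    raise FormatError(
                        f"unknown element for atom {atom.get_fullname().strip()!r} "
                        f"in residue {residue.get_resname()} {residue.id[1]}")
                try:
                    mass = atomic_mass(element)
                except KeyError as e:
                    raise FormatError(str(e)) from e
                atoms.append(AtomRecord(
                    atom_id=len(atoms),
                    element=element.upper(),
                    atom_name=atom.get_name(),
                    residue_name=residue.get_resname().strip(),
                    residue_id=residue.id[1],
                    chain_id=chain.id if chain.id.strip() else "A",
                    position=np.array(atom.coord, dtype=float),
                    mass=mass,
                ))
    if seen_altloc:
        warnings.warn("alternate locations present; kept the first altloc only")
    system = MolecularSystem(atoms=atoms,
                             bonds=infer_bonds(atoms, bond_tolerance), roles={})
    system.compute_angle_refs()
    return system


def read_models(path, bond_tolerance: float = 0.15) -> list[MolecularSystem]:
    """Read all models of a PDB file, one MolecularSystem per model."""
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        structure = parser.get_structure("s", str(path))
    except Exception as e:  # Biopython raises assorted exception types
        raise FormatError(f"cannot parse PDB file {path}: {e}") from e
    systems = [_system_from_model(m, bond_tolerance) for m in structure]
    if not systems:
        raise FormatError(f"no models found in {path}")
    return systems


def read_structure(path, bond_tolerance: float = 0.15):
    """Read a PDB file.

    Returns a single :class:`MolecularSystem` for a one-model file, or a list
    of systems (one per model) for a multi-model file.  HETATM records are
    accepted for the metal, substrate, cofactor and water.
    """
    systems = read_models(path, bond_tolerance)
    return systems[0] if len(systems) == 1 else systems


def _is_het(system: MolecularSystem, atom_id: int) -> bool:
    for role in ("metal", "substrate", "cofactor", "water"):
        if atom_id in system.roles.get(role, ()):
            return True
    return system.atoms[atom_id].residue_name not in _STANDARD_AA and \
        system.atoms[atom_id].residue_name not in {"ARM", "BAS", "GLB"}


def write_structure(system: MolecularSystem, path) -> None:
    """Write a system as fixed-width PDB (ATOM/HETATM per role)."""
    pos = system.positions
    if np.any(np.abs(pos) >= 10000) or np.any(pos <= -1000):
        raise ValueError("coordinates outside the PDB fixed-width range")
    builder = StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    builder.init_seg("    ")
    current = (None, None)
    for a in system.atoms:
        if current[0] != a.chain_id:
            builder.init_chain(a.chain_id)
        het = "H_" + a.residue_name if _is_het(system, a.atom_id) else " "
        if current != (a.chain_id, (a.residue_id, a.residue_name)):
            builder.init_residue(a.residue_name, het, a.residue_id, " ")
            current = (a.chain_id, (a.residue_id, a.residue_name))
        name = a.atom_name if len(a.atom_name) == 4 else a.atom_name.ljust(3)
        builder.init_atom(name, a.position.astype(np.float64), 0.0, 1.0, " ",
                          name, a.atom_id + 1, element=a.element.upper())
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# trajectory output (multi-frame XYZ + TSV energy sidecar)


def write_trajectory(snapshots, path, energies, times=None) -> None:
    """Write snapshots as multi-frame XYZ plus a ``<path>.tsv`` sidecar.

    ``snapshots`` may be MolecularSystems or (system, positions) handled by
    the caller; all frames must share atom ordering.  The sidecar holds one
    row per frame: frame index, DMD time (t.u.), potential energy (kcal/mol).
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("empty snapshot list")
    if len(energies) != len(snapshots):
        raise ValueError("one energy per snapshot required")
    n = snapshots[0].n_atoms
    elements = [a.element for a in snapshots[0].atoms]
    if times is None:
        times = list(range(len(snapshots)))
    path = Path(path)
    with open(path, "w") as fh:
        for k, snap in enumerate(snapshots):
            if snap.n_atoms != n:
                raise ValueError(f"frame {k}: atom count {snap.n_atoms} != {n}")
            fh.write(f"{n}\n")
            fh.write(f"frame {k} t.u. {times[k]:g} E {energies[k]:.6f}\n")
            for el, p in zip(elements, snap.positions):
                fh.write(f"{el:<2s} {p[0]:14.6f} {p[1]:14.6f} {p[2]:14.6f}\n")
    sidecar = path.with_suffix(path.suffix + ".tsv")
    with open(sidecar, "w") as fh:
        fh.write("frame\ttime_tu\tpotential_kcal_mol\n")
        for k, (t, e) in enumerate(zip(times, energies)):
            fh.write(f"{k}\t{t:g}\t{e:.6f}\n")


def read_xyz_frames(path) -> tuple[list[str], np.ndarray]:
    """Read a multi-frame XYZ file written by :func:`write_trajectory`.

    Returns (element labels, positions of shape (n_frames, n_atoms, 3)).
    """
    frames = []
    elements: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].split()[0])
        except ValueError as e:
            raise FormatError(f"bad XYZ atom-count line {k + 1}: {lines[k]!r}") from e
        body = lines[k + 2: k + 2 + n]
        if len(body) < n:
            raise FormatError(f"truncated XYZ frame starting at line {k + 1}")
        frame = []
        els = []
        for ln in body:
            parts = ln.split()
            els.append(parts[0])
            frame.append([float(x) for x in parts[1:4]])
        if not elements:
            elements = els
        frames.append(frame)
        k += 2 + n
    return elements, np.array(frames)


# ---------------------------------------------------------------------------
# system bundle: PDB + JSON sidecar (roles, freeze flags, references and the
# backend parameterization cannot live inside PDB columns)


def write_roles(system: MolecularSystem, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: sorted(v) for k, v in system.roles.items()}, fh, indent=1)


def read_roles(path) -> dict[str, set[int]]:
    with open(path) as fh:
        return {k: set(v) for k, v in json.load(fh).items()}


def _sidecar_path(pdb_path) -> Path:
    p = Path(pdb_path)
    return p.with_suffix(p.suffix + ".json")


def save_system(system: MolecularSystem, pdb_path, sidecar_path=None) -> None:
    """Write a full system bundle: coordinates as PDB + a JSON sidecar."""
    write_structure(system, pdb_path)
    meta = {
        "roles": {k: sorted(v) for k, v in system.roles.items()},
        "frozen": sorted(int(a.atom_id) for a in system.atoms if a.frozen),
        "bonds": [[i, j, r] for i, j, r in system.bonds.pairs()],
        "angle_refs": ([[i, j, r] for (i, j), r in sorted(system.angle_refs.items())]
                       if system.angle_refs else None),
        "packing_refs": ([[i, j, r] for (i, j), r in
                          sorted(system.packing_refs.items())]
                         if system.packing_refs else None),
        "backend_params": (system.backend_params.to_dict()
                           if system.backend_params is not None else None),
    }
    with open(sidecar_path or _sidecar_path(pdb_path), "w") as fh:
        json.dump(meta, fh)


def load_system(pdb_path, sidecar_path=None) -> MolecularSystem:
    """Read a system bundle written by :func:`save_system`."""
    from .backend import SurrogateParams

    system = read_structure(pdb_path)
    if isinstance(system, list):
        raise FormatError("system bundles are single-model")
    sidecar = Path(sidecar_path or _sidecar_path(pdb_path))
    if not sidecar.exists():
        return system
    with open(sidecar) as fh:
        meta = json.load(fh)
    system.roles = {k: set(v) for k, v in meta.get("roles", {}).items()}
    for i in meta.get("frozen", []):
        system.atoms[i].frozen = True
    if meta.get("bonds") is not None:
        bonds = BondTable()
        for i, j, r in meta["bonds"]:
            bonds.add(int(i), int(j), float(r))
        system.bonds = bonds
    if meta.get("angle_refs") is not None:
        system.angle_refs = {(int(i), int(j)): float(r)
                             for i, j, r in meta["angle_refs"]}
    if meta.get("packing_refs") is not None:
        system.packing_refs = {(int(i), int(j)): float(r)
                               for i, j, r in meta["packing_refs"]}
    if meta.get("backend_params") is not None:
        system.backend_params = SurrogateParams.from_dict(meta["backend_params"])
    system.validate()
    return system
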