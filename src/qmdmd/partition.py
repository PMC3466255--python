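"""Three-domain assignment, hydrogen capping, freeze masks, constraints.

The system is split into a metal core (``qm_only``: the cation plus its
directly coordinated donor atoms, frozen during sampling), a shared
active-site region (``qm_dmd``: truncated side-chain fragments, substrate,
water, cofactor fragment) and the remainder (``dmd_only``).  The "breathing
boundary" is realized as two static masks used at different phases: the
sampler sees the core frozen; the energy backend sees the extracted cluster
with its saturating hydrogens and their bond partners frozen.

A severed boundary bond is saturated by a hydrogen placed along the original
bond at 0.7052 × the bond length from the inner atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CAP_FACTOR
from .model_io import MolecularSystem


@dataclass(frozen=True)
class TruncationRule:
    """Cut the named bond of one residue; keep the fragment on the inner side."""

    residue_id: int
    inner_atom: str
    outer_atom: str


@dataclass
class DomainPartition:
    qm_only: set
    qm_dmd: set
    dmd_only: set
    boundary_bonds: list          # (inner_id, outer_id, reference_length)
    n_atoms: int

    def __post_init__(self):
        sets = (self.qm_only, self.qm_dmd, self.dmd_only)
        total = len(self.qm_only) + len(self.qm_dmd) + len(self.dmd_only)
        union = self.qm_only | self.qm_dmd | self.dmd_only
        if total != len(union) or union != set(range(self.n_atoms)):
            raise ValueError("domains must disjointly cover all atoms")
        cluster = self.qm_only | self.qm_dmd
        for inner, outer, _r in self.boundary_bonds:
            if inner not in cluster or outer not in self.dmd_only:
                raise ValueError(f"boundary bond ({inner},{outer}) does not "
                                 "cross the cluster boundary")

    @property
    def cluster_atoms(self) -> set:
        return self.qm_only | self.qm_dmd


@dataclass
class CapHydrogen:
    parent_inner: int
    direction: np.ndarray         # unit vector inner → original outer
    position: np.ndarray
    source_bond: tuple            # (inner, outer, reference_length)


@dataclass
class CappedCluster:
    member_atoms: np.ndarray      # sorted system atom ids
    positions: np.ndarray         # (n_members, 3), copied from the system
    caps: list
    frozen_in_qm: set             # member ids frozen during optimization
    frozen_in_dmd: set            # qm_only ids (frozen during sampling)
    n_system_atoms: int
    # frame positions of the severed bonds' outer partners, so the cluster
    # can be evaluated standalone
    outer_positions: dict = field(default_factory=dict)

    def index_of(self, atom_id: int) -> int:
        idx = int(np.searchsorted(self.member_atoms, atom_id))
        if idx >= len(self.member_atoms) or self.member_atoms[idx] != atom_id:
            raise KeyError(f"atom {atom_id} is not a cluster member")
        return idx

    def full_positions(self, base: np.ndarray | None = None):
        """Scatter member positions into a full-size array + activity mask.

        Cap hydrogens are geometric valence saturators; the analytic backend
        has no term for them, so they do not appear in the mask.
        """
        if base is None:
            full = np.zeros((self.n_system_atoms, 3))
        else:
            full = np.array(base, dtype=float)
        full[self.member_atoms] = self.positions
        for i, p in self.outer_positions.items():
            full[i] = p
        mask = np.zeros(self.n_system_atoms, dtype=bool)
        mask[self.member_atoms] = True
        return full, mask

    def with_positions(self, full: np.ndarray) -> "CappedCluster":
        return CappedCluster(
            self.member_atoms, np.array(full[self.member_atoms]),
            [CapHydrogen(c.parent_inner, c.direction.copy(),
                         c.position.copy(), c.source_bond)
             for c in self.caps],
            set(self.frozen_in_qm), set(self.frozen_in_dmd),
            self.n_system_atoms,
            {i: np.array(p) for i, p in self.outer_positions.items()})

    @property
    def free_atoms(self) -> list:
        return [int(i) for i in self.member_atoms if i not in self.frozen_in_qm]

    @property
    def boundary_outer_atoms(self) -> list:
        """Frame atoms the caps stand in for (fixed during evaluation)."""
        return sorted({c.source_bond[1] for c in self.caps})

    def evaluation_mask(self) -> np.ndarray:
        """Activity mask for backend evaluation: members plus the severed
        bonds' outer partners.  The analytic surrogate realizes the
        saturating role of the cap hydrogens by retaining the frame terms of
        each severed bond, with the outer atom frozen at its frame position
        (the cap hydrogens themselves carry no terms)."""
        mask = np.zeros(self.n_system_atoms, dtype=bool)
        mask[self.member_atoms] = True
        mask[self.boundary_outer_atoms] = True
        return mask


@dataclass
class ConstraintSet:
    pairs: list = field(default_factory=list)   # (a, b, target, half_width)

    def add(self, a: int, b: int, target: float, half_width: float):
        if half_width <= 0 or target <= 0:
            raise ValueError("constraint needs positive target and half_width")
        self.pairs.append((int(a), int(b), float(target), float(half_width)))

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


# ---------------------------------------------------------------------------


def default_selection(system: MolecularSystem) -> list[TruncationRule]:
    """One truncation rule per anchored residue: cut the bond to its ANC atom."""
    rules = []
    seen = set()
    for a in system.atoms:
        if a.atom_name != "ANC" or a.residue_id in seen:
            continue
        inner_ids = [j for j in system.bonds.neighbors(a.atom_id)]
        if not inner_ids:
            continue
        inner = system.atoms[inner_ids[0]]
        if inner.residue_id != a.residue_id:
            continue
        rules.append(TruncationRule(a.residue_id, inner.atom_name, "ANC"))
        seen.add(a.residue_id)
    return rules


def _fragment_from_rule(system: MolecularSystem, rule: TruncationRule):
    res_atoms = [a.atom_id for a in system.atoms
                 if a.residue_id == rule.residue_id]
    if not res_atoms:
        raise ValueError(f"rule names missing residue {rule.residue_id}")
    name_map = {}
    for i in res_atoms:
        name_map.setdefault(system.atoms[i].atom_name, i)
    for nm in (rule.inner_atom, rule.outer_atom):
        if nm not in name_map:
            raise ValueError(f"rule names missing atom {nm!r} in residue "
                             f"{rule.residue_id}")
    inner, outer = name_map[rule.inner_atom], name_map[rule.outer_atom]
    if (inner, outer) not in system.bonds:
        raise ValueError(f"truncation bond {rule.inner_atom}–{rule.outer_atom} "
                         f"of residue {rule.residue_id} is not a bond")
    # flood from the inner side without crossing the cut bond
    frontier = [inner]
    frag = {inner}
    while frontier:
        i = frontier.pop()
        for j in system.bonds.neighbors(i):
            if {i, j} == {inner, outer} or j in frag:
                continue
            frag.add(j)
            frontier.append(j)
    if outer in frag:
        raise ValueError(f"truncation bond of residue {rule.residue_id} does "
                         "not separate the fragment (ring through the cut)")
    return frag


def assign_domains(system: MolecularSystem,
                   qm_residue_selection: list[TruncationRule] | None = None,
                   coordination_cutoff: float = 2.6) -> DomainPartition:
    """Three-domain assignment at the current geometry.

    ``qm_only`` is the metal plus every heavy atom within
    ``coordination_cutoff`` of it; ``qm_dmd`` is the union of the selected
    truncated fragments with the substrate, water and cofactor roles (minus
    the core); everything else is ``dmd_only``.
    """
    if qm_residue_selection is None:
        qm_residue_selection = default_selection(system)
    pos = system.positions
    metal = system.metal_id
    dists = np.linalg.norm(pos - pos[metal], axis=1)
    qm_only = {metal}
    for i in system.heavy_atoms():
        if i != metal and dists[i] < coordination_cutoff:
            qm_only.add(i)

    qm_dmd = set()
    for rule in qm_residue_selection:
        qm_dmd |= _fragment_from_rule(system, rule)
    for role in ("substrate", "water", "cofactor"):
        qm_dmd |= system.roles.get(role, set())
    qm_dmd -= qm_only
    if not qm_dmd:
        raise ValueError("empty active-site selection: the capped cluster "
                         "would contain only the frozen core")

    dmd_only = set(range(system.n_atoms)) - qm_only - qm_dmd
    cluster = qm_only | qm_dmd
    boundary = []
    for i, j, r in system.bonds.pairs():
        if (i in cluster) != (j in cluster):
            inner, outer = (i, j) if i in cluster else (j, i)
            boundary.append((inner, outer, r))
    return DomainPartition(qm_only=qm_only, qm_dmd=qm_dmd, dmd_only=dmd_only,
                           boundary_bonds=boundary, n_atoms=system.n_atoms)


def extract_capped_cluster(system: MolecularSystem,
                           partition: DomainPartition) -> CappedCluster:
    """Pull out the active-site cluster and saturate severed bonds.

    Each boundary bond gets one cap hydrogen at 0.7052 × the current bond
    length along the inner→outer direction; caps and their inner bond
    partners (plus statically frozen scaffold atoms) are frozen for the
    subsequent optimization.
    """
    members = np.array(sorted(partition.cluster_atoms), dtype=int)
    pos = system.positions
    caps = []
    frozen_qm = set()
    for inner, outer, ref in partition.boundary_bonds:
        vec = pos[outer] - pos[inner]
        length = float(np.linalg.norm(vec))
        if length < 1e-9:
            raise ValueError(f"boundary bond ({inner},{outer}) has zero length")
        direction = vec / length
        el_in = system.atoms[inner].element.upper()
        el_out = system.atoms[outer].element.upper()
        if el_in not in ("C", "N") or el_out not in ("C", "N"):
            warnings.warn(f"capping a {el_in}–{el_out} boundary bond with the "
                          "C–C/N placement factor")
        caps.append(CapHydrogen(parent_inner=inner, direction=direction,
                                position=pos[inner] + CAP_FACTOR * length * direction,
                                source_bond=(inner, outer, ref)))
        frozen_qm.add(inner)
    frozen_qm |= {int(i) for i in members if system.atoms[i].frozen}
    outer = {int(o): np.array(pos[o]) for _i, o, _r in partition.boundary_bonds}
    return CappedCluster(member_atoms=members,
                         positions=np.array(pos[members]),
                         caps=caps,
                         frozen_in_qm=frozen_qm,
                         frozen_in_dmd=set(partition.qm_only),
                         n_system_atoms=system.n_atoms,
                         outer_positions=outer)


def constraints_from_cluster(cluster: CappedCluster, pair_spec,
                             half_width: float = 0.01) -> ConstraintSet:
    """Distance windows (current value ± half_width) for the sampler.

    Targets are read off the cluster geometry, i.e. the optimized values the
    backend produced.  Cap hydrogens have no identity in the full system and
    cannot be constrained.
    """
    cs = ConstraintSet()
    seen = set()
    for a, b in pair_spec:
        key = (min(a, b), max(a, b))
        if key in seen:
            warnings.warn(f"duplicate constraint pair {key}; keeping one")
            continue
        seen.add(key)
        try:
            ia, ib = cluster.index_of(a), cluster.index_of(b)
        except KeyError as e:
            raise ValueError(f"constraint pair ({a},{b}) is not inside the "
                             "cluster (cap hydrogens cannot be constrained)") from e
        target = float(np.linalg.norm(cluster.positions[ia] - cluster.positions[ib]))
        cs.add(a, b, target, half_width)
    return cs


def reinstall_cluster(system: MolecularSystem,
                      cluster: CappedCluster) -> MolecularSystem:
    """Write the (optimized) cluster geometry back into the full system.

    Cap hydrogens are discarded; all non-member atoms are untouched.  A
    member displaced by more than 5 Å from its pre-extraction position is a
    boundary mismatch worth a warning, not an error.
    """
    out = system.copy()
    pos = out.positions
    moved = np.linalg.norm(pos[cluster.member_atoms] - cluster.positions, axis=1)
    if np.any(moved > 5.0):
        worst = cluster.member_atoms[int(np.argmax(moved))]
        warnings.warn(f"cluster member {worst} moved {moved.max():.2f} Å "
                      "from its pre-extraction position")
    pos[cluster.member_atoms] = cluster.positions
    out.set_positions(pos)
    return out
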