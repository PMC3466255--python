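"""Synthetic toy metal sites with known ground truth.

The generator emulates a metal-centered active site: a central cation with
octahedral-like coordination by carboxylate/amide/water/bidentate-substrate
donors sitting on flexible anchored arms, plus a donor S–CH3 group aimed at
the acceptor oxygen of the substrate.  Donor-head distances default to the
experimentally determined Mg-site geometry, so every requested native metric
is met exactly at the constructed ground-truth positions.

The construction also parameterizes the analytic surrogate backend at the
ground-truth geometry (native positions are a backend minimum by
construction), which is what makes distort-and-recover experiments
meaningful: the pipeline must find its way back to a known answer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve

from . import metrics as _metrics
from .backend import (HBondTerm, ProtonTerm, SurrogateParams, TransferTerm)
from .constants import atomic_mass
from .model_io import AtomRecord, BondTable, MolecularSystem

DEFAULT_NATIVE_DISTANCES = {
    "Metal – O1(Arm1)": 2.13,
    "Metal – O2(Arm1)": 3.28,
    "Metal – O(Arm2)": 2.35,
    "Metal – O1(Arm3)": 2.24,
    "Metal – O(water)": 2.04,
    "Metal – O1(Sub)": 2.14,
    "Metal – O2(Sub)": 2.21,
    "O2(Sub) – C(Don)": 2.71,
    "O2(Sub) – S(Don)": 4.51,
    "O(Arm1) – O(water)": 2.77,
    "O(Glu) – O(water)": 3.81,
}

#: standard ionic radii (Å) and formal charges for the stock variants
METAL_PRESETS = {
    "mg": ("MG", 0.72, 2.0),
    "ca": ("CA", 1.00, 2.0),
    "fe2": ("FE", 0.78, 2.0),
    "fe3": ("FE", 0.645, 3.0),
}

_BOND_CC = 1.52
_BOND_CO_CARBOX = 1.26
_BOND_CO_SUB = 1.36
_BOND_OH = 0.98
_HBOND_BASE = 1.70


class InfeasibleGeometry(ValueError):
    """Requested native distances cannot be realized simultaneously."""


@dataclass
class ToySiteSpec:
    metal_label: str = "MG"
    metal_radius: float = 0.72
    metal_charge: float = 2.0
    n_arms: int = 3
    include_water: bool = True
    include_substrate: bool = True
    include_donor: bool = True
    native_distances: dict = field(default_factory=lambda: dict(DEFAULT_NATIVE_DISTANCES))
    arm_length: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0.4 < self.metal_radius < 1.4):
            raise ValueError(f"metal_radius {self.metal_radius} outside (0.4, 1.4)")
        if not (2 <= self.n_arms <= 6):
            raise ValueError(f"n_arms {self.n_arms} outside [2, 6]")
        if self.arm_length < 1:
            raise ValueError("arm_length must be >= 1")
        for k, v in self.native_distances.items():
            if not v > 0:
                raise ValueError(f"native distance {k!r} must be positive")
        if self.include_donor and not self.include_substrate:
            raise ValueError("the donor S–CH3 group needs the substrate "
                             "acceptor oxygen; set include_substrate=True")


@dataclass
class GroundTruth:
    native_positions: np.ndarray
    native_metrics: dict
    params: SurrogateParams
    spec: ToySiteSpec


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _perp(v):
    v = _unit(v)
    trial = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, trial))


class _Builder:
    def __init__(self):
        self.atoms: list[AtomRecord] = []
        self.bonds = BondTable()
        self.roles: dict[str, set[int]] = {r: set() for r in
                                           ("metal", "substrate", "cofactor",
                                            "water", "site_residues")}

    def add(self, element, name, resname, resid, pos, frozen=False, role=None):
        i = len(self.atoms)
        self.atoms.append(AtomRecord(
            atom_id=i, element=element, atom_name=name, residue_name=resname,
            residue_id=resid, chain_id="A", position=np.asarray(pos, float),
            mass=atomic_mass(element), frozen=frozen))
        if role:
            self.roles[role].add(i)
        return i

    def bond(self, i, j):
        d = float(np.linalg.norm(self.atoms[i].position - self.atoms[j].position))
        self.bonds.add(i, j, d)


def _grow_chain(b: _Builder, start_id, direction, resname, resid, n_linkers,
                step=_BOND_CC, kink_deg=35.0):
    """Zig-zag linker chain outward from ``start_id``, ending in a frozen
    anchor; returns (linker ids, anchor id)."""
    e = _unit(direction)
    p = _perp(e)
    kink = np.radians(kink_deg)
    cur = b.atoms[start_id].position
    ids = []
    for k in range(n_linkers):
        sgn = 1.0 if k % 2 == 0 else -1.0
        cur = cur + step * (np.cos(kink) * e + np.sin(kink) * sgn * p)
        i = b.add("C", f"L{k + 1}", resname, resid, cur, role="site_residues")
        b.bond(ids[-1] if ids else start_id, i)
        ids.append(i)
    sgn = 1.0 if n_linkers % 2 == 0 else -1.0
    anchor_pos = cur + step * (np.cos(kink) * e + np.sin(kink) * sgn * p)
    anc = b.add("C", "ANC", resname, resid, anchor_pos, frozen=True,
                role="site_residues")
    b.bond(ids[-1] if ids else start_id, anc)
    return ids, anc


def _solve_carboxylate(d_o1, d_o2, axis_dir, plane_dir):
    """In-plane positions of the carboxyl carbon and the dangling oxygen of a
    bidentate-capable carboxylate whose coordinating O sits on ``axis_dir``."""
    o1 = d_o1 * np.asarray(axis_dir, float)
    e = _unit(axis_dir)
    p = _unit(plane_dir)
    d_oo = 2.0 * _BOND_CO_CARBOX * np.sin(np.radians(62.0))

    def eqs(x):
        cg = o1 + x[0] * e + x[1] * p
        o2 = o1 + x[2] * e + x[3] * p
        return [np.linalg.norm(cg - o1) - _BOND_CO_CARBOX,
                np.linalg.norm(o2 - cg) - _BOND_CO_CARBOX,
                np.linalg.norm(o2) - d_o2,
                np.linalg.norm(o2 - o1) - d_oo]

    x, info, ier, _ = fsolve(eqs, [1.1, 0.6, 0.7, 2.1], full_output=True)
    if ier != 1 or np.max(np.abs(eqs(x))) > 1e-9:
        raise InfeasibleGeometry(
            f"carboxylate head infeasible for Metal–O1 {d_o1:.2f} / "
            f"Metal–O2 {d_o2:.2f}")
    return o1 + x[0] * e + x[1] * p, o1 + x[2] * e + x[3] * p


def _solve_substrate_body(o1, o2):
    """Chelate body carbons C1, C2 bridging the two coordinating oxygens."""
    mid = _unit(o1 + o2)
    ex = _unit(o1)
    ey = _unit(o2 - (o2 @ ex) * ex)

    def eqs(x):
        c1 = x[0] * ex + x[1] * ey
        c2 = x[2] * ex + x[3] * ey
        return [np.linalg.norm(c1 - o1) - _BOND_CO_SUB,
                np.linalg.norm(c2 - o2) - _BOND_CO_SUB,
                np.linalg.norm(c1 - c2) - 1.40,
                np.linalg.norm(c1) - np.linalg.norm(c2)]

    x, info, ier, _ = fsolve(eqs, [2.8, 1.5, 1.5, 2.8], full_output=True)
    if ier != 1 or np.max(np.abs(eqs(x))) > 1e-9:
        raise InfeasibleGeometry("substrate chelate body infeasible for the "
                                 "requested Metal–O1(Sub)/Metal–O2(Sub)")
    c1 = x[0] * ex + x[1] * ey
    c2 = x[2] * ex + x[3] * ey
    if _unit(c1 + c2) @ mid < 0:   # keep the outward solution
        raise InfeasibleGeometry("substrate body folded through the metal")
    return c1, c2


def make_toy_site(spec: ToySiteSpec | None = None):
    """Build the toy site; returns (MolecularSystem, GroundTruth).

    Deterministic for a given spec; ``spec.seed`` seeds downstream stages
    (sampling), not the construction, which is closed-form.
    """
    spec = spec or ToySiteSpec()
    nd = spec.native_distances
    b = _Builder()
    metal = b.add(spec.metal_label, "M", "MTL", 0, [0.0, 0.0, 0.0], role="metal")

    resid = 1
    # --- metal-coordinating arms on the -x / -y / -z octahedral slots -------
    arm_dirs = [np.array([-1.0, 0, 0]), np.array([0, -1.0, 0]),
                np.array([0, 0, -1.0])]
    free_slots = []
    if not spec.include_water:
        free_slots.append(np.array([0, 0, 1.0]))
    if not spec.include_substrate:
        free_slots += [np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
    while len(arm_dirs) < spec.n_arms:
        if not free_slots:
            raise InfeasibleGeometry("not enough octahedral slots for n_arms")
        arm_dirs.append(free_slots.pop(0))
    arm_dirs = arm_dirs[:spec.n_arms]

    for k, e in enumerate(arm_dirs, start=1):
        p = _perp(e)
        if k == 1:
            # carboxylate-like, bidentate-capable (one dangling O)
            d1 = nd.get("Metal – O1(Arm1)", 2.13)
            d2 = nd.get("Metal – O2(Arm1)", 3.28)
            # dangling O points into the open octant between the other arms
            cg_pos, o2_pos = _solve_carboxylate(d1, d2, e, _unit([0, -1.0, -1.0]))
            od1 = b.add("O", "OD1", "ARM", resid, d1 * e, role="site_residues")
            cg = b.add("C", "CG", "ARM", resid, cg_pos, role="site_residues")
            od2 = b.add("O", "OD2", "ARM", resid, o2_pos, role="site_residues")
            b.bond(od1, cg)
            b.bond(od2, cg)
            head = cg
        elif k == 2:
            d = nd.get("Metal – O(Arm2)", 2.35)
            oe = b.add("O", "OE1", "ARM", resid, d * e, role="site_residues")
            cg = b.add("C", "CG", "ARM", resid,
                       d * e + _BOND_CO_CARBOX * _unit(0.94 * e + 0.34 * p),
                       role="site_residues")
            b.bond(oe, cg)
            head = cg
        elif k == 3:
            # amide-like head: O=C–N
            d = nd.get("Metal – O1(Arm3)", 2.24)
            og = b.add("O", "OG1", "ARM", resid, d * e, role="site_residues")
            cg_pos = d * e + 1.24 * _unit(0.94 * e + 0.34 * p)
            cg = b.add("C", "CG", "ARM", resid, cg_pos, role="site_residues")
            q = np.cross(e, p)   # out of the chain zig-zag plane
            ng = b.add("N", "NG1", "ARM", resid,
                       cg_pos + 1.33 * _unit(0.2 * e + 0.98 * q),
                       role="site_residues")
            b.bond(og, cg)
            b.bond(cg, ng)
            head = cg
        else:
            d = nd.get(f"Metal – O(Arm{k})", 2.20)
            ox = b.add("O", f"OX{k}", "ARM", resid, d * e, role="site_residues")
            cg = b.add("C", "CG", "ARM", resid,
                       d * e + _BOND_CO_CARBOX * _unit(0.94 * e + 0.34 * p),
                       role="site_residues")
            b.bond(ox, cg)
            head = cg
        _grow_chain(b, head, e, "ARM", resid, spec.arm_length)
        resid += 1

    # --- water (tilted toward the Arm1 oxygen to meet the O···O distance) ---
    water_o = None
    glu_dir = _unit([0.75, 0.35, 0.56])
    if spec.include_water:
        dw = nd.get("Metal – O(water)", 2.04)
        d1 = nd.get("Metal – O1(Arm1)", 2.13)
        woa = nd.get("O(Arm1) – O(water)")
        if woa is None:
            w_pos = np.array([0.0, 0.0, dw])
        else:
            s = (dw**2 + d1**2 - woa**2) / (2.0 * dw * d1)
            if not -1.0 <= s <= 1.0:
                raise InfeasibleGeometry(
                    "triangle violation among Metal / O1(Arm1) / O(water): "
                    f"requested O(Arm1)–O(water) {woa:.2f}")
            phi = np.arcsin(s)
            w_pos = dw * np.array([-np.sin(phi), 0.0, np.cos(phi)])
        water_o = b.add("O", "OW", "HOH", resid, w_pos, role="water")
        hw1 = b.add("H", "HW1", "HOH", resid, w_pos + 0.96 * glu_dir,
                    role="water")
        m2 = np.cos(np.radians(104.5)) * glu_dir + \
            np.sin(np.radians(104.5)) * _perp(glu_dir)
        if m2 @ _unit(w_pos) < 0:
            m2 = np.cos(np.radians(104.5)) * glu_dir - \
                np.sin(np.radians(104.5)) * _perp(glu_dir)
        hw2 = b.add("H", "HW2", "HOH", resid, w_pos + 0.96 * m2, role="water")
        b.bond(water_o, hw1)
        b.bond(water_o, hw2)
        # Glu-like hydrogen-bond acceptor arm off the water
        dg = nd.get("O(Glu) – O(water)", 3.81)
        oz_pos = w_pos + dg * glu_dir
        oz = b.add("O", "OZ1", "GLB", resid + 1, oz_pos, role="site_residues")
        ch = b.add("C", "CH", "GLB", resid + 1, oz_pos + 1.43 * glu_dir,
                   role="site_residues")
        b.bond(oz, ch)
        _grow_chain(b, ch, glu_dir, "GLB", resid + 1, max(1, spec.arm_length - 1))
        resid += 2

    # --- bidentate substrate, base arm, donor S–CH3 group -------------------
    transfer = proton = None
    hbonds = []
    sub = {}
    if spec.include_substrate:
        d1 = nd.get("Metal – O1(Sub)", 2.14)
        d2 = nd.get("Metal – O2(Sub)", 2.21)
        o1_pos = np.array([d1, 0.0, 0.0])
        o2_pos = np.array([0.0, d2, 0.0])
        c1_pos, c2_pos = _solve_substrate_body(o1_pos, o2_pos)
        o1 = b.add("O", "O1", "SUB", resid, o1_pos, role="substrate")
        o2 = b.add("O", "O2", "SUB", resid, o2_pos, role="substrate")
        c1 = b.add("C", "C1", "SUB", resid, c1_pos, role="substrate")
        c2 = b.add("C", "C2", "SUB", resid, c2_pos, role="substrate")
        b.bond(o1, c1)
        b.bond(o2, c2)
        b.bond(c1, c2)
        # abstractable proton on O2, hydrogen-bonded to the base nitrogen
        nb_dir = _unit([-0.20, 0.80, 0.56])
        ho2 = b.add("H", "HO2", "SUB", resid, o2_pos + _BOND_OH * nb_dir,
                    role="substrate")
        b.bond(o2, ho2)
        nz_pos = o2_pos + (_BOND_OH + _HBOND_BASE) * nb_dir
        nz = b.add("N", "NZ1", "BAS", resid + 1, nz_pos, role="site_residues")
        cb = b.add("C", "CB", "BAS", resid + 1, nz_pos + 1.47 * nb_dir,
                   role="site_residues")
        b.bond(nz, cb)
        _grow_chain(b, cb, nb_dir, "BAS", resid + 1, max(1, spec.arm_length - 1))
        sub = dict(o1=o1, o2=o2, c1=c1, c2=c2, ho2=ho2, nz=nz)
        hbonds.append(HBondTerm(donor=o2, hydrogen=ho2, acceptor=nz,
                                d0=_HBOND_BASE))
        resid += 2

        if spec.include_donor:
            d_oc = nd.get("O2(Sub) – C(Don)", 2.71)
            d_os = nd.get("O2(Sub) – S(Don)", 4.51)
            d_sc = d_os - d_oc
            if not 0.5 < d_sc < 3.0:
                raise InfeasibleGeometry(
                    "triangle violation among O2(Sub) / C(Don) / S(Don): "
                    f"implied S–C bond {d_sc:.2f} Å")
            vd = _unit([0.10, 0.25, -0.96])
            cm_pos = o2_pos + d_oc * vd
            s_pos = o2_pos + d_os * vd
            cm = b.add("C", "CM", "SAM", resid, cm_pos, role="cofactor")
            s_at = b.add("S", "S", "SAM", resid, s_pos, frozen=True,
                         role="cofactor")
            vt = _unit([0.80, -0.20, -0.56])
            ct = b.add("C", "CT", "SAM", resid, s_pos + 1.82 * vt, frozen=True,
                       role="cofactor")
            anc = b.add("C", "ANC", "SAM", resid, s_pos + 1.82 * vt + _BOND_CC * vt,
                        frozen=True)
            b.bond(cm, s_at)
            b.bond(s_at, ct)
            b.bond(ct, anc)
            sub.update(cm=cm, s=s_at)
            transfer = TransferTerm(s=s_at, c=cm, o=o2, xi_well=d_oc - d_sc,
                                    eta0=d_os, radius_ref=spec.metal_radius)
            proton = ProtonTerm(o=o2, h=ho2)
            resid += 1

    # water H-bond to the Glu-like oxygen
    if spec.include_water:
        oz = next(i for i in sorted(b.roles["site_residues"])
                  if b.atoms[i].atom_name == "OZ1")
        hw1 = next(i for i in sorted(b.roles["water"])
                   if b.atoms[i].atom_name == "HW1")
        hbonds.append(HBondTerm(donor=water_o, hydrogen=hw1, acceptor=oz,
                                d0=float(np.linalg.norm(
                                    b.atoms[oz].position - b.atoms[hw1].position))))

    system = MolecularSystem(atoms=b.atoms, bonds=b.bonds, roles=b.roles)
    system.compute_angle_refs()
    _attach_packing_refs(system)
    params = _build_surrogate_params(system, spec, hbonds, transfer, proton, sub)
    system.backend_params = params

    specs = _metrics.default_metric_specs(spec.include_substrate,
                                          spec.include_water,
                                          spec.include_donor)
    native_metrics = {}
    for ms in specs:
        try:
            native_metrics[ms.label] = _metrics.measure(system, ms)
        except KeyError:
            pass
    truth = GroundTruth(native_positions=system.positions,
                        native_metrics=native_metrics, params=params, spec=spec)
    return system, truth


def _attach_packing_refs(system: MolecularSystem) -> None:
    """Cage references: each mobile heavy atom vs its 4 nearest frozen heavy
    scaffold atoms, at the native distances.  The sampler turns these into
    finite attractive wells that emulate the packing of a real protein
    around the active-site arms; four generically non-coplanar references
    also break the mirror-image degeneracy that any three leave behind."""
    pos = system.positions
    heavy = set(system.heavy_atoms())
    frozen_heavy = [i for i in sorted(heavy) if system.atoms[i].frozen]
    refs = {}
    for i in sorted(heavy):
        if system.atoms[i].frozen or i == system.metal_id:
            continue
        near = system.bonds.neighbors(i)
        near |= {k for j in near for k in system.bonds.neighbors(j)}
        eligible = [f for f in frozen_heavy if f not in near]
        d = np.array([np.linalg.norm(pos[i] - pos[f]) for f in eligible])
        for k in np.argsort(d)[:4]:
            f = eligible[k]
            refs[(min(i, f), max(i, f))] = float(d[k])
    system.packing_refs = refs


# ---------------------------------------------------------------------------
# surrogate parameterization at the native geometry


def _build_surrogate_params(system: MolecularSystem, spec: ToySiteSpec,
                            hbonds, transfer, proton, sub) -> SurrogateParams:
    pos = system.positions
    n = system.n_atoms
    metal = system.metal_id
    heavy = set(system.heavy_atoms())
    frozen = set(np.nonzero(system.frozen_mask)[0])
    special = set()
    if transfer is not None:
        special.add(transfer.c)          # methyl carbon: owned by the two-well
    if proton is not None:
        special.add(proton.h)            # abstractable proton: owned by coupling

    # donors = heavy atoms within coordination distance of the metal
    dists = np.linalg.norm(pos - pos[metal], axis=1)
    donors = sorted(i for i in heavy - {metal}
                    if dists[i] < 2.6 and i not in special)

    harm = []   # (i, j, r0, k)

    def add_harm(i, j, k):
        if i == j or i in special or j in special or metal in (i, j):
            return
        harm.append((min(i, j), max(i, j),
                     float(np.linalg.norm(pos[i] - pos[j])), k))

    bonded_pairs = set()
    for i, j, _r in system.bonds.pairs():
        bonded_pairs.add((i, j))
        add_harm(i, j, 300.0)
    one_three = set()
    for j in range(n):
        nb = sorted(system.bonds.neighbors(j))
        for a in range(len(nb)):
            for c in range(a + 1, len(nb)):
                pair = (min(nb[a], nb[c]), max(nb[a], nb[c]))
                if pair not in bonded_pairs:
                    one_three.add(pair)
                    add_harm(*pair, 80.0)

    # distance-cutoff contacts among heavy atoms: the elastic-network part
    seen = bonded_pairs | one_three
    heavy_sorted = sorted(heavy - {metal})
    for a_idx, i in enumerate(heavy_sorted):
        for j in heavy_sorted[a_idx + 1:]:
            if (i, j) in seen or i in special or j in special:
                continue
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < 5.0:
                harm.append((i, j, d, 8.0))
                seen.add((i, j))

    # weak frame tethers: every mobile heavy atom to the metal and to its two
    # nearest frozen scaffold atoms (keeps the network minimum unique)
    frozen_list = sorted(frozen)
    for i in heavy_sorted:
        if i in frozen or i in special:
            continue
        if i not in donors:
            harm.append((min(i, metal), max(i, metal), float(dists[i]), 2.0))
        if frozen_list:
            df = np.array([np.linalg.norm(pos[i] - pos[f]) for f in frozen_list])
            for f_idx in np.argsort(df)[:3]:
                f = frozen_list[f_idx]
                pair = (min(i, f), max(i, f))
                if pair not in seen:
                    harm.append((*pair, float(df[f_idx]), 3.0))
                    seen.add(pair)

    # 12-6 background for the remaining medium-range heavy pairs; the vdW
    # contact minimum sits well inside the native separations, so these act
    # as excluded-volume guards with only feeble forces at the ground truth
    from .constants import vdw_radius
    lj = []
    for a_idx, i in enumerate(heavy_sorted):
        for j in heavy_sorted[a_idx + 1:]:
            if (i, j) in seen or i in special or j in special:
                continue
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < 8.0:
                sigma = 0.90 * (vdw_radius(system.atoms[i].element)
                                + vdw_radius(system.atoms[j].element))
                lj.append((i, j, sigma, 0.05))

    harm = sorted(harm)
    morse_j = np.array(donors, dtype=int)
    morse_offset = np.array([dists[j] - spec.metal_radius for j in donors])

    nb_exclusions = [(hb.hydrogen, hb.acceptor) for hb in hbonds]
    if transfer is not None:
        for key in ("o1", "o2", "c1", "c2", "ho2"):
            if key in sub:
                nb_exclusions.append((transfer.c, sub[key]))

    return SurrogateParams(
        n_atoms=n,
        harm_i=np.array([t[0] for t in harm], dtype=int),
        harm_j=np.array([t[1] for t in harm], dtype=int),
        harm_r0=np.array([t[2] for t in harm]),
        harm_k=np.array([t[3] for t in harm]),
        metal=metal,
        morse_j=morse_j,
        morse_offset=morse_offset,
        metal_radius=spec.metal_radius,
        metal_charge=spec.metal_charge,
        lj_i=np.array([t[0] for t in lj], dtype=int),
        lj_j=np.array([t[1] for t in lj], dtype=int),
        lj_sigma=np.array([t[2] for t in lj]),
        lj_eps=np.array([t[3] for t in lj]),
        hbonds=hbonds,
        transfer=transfer,
        proton=proton,
        nb_exclusions=nb_exclusions,
    )


# ---------------------------------------------------------------------------
# operators


def distort(system: MolecularSystem, sigma: float, seed: int) -> MolecularSystem:
    """Gaussian positional noise on every non-frozen atom.

    Frozen atoms (anchors, donor-group scaffold) are untouched; bonds and
    roles are unchanged.  The distorted copy is what recovery experiments
    start from.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = system.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(system.n_atoms, 3))
    noise[system.frozen_mask] = 0.0
    out.set_positions(system.positions + noise)
    return out


def make_metal_variant(system: MolecularSystem, metal_radius: float,
                       metal_charge: float,
                       label: str | None = None) -> MolecularSystem:
    """Swap the metal's backend parameters (and optionally its label).

    Geometry is deliberately unchanged — relaxing to the new cation's
    preferred coordination is the pipeline's job.
    """
    if "metal" not in system.roles or not system.roles["metal"]:
        raise ValueError("system has no metal role")
    out = system.copy()
    if label is not None:
        m = out.atoms[out.metal_id]
        m.element = label.upper() if label.upper() in ("MG", "CA", "FE") else m.element
        m.atom_name = "M"
        m.residue_name = "MTL"
        try:
            m.mass = atomic_mass(label)
        except KeyError:
            pass
    if out.backend_params is not None:
        out.backend_params = out.backend_params.with_metal(metal_radius,
                                                           metal_charge)
    return out


def make_preset(preset: str, seed: int = 0, **overrides):
    """Convenience: toy site for one of the stock metal presets."""
    label, radius, charge = METAL_PRESETS[preset]
    spec = ToySiteSpec(metal_label=label, metal_radius=radius,
                       metal_charge=charge, seed=seed, **overrides)
    return make_toy_site(spec)
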