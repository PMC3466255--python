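"""Event-driven discrete molecular dynamics on stepwise potentials.

Atoms move ballistically between instantaneous events; at a shell crossing
the pair's radial velocity is updated by exact energy/momentum conservation
(or reflected if the kinetic energy cannot pay the step), so total energy is
conserved to rounding between thermostat events.  Supported stepwise
potentials:

* covalent bonds — infinite square wells [0.95·ref, 1.05·ref];
* constraint windows — infinite square wells [target − w, target + w]
  transferred from the optimized cluster (w defaults to 0.01 Å);
* generic nonbonded pairs — a hard core at 0.85·(r_vdw,i + r_vdw,j) with two
  attractive shells at 1.0× and 1.25× of the vdW contact (depths −0.10 and
  −0.05 kcal/mol).

The thermostat is Andersen-style: each free atom suffers ghost collisions as
a Poisson process and has its velocity resampled from Maxwell–Boltzmann at
the set-point.  Reduced units: temperature θ in kcal/mol with
⟨KE⟩ = (3 N_free / 2) θ; the time unit is ≈ 48.89 fs.

Frozen atoms (static scaffold plus the metal core during sampling) never
move; fully frozen pairs carry no potential.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import vdw_radius
from .model_io import MolecularSystem
from .partition import ConstraintSet, DomainPartition

_INF = np.inf


@dataclass
class DMDParams:
    temperature: float = 0.10        # reduced θ, kcal/mol
    heat_exchange_rate: float = 0.1  # ghost collisions per atom per t.u.
    duration: float = 10_000.0       # t.u.
    save_interval: float = 10.0      # t.u.
    seed: int = 0
    tu_to_fs: float = 50.0           # nominal conversion for reporting only

    def __post_init__(self):
        for name in ("temperature", "duration", "save_interval", "tu_to_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.heat_exchange_rate < 0:
            raise ValueError("heat_exchange_rate must be >= 0")
        n = self.duration / self.save_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("save_interval must divide duration")

    @property
    def n_snapshots(self) -> int:
        return int(round(self.duration / self.save_interval))


@dataclass
class Schedule:
    """Annealing + production schedule of one sampling phase."""

    anneal_peak: float = 0.20
    anneal_final: float = 0.10
    anneal_steps: int = 5
    anneal_step_tu: float = 500.0
    production_tu: float = 10_000.0
    production_temperature: float = 0.10
    exchange_rate: float = 0.1
    save_interval: float = 10.0

    def anneal_temperatures(self):
        return list(np.linspace(self.anneal_peak, self.anneal_final,
                                self.anneal_steps))


@dataclass
class Trajectory:
    times: np.ndarray                 # t.u., strictly increasing
    positions: np.ndarray             # (n_snapshots, n_atoms, 3)
    potential_energies: np.ndarray    # kcal/mol
    kinetic_energies: np.ndarray      # kcal/mol
    params: DMDParams
    n_events: int = 0
    n_free: int = 0
    initial_energy: float = 0.0       # KE + PE at t = 0
    max_constraint_dev: float = 0.0   # max |d − target| seen at events/snapshots

    def __post_init__(self):
        dt = np.diff(self.times)
        if len(dt) and not np.all(dt > 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def n_snapshots(self):
        return len(self.times)

    @property
    def final_positions(self):
        return self.positions[-1]


@dataclass
class PotentialTable:
    pair_i: np.ndarray
    pair_j: np.ndarray
    shell_ptr: np.ndarray     # CSR over squared shell radii
    shell_r2: np.ndarray
    u_ptr: np.ndarray         # CSR over region energies (len shells + 1)
    u: np.ndarray
    con_mask: np.ndarray      # pair carries a constraint window
    con_ref: np.ndarray       # constraint target (0 where not constrained)
    frozen: np.ndarray        # the freeze mask the table was built against
    kinds: list               # per-pair: "bond" | "constraint" | "bond+constraint" | "nonbonded"

    @property
    def n_pairs(self):
        return len(self.pair_i)

    def window(self, p: int):
        """Allowed radial interval [lo, hi] of pair p (hi may be inf)."""
        lo = math.sqrt(self.shell_r2[self.shell_ptr[p]])
        last_u = self.u[self.u_ptr[p + 1] - 1]
        hi = math.sqrt(self.shell_r2[self.shell_ptr[p + 1] - 1]) \
            if not np.isfinite(last_u) else _INF
        return lo, hi


# ---------------------------------------------------------------------------
# potential construction


def build_potentials(system: MolecularSystem,
                     constraints: ConstraintSet | None = None,
                     partition: DomainPartition | None = None,
                     core_factor: float = 0.85,
                     well_depths: tuple = (-0.10, -0.05),
                     bond_window: float = 0.05,
                     angle_window: float = 0.10,
                     positions: np.ndarray | None = None) -> PotentialTable:
    """Classify every interacting pair and build its stepwise potential.

    Each pair carries exactly one potential, with priority
    bond∩constraint > bond > constraint > angle (1-3) > nonbonded.  The 1-3
    square wells (±``angle_window``, referenced at the build-time geometry)
    stand in for the angle terms of a full force-field parameterization.
    1-2/1-3/1-4 pairs, pairs involving the metal, declared H-bond contacts
    and fully frozen pairs get no generic nonbonded shells.  A bond and a
    constraint on the same pair with an empty window intersection is an
    error.
    """
    n = system.n_atoms
    frozen = system.frozen_mask.copy()
    if partition is not None:
        for i in partition.qm_only:
            frozen[i] = True
    metal = system.metal_id if system.roles.get("metal") else -1

    bonds = {}
    for i, j, r in system.bonds.pairs():
        bonds[(i, j)] = r
    # bonded-topology exclusions: 1-3 and 1-4 pairs carry no nonbonded shells
    pure13 = set()
    for j in range(n):
        nb = sorted(system.bonds.neighbors(j))
        for a in range(len(nb)):
            for c in range(a + 1, len(nb)):
                pure13.add((nb[a], nb[c]))
    one_three = set(pure13)
    for (i, j) in list(bonds):
        for a in system.bonds.neighbors(i):
            for c in system.bonds.neighbors(j):
                if a != j and c != i and a != c:
                    one_three.add((min(a, c), max(a, c)))
    con = {}
    if constraints is not None:
        for a, b, target, w in constraints:
            con[(min(a, b), max(a, b))] = (target, w)
    exclusions = set()
    bp = getattr(system, "backend_params", None)
    if bp is not None:
        for a, b in getattr(bp, "nb_exclusions", ()):
            exclusions.add((min(a, b), max(a, b)))

    pair_i, pair_j, kinds = [], [], []
    shells, energies = [], []

    def emit(i, j, kind, r_list, u_list):
        pair_i.append(i)
        pair_j.append(j)
        kinds.append(kind)
        shells.append([r * r for r in r_list])
        energies.append(u_list)

    for (i, j), r in sorted(bonds.items()):
        if frozen[i] and frozen[j]:
            continue
        lo, hi = (1 - bond_window) * r, (1 + bond_window) * r
        kind = "bond"
        if (i, j) in con:
            target, w = con.pop((i, j))
            lo2, hi2 = max(lo, target - w), min(hi, target + w)
            if lo2 >= hi2:
                raise ValueError(
                    f"bond and constraint windows on pair ({i},{j}) do not "
                    f"intersect: [{lo:.3f},{hi:.3f}] vs "
                    f"[{target - w:.3f},{target + w:.3f}]")
            lo, hi = lo2, hi2
            kind = "bond+constraint"
        emit(i, j, kind, [lo, hi], [_INF, 0.0, _INF])

    for (i, j), (target, w) in sorted(con.items()):
        if frozen[i] and frozen[j]:
            continue
        emit(i, j, "constraint", [target - w, target + w], [_INF, 0.0, _INF])

    # 1-3 angle-analog wells, referenced at the topology's rest geometry
    pos_now = system.positions if positions is None else np.asarray(positions)
    refs13 = system.angle_refs or {}
    if angle_window > 0:
        done = {(min(a, b), max(a, b)) for a, b in zip(pair_i, pair_j)}
        for (i, j) in sorted(pure13):
            if (frozen[i] and frozen[j]) or (i, j) in done:
                continue
            r = refs13.get((i, j))
            if r is None:
                r = float(np.linalg.norm(pos_now[i] - pos_now[j]))
            emit(i, j, "angle",
                 [(1 - angle_window) * r, (1 + angle_window) * r],
                 [_INF, 0.0, _INF])

    # packing cages: finite attractive wells around the rest distance of a
    # mobile atom to its frozen-frame references (deepest region at the rest
    # distance; escape costs a few θ, so arms rattle instead of diffusing)
    done = {(min(a, b), max(a, b)) for a, b in zip(pair_i, pair_j)}
    for (i, j), d0 in sorted((system.packing_refs or {}).items()):
        if (frozen[i] and frozen[j]) or (i, j) in done or (i, j) in bonds \
                or (i, j) in one_three or metal in (i, j):
            continue
        core = core_factor * (vdw_radius(system.atoms[i].element)
                              + vdw_radius(system.atoms[j].element))
        if core < d0 - 0.3:
            emit(i, j, "packing", [core, d0 - 0.3, d0 + 0.3, d0 + 0.9],
                 [_INF, -0.15, -0.5, -0.15, 0.0])
        elif core < d0 + 0.3:
            emit(i, j, "packing", [core, d0 + 0.3, d0 + 0.9],
                 [_INF, -0.5, -0.15, 0.0])
        else:
            continue
        done.add((i, j))

    d1, d2 = well_depths
    con_keys = {(min(a, b), max(a, b)) for a, b, *_ in (constraints or [])}
    con_keys |= done
    for i in range(n):
        for j in range(i + 1, n):
            if frozen[i] and frozen[j]:
                continue
            if metal in (i, j):
                continue
            key = (i, j)
            if key in bonds or key in one_three or key in exclusions:
                continue
            if key in con_keys:
                continue
            sigma = vdw_radius(system.atoms[i].element) + \
                vdw_radius(system.atoms[j].element)
            emit(i, j, "nonbonded",
                 [core_factor * sigma, sigma, 1.25 * sigma],
                 [_INF, d1, d2, 0.0])

    shell_ptr = np.zeros(len(pair_i) + 1, dtype=np.int64)
    u_ptr = np.zeros(len(pair_i) + 1, dtype=np.int64)
    for p, (s, u) in enumerate(zip(shells, energies)):
        shell_ptr[p + 1] = shell_ptr[p] + len(s)
        u_ptr[p + 1] = u_ptr[p] + len(u)
    con_mask = np.array([k in ("constraint", "bond+constraint") for k in kinds],
                        dtype=np.bool_)
    con_ref = np.zeros(len(pair_i))
    for p, (i, j) in enumerate(zip(pair_i, pair_j)):
        if con_mask[p]:
            if constraints is not None:
                for a, b, target, w in constraints:
                    if (min(a, b), max(a, b)) == (i, j):
                        con_ref[p] = target
    return PotentialTable(
        pair_i=np.array(pair_i, dtype=np.int64),
        pair_j=np.array(pair_j, dtype=np.int64),
        shell_ptr=shell_ptr,
        shell_r2=np.array([x for s in shells for x in s]),
        u_ptr=u_ptr,
        u=np.array([x for u in energies for x in u]),
        con_mask=con_mask,
        con_ref=con_ref,
        frozen=frozen,
        kinds=kinds,
    )


# ---------------------------------------------------------------------------
# numba core


@njit(cache=True)
def _heap_swap(heap, hpos, a, b):
    heap[a], heap[b] = heap[b], heap[a]
    hpos[heap[a]] = a
    hpos[heap[b]] = b


@njit(cache=True)
def _heap_less(key, heap, a, b):
    ka, kb = key[heap[a]], key[heap[b]]
    if ka != kb:
        return ka < kb
    return heap[a] < heap[b]


@njit(cache=True)
def _heap_up(heap, hpos, key, i):
    while i > 0:
        parent = (i - 1) // 2
        if _heap_less(key, heap, i, parent):
            _heap_swap(heap, hpos, i, parent)
            i = parent
        else:
            break


@njit(cache=True)
def _heap_down(heap, hpos, key, size, i):
    while True:
        lo = i
        left, right = 2 * i + 1, 2 * i + 2
        if left < size and _heap_less(key, heap, left, lo):
            lo = left
        if right < size and _heap_less(key, heap, right, lo):
            lo = right
        if lo == i:
            break
        _heap_swap(heap, hpos, i, lo)
        i = lo


@njit(cache=True)
def _heap_update(heap, hpos, key, size, slot, t):
    key[slot] = t
    p = hpos[slot]
    _heap_up(heap, hpos, key, p)
    _heap_down(heap, hpos, key, size, p)


@njit(cache=True)
def _predict(p, tnow, pos, vel, t_at, pair_i, pair_j, sptr, s_r2, region):
    i = pair_i[p]
    j = pair_j[p]
    drx = (pos[j, 0] + vel[j, 0] * (tnow - t_at[j])) - \
          (pos[i, 0] + vel[i, 0] * (tnow - t_at[i]))
    dry = (pos[j, 1] + vel[j, 1] * (tnow - t_at[j])) - \
          (pos[i, 1] + vel[i, 1] * (tnow - t_at[i]))
    drz = (pos[j, 2] + vel[j, 2] * (tnow - t_at[j])) - \
          (pos[i, 2] + vel[i, 2] * (tnow - t_at[i]))
    dvx = vel[j, 0] - vel[i, 0]
    dvy = vel[j, 1] - vel[i, 1]
    dvz = vel[j, 2] - vel[i, 2]
    a = dvx * dvx + dvy * dvy + dvz * dvz
    if a <= 0.0:
        return np.inf
    b = drx * dvx + dry * dvy + drz * dvz
    r2 = drx * drx + dry * dry + drz * drz
    k = region[p]
    m = sptr[p + 1] - sptr[p]
    best = np.inf
    if k > 0 and b < 0.0:
        s2 = s_r2[sptr[p] + k - 1]
        c = r2 - s2
        if c < 0.0:
            c = 0.0
        disc = b * b - a * c
        if disc > 0.0:
            dt = (-b - math.sqrt(disc)) / a
            if dt < best:
                best = dt
    if k < m:
        s2 = s_r2[sptr[p] + k]
        c = r2 - s2
        if c > 0.0:
            c = 0.0
        dt = (-b + math.sqrt(b * b - a * c)) / a
        if 0.0 <= dt < best:
            best = dt
    return best


@njit(cache=True)
def _run_core(pos, vel, t_at, mass, free, pair_i, pair_j, sptr, s_r2, uptr, u,
              region, con_mask, con_ref, adj_ptr, adj_pair,
              temperature, exch_rate, duration, save_interval, seed,
              draw_velocities):
    n_atoms = pos.shape[0]
    n_pairs = len(pair_i)
    n_slots = n_pairs + n_atoms
    n_snap = int(round(duration / save_interval))

    np.random.seed(seed)
    if draw_velocities:
        for i in range(n_atoms):
            if free[i]:
                s = math.sqrt(temperature / mass[i])
                for c in range(3):
                    vel[i, c] = np.random.normal(0.0, s)
            else:
                for c in range(3):
                    vel[i, c] = 0.0

    # initial potential energy from region energies
    pe = 0.0
    for p in range(n_pairs):
        pe += u[uptr[p] + region[p]]
    ke = 0.0
    for i in range(n_atoms):
        ke += 0.5 * mass[i] * (vel[i, 0]**2 + vel[i, 1]**2 + vel[i, 2]**2)
    e_init = ke + pe

    key = np.full(n_slots, np.inf)
    heap = np.arange(n_slots)
    hpos = np.arange(n_slots)
    for p in range(n_pairs):
        key[p] = _predict(p, 0.0, pos, vel, t_at, pair_i, pair_j, sptr, s_r2,
                          region)
    if exch_rate > 0.0:
        for i in range(n_atoms):
            if free[i]:
                key[n_pairs + i] = np.random.exponential(1.0 / exch_rate)
    # heapify
    for i in range(n_slots // 2 - 1, -1, -1):
        _heap_down(heap, hpos, key, n_slots, i)

    snaps = np.empty((n_snap, n_atoms, 3))
    snap_pe = np.empty(n_snap)
    snap_ke = np.empty(n_snap)
    max_dev = 0.0
    n_events = 0
    status = 0
    t_now = 0.0
    next_snap = save_interval
    snap_idx = 0
    max_events = 400_000_000

    while snap_idx < n_snap:
        slot = heap[0]
        t_ev = key[slot]
        if t_ev > next_snap or not np.isfinite(t_ev):
            # advance everything to the snapshot time and record
            for i in range(n_atoms):
                if free[i]:
                    dt = next_snap - t_at[i]
                    pos[i, 0] += vel[i, 0] * dt
                    pos[i, 1] += vel[i, 1] * dt
                    pos[i, 2] += vel[i, 2] * dt
                t_at[i] = next_snap
            ke = 0.0
            for i in range(n_atoms):
                ke += 0.5 * mass[i] * (vel[i, 0]**2 + vel[i, 1]**2
                                       + vel[i, 2]**2)
            snaps[snap_idx] = pos
            snap_pe[snap_idx] = pe
            snap_ke[snap_idx] = ke
            for p in range(n_pairs):
                if con_mask[p]:
                    i = pair_i[p]
                    j = pair_j[p]
                    d = math.sqrt((pos[j, 0] - pos[i, 0])**2
                                  + (pos[j, 1] - pos[i, 1])**2
                                  + (pos[j, 2] - pos[i, 2])**2)
                    dev = abs(d - con_ref[p])
                    if dev > max_dev:
                        max_dev = dev
            t_now = next_snap
            next_snap += save_interval
            snap_idx += 1
            continue

        if t_ev < t_now - 1e-9:
            status = 1  # event-queue inconsistency
            break
        n_events += 1
        if n_events > max_events:
            status = 2
            break
        t_now = t_ev

        if slot >= n_pairs:
            # thermostat ghost collision
            i = slot - n_pairs
            dt = t_ev - t_at[i]
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt
            t_at[i] = t_ev
            s = math.sqrt(temperature / mass[i])
            for c in range(3):
                vel[i, c] = np.random.normal(0.0, s)
            _heap_update(heap, hpos, key, n_slots, slot,
                         t_ev + np.random.exponential(1.0 / exch_rate))
            for a in range(adj_ptr[i], adj_ptr[i + 1]):
                q = adj_pair[a]
                _heap_update(heap, hpos, key, n_slots, q,
                             t_ev + _predict(q, t_ev, pos, vel, t_at, pair_i,
                                             pair_j, sptr, s_r2, region))
            continue

        p = slot
        i = pair_i[p]
        j = pair_j[p]
        for idx in (i, j):
            if free[idx]:
                dt = t_ev - t_at[idx]
                pos[idx, 0] += vel[idx, 0] * dt
                pos[idx, 1] += vel[idx, 1] * dt
                pos[idx, 2] += vel[idx, 2] * dt
            t_at[idx] = t_ev
        drx = pos[j, 0] - pos[i, 0]
        dry = pos[j, 1] - pos[i, 1]
        drz = pos[j, 2] - pos[i, 2]
        dist = math.sqrt(drx * drx + dry * dry + drz * drz)
        nx, ny, nz = drx / dist, dry / dist, drz / dist
        v_r = ((vel[j, 0] - vel[i, 0]) * nx + (vel[j, 1] - vel[i, 1]) * ny
               + (vel[j, 2] - vel[i, 2]) * nz)

        # which boundary: nearest shell radius to the contact distance
        k = region[p]
        m = sptr[p + 1] - sptr[p]
        outward = v_r > 0.0
        if k == 0:
            outward = True
        elif k == m:
            outward = False
        k2 = k + 1 if outward else k - 1

        if free[i] and free[j]:
            mu = mass[i] * mass[j] / (mass[i] + mass[j])
        elif free[i]:
            mu = mass[i]
        else:
            mu = mass[j]
        dU = u[uptr[p] + k2] - u[uptr[p] + k]
        if not np.isfinite(dU):
            v_r2 = -v_r
        elif 0.5 * mu * v_r * v_r > dU:
            sgn = 1.0 if v_r > 0.0 else -1.0
            v_r2 = sgn * math.sqrt(v_r * v_r - 2.0 * dU / mu)
            region[p] = k2
            pe += dU
        else:
            v_r2 = -v_r
        imp = mu * (v_r2 - v_r)
        if free[i]:
            vel[i, 0] -= imp * nx / mass[i]
            vel[i, 1] -= imp * ny / mass[i]
            vel[i, 2] -= imp * nz / mass[i]
        if free[j]:
            vel[j, 0] += imp * nx / mass[j]
            vel[j, 1] += imp * ny / mass[j]
            vel[j, 2] += imp * nz / mass[j]

        if con_mask[p]:
            dev = abs(dist - con_ref[p])
            if dev > max_dev:
                max_dev = dev

        for a in range(adj_ptr[i], adj_ptr[i + 1]):
            q = adj_pair[a]
            _heap_update(heap, hpos, key, n_slots, q,
                         t_ev + _predict(q, t_ev, pos, vel, t_at, pair_i,
                                         pair_j, sptr, s_r2, region))
        for a in range(adj_ptr[j], adj_ptr[j + 1]):
            q = adj_pair[a]
            if q != p:
                _heap_update(heap, hpos, key, n_slots, q,
                             t_ev + _predict(q, t_ev, pos, vel, t_at, pair_i,
                                             pair_j, sptr, s_r2, region))

    return snaps, snap_pe, snap_ke, max_dev, n_events, e_init, status


# ---------------------------------------------------------------------------
# python-side orchestration


def _initial_regions(pos, table: PotentialTable):
    regions = np.zeros(table.n_pairs, dtype=np.int64)
    for p in range(table.n_pairs):
        i, j = table.pair_i[p], table.pair_j[p]
        r2 = float(np.sum((pos[j] - pos[i]) ** 2))
        s = table.shell_r2[table.shell_ptr[p]:table.shell_ptr[p + 1]]
        regions[p] = int(np.searchsorted(s, r2))
    return regions


def _violations(pos, table: PotentialTable, regions=None):
    if regions is None:
        regions = _initial_regions(pos, table)
    bad = []
    for p in range(table.n_pairs):
        if not np.isfinite(table.u[table.u_ptr[p] + regions[p]]):
            bad.append(p)
    return bad


def relieve_clashes(pos, table: PotentialTable):
    """Descent on overlap depth until no pair sits in a forbidden region.

    Minimizes a smooth penalty (squared distance to the inside of each
    pair's allowed window, with a small interior margin) over the free
    atoms.  Raises if a violation involves two frozen atoms or cannot be
    resolved.
    """
    from scipy.optimize import minimize

    pos0 = np.array(pos, dtype=float)
    frozen = table.frozen
    for p in _violations(pos0, table):
        i, j = int(table.pair_i[p]), int(table.pair_j[p])
        if frozen[i] and frozen[j]:
            raise RuntimeError(f"frozen pair ({i},{j}) violates its potential "
                               "window; cannot relieve")
    free_idx = np.nonzero(~frozen)[0]
    n_pairs = table.n_pairs
    lo_w = np.empty(n_pairs)
    hi_w = np.empty(n_pairs)
    for p in range(n_pairs):
        lo_w[p], hi_w[p] = table.window(p)
    finite = np.isfinite(hi_w)
    center = np.where(finite, 0.5 * (lo_w + hi_w), lo_w)
    half = np.where(finite, 0.5 * (hi_w - lo_w), 0.0)
    pi, pj = table.pair_i, table.pair_j

    def make_fun(scale):
        # finite wells widened by `scale` during the homotopy; hard cores
        # keep a small interior margin throughout
        los = np.where(finite, center - scale * 0.9 * half, lo_w + 0.02)
        his = np.where(finite, center + scale * 0.9 * half, np.inf)

        def fun(x):
            p = pos0.copy()
            p[free_idx] = x.reshape(-1, 3)
            dvec = p[pj] - p[pi]
            d = np.maximum(np.linalg.norm(dvec, axis=1), 1e-9)
            excess = np.where(d < los, d - los, np.where(d > his, d - his, 0.0))
            e = float(np.sum(excess**2))
            g = np.zeros_like(p)
            f = (2.0 * excess / d)[:, None] * dvec
            np.add.at(g, pj, f)
            np.add.at(g, pi, -f)
            return e, g[free_idx].ravel()
        return fun

    rng = np.random.default_rng(1234)
    x0 = pos0[free_idx].ravel()
    for attempt in range(6):
        x = x0.copy()
        for scale in (6.0, 3.0, 1.5, 1.0):
            res = minimize(make_fun(scale), x, jac=True, method="L-BFGS-B",
                           options={"maxiter": 3000, "ftol": 1e-18,
                                    "gtol": 1e-12})
            x = res.x
        out = pos0.copy()
        out[free_idx] = x.reshape(-1, 3)
        bad = _violations(out, table)
        if not bad:
            return out
        x0 = pos0[free_idx].ravel() + rng.normal(
            0.0, 0.05 * (attempt + 1), size=x0.shape)
    names = [(int(table.pair_i[p]), int(table.pair_j[p]), table.kinds[p])
             for p in bad[:8]]
    raise RuntimeError(f"clash relief did not converge; violated pairs {names}")


def _adjacency(table: PotentialTable, n_atoms: int):
    lists = [[] for _ in range(n_atoms)]
    for p in range(table.n_pairs):
        lists[table.pair_i[p]].append(p)
        lists[table.pair_j[p]].append(p)
    ptr = np.zeros(n_atoms + 1, dtype=np.int64)
    flat = []
    for i, lst in enumerate(lists):
        ptr[i + 1] = ptr[i] + len(lst)
        flat.extend(lst)
    return ptr, np.array(flat, dtype=np.int64)


def run_phase(system: MolecularSystem, partition: DomainPartition | None,
              potentials: PotentialTable, params: DMDParams,
              start_positions: np.ndarray | None = None) -> Trajectory:
    """One constant-temperature DMD phase; returns saved snapshots.

    The metal core (``partition.qm_only``) and statically frozen atoms never
    move.  If the starting geometry violates a hard window, a clash-relief
    pre-step fixes it with a warning.
    """
    pos = np.array(system.positions if start_positions is None
                   else start_positions, dtype=float)
    table = potentials
    if _violations(pos, table):
        warnings.warn("initial geometry violates stepwise windows; running "
                      "clash-relief pre-step")
        pos = relieve_clashes(pos, table)
    regions = _initial_regions(pos, table)
    free = ~table.frozen
    mass = system.masses
    adj_ptr, adj_pair = _adjacency(table, system.n_atoms)
    vel = np.zeros_like(pos)
    t_at = np.zeros(system.n_atoms)
    snaps, pe, ke, max_dev, n_events, e_init, status = _run_core(
        pos, vel, t_at, mass, free, table.pair_i, table.pair_j,
        table.shell_ptr, table.shell_r2, table.u_ptr, table.u, regions,
        table.con_mask, table.con_ref, adj_ptr, adj_pair,
        float(params.temperature), float(params.heat_exchange_rate),
        float(params.duration), float(params.save_interval),
        int(params.seed) % (2**31 - 1), True)
    if status == 1:
        raise RuntimeError("event-queue inconsistency (negative time)")
    if status == 2:
        raise RuntimeError("event budget exhausted")
    times = params.save_interval * np.arange(1, params.n_snapshots + 1)
    return Trajectory(times=times, positions=snaps, potential_energies=pe,
                      kinetic_energies=ke, params=params, n_events=int(n_events),
                      n_free=int(free.sum()), initial_energy=float(e_init),
                      max_constraint_dev=float(max_dev))


def run_schedule(system: MolecularSystem, partition: DomainPartition | None,
                 potentials: PotentialTable, seed: int,
                 schedule: Schedule | None = None) -> Trajectory:
    """Anneal (ramp to the peak, stepwise decrease) then collect production.

    Only production snapshots are returned.  The temperature set-point
    changes instantaneously at each step boundary; velocities are redrawn
    from Maxwell–Boltzmann at each new set-point.
    """
    schedule = schedule or Schedule()
    pos = system.positions
    for k, theta in enumerate(schedule.anneal_temperatures()):
        params = DMDParams(temperature=float(theta),
                           heat_exchange_rate=schedule.exchange_rate,
                           duration=schedule.anneal_step_tu,
                           save_interval=schedule.anneal_step_tu,
                           seed=seed + 17 * (k + 1))
        traj = run_phase(system, partition, potentials, params,
                         start_positions=pos)
        pos = traj.final_positions
    params = DMDParams(temperature=schedule.production_temperature,
                       heat_exchange_rate=schedule.exchange_rate,
                       duration=schedule.production_tu,
                       save_interval=schedule.save_interval,
                       seed=seed)
    return run_phase(system, partition, potentials, params,
                     start_positions=pos)


def remove_clashes(system: MolecularSystem,
                   partition: DomainPartition | None,
                   potentials: PotentialTable, seed: int) -> MolecularSystem:
    """Short high-exchange run that shakes out bad contacts.

    1,000 t.u. at θ = 0.10 with a heat-exchange rate of 10 t.u.⁻¹; returns
    the final frame as a new system.
    """
    params = DMDParams(temperature=0.10, heat_exchange_rate=10.0,
                       duration=1000.0, save_interval=100.0, seed=seed)
    traj = run_phase(system, partition, potentials, params)
    out = system.copy()
    out.set_positions(traj.final_positions)
    return out
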