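"""Ensemble machinery and the sampling/optimization iteration loop.

One iteration: anneal + production sampling → hierarchical clustering of the
snapshot ensemble on pairwise Kabsch RMSD → two representatives per cluster
(closest to the centroid, lowest sampling energy) → backend single points →
rank-sum choice of a single structure → extract + cap + partial optimization
→ reinstallation → energy-based acceptance against the iteration's input
(the lower active-site-subset energy carries forward).  Constraint windows
for the next round of sampling are read off the freshly optimized cluster.

The loop's convergence record mirrors the usual traces: frame RMSD between
consecutive carried structures, all-atom RMSD of the active-site region, and
the subset energy per iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from . import model_io
from .backend import SurrogateBackend
from .dmd import Schedule, Trajectory, build_potentials, remove_clashes, run_schedule
from .model_io import MolecularSystem
from .partition import (CappedCluster, DomainPartition, assign_domains,
                        constraints_from_cluster, extract_capped_cluster,
                        reinstall_cluster)


# ---------------------------------------------------------------------------
# Kabsch RMSD


def kabsch_rmsd(A: np.ndarray, B: np.ndarray, selection=None) -> float:
    """Minimal RMSD of B onto A over rigid rotation + translation (Å)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if selection is not None:
        sel = np.asarray(sorted(selection), dtype=int)
        A, B = A[sel], B[sel]
    if len(A) < 3:
        raise ValueError("Kabsch superposition needs at least 3 atoms")
    X = A - A.mean(axis=0)
    Y = B - B.mean(axis=0)
    C = X.T @ Y
    U, S, Vt = np.linalg.svd(C)
    if np.linalg.det(U @ Vt) < 0:
        S = S.copy()
        S[-1] = -S[-1]
    msd = (np.sum(X * X) + np.sum(Y * Y) - 2.0 * np.sum(S)) / len(A)
    return float(np.sqrt(max(msd, 0.0)))


def pairwise_rmsd_matrix(coords: np.ndarray, chunk: int = 64) -> np.ndarray:
    """All-pairs Kabsch RMSD for frames of shape (n_frames, n_atoms, 3)."""
    X = coords - coords.mean(axis=1, keepdims=True)
    n, k, _ = X.shape
    G = np.einsum("nij,nij->n", X, X)
    D = np.zeros((n, n))
    for a0 in range(0, n, chunk):
        a1 = min(a0 + chunk, n)
        C = np.einsum("aki,bkj->abij", X[a0:a1], X)
        U, S, Vt = np.linalg.svd(C)
        det = np.linalg.det(U @ Vt)
        S[..., -1] = np.where(det < 0, -S[..., -1], S[..., -1])
        msd = (G[a0:a1, None] + G[None, :] - 2.0 * S.sum(axis=-1)) / k
        D[a0:a1] = np.sqrt(np.clip(msd, 0.0, None))
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# ensemble clustering and selection


def cluster_ensemble(trajectory: Trajectory, k: int = 5, selection=None,
                     rmsd_matrix: np.ndarray | None = None):
    """Average-linkage clustering of snapshots on pairwise Kabsch RMSD.

    Returns (labels 0..k-1 per snapshot, rmsd matrix).  Deterministic for a
    fixed snapshot order; degenerate (identical) snapshots are allowed and
    split by snapshot index.
    """
    n = trajectory.n_snapshots
    if k < 1 or k > n:
        raise ValueError(f"cannot make {k} clusters from {n} snapshots")
    sel = (np.arange(trajectory.positions.shape[1]) if selection is None
           else np.asarray(sorted(selection), dtype=int))
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(trajectory.positions[:, sel])
    if k == 1:
        return np.zeros(n, dtype=int), rmsd_matrix
    Z = linkage(squareform(rmsd_matrix, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    if labels.max() + 1 < k:
        # fully degenerate ensembles: pad by splitting the first snapshots off
        labels = labels.copy()
        extra = k - (labels.max() + 1)
        for i in range(extra):
            labels[i] = labels.max() + 1
    return labels, rmsd_matrix


@dataclass
class Representative:
    cluster: int
    centroid_snapshot: int
    min_energy_snapshot: int

    @property
    def snapshot_ids(self):
        return {self.centroid_snapshot, self.min_energy_snapshot}


def select_representatives(assignment, trajectory: Trajectory,
                           rmsd_matrix: np.ndarray) -> list[Representative]:
    """Centroid (min summed RMSD to cluster members) and lowest sampling
    energy, per cluster."""
    assignment = np.asarray(assignment)
    reps = []
    for c in range(assignment.max() + 1):
        members = np.nonzero(assignment == c)[0]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        sub = rmsd_matrix[np.ix_(members, members)]
        centroid = int(members[np.argmin(sub.sum(axis=1))])
        emin = int(members[np.argmin(trajectory.potential_energies[members])])
        reps.append(Representative(c, centroid, emin))
    return reps


def score_and_choose(rep_snapshots, qm_energies, dmd_energies) -> int:
    """Rank-sum scoring: rank(backend energy) + rank(sampling energy).

    Lowest combined score wins; ties go to the lower backend energy, then to
    the lower snapshot index.  Returns the chosen snapshot id.
    """
    qm = np.asarray(qm_energies, dtype=float)
    dmd_e = np.asarray(dmd_energies, dtype=float)
    if not (np.all(np.isfinite(qm)) and np.all(np.isfinite(dmd_e))):
        raise ValueError("energies must be finite")
    score = rankdata(qm, method="min") + rankdata(dmd_e, method="min")
    order = sorted(range(len(rep_snapshots)),
                   key=lambda i: (score[i], qm[i], rep_snapshots[i]))
    return int(rep_snapshots[order[0]])


def accept_iteration(input_system: MolecularSystem,
                     output_system: MolecularSystem,
                     subset, backend: SurrogateBackend):
    """Energy-based acceptance on the active-site subset.

    Returns (carried_system, which, e_input, e_output); ties prefer the
    output (progress).
    """
    subset = sorted(subset)
    if not subset:
        raise ValueError("acceptance subset is empty")
    mask = np.zeros(input_system.n_atoms, dtype=bool)
    mask[subset] = True
    e_in = backend.energy(input_system.positions, mask)
    e_out = backend.energy(output_system.positions, mask)
    if e_out <= e_in:
        return output_system, "output", e_in, e_out
    return input_system, "input", e_in, e_out


# ---------------------------------------------------------------------------
# iteration loop


def default_constraint_pairs(system: MolecularSystem) -> list:
    """Stock "green-line" pairs for toy sites: substrate body and methyl
    carbons to the metal/acceptor, plus each arm's first linker to the metal."""
    pairs = []
    m = system.metal_id
    for name in ("C1", "C2"):
        hit = system.find_atoms(name, role="substrate")
        if hit:
            pairs.append((hit[0], m))
    cm = system.find_atoms("CM", role="cofactor")
    o2 = system.find_atoms("O2", role="substrate")
    if cm and o2:
        pairs.append((cm[0], o2[0]))
    for a in system.atoms:
        if a.atom_name == "L1" and a.residue_name == "ARM":
            pairs.append((a.atom_id, m))
    return pairs


def acceptance_subset(system: MolecularSystem) -> set:
    """Active-site subset for the acceptance rule: metal, substrate, water
    and the site-residue fragments.  The cofactor and the statically frozen
    scaffold (anchors: the frame, not the active site) are excluded."""
    subset = set()
    for role in ("metal", "substrate", "water", "site_residues"):
        subset |= system.roles.get(role, set())
    return {i for i in subset if not system.atoms[i].frozen}


@dataclass
class IterationState:
    index: int
    chosen_snapshot: int
    representative_snapshots: list
    qm_energies: list
    dmd_energies: list
    accepted: str                     # "input" | "output"
    e_input: float
    e_output: float
    subset_energy: float              # of the carried structure
    frame_rmsd: float                 # heavy-atom RMSD to the previous carried
    region_rmsd: float                # all-atom RMSD of the active-site region
    positions: np.ndarray             # carried structure
    optimizer_converged: bool = True
    trajectory: Trajectory | None = None


class QmdmdRun:
    """Stateful iteration loop; ``step()`` runs one iteration.

    The clash-removal pre-run and the initial optimization that seeds the
    first constraint set happen once, in ``prepare()`` (called lazily).
    """

    def __init__(self, system: MolecularSystem, seed: int = 0,
                 schedule: Schedule | None = None, k_clusters: int = 5,
                 constraint_pairs=None, coordination_cutoff: float = 2.6,
                 constraint_half_width: float = 0.01, qm_tol: float = 1e-4,
                 keep_trajectories: bool = False):
        if system.backend_params is None:
            raise ValueError("system carries no backend parameterization")
        self.backend = SurrogateBackend(system.backend_params)
        self.system = system.copy()
        self.seed = int(seed)
        self.schedule = schedule or Schedule()
        self.k = int(k_clusters)
        self.constraint_pairs = (default_constraint_pairs(system)
                                 if constraint_pairs is None else
                                 list(constraint_pairs))
        self.cutoff = coordination_cutoff
        self.half_width = constraint_half_width
        self.qm_tol = qm_tol
        self.keep_trajectories = keep_trajectories
        self.subset = acceptance_subset(system)
        self.history: list[IterationState] = []
        self.constraints = None
        self._prepared = False

    # -- helpers ----------------------------------------------------------

    def _iter_seed(self, stage: int) -> int:
        return (self.seed * 100003 + stage * 9176 + 13) % (2**31 - 1)

    def _reactant_restraint(self):
        """Keeps the transfer coordinate on the reactant side during the
        sampling loop's optimizations: the iterative protocol equilibrates
        the reactant state; barrier crossing belongs to the mechanistic
        stage.  One-sided harmonic on ξ below half the reactant-well value."""
        tr = self.backend.params.transfer
        if tr is None:
            return None
        k_r = 50.0
        xi_min = 0.5 * tr.xi_well

        def pen(pos):
            vo = pos[tr.o] - pos[tr.c]
            vs = pos[tr.s] - pos[tr.c]
            dOC = np.linalg.norm(vo)
            dSC = np.linalg.norm(vs)
            xi = dOC - dSC
            g = np.zeros_like(pos)
            if xi >= xi_min:
                return 0.0, g
            e = 0.5 * k_r * (xi - xi_min) ** 2
            dE_dxi = k_r * (xi - xi_min)
            uo, us = vo / dOC, vs / dSC
            g[tr.o] += dE_dxi * uo
            g[tr.s] += -dE_dxi * us
            g[tr.c] += -dE_dxi * uo + dE_dxi * us
            return e, g
        return pen

    def _optimize_cluster(self, cluster: CappedCluster, base_positions):
        full, _ = cluster.full_positions(base_positions)
        mask = cluster.evaluation_mask()
        new_full, res = self.backend.partial_optimize(
            full, cluster.free_atoms, active=mask, tol=self.qm_tol,
            extra_objective=self._reactant_restraint())
        return cluster.with_positions(new_full), res

    def subset_energy(self, positions) -> float:
        mask = np.zeros(self.system.n_atoms, dtype=bool)
        mask[sorted(self.subset)] = True
        return float(self.backend.energy(positions, mask))

    # -- protocol ---------------------------------------------------------

    def prepare(self):
        """Clash removal, then one optimization pass to seed constraints.

        The clash-removal run precedes the partitioning machinery (no
        backend pass has happened yet), so only statically frozen scaffold
        atoms are held fixed during it.
        """
        table = build_potentials(self.system, None, None)
        self.system = remove_clashes(self.system, None, table,
                                     self._iter_seed(0))
        part = assign_domains(self.system, coordination_cutoff=self.cutoff)
        cluster = extract_capped_cluster(self.system, part)
        opt, res = self._optimize_cluster(cluster, self.system.positions)
        self.system = reinstall_cluster(self.system, opt)
        self.constraints = constraints_from_cluster(opt, self.constraint_pairs,
                                                    self.half_width)
        self._prepared = True

    def step(self) -> IterationState:
        if not self._prepared:
            self.prepare()
        it = len(self.history) + 1
        prev_positions = self.system.positions

        partition = assign_domains(self.system, coordination_cutoff=self.cutoff)
        table = build_potentials(self.system, self.constraints, partition)
        traj = run_schedule(self.system, partition, table,
                            self._iter_seed(it), self.schedule)

        heavy = set(self.system.heavy_atoms())
        region = sorted(partition.cluster_atoms & heavy)
        labels, D = cluster_ensemble(traj, self.k, selection=region)
        reps = select_representatives(labels, traj, D)
        snap_ids = sorted({s for r in reps for s in r.snapshot_ids})

        mask = np.zeros(self.system.n_atoms, dtype=bool)
        mask[sorted(partition.cluster_atoms)] = True
        mask[[b[1] for b in partition.boundary_bonds]] = True
        qm_e, dmd_e = [], []
        for s in snap_ids:
            qm_e.append(self.backend.energy(traj.positions[s], mask))
            dmd_e.append(float(traj.potential_energies[s]))
        chosen = score_and_choose(snap_ids, qm_e, dmd_e)

        chosen_system = self.system.copy()
        chosen_system.set_positions(traj.positions[chosen])
        chosen_partition = assign_domains(chosen_system,
                                          coordination_cutoff=self.cutoff)
        cluster = extract_capped_cluster(chosen_system, chosen_partition)
        opt, res = self._optimize_cluster(cluster, chosen_system.positions)
        output_system = reinstall_cluster(chosen_system, opt)

        carried, which, e_in, e_out = accept_iteration(
            self.system, output_system, self.subset, self.backend)
        if which == "output":
            self.constraints = constraints_from_cluster(
                opt, self.constraint_pairs, self.half_width)
        self.system = carried.copy()

        frame_rmsd = kabsch_rmsd(prev_positions, self.system.positions,
                                 selection=sorted(heavy))
        region_all = sorted(partition.cluster_atoms)
        region_rmsd = kabsch_rmsd(prev_positions, self.system.positions,
                                  selection=region_all)
        state = IterationState(
            index=it, chosen_snapshot=chosen,
            representative_snapshots=snap_ids, qm_energies=qm_e,
            dmd_energies=dmd_e, accepted=which, e_input=e_in, e_output=e_out,
            subset_energy=min(e_in, e_out), frame_rmsd=frame_rmsd,
            region_rmsd=region_rmsd, positions=self.system.positions,
            optimizer_converged=res.converged,
            trajectory=traj if self.keep_trajectories else None)
        self.history.append(state)
        return state

    def run(self, n_iterations: int = 20) -> list[IterationState]:
        for _ in range(n_iterations):
            self.step()
        return self.history


def run_qmdmd(system: MolecularSystem, n_iterations: int = 20, seed: int = 0,
              outdir=None, **kwargs) -> list[IterationState]:
    """Run the full iterative protocol; optionally archive to ``outdir``.

    The archive holds one PDB per iteration (the carried structure), a
    convergence TSV (iteration, frame RMSD, region RMSD, subset energy) and
    a JSON selection log.  Completed iterations are preserved on disk even
    if a later stage fails.
    """
    run = QmdmdRun(system, seed=seed, **kwargs)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        for i in range(n_iterations):
            state = run.step()
            if out is not None:
                _archive_iteration(run, state, out)
    finally:
        if out is not None and run.history:
            _write_convergence(run.history, out / "convergence.tsv")
    return run.history


def _archive_iteration(run: QmdmdRun, state: IterationState, out: Path):
    it_dir = out / f"iter_{state.index:02d}"
    it_dir.mkdir(exist_ok=True)
    model_io.write_structure(run.system, it_dir / "system.pdb")
    if state.trajectory is not None:
        snaps = []
        for frame in state.trajectory.positions:
            s = run.system.copy()
            s.set_positions(frame)
            snaps.append(s)
        model_io.write_trajectory(
            snaps, it_dir / "traj.xyz",
            energies=list(state.trajectory.potential_energies),
            times=list(state.trajectory.times))
    with open(it_dir / "selection.json", "w") as fh:
        json.dump({
            "iteration": state.index,
            "representatives": list(map(int, state.representative_snapshots)),
            "qm_energies": [float(x) for x in state.qm_energies],
            "dmd_energies": [float(x) for x in state.dmd_energies],
            "chosen_snapshot": int(state.chosen_snapshot),
            "accepted": state.accepted,
            "e_input": state.e_input,
            "e_output": state.e_output,
        }, fh, indent=1)


def _write_convergence(history, path):
    with open(path, "w") as fh:
        fh.write("iteration\tframe_rmsd\tregion_rmsd\tsubset_energy\taccepted\n")
        for s in history:
            fh.write(f"{s.index}\t{s.frame_rmsd:.4f}\t{s.region_rmsd:.4f}\t"
                     f"{s.subset_energy:.6f}\t{s.accepted}\n")


# ---------------------------------------------------------------------------
# static-cluster control (no repacking)


def static_cluster_mode(system: MolecularSystem,
                        partition: DomainPartition | None = None,
                        backend: SurrogateBackend | None = None,
                        tol: float = 1e-4):
    """No-repacking control: one extract → optimize pass, no sampling.

    The surrounding frame never adjusts; reports should label results from
    this mode as the "no-repacking control".
    """
    if backend is None:
        backend = SurrogateBackend(system.backend_params)
    if partition is None:
        partition = assign_domains(system)
    cluster = extract_capped_cluster(system, partition)
    full, _ = cluster.full_positions(system.positions)
    new_full, res = backend.partial_optimize(full, cluster.free_atoms,
                                             active=cluster.evaluation_mask(),
                                             tol=tol)
    return cluster.with_positions(new_full), res
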