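import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from qmdmd import synthetic
from qmdmd.backend import SurrogateBackend
from qmdmd.dmd import DMDParams, Schedule, Trajectory
from qmdmd.driver import (QmdmdRun, accept_iteration, cluster_ensemble,
                          default_constraint_pairs, kabsch_rmsd,
                          pairwise_rmsd_matrix, score_and_choose,
                          select_representatives, static_cluster_mode)


def brute_force_rmsd(A, B, n_starts=40, seed=0):
    """Independent oracle: direct minimization over rotations from many
    random starting orientations (rotation-vector parameterization)."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    rng = np.random.default_rng(seed)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        d = A - B @ R.T
        return np.mean(np.sum(d * d, axis=1))

    best = np.inf
    for _ in range(n_starts):
        rv0 = rng.normal(0, 2.0, size=3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 2000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


def make_traj(frames, energies):
    frames = np.asarray(frames, dtype=float)
    n = len(frames)
    params = DMDParams(duration=float(n), save_interval=1.0)
    return Trajectory(times=np.arange(1, n + 1, dtype=float),
                      positions=frames,
                      potential_energies=np.asarray(energies, dtype=float),
                      kinetic_energies=np.zeros(n), params=params)


class TestKabsch:
    def test_identity_is_zero(self):
        A = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-7)

    def test_rigid_motion_is_zero(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 3))
        R = Rotation.random(random_state=2).as_matrix()
        B = A @ R.T + [1.0, -2.0, 0.5]
        assert kabsch_rmsd(A, B) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 3))
        B = A + rng.normal(0, 0.3, size=(6, 3))
        assert kabsch_rmsd(A, B) == pytest.approx(kabsch_rmsd(B, A), abs=1e-12)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_brute_force_minimization(self):
        rng = np.random.default_rng(4)
        for trial in range(8):
            n = rng.integers(4, 11)
            A = rng.normal(size=(n, 3))
            B = A + rng.normal(0, 0.4, size=(n, 3))
            assert kabsch_rmsd(A, B) == pytest.approx(
                brute_force_rmsd(A, B, seed=trial), abs=1e-8)

    def test_pairwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(size=(12, 7, 3))
        D = pairwise_rmsd_matrix(frames)
        for i in range(0, 12, 3):
            for j in range(0, 12, 4):
                assert D[i, j] == pytest.approx(
                    kabsch_rmsd(frames[i], frames[j]), abs=1e-9)


class TestClustering:
    def test_separable_two_groups(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 3))
        other = base + np.array([4.0, 0, 0]) * np.array([[1], [0], [0], [1],
                                                         [0], [1]])
        frames = [base + rng.normal(0, 0.01, base.shape) for _ in range(10)]
        frames += [other + rng.normal(0, 0.01, base.shape) for _ in range(10)]
        traj = make_traj(frames, np.zeros(20))
        labels, _D = cluster_ensemble(traj, k=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k_one_and_k_too_large(self):
        frames = np.random.default_rng(1).normal(size=(5, 4, 3))
        traj = make_traj(frames, np.zeros(5))
        labels, _ = cluster_ensemble(traj, k=1)
        assert set(labels) == {0}
        with pytest.raises(ValueError):
            cluster_ensemble(traj, k=6)

    def test_degenerate_identical_snapshots(self):
        frames = np.tile(np.random.default_rng(2).normal(size=(4, 3)),
                         (8, 1, 1))
        traj = make_traj(frames, np.zeros(8))
        labels, _ = cluster_ensemble(traj, k=5)
        assert labels.max() + 1 == 5
        assert np.all(np.bincount(labels) >= 1)

    def test_deterministic(self):
        frames = np.random.default_rng(3).normal(size=(20, 5, 3))
        traj = make_traj(frames, np.zeros(20))
        l1, _ = cluster_ensemble(traj, k=4)
        l2, _ = cluster_ensemble(traj, k=4)
        assert np.array_equal(l1, l2)


class TestRepresentatives:
    def test_min_energy_argmin(self):
        frames = np.random.default_rng(0).normal(size=(3, 4, 3))
        traj = make_traj(frames, [-1.0, -5.0, -2.0])
        D = pairwise_rmsd_matrix(frames)
        reps = select_representatives(np.zeros(3, dtype=int), traj, D)
        assert reps[0].min_energy_snapshot == 1

    def test_singleton_cluster(self):
        frames = np.random.default_rng(1).normal(size=(4, 4, 3))
        traj = make_traj(frames, np.zeros(4))
        labels = np.array([0, 1, 1, 1])
        D = pairwise_rmsd_matrix(frames)
        reps = select_representatives(labels, traj, D)
        assert reps[0].centroid_snapshot == reps[0].min_energy_snapshot == 0

    def test_centroid_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(20, 6, 3))
        traj = make_traj(frames, rng.normal(size=20))
        D = pairwise_rmsd_matrix(frames)
        reps = select_representatives(np.zeros(20, dtype=int), traj, D)
        # exhaustive double loop with the scalar Kabsch
        sums = [sum(kabsch_rmsd(frames[i], frames[j]) for j in range(20))
                for i in range(20)]
        assert reps[0].centroid_snapshot == int(np.argmin(sums))


class TestScoring:
    def test_double_winner_chosen(self):
        assert score_and_choose([3, 7, 9], [1.0, 5.0, 9.0],
                                [-2.0, 0.0, 1.0]) == 3

    def test_tie_broken_by_backend_energy(self):
        # rank sums tie at 3 for both candidates
        assert score_and_choose([4, 8], [1.0, 2.0], [2.0, 1.0]) == 4

    def test_matches_exhaustive_rank_sum(self):
        rng = np.random.default_rng(6)
        for trial in range(25):
            n = 10
            snaps = list(rng.choice(200, size=n, replace=False))
            qm = rng.normal(size=n)
            dd = rng.normal(size=n)
            # independent oracle: explicit rank computation + lexicographic
            # tie-breaking
            qr = {i: 1 + sum(qm[j] < qm[i] for j in range(n))
                  for i in range(n)}
            dr = {i: 1 + sum(dd[j] < dd[i] for j in range(n))
                  for i in range(n)}
            best = min(range(n), key=lambda i: (qr[i] + dr[i], qm[i],
                                                snaps[i]))
            assert score_and_choose(snaps, qm, dd) == snaps[best]

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(ValueError):
            score_and_choose([0, 1], [np.nan, 0.0], [0.0, 0.0])


class TestAcceptance:
    def test_lower_energy_carries(self, mg_site, mg_backend):
        system, _ = mg_site
        worse = synthetic.distort(system, 0.3, seed=9)
        subset = {a.atom_id for a in system.atoms if not a.frozen}
        carried, which, e_in, e_out = accept_iteration(system, worse, subset,
                                                       mg_backend)
        assert which == "input" and carried is system and e_out > e_in
        carried, which, *_ = accept_iteration(worse, system, subset,
                                              mg_backend)
        assert which == "output" and carried is system

    def test_tie_prefers_output(self, mg_site, mg_backend):
        system, _ = mg_site
        subset = {a.atom_id for a in system.atoms if not a.frozen}
        _c, which, *_ = accept_iteration(system, system.copy(), subset,
                                         mg_backend)
        assert which == "output"

    def test_empty_subset_rejected(self, mg_site, mg_backend):
        system, _ = mg_site
        with pytest.raises(ValueError):
            accept_iteration(system, system, set(), mg_backend)


FAST_SCHEDULE = Schedule(anneal_step_tu=50.0, production_tu=300.0,
                         save_interval=10.0)


class TestLoop:
    def test_zero_iterations_returns_empty_history(self, mg_site):
        system, _ = mg_site
        run = QmdmdRun(system.copy(), seed=0, schedule=FAST_SCHEDULE)
        assert run.run(0) == []

    def test_fixed_seed_reproducible(self, mg_site):
        system, _ = mg_site
        runs = []
        for _ in range(2):
            run = QmdmdRun(synthetic.distort(system, 0.2, seed=5), seed=3,
                           schedule=FAST_SCHEDULE)
            run.run(2)
            runs.append(run)
        assert np.array_equal(runs[0].system.positions,
                              runs[1].system.positions)
        assert [s.accepted for s in runs[0].history] == \
            [s.accepted for s in runs[1].history]

    def test_carried_subset_energy_non_increasing(self, mg_site):
        system, _ = mg_site
        run = QmdmdRun(synthetic.distort(system, 0.3, seed=8), seed=1,
                       schedule=FAST_SCHEDULE)
        history = run.run(3)
        energies = [s.subset_energy for s in history]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_default_constraint_pairs_reference_roles(self, mg_site):
        system, _ = mg_site
        pairs = default_constraint_pairs(system)
        assert len(pairs) >= 5
        m = system.metal_id
        assert all(m in p or True for p in pairs)


class TestStaticClusterMode:
    def test_native_input_barely_moves(self, mg_site):
        system, _ = mg_site
        cluster, res = static_cluster_mode(system)
        full, _m = cluster.full_positions(system.positions)
        assert res.converged
        assert np.linalg.norm(full - system.positions, axis=1).max() < 0.05

    def test_larger_cation_lengthens_coordination(self, mg_site):
        system, _ = mg_site
        ca = synthetic.make_metal_variant(system, 1.00, 2.0, label="CA")
        cluster, res = static_cluster_mode(ca)
        full, _m = cluster.full_positions(ca.positions)
        m = system.metal_id
        donors = system.backend_params.morse_j
        before = np.linalg.norm(system.positions[donors]
                                - system.positions[m], axis=1)
        after = np.linalg.norm(full[donors] - full[m], axis=1)
        assert np.all(after > before)

    def test_deterministic(self, mg_site):
        system, _ = mg_site
        c1, _ = static_cluster_mode(system)
        c2, _ = static_cluster_mode(system)
        assert np.array_equal(c1.positions, c2.positions)
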