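import numpy as np
import pytest

from qmdmd import synthetic
from qmdmd.dmd import (DMDParams, Schedule, build_potentials, remove_clashes,
                       run_phase, run_schedule, _violations)
from qmdmd.driver import default_constraint_pairs
from qmdmd.partition import (ConstraintSet, assign_domains,
                             constraints_from_cluster, extract_capped_cluster)


@pytest.fixture(scope="module")
def sampling_setup(mg_site):
    """Toy site + partition + default constraints + potential table."""
    system, _truth = mg_site
    system = system.copy()
    part = assign_domains(system)
    cluster = extract_capped_cluster(system, part)
    cons = constraints_from_cluster(cluster, default_constraint_pairs(system))
    table = build_potentials(system, cons, part)
    return system, part, cons, table


class TestBuildPotentials:
    def test_constraint_window(self, mg_site):
        system, _ = mg_site
        cs = ConstraintSet()
        cs.add(system.metal_id, system.find_atoms("C1", role="substrate")[0],
               2.10, 0.01)
        table = build_potentials(system, cs, None)
        p = [k for k, kind in enumerate(table.kinds)
             if kind == "constraint"][0]
        lo, hi = table.window(p)
        assert (lo, hi) == (pytest.approx(2.09), pytest.approx(2.11))

    def test_bond_window_five_percent(self, sampling_setup):
        system, _part, _cons, table = sampling_setup
        for p, kind in enumerate(table.kinds):
            if kind == "bond":
                i, j = int(table.pair_i[p]), int(table.pair_j[p])
                ref = system.bonds.length(i, j)
                lo, hi = table.window(p)
                assert lo == pytest.approx(0.95 * ref)
                assert hi == pytest.approx(1.05 * ref)
                break
        else:
            pytest.fail("no plain bond pair found")

    def test_fully_frozen_pairs_excluded(self, sampling_setup):
        system, part, _cons, table = sampling_setup
        frozen = table.frozen
        for p in range(table.n_pairs):
            assert not (frozen[table.pair_i[p]] and frozen[table.pair_j[p]])

    def test_metal_has_no_nonbonded_shells(self, sampling_setup):
        system, _part, _cons, table = sampling_setup
        m = system.metal_id
        for p in range(table.n_pairs):
            if m in (table.pair_i[p], table.pair_j[p]):
                assert table.kinds[p] in ("constraint", "bond+constraint")

    def test_conflicting_windows_error(self, mg_site):
        system, _ = mg_site
        i, j, ref = next(iter(system.bonds.pairs()))
        cs = ConstraintSet()
        cs.add(i, j, ref * 2.0, 0.01)   # far outside the ±5% bond window
        with pytest.raises(ValueError, match="do not intersect"):
            build_potentials(system, cs, None)

    def test_native_geometry_is_window_clean(self, sampling_setup):
        system, _part, _cons, table = sampling_setup
        assert _violations(system.positions, table) == []


class TestRunPhase:
    def test_snapshot_accounting_small(self, sampling_setup):
        system, part, _cons, table = sampling_setup
        params = DMDParams(duration=200.0, save_interval=10.0, seed=4)
        traj = run_phase(system, part, table, params)
        assert traj.n_snapshots == 20
        assert np.array_equal(traj.times, 10.0 * np.arange(1, 21))

    def test_frozen_atoms_bit_identical(self, sampling_setup):
        system, part, _cons, table = sampling_setup
        params = DMDParams(duration=100.0, save_interval=10.0, seed=5)
        traj = run_phase(system, part, table, params)
        frozen = np.nonzero(table.frozen)[0]
        for frame in traj.positions:
            assert np.array_equal(frame[frozen], system.positions[frozen])

    def test_energy_conserved_without_thermostat(self, sampling_setup):
        system, part, _cons, table = sampling_setup
        params = DMDParams(duration=100.0, save_interval=2.0, seed=6,
                           heat_exchange_rate=0.0)
        traj = run_phase(system, part, table, params)
        assert traj.n_events > 1000
        drift = np.abs(traj.kinetic_energies + traj.potential_energies
                       - traj.initial_energy)
        assert drift.max() <= 1e-9

    def test_constraints_respected(self, sampling_setup):
        system, part, cons, table = sampling_setup
        params = DMDParams(duration=300.0, save_interval=10.0, seed=7)
        traj = run_phase(system, part, table, params)
        assert traj.max_constraint_dev <= 0.01 + 1e-9
        # and directly on the snapshots
        for a, b, target, w in cons:
            d = np.linalg.norm(traj.positions[:, a] - traj.positions[:, b],
                               axis=1)
            assert np.all(np.abs(d - target) <= w + 1e-9)

    def test_reproducible_for_seed(self, sampling_setup):
        system, part, _cons, table = sampling_setup
        params = DMDParams(duration=100.0, save_interval=10.0, seed=8)
        t1 = run_phase(system, part, table, params)
        t2 = run_phase(system, part, table, params)
        assert np.array_equal(t1.positions, t2.positions)


class TestSchedule:
    def test_production_span_and_annealing_excluded(self, sampling_setup):
        system, part, _cons, table = sampling_setup
        sched = Schedule(anneal_step_tu=20.0, production_tu=200.0,
                         save_interval=10.0)
        traj = run_schedule(system, part, table, seed=1, schedule=sched)
        assert traj.n_snapshots == 20
        assert traj.times[-1] == pytest.approx(200.0)
        assert traj.params.temperature == pytest.approx(0.10)

    def test_anneal_temperatures_linear(self):
        sched = Schedule()
        temps = sched.anneal_temperatures()
        assert temps[0] == pytest.approx(0.20)
        assert temps[-1] == pytest.approx(0.10)
        assert len(temps) == 5
        steps = np.diff(temps)
        assert np.allclose(steps, steps[0])

    def test_nominal_duration_conversion(self):
        params = DMDParams()
        assert params.duration * params.tu_to_fs == pytest.approx(5e8 * 1e-3)


class TestRemoveClashes:
    def test_clash_free_input_stays_window_clean(self, sampling_setup):
        system, part, _cons, table = sampling_setup
        out = remove_clashes(system, part, table, seed=3)
        assert _violations(out.positions, table) == []

    def test_overlapping_pair_resolved(self, mg_site):
        system, _ = mg_site
        bad = synthetic.distort(system, 0.5, seed=21)
        table = build_potentials(bad, None, None)
        with pytest.warns(UserWarning, match="clash-relief"):
            out = remove_clashes(bad, None, table, seed=3)
        assert _violations(out.positions, table) == []

    def test_deterministic(self, sampling_setup):
        system, part, _cons, table = sampling_setup
        o1 = remove_clashes(system, part, table, seed=9)
        o2 = remove_clashes(system, part, table, seed=9)
        assert np.array_equal(o1.positions, o2.positions)


def test_params_validation():
    with pytest.raises(ValueError):
        DMDParams(duration=100.0, save_interval=7.0)
    with pytest.raises(ValueError):
        DMDParams(temperature=-0.1)
    with pytest.raises(ValueError):
        DMDParams(heat_exchange_rate=-1.0)
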