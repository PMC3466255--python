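import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmdmd.constants import CAP_FACTOR
from qmdmd.model_io import AtomRecord, BondTable, MolecularSystem
from qmdmd.partition import (DomainPartition, TruncationRule, assign_domains,
                             constraints_from_cluster, default_selection,
                             extract_capped_cluster, reinstall_cluster)
from qmdmd.synthetic import ToySiteSpec, make_toy_site


def test_qm_only_holds_metal_plus_coordinating_donors(mg_site, mg_partition):
    system, truth = mg_site
    # independent oracle: direct distance scan over heavy atoms
    pos = truth.native_positions
    m = system.metal_id
    expected = {m} | {i for i in system.heavy_atoms()
                      if i != m and np.linalg.norm(pos[i] - pos[m]) < 2.6}
    assert mg_partition.qm_only == expected
    assert len(mg_partition.qm_only) == 7      # metal + 6 donor atoms


def test_domains_disjointly_cover(mg_partition, mg_site):
    system, _ = mg_site
    union = (mg_partition.qm_only | mg_partition.qm_dmd
             | mg_partition.dmd_only)
    assert union == set(range(system.n_atoms))
    assert not (mg_partition.qm_only & mg_partition.qm_dmd)
    assert not (mg_partition.qm_only & mg_partition.dmd_only)
    with pytest.raises(ValueError):
        DomainPartition(qm_only={0}, qm_dmd={0, 1}, dmd_only={2},
                        boundary_bonds=[], n_atoms=3)


def test_empty_selection_on_bare_site_errors():
    bare, _ = make_toy_site(ToySiteSpec(include_water=False,
                                        include_substrate=False,
                                        include_donor=False))
    with pytest.raises(ValueError, match="empty active-site selection"):
        assign_domains(bare, qm_residue_selection=[])


def test_single_rule_yields_single_fragment_boundary_bond():
    bare, _ = make_toy_site(ToySiteSpec(include_water=False,
                                        include_substrate=False,
                                        include_donor=False))
    rules = [default_selection(bare)[0]]
    part = assign_domains(bare, qm_residue_selection=rules)
    # exactly one truncation bond comes from the selected fragment; the
    # remaining boundary bonds seal the frozen metal core's severed bonds
    from_fragment = [b for b in part.boundary_bonds if b[0] in part.qm_dmd]
    assert len(from_fragment) == 1
    assert all(b[0] in part.qm_only for b in part.boundary_bonds
               if b not in from_fragment)


def test_rule_errors():
    system, _ = make_toy_site()
    with pytest.raises(ValueError, match="missing residue"):
        assign_domains(system, [TruncationRule(99, "L2", "ANC")])
    with pytest.raises(ValueError, match="missing atom"):
        assign_domains(system, [TruncationRule(1, "QQ", "ANC")])


class TestCapping:
    def test_printed_factor_on_unit_cases(self, mg_site):
        system, _ = mg_site
        sys2 = system.copy()
        part = assign_domains(sys2)
        cluster = extract_capped_cluster(sys2, part)
        pos = sys2.positions
        for cap in cluster.caps:
            inner, outer, _ref = cap.source_bond
            length = np.linalg.norm(pos[outer] - pos[inner])
            placed = np.linalg.norm(cap.position - pos[inner])
            assert placed == pytest.approx(CAP_FACTOR * length, abs=1e-9)
            cosang = (cap.position - pos[inner]) @ (pos[outer] - pos[inner]) \
                / (placed * length)
            assert cosang == pytest.approx(1.0, abs=1e-12)

    def test_axis_aligned_example(self):
        atoms = [
            AtomRecord(0, "C", "CA", "RES", 1, "A", np.zeros(3), 12.011),
            AtomRecord(1, "C", "CB", "RES", 1, "A", np.array([2.0, 0, 0]),
                       12.011),
        ]
        bonds = BondTable()
        bonds.add(0, 1, 1.5)
        system = MolecularSystem(atoms=atoms, bonds=bonds,
                                 roles={"metal": set()})
        part = DomainPartition(qm_only=set(), qm_dmd={0}, dmd_only={1},
                               boundary_bonds=[(0, 1, 1.5)], n_atoms=2)
        cluster = extract_capped_cluster(system, part)
        assert cluster.caps[0].position == pytest.approx([2 * CAP_FACTOR, 0, 0])

    @settings(max_examples=40, deadline=None)
    @given(inner=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
           outer=st.tuples(*[st.floats(-5, 5) for _ in range(3)]))
    def test_ratio_invariant_any_geometry(self, inner, outer):
        inner = np.array(inner)
        outer = np.array(outer)
        length = np.linalg.norm(outer - inner)
        if length < 1e-3:
            return
        atoms = [
            AtomRecord(0, "C", "CA", "RES", 1, "A", inner, 12.011),
            AtomRecord(1, "C", "CB", "RES", 1, "A", outer, 12.011),
        ]
        bonds = BondTable()
        bonds.add(0, 1, float(np.clip(length, 0.6, 2.9)))
        system = MolecularSystem(atoms=atoms, bonds=bonds, roles={})
        part = DomainPartition(qm_only=set(), qm_dmd={0}, dmd_only={1},
                               boundary_bonds=[(0, 1, length)], n_atoms=2)
        cluster = extract_capped_cluster(system, part)
        placed = np.linalg.norm(cluster.caps[0].position - inner)
        assert placed / length == pytest.approx(CAP_FACTOR, abs=1e-12)

    def test_caps_and_partners_frozen(self, mg_site, mg_partition,
                                      mg_cluster):
        system, _ = mg_site
        n_caps = len(mg_cluster.caps)
        assert n_caps == len(mg_partition.boundary_bonds)
        partners = {c.parent_inner for c in mg_cluster.caps}
        assert partners <= mg_cluster.frozen_in_qm
        assert mg_cluster.frozen_in_dmd == mg_partition.qm_only


class TestConstraints:
    def test_targets_copy_current_distance(self, mg_cluster):
        a, b = int(mg_cluster.member_atoms[0]), int(mg_cluster.member_atoms[1])
        cs = constraints_from_cluster(mg_cluster, [(a, b)], half_width=0.01)
        ia, ib = mg_cluster.index_of(a), mg_cluster.index_of(b)
        d = np.linalg.norm(mg_cluster.positions[ia] - mg_cluster.positions[ib])
        assert list(cs)[0] == (a, b, pytest.approx(d), 0.01)

    def test_empty_spec(self, mg_cluster):
        assert len(constraints_from_cluster(mg_cluster, [])) == 0

    def test_duplicate_pair_warns_and_dedupes(self, mg_cluster):
        a, b = int(mg_cluster.member_atoms[0]), int(mg_cluster.member_atoms[1])
        with pytest.warns(UserWarning, match="duplicate"):
            cs = constraints_from_cluster(mg_cluster, [(a, b), (b, a)])
        assert len(cs) == 1

    def test_non_member_pair_rejected(self, mg_site, mg_cluster):
        system, _ = mg_site
        outside = sorted(set(range(system.n_atoms))
                         - set(map(int, mg_cluster.member_atoms)))[0]
        member = int(mg_cluster.member_atoms[0])
        with pytest.raises(ValueError, match="not inside the cluster"):
            constraints_from_cluster(mg_cluster, [(member, outside)])


class TestReinstall:
    def test_extract_reinstall_is_identity(self, mg_site, mg_partition):
        system, _ = mg_site
        cluster = extract_capped_cluster(system, mg_partition)
        back = reinstall_cluster(system, cluster)
        assert np.array_equal(back.positions, system.positions)

    def test_single_member_move_propagates(self, mg_site, mg_partition):
        system, _ = mg_site
        cluster = extract_capped_cluster(system, mg_partition)
        cluster.positions[0] += [0.2, 0, 0]
        moved_id = int(cluster.member_atoms[0])
        back = reinstall_cluster(system, cluster)
        delta = np.linalg.norm(back.positions - system.positions, axis=1)
        assert delta[moved_id] == pytest.approx(0.2)
        assert np.count_nonzero(delta > 1e-12) == 1

    def test_large_displacement_warns(self, mg_site, mg_partition):
        system, _ = mg_site
        cluster = extract_capped_cluster(system, mg_partition)
        cluster.positions[0] += [6.0, 0, 0]
        with pytest.warns(UserWarning, match="moved"):
            reinstall_cluster(system, cluster)

    def test_zero_length_boundary_bond_rejected(self, mg_site):
        system, _ = mg_site
        bad = system.copy()
        part = assign_domains(bad)
        inner, outer, _r = part.boundary_bonds[0]
        pos = bad.positions
        pos[outer] = pos[inner]
        bad.set_positions(pos)
        with pytest.raises(ValueError, match="zero length"):
            extract_capped_cluster(bad, part)
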