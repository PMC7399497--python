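"""Oligomer construction, interface graphs and avidity arithmetic."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pdzscaffold import scaffold as sc
from pdzscaffold.spacegroup import SymmetryOperation
from pdzscaffold.structures import CoordinateSet, radius_of_gyration
from pdzscaffold.synthetic_data import DumbbellSpec, make_dumbbell

SERIES = ("1e", "2e", "4e", "8e", "12e", "16e", "20e", "24e")


@pytest.mark.parametrize("name,n", list(zip(SERIES, (1, 2, 4, 8, 12, 16, 20, 24))))
def test_preset_sizes(name, n):
    assert len(sc.preset_ops(name)) == n


def test_24e_covers_all_cosets_once():
    keys = {
        (op.reduced().rotation, tuple(op.reduced().translation))
        for op in sc.preset_ops("24e")
    }
    assert len(keys) == 24


def test_unknown_preset():
    with pytest.raises(KeyError, match="available"):
        sc.preset_ops("3e")


class TestCombinatorialDegrees:
    def test_monomer_has_no_interfaces(self):
        a = sc.combinatorial_assembly("1e")
        assert sc.interface_degree(a, 0) == (0, 0, 0, 0)

    def test_dimer_degree_is_two_reciprocal_contacts(self):
        a = sc.combinatorial_assembly("2e")
        for i in range(2):
            assert sc.interface_degree(a, i) == (2, 0, 0, 2)

    def test_tetramer_ring_plus_dimer(self):
        a = sc.combinatorial_assembly("4e")
        degs = sorted(sc.interface_degree(a, i)[3] for i in range(4))
        assert degs == [2, 2, 2, 4]

    def test_full_lattice_degree_decomposition(self):
        assert sc.full_lattice_degree() == (2, 2, 1, 5)

    def test_index_out_of_range(self):
        a = sc.combinatorial_assembly("2e")
        with pytest.raises(IndexError):
            sc.interface_degree(a, 5)


class TestDissociationCost:
    def test_isolated_monomer(self):
        assert sc.dissociation_cost(sc.combinatorial_assembly("1e"), 0) == 0

    def test_dimer_and_tetramer_cost_two(self):
        assert sc.dissociation_cost(sc.combinatorial_assembly("2e"), 0) == 2
        a4 = sc.combinatorial_assembly("4e")
        assert min(sc.dissociation_cost(a4, i) for i in range(4)) == 2

    def test_monotone_along_series(self):
        """The maximum (interior-copy) dissociation cost never decreases as
        the oligomer grows, saturating at the lattice value of 5."""
        prev = 0
        for name in SERIES:
            a = sc.combinatorial_assembly(name)
            interior = max(sc.dissociation_cost(a, i) for i in range(a.n))
            assert interior >= prev
            prev = interior
        assert prev == sc.full_lattice_degree()[3] == 5


class TestAssemblyDelta:
    @staticmethod
    def _halves(cfg):
        ops = [SymmetryOperation.from_triplet(t)
               for t in sc.OCTAMER_CONFIGURATIONS[cfg]]
        return (sc.combinatorial_assembly(ops[:4]),
                sc.combinatorial_assembly(ops[4:]))

    def test_favored_octamer_forms_three(self):
        assert sc.assembly_delta(*self._halves("favored")) == 3

    @pytest.mark.parametrize("cfg", ["alt1", "alt2"])
    def test_non_favored_octamer_forms_two(self, cfg):
        assert sc.assembly_delta(*self._halves(cfg)) == 2

    def test_self_union_clashes(self):
        a = sc.combinatorial_assembly("4e")
        with pytest.raises(sc.ClashError):
            sc.assembly_delta(a, a)

    def test_interface_counts_are_path_independent(self):
        """8e built directly carries the same graph as 4e + docked 4e."""
        direct = sc.combinatorial_assembly("8e")
        a, b = self._halves("favored")
        w_direct = sum(e.weight for e in direct.interfaces)
        w_joined = (sum(e.weight for e in a.interfaces)
                    + sum(e.weight for e in b.interfaces)
                    + sc.assembly_delta(a, b))
        assert w_direct == w_joined


class TestGeometricAssemblies:
    def test_reference_monomer_rg_in_band(self):
        rg = radius_of_gyration(sc.reference_monomer())
        assert 21.0 <= rg <= 25.0

    def test_full_unit_cell_is_clash_free(self):
        mono = sc.reference_monomer()
        asm = sc.build_oligomer(mono, "24e", graph="geometric")
        assert asm.n == 24
        # pairwise minimum-distance scan (the builder already raises on clash)
        for i in range(asm.n):
            for j in range(i + 1, asm.n):
                d = cdist(asm.copies[i].coords, asm.copies[j].coords).min()
                assert d >= sc.CLASH_THRESHOLD

    def test_geometric_graph_matches_relation_graph(self):
        """Domain-centroid contact detection reproduces the combinatorial
        graph on the full unit-cell assembly."""
        mono = sc.reference_monomer()
        geo = sc.build_oligomer(mono, "24e", graph="geometric")
        rel = sc.combinatorial_assembly("24e")
        as_set = lambda a: {(e.i, e.j, e.kind) for e in a.interfaces}
        assert as_set(geo) == as_set(rel)

    def test_clash_error_reports_pair(self):
        mono = sc.reference_monomer()
        ident = SymmetryOperation.identity()
        with pytest.raises(sc.ClashError, match="minimum distance"):
            sc.build_oligomer(mono, [ident, ident])

    def test_dimer_pair_of_operations_returns_to_start(self):
        """The 2e relation is an exact involution: applying it twice is the
        identity (not merely a lattice translate)."""
        (dim_op,) = sc.RELATION_OPS[sc.InterfaceType.AB_DE]
        assert (dim_op @ dim_op).is_identity


def _planted_dimer(seed=3, offset=(0.0, 14.0, 20.0)):
    mono = make_dumbbell(DumbbellSpec(separation=46.0), seed=seed)
    coords_a = mono.coords + np.asarray(offset)
    coords_b = coords_a @ np.diag([1.0, -1.0, -1.0]).T
    return CoordinateSet(
        chain_ids=np.array(["A"] * len(coords_a) + ["B"] * len(coords_b)),
        res_seq=np.concatenate([mono.res_seq, mono.res_seq]),
        res_names=np.concatenate([mono.res_names, mono.res_names]),
        atom_names=np.concatenate([mono.atom_names, mono.atom_names]),
        coords=np.vstack([coords_a, coords_b]),
        weights=np.concatenate([mono.weights, mono.weights]),
        label="planted dimer",
    )


class TestTrimerOfDimersSearch:
    def test_twofold_axis_identified(self):
        axis, _ = sc.identify_twofold_axis(_planted_dimer())
        assert abs(abs(axis[0]) - 1.0) < 1e-9

    def test_planted_dx_recovered_exactly(self):
        dimer = _planted_dimer()
        axis, centre = sc.identify_twofold_axis(dimer)
        base = dimer.coords - centre
        rot = sc._rotation_about(np.array([1.0, 0.0, 0.0]), 35.0)
        placed = base @ rot.T + np.array([37.0, 0.0, 0.0])
        d_ref = float(cdist(placed, placed @ sc._C3_111.T).min())
        res = sc.trimer_of_dimers_search(dimer, d_ref, rot_step=5.0, dx_step=1.0)
        assert res.dx == pytest.approx(37.0)
        assert res.rotation == pytest.approx(35.0)
        assert res.a == pytest.approx(4.0 * res.dx)

    def test_resolution_error_from_qmax(self):
        dimer = _planted_dimer()
        res = sc.trimer_of_dimers_search(dimer, 20.0, q_max=0.4)
        assert res.resolution_error == pytest.approx(2 * np.pi / 0.8, rel=1e-12)
        assert round(res.resolution_error) == 8

    def test_invalid_grid_steps(self):
        with pytest.raises(ValueError):
            sc.trimer_of_dimers_search(_planted_dimer(), 20.0, rot_step=0.0)
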