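import numpy as np
import pytest

from _helpers import make_monomer, manual_pair_table
from pempni.energy_features import (
    EnergyTableError,
    EnergyTerms,
    GROUP_PARTITIONS,
    PairEnergyTable,
    assemble_energy_block,
    eini,
    epi,
    epp,
    etor,
    ewc,
    read_pair_energy_table,
    residue_energy,
    shell_index,
)
from pempni.structure_io import (
    ComplexStructure,
    InterfaceSet,
    MonomerKey,
    bind_mutation,
    detect_interface,
    MutationRecord,
)
from pempni.synthetic_fixtures import draw_wt_table


def line_complex(prot_x, nuc_x, nuc_z=4.0):
    """Single-atom monomers along x: controllable pairwise distances."""
    monomers = [make_monomer("A", i + 1, [(x, 0, 0)]) for i, x in enumerate(prot_x)]
    monomers += [
        make_monomer("B", j + 1, [(x, 0, nuc_z)], kind="dna_nucleotide", code="G")
        for j, x in enumerate(nuc_x)
    ]
    return ComplexStructure(id="line", monomers=monomers,
                            chain_types={"A": "protein", "B": "DNA"})


def table_from_totals(structure, totals):
    """Table whose `total` comes from the mapping; components split 4 ways."""
    entries = {}
    for pair, tot in totals.items():
        comp = tot / 4.0
        entries[pair] = np.array([tot, comp, comp, comp, comp])
    return PairEnergyTable(complex_id=structure.id, state="wild_type",
                           gb_model_tag="synthetic", entries=entries)


K = lambda c, s: MonomerKey(c, s, "")


class TestReader:
    @pytest.fixture
    def two_mono(self):
        return line_complex([0.0], [0.0], nuc_z=4.0)

    def _write(self, tmp_path, rows):
        p = tmp_path / "table.csv"
        header = "chain_i,seq_i,icode_i,chain_j,seq_j,icode_j,total,ele,vdw,gb,sa"
        p.write_text("\n".join([header] + rows) + "\n")
        return p

    def test_three_entries(self, tmp_path, two_mono):
        rows = [
            "A,1,,A,1,,1.0,1.0,0,0,0",
            "B,1,,B,1,,2.0,2.0,0,0,0",
            "A,1,,B,1,,-0.5,-0.5,0,0,0",
        ]
        t = read_pair_energy_table(self._write(tmp_path, rows), two_mono)
        assert len(t.entries) == 3

    def test_directional_rows_are_summed(self, tmp_path, two_mono):
        rows = [
            "A,1,,A,1,,0,0,0,0,0",
            "B,1,,B,1,,0,0,0,0,0",
            "A,1,,B,1,,0.5,0.5,0,0,0",
            "B,1,,A,1,,0.5,0.5,0,0,0",
        ]
        t = read_pair_energy_table(self._write(tmp_path, rows), two_mono)
        assert t.pair(K("A", 1), K("B", 1))[0] == pytest.approx(1.0)
        assert len(t.entries) == 3

    def test_unresolvable_key_names_row(self, tmp_path, two_mono):
        rows = ["A,1,,A,1,,0,0,0,0,0", "B,1,,B,1,,0,0,0,0,0",
                "Z,9,,A,1,,1,1,0,0,0"]
        with pytest.raises(EnergyTableError, match="row 2"):
            read_pair_energy_table(self._write(tmp_path, rows), two_mono)

    def test_missing_self_entry(self, tmp_path, two_mono):
        rows = ["A,1,,A,1,,0,0,0,0,0"]
        with pytest.raises(EnergyTableError, match="self entry"):
            read_pair_energy_table(self._write(tmp_path, rows), two_mono)

    def test_closure_violation(self, tmp_path, two_mono):
        rows = ["A,1,,A,1,,5.0,0,0,0,0", "B,1,,B,1,,0,0,0,0,0"]
        with pytest.raises(EnergyTableError, match="closure"):
            read_pair_energy_table(self._write(tmp_path, rows), two_mono)


class TestShells:
    def test_boundaries_half_open(self):
        assert shell_index(3.0) == 1  # exactly 3.0 falls in (0, 3]
        assert shell_index(3.0001) == 2
        assert shell_index(5.0) == 3
        assert shell_index(6.0) == 4
        assert shell_index(6.5) == 5

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            shell_index(0.0)


class TestAggregations:
    @pytest.fixture
    def structure(self):
        # protein at x = 0, 2.5, 8; nucleotide above x=0 at 4 A
        return line_complex([0.0, 2.5, 8.0], [0.0])

    @pytest.fixture
    def table(self, structure):
        rng = np.random.default_rng(0)
        return manual_pair_table(structure, rng)

    def test_ewc_is_total_sum(self, table):
        expected = sum(t for t in table.entries.values())
        np.testing.assert_allclose(ewc(table).as_array(), expected)

    def test_ewc_empty_table_rejected(self):
        empty = PairEnergyTable("x", "wild_type", "synthetic", {})
        with pytest.raises(EnergyTableError):
            ewc(empty)

    def test_etor_constructed_shells(self, structure):
        # target A:1; A:2 at 2.5 (shell 1), A:3 at 8 (shell 5)
        totals = {
            (K("A", 1), K("A", 1)): 2.0,
            (K("A", 2), K("A", 2)): 9.0,
            (K("A", 3), K("A", 3)): 9.0,
            (K("B", 1), K("B", 1)): 9.0,
            (K("A", 1), K("A", 2)): 0.5,
            (K("A", 1), K("A", 3)): -1.0,
        }
        t = table_from_totals(structure, totals)
        shells = etor(t, structure, K("A", 1))
        np.testing.assert_allclose(shells[:, 0], [2.0, 0.5, 0, 0, 0, -1.0])

    def test_etor_conservation(self, structure, table):
        target = K("A", 1)
        shells = etor(table, structure, target)
        expected = table.self_entry(target).copy()
        for o in structure.protein_monomers:
            if o.key != target:
                pe = table.pair(target, o.key)
                if pe is not None:
                    expected = expected + pe
        np.testing.assert_allclose(shells.sum(axis=0), expected, atol=1e-10)

    def test_etor_rejects_nucleotide_target(self, structure, table):
        with pytest.raises(EnergyTableError):
            etor(table, structure, K("B", 1))

    def test_residue_energy_sum_identity(self, structure, table):
        # sum_res residue_energy == ewc + sum of off-diagonal entries
        total = sum(
            residue_energy(table, k) for k in structure.keys()
        )
        offdiag = sum(
            (t for (a, b), t in table.entries.items() if a != b), np.zeros(5)
        )
        np.testing.assert_allclose(total, ewc(table).as_array() + offdiag,
                                   atol=1e-10)

    def test_epp_shell_zero_is_target_residue_energy(self, structure, table):
        target = K("A", 1)
        shells = epp(table, structure, target)
        np.testing.assert_allclose(shells[0], residue_energy(table, target))

    def test_epp_conservation(self, structure, table):
        shells = epp(table, structure, K("A", 1))
        expected = sum(
            residue_energy(table, m.key) for m in structure.protein_monomers
        )
        np.testing.assert_allclose(shells.sum(axis=0), expected, atol=1e-10)

    def test_epp_moving_residue_changes_shell_not_total(self):
        for x in (3.5, 4.5):
            s = line_complex([0.0, x], [0.0])
            t = table_from_totals(s, {
                (K("A", 1), K("A", 1)): 1.0, (K("A", 2), K("A", 2)): 3.0,
                (K("B", 1), K("B", 1)): 0.0, (K("A", 1), K("A", 2)): 0.0,
            })
            shells = epp(t, s, K("A", 1))
            expect = np.zeros(6)
            expect[0] = 1.0
            expect[2 if x == 3.5 else 3] = 3.0
            np.testing.assert_allclose(shells[:, 0], expect)
            assert shells[:, 0].sum() == pytest.approx(4.0)


class TestInterfacePartitions:
    @pytest.fixture
    def structure(self):
        # A:1 contacts B:1 (4 A); A:2 far from everything nucleic
        return line_complex([0.0, 20.0], [0.0])

    @pytest.fixture
    def iface(self, structure):
        return detect_interface(structure)

    def test_membership(self, iface):
        assert iface.interface_residues == {K("A", 1)}
        assert iface.interface_nucleotides == {K("B", 1)}

    def test_cross_boundary_pair_is_noninterface(self, structure, iface):
        # pair (interface residue, non-interface residue) -> noninterface
        totals = {
            (K("A", 1), K("A", 1)): 0.0, (K("A", 2), K("A", 2)): 0.0,
            (K("B", 1), K("B", 1)): 0.0,
            (K("A", 1), K("A", 2)): 7.0,
        }
        t = table_from_totals(structure, totals)
        parts = eini(t, iface)
        assert parts[0, 0] == pytest.approx(0.0)
        assert parts[1, 0] == pytest.approx(7.0)

    def test_eini_conservation(self, structure, iface):
        rng = np.random.default_rng(1)
        t = manual_pair_table(structure, rng)
        parts = eini(t, iface)
        np.testing.assert_allclose(parts.sum(axis=0), ewc(t).as_array(),
                                   atol=1e-10)

    def test_everything_interfacial_degenerate(self, structure):
        all_iface = InterfaceSet.from_pairs(
            [(K("A", 1), K("B", 1)), (K("A", 2), K("B", 1))], cutoff=5.0
        )
        rng = np.random.default_rng(2)
        t = manual_pair_table(structure, rng)
        parts = eini(t, all_iface)
        np.testing.assert_allclose(parts[0], ewc(t).as_array(), atol=1e-10)
        np.testing.assert_allclose(parts[1], 0.0, atol=1e-12)

    def test_epi_constructed_example(self, structure, iface):
        totals = {
            (K("A", 1), K("A", 1)): 1.0, (K("A", 2), K("A", 2)): 0.0,
            (K("B", 1), K("B", 1)): 2.0,
            (K("A", 1), K("B", 1)): -3.0,
        }
        t = table_from_totals(structure, totals)
        parts = epi(t, structure, iface)
        np.testing.assert_allclose(parts[:, 0], [1.0, -3.0, 2.0])

    def test_epi_sums_to_eini_interface(self, structure, iface):
        rng = np.random.default_rng(3)
        t = manual_pair_table(structure, rng)
        np.testing.assert_allclose(
            epi(t, structure, iface).sum(axis=0), eini(t, iface)[0], atol=1e-10
        )


class TestAssembleBlock:
    @pytest.fixture
    def pieces(self, toy):
        tm = toy.mutations[0]
        return toy.wt_structure, tm

    def test_identical_tables_zero_difference(self, pieces):
        wt_structure, tm = pieces
        blocks = assemble_energy_block(
            tm.wt_table, tm.wt_table, wt_structure, wt_structure, tm.record
        )
        for b in blocks.values():
            np.testing.assert_allclose(b.diff, 0.0, atol=1e-12)

    def test_vector_lengths(self, pieces):
        wt_structure, tm = pieces
        blocks = assemble_energy_block(
            tm.wt_table, tm.mut_table, wt_structure, tm.mut_structure, tm.record
        )
        lengths = {g: len(b.vector) for g, b in blocks.items()}
        assert lengths == {"EWC": 10, "ETOR": 60, "EPP": 60, "EINI": 20,
                           "EPI": 30}

    def test_gb_tag_mismatch_rejected(self, pieces):
        wt_structure, tm = pieces
        other = PairEnergyTable(tm.mut_table.complex_id, "mutant", "HCT",
                                tm.mut_table.entries)
        with pytest.raises(EnergyTableError, match="GB model"):
            assemble_energy_block(tm.wt_table, other, wt_structure,
                                  tm.mut_structure, tm.record)

    def test_single_pair_perturbation_is_localized(self, pieces):
        wt_structure, tm = pieces
        target = tm.record.monomer_key
        base = assemble_energy_block(
            tm.wt_table, tm.wt_table, wt_structure, wt_structure, tm.record
        )
        # perturb total of one (target, other-protein) pair by +1.0
        other = next(
            m.key for m in wt_structure.protein_monomers if m.key != target
        )
        entries = {p: t.copy() for p, t in tm.wt_table.entries.items()}
        pair = (target, other) if (target, other) in entries else (other, target)
        entries[pair][0] += 1.0
        pert = PairEnergyTable(tm.wt_table.complex_id, "mutant", "synthetic",
                               entries)
        blocks = assemble_energy_block(
            tm.wt_table, pert, wt_structure, wt_structure, tm.record
        )
        # EWC total difference moves by exactly +1
        assert blocks["EWC"].diff[0, 0] == pytest.approx(1.0)
        # ETOR: exactly one shell's total difference changes
        d = blocks["ETOR"].diff[:, 0] - base["ETOR"].diff[:, 0]
        assert np.count_nonzero(np.abs(d) > 1e-9) == 1

    def test_unbound_mutation_rejected(self, pieces):
        wt_structure, tm = pieces
        rec = MutationRecord("x", "A", 1, "A", "G")
        with pytest.raises(ValueError, match="bound"):
            assemble_energy_block(tm.wt_table, tm.mut_table, wt_structure,
                                  tm.mut_structure, rec)


class TestInvariants:
    def test_row_permutation_invariance(self, toy, tmp_path):
        tm = toy.mutations[0]
        structure = toy.wt_structure
        from pempni.synthetic_fixtures import table_to_csv

        text = table_to_csv(tm.wt_table)
        lines = text.strip().split("\n")
        header, rows = lines[0], lines[1:]
        rng = np.random.default_rng(4)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p1.write_text("\n".join([header] + rows) + "\n")
        p2.write_text("\n".join([header] + shuffled) + "\n")
        t1 = read_pair_energy_table(p1, structure)
        t2 = read_pair_energy_table(p2, structure)
        target = tm.record.monomer_key
        np.testing.assert_allclose(
            etor(t1, structure, target), etor(t2, structure, target)
        )
        np.testing.assert_allclose(ewc(t1).as_array(), ewc(t2).as_array())

    def test_linearity_under_scaling(self, toy):
        tm = toy.mutations[0]
        structure = toy.wt_structure
        iface = detect_interface(structure)
        target = tm.record.monomer_key
        t = tm.wt_table
        scaled = PairEnergyTable(
            t.complex_id, t.state, t.gb_model_tag,
            {p: 2.5 * v for p, v in t.entries.items()},
        )
        np.testing.assert_allclose(
            etor(scaled, structure, target), 2.5 * etor(t, structure, target)
        )
        np.testing.assert_allclose(
            eini(scaled, iface), 2.5 * eini(t, iface), atol=1e-10
        )
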