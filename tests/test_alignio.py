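import numpy as np
import pytest

from dirpred.alignio import (
    Alignment,
    build_reference_map,
    pair_by_species,
    project_orthologs_onto_master,
    read_alignment,
    write_alignment,
)
from dirpred.exceptions import (
    AlignmentShapeError,
    ConsistencyError,
    DegenerateInputError,
    IdentityError,
    InputError,
    PairingError,
)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


class TestReadAlignment:
    def test_basic_read(self, tmp_path):
        f = write_fasta(tmp_path / "a.fasta", [("a_sp1", "ACDE"), ("b_sp2", "AC-E")])
        aln = read_alignment(f)
        assert aln.n_rows == 2 and aln.n_cols == 4
        assert aln.seqs == ["ACDE", "AC-E"]

    def test_normalization_case_and_dot_gap(self, tmp_path):
        f = write_fasta(tmp_path / "a.fasta", [("a", "ac.e")])
        assert read_alignment(f).seqs == ["AC-E"]

    def test_ambiguity_codes_become_gaps(self, tmp_path):
        f = write_fasta(tmp_path / "a.fasta", [("a", "AXBZuO")])
        assert read_alignment(f).seqs == ["A-----"]

    def test_ragged_raises(self, tmp_path):
        f = write_fasta(tmp_path / "a.fasta", [("a", "ACDE"), ("b", "ACD")])
        with pytest.raises(AlignmentShapeError):
            read_alignment(f)

    def test_ragged_padded_when_not_required(self, tmp_path):
        f = write_fasta(tmp_path / "a.fasta", [("a", "ACDE"), ("b", "ACD")])
        aln = read_alignment(f, require_equal_length=False)
        assert aln.seqs[1] == "ACD-"

    def test_duplicate_ids_raise(self, tmp_path):
        f = write_fasta(tmp_path / "a.fasta", [("a", "AC"), ("a", "AC")])
        with pytest.raises(IdentityError):
            read_alignment(f)

    def test_empty_file_raises(self, tmp_path):
        f = tmp_path / "empty.fasta"
        f.write_text("")
        with pytest.raises(InputError):
            read_alignment(f)

    def test_round_trip_byte_identical(self, tmp_path, rng):
        from conftest import random_alignment

        aln = random_alignment(rng, 6, 40, gap_prob=0.1)
        f1, f2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_alignment(aln, f1)
        write_alignment(read_alignment(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestReferenceMap:
    def test_gapped_reference(self):
        aln = Alignment(["r", "o"], ["AC-E", "ACDE"])
        m = build_reference_map(aln, "r")
        assert list(m.columns) == [0, 1, 3]
        assert m.residues == "ACE"
        assert m.column_of(3) == 3

    def test_ungapped_is_identity_shift(self):
        aln = Alignment(["r"], ["ACDEFG"])
        m = build_reference_map(aln, "r")
        assert list(m.columns) == list(range(6))
        assert m.n_sites == 6

    def test_all_gap_reference_raises(self):
        aln = Alignment(["r", "o"], ["----", "ACDE"])
        with pytest.raises(DegenerateInputError):
            build_reference_map(aln, "r")

    def test_missing_reference_raises(self):
        aln = Alignment(["r"], ["ACDE"])
        with pytest.raises(IdentityError):
            build_reference_map(aln, "nope")

    def test_composition_returns_reference_residue(self, rng):
        from conftest import random_alignment

        aln = random_alignment(rng, 5, 30, gap_prob=0.2)
        ref = aln.ids[0]
        m = build_reference_map(aln, ref)
        row = aln.row(ref)
        for pos in range(1, m.n_sites + 1):
            assert row[m.column_of(pos)] == m.residue_of(pos)


class TestPairBySpecies:
    def test_intersection(self):
        lig = Alignment([f"L_sp{i}" for i in range(5)], ["AC"] * 5)
        rec = Alignment([f"R_sp{i}" for i in range(1, 5)], ["DE"] * 4)
        paired = pair_by_species(lig, rec)
        assert len(paired.species_order) == 4
        assert paired.ligand_block.n_rows == paired.receptor_block.n_rows == 4

    def test_order_follows_ligand(self):
        lig = Alignment(["L_b", "L_a", "L_c"], ["AC"] * 3)
        rec = Alignment(["R_a", "R_b", "R_c"], ["DE"] * 3)
        assert pair_by_species(lig, rec).species_order == ["b", "a", "c"]

    def test_duplicate_species_dropped(self):
        lig = Alignment(["L1_sp1", "L2_sp1", "L_sp2"], ["AC"] * 3)
        rec = Alignment(["R_sp1", "R_sp2"], ["DE"] * 2)
        assert pair_by_species(lig, rec).species_order == ["sp2"]

    def test_disjoint_raises(self):
        lig = Alignment(["L_sp1"], ["AC"])
        rec = Alignment(["R_sp2"], ["DE"])
        with pytest.raises(PairingError):
            pair_by_species(lig, rec)


class TestProjection:
    def test_master_gap_becomes_all_gap_column(self):
        master = Alignment(["p1_sp1", "p2_sp1"], ["AC-E", "ACDE"])
        orth = Alignment(["p1_sp1", "p1_sp2"], ["ACE", "AGE"])
        proj = project_orthologs_onto_master(master, {"p1": orth}, {"p1": "p1_sp1"})
        block = proj.blocks["p1"]
        assert block.n_cols == 4
        assert block.column(2) == "--"
        assert block.seqs[0] == "AC-E"

    def test_insertion_columns_dropped(self):
        master = Alignment(["p1_sp1"], ["ACE"])
        # ortholog alignment has an insertion column (gap in reference)
        orth = Alignment(["p1_sp1", "p1_sp2"], ["AC-E", "ACDE"])
        proj = project_orthologs_onto_master(master, {"p1": orth}, {"p1": "p1_sp1"})
        assert proj.blocks["p1"].seqs == ["ACE", "ACE"]

    def test_identity_case(self):
        master = Alignment(["p1_sp1"], ["ACDE"])
        orth = Alignment(["p1_sp1", "p1_sp2"], ["ACDE", "AGDE"])
        proj = project_orthologs_onto_master(master, {"p1": orth}, {"p1": "p1_sp1"})
        assert proj.blocks["p1"].seqs == orth.seqs

    def test_reference_mismatch_raises(self):
        master = Alignment(["p1_sp1"], ["ACDE"])
        orth = Alignment(["p1_sp1"], ["ACDF"])
        with pytest.raises(ConsistencyError):
            project_orthologs_onto_master(master, {"p1": orth}, {"p1": "p1_sp1"})

    def test_residue_content_preserved(self, default_system):
        s = default_system
        proj = project_orthologs_onto_master(s.master, s.ortholog_msas, s.ref_ids)
        joint = proj.joint()
        assert joint.n_rows == sum(a.n_rows for a in s.ortholog_msas.values())
        for p, block in proj.blocks.items():
            src = s.ortholog_msas[p]
            # fixture bundles are ungapped, so projection is the identity
            assert block.seqs == src.seqs
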