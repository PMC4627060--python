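import pytest

from cosbr.seqcore import (
    DnaMolecule,
    Feature,
    GeneModel,
    find_occurrences,
    load_locus,
    molecules_equivalent,
    read_construct,
    reverse_complement,
    revcomp,
    rotate,
    translate,
    write_construct,
)

BED12 = "{chrom}\t100\t700\tmygene\t0\t{strand}\t150\t650\t0\t3\t100,120,150\t0,200,450\n"


def _write_locus(tmp_path, seq, name="loc1"):
    fa = tmp_path / "locus.fasta"
    fa.write_text(f">{name}\n{seq}\n")
    return fa


@pytest.fixture
def seq1000():
    import numpy as np

    rng = np.random.default_rng(3)
    return "".join(rng.choice(list("ACGT"), 1000))


class TestLoadLocus:
    def test_bed12_three_exons(self, tmp_path, seq1000):
        fa = _write_locus(tmp_path, seq1000)
        bed = tmp_path / "g.bed"
        bed.write_text(BED12.format(chrom="loc1", strand="+"))
        mol, gene = load_locus(fa, bed)
        assert mol.seq == seq1000
        assert gene.exons == [(100, 200), (300, 420), (550, 700)]
        assert gene.cds == [(150, 200), (300, 420), (550, 650)]
        assert len(mol.features_of("exon")) == 3

    def test_minus_strand_reverses_exon_order(self, tmp_path, seq1000):
        fa = _write_locus(tmp_path, seq1000)
        bed = tmp_path / "g.bed"
        bed.write_text(BED12.format(chrom="loc1", strand="-"))
        _, gene = load_locus(fa, bed)
        # exon 1 is 5'-most in gene orientation = rightmost genomic
        assert gene.exons[0] == (550, 700)
        assert gene.exons[-1] == (100, 200)

    def test_multi_record_fasta_rejected(self, tmp_path):
        fa = tmp_path / "two.fasta"
        fa.write_text(">a\nACGT\n>b\nACGT\n")
        bed = tmp_path / "g.bed"
        bed.write_text("a\t0\t4\tg\t0\t+\n")
        with pytest.raises(ValueError, match="one FASTA record"):
            load_locus(fa, bed)

    def test_gff_parse_and_cds_outside_exon(self, tmp_path, seq1000):
        fa = _write_locus(tmp_path, seq1000)
        good = tmp_path / "good.gff"
        good.write_text(
            "loc1\t.\texon\t101\t200\t.\t+\t.\tID=e1\n"
            "loc1\t.\texon\t301\t400\t.\t+\t.\tID=e2\n"
            "loc1\t.\tCDS\t121\t200\t.\t+\t.\tID=c1\n"
        )
        _, gene = load_locus(fa, good)
        assert gene.exons == [(100, 200), (300, 400)]
        bad = tmp_path / "bad.gff"
        bad.write_text(
            "loc1\t.\texon\t101\t200\t.\t+\t.\tID=e1\n"
            "loc1\t.\tCDS\t151\t260\t.\t+\t.\tID=c1\n"  # runs past its exon
        )
        with pytest.raises(ValueError, match="not contained"):
            load_locus(fa, bad)

    def test_unknown_strand_rejected(self, tmp_path, seq1000):
        fa = _write_locus(tmp_path, seq1000)
        bed = tmp_path / "g.bed"
        bed.write_text("loc1\t100\t200\tg\t0\t.\n")
        with pytest.raises(ValueError, match="strand"):
            load_locus(fa, bed)


class TestReverseComplement:
    def test_involution_with_features(self, seq1000):
        mol = DnaMolecule(
            "m",
            seq1000,
            "linear",
            [Feature("exon", 10, 60, "+", "e1"), Feature("marker", 200, 300, "-", "mk")],
        )
        back = reverse_complement(reverse_complement(mol))
        assert back.seq == mol.seq
        assert [(f.kind, f.start, f.end, f.strand) for f in back.features] == [
            (f.kind, f.start, f.end, f.strand) for f in mol.features
        ]

    def test_palindrome(self):
        assert revcomp("ACGT") == "ACGT"

    def test_feature_coordinate_remap(self):
        mol = DnaMolecule("m", "AACCGGTTAA", "linear", [Feature("marker", 0, 4, "+", "x")])
        rc = reverse_complement(mol)
        f = rc.features[0]
        assert (f.start, f.end, f.strand) == (6, 10, "-")

    def test_feature_lengths_preserved(self, seq1000):
        mol = DnaMolecule(
            "m",
            seq1000,
            "circular",
            [Feature("marker", 980, 20, "+", "wrap"), Feature("exon", 5, 105, "+", "e")],
        )
        rc = reverse_complement(mol)
        assert sorted(f.length(1000) for f in rc.features) == sorted(f.length(1000) for f in mol.features)


class TestCircular:
    def test_rotation_invariant_search(self, seq1000):
        mol = DnaMolecule("c", seq1000, "circular")
        pat = seq1000[990:] + seq1000[:10]  # spans the stored origin
        for off in (0, 137, 995):
            rot = rotate(mol, off)
            assert len(find_occurrences(pat, rot, both_strands=False)) == 1

    def test_rotation_preserves_equivalence(self, seq1000):
        mol = DnaMolecule("c", seq1000, "circular")
        assert molecules_equivalent(mol, rotate(mol, 421))
        assert molecules_equivalent(mol, reverse_complement(rotate(mol, 421)))

    def test_rotated_feature_end_at_origin(self):
        mol = DnaMolecule("c", "ACGTACGTAC", "circular", [Feature("marker", 2, 6, "+", "x")])
        rot = rotate(mol, 6)  # feature end lands exactly on the new origin
        f = rot.features[0]
        assert (f.start, f.end) == (6, 10)
        assert not f.wraps()


class TestGenBankIO:
    def test_round_trip_preserves_sequence_and_features(self, tmp_path, seq1000):
        mol = DnaMolecule(
            "plasmid1",
            seq1000,
            "circular",
            [
                Feature("loxP", 100, 134, "+", "loxP"),
                Feature("FRT", 200, 234, "-", "FRT"),
                Feature("primer_site", 300, 320, "+", "scrF"),
            ],
        )
        path = tmp_path / "p.gb"
        write_construct(mol, path, "genbank")
        assert "circular" in path.read_text().splitlines()[0]
        back = read_construct(path)
        assert back.seq == mol.seq
        assert back.topology == "circular"
        assert sorted((f.kind, f.start, f.end, f.strand) for f in back.features) == sorted(
            (f.kind, f.start, f.end, f.strand) for f in mol.features
        )

    def test_oligo_feature_position_survives(self, tmp_path):
        from cosbr.designer import design_lox_oligo
        from cosbr.fixtures import FixtureSpec, make_locus

        locus, _ = make_locus(FixtureSpec(seed=5))
        oligo = design_lox_oligo(locus, 9000)
        path = tmp_path / "oligo.gb"
        write_construct(oligo, path, "genbank")
        back = read_construct(path)
        lox = back.features_of("loxP")[0]
        assert (lox.start, lox.end) == (83, 117)

    def test_fasta_is_sequence_only(self, tmp_path, seq1000):
        mol = DnaMolecule("m", seq1000, "linear", [Feature("exon", 1, 5, "+", "e")])
        path = tmp_path / "m.fasta"
        write_construct(mol, path, "fasta")
        text = path.read_text()
        assert text.startswith(">m")
        assert "exon" not in text


class TestValidation:
    def test_bad_alphabet(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            DnaMolecule("m", "ACGX")

    def test_site_feature_length_enforced(self):
        with pytest.raises(ValueError, match="34 bp"):
            DnaMolecule("m", "A" * 100, "linear", [Feature("loxP", 0, 30, "+", "bad")])

    def test_gene_model_exon_order_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            GeneModel("g", "+", [(100, 200), (0, 50)])

    def test_translate(self):
        assert translate("ATGAAATAA") == "MK*"
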