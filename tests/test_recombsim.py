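import warnings

import numpy as np
import pytest

from cosbr.designer import design_lox_oligo
from cosbr.fixtures import FixtureSpec, make_end_to_end_fixture, make_locus, make_mock_bac
from cosbr.pipeline import run_pipeline
from cosbr.recombsim import (
    AmbiguousHomologyError,
    HomologyNotFoundError,
    RecombineeringError,
    compare_fragment_sets,
    digest,
    gap_repair,
    pcr,
    pooled_band_sizes,
    recombineer_ds,
    recombineer_ss,
    site_specific_recombine,
)
from cosbr.seqcore import (
    DnaMolecule,
    Feature,
    LOXP_SITE,
    molecules_equivalent,
    reverse_complement,
    revcomp,
    rotate,
)


def _rand(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="module")
def locus():
    return make_locus(FixtureSpec(seed=61))[0]


class TestRecombineerDs:
    def test_cassette_prep_size_shift(self, e2e):
        """Marker insertion via the internal 71/60-nt homologies turns the
        463-nt synthesized insert region into 2,232 nt (463-71-60+1900)."""
        prep = recombineer_ds(e2e.puc_plasmid, e2e.selection_fragment, 50)
        insert_region = len(prep) - (len(e2e.puc_plasmid) - len(e2e.design.cassette_insert))
        assert insert_region == 2232

    def test_identity_replacement_is_noop(self, locus):
        donor = DnaMolecule("d", locus.seq[4_000:4_400])
        product = recombineer_ds(locus, donor, 50)
        assert product.seq == locus.seq

    def test_ambiguous_arm_rejected(self):
        core = _rand(500, 1)
        arm = _rand(60, 2)
        target = DnaMolecule("t", _rand(200, 3) + arm + core + arm + _rand(200, 4))
        donor = DnaMolecule("d", arm + "ACGT" * 10 + arm)
        with pytest.raises(AmbiguousHomologyError):
            recombineer_ds(target, donor, 50)

    def test_missing_arm_rejected(self, locus):
        donor = DnaMolecule("d", _rand(300, 9))
        with pytest.raises(HomologyNotFoundError):
            recombineer_ds(locus, donor, 50)

    def test_length_conservation_rule(self, locus):
        """len(product) = len(target) - replaced span + payload."""
        payload = _rand(777, 5)
        donor = DnaMolecule("d", locus.seq[3_000:3_100] + payload + locus.seq[3_600:3_700])
        product = recombineer_ds(locus, donor, 50)
        assert len(product) == len(locus) - 700 + len(donor)


class TestRecombineerSs:
    def test_loxp_oligo_inserts_34(self, locus):
        oligo = design_lox_oligo(locus, 9_000)
        product = recombineer_ss(locus, oligo, 50)
        assert len(product) == len(locus) + 34
        assert product.seq[:9_000] == locus.seq[:9_000]
        assert product.seq[9_000:9_034] == LOXP_SITE
        assert product.seq[9_034:] == locus.seq[9_000:]

    def test_strand_symmetric(self, locus):
        oligo = design_lox_oligo(locus, 9_000)
        assert recombineer_ss(locus, oligo, 50).seq == recombineer_ss(locus, reverse_complement(oligo), 50).seq

    def test_replacement_when_flanks_span_interval(self, locus):
        oligo = DnaMolecule("rep", locus.seq[5_000:5_083] + LOXP_SITE + locus.seq[5_583:5_666])
        product = recombineer_ss(locus, oligo, 50)
        assert len(product) == len(locus) - 500 + 34


class TestGapRepair:
    def test_published_size_arithmetic(self):
        """5,000-nt linearized vector with 200-nt arms retrieving an
        8,000-nt interval -> 12,600-nt circle (each arm counted once)."""
        bac_seq = _rand(30_000, 7)
        interval = bac_seq[10_000:18_000]
        vec = DnaMolecule("v", interval[-200:] + _rand(4_600, 8) + interval[:200])
        bac = DnaMolecule("b", bac_seq, "circular")
        product = gap_repair(bac, vec, 50)
        assert len(product) == 5_000 + 8_000 - 2 * 200
        assert product.is_circular

    def test_carries_cotargeted_features(self, pipeline_result):
        final = pipeline_result.final_cko
        assert len(final.features_of("loxP")) == 2
        assert len(final.features_of("FRT")) == 2
        assert any("neo" in f.label for f in final.features_of("marker"))

    def test_degenerate_interval_rejected(self):
        bac_seq = _rand(30_000, 7)
        arm = bac_seq[10_000:10_200]
        vec = DnaMolecule("v", arm + _rand(4_600, 8) + arm)
        with pytest.raises((RecombineeringError, AmbiguousHomologyError)):
            gap_repair(DnaMolecule("b", bac_seq, "circular"), vec, 50)

    def test_circular_vector_rejected(self):
        bac = DnaMolecule("b", _rand(10_000, 7), "circular")
        vec = DnaMolecule("v", _rand(4_000, 8), "circular")
        with pytest.raises(RecombineeringError, match="linearized"):
            gap_repair(bac, vec, 50)


class TestSiteSpecificRecombination:
    def _circle_with_sites(self, gap=1_000, strand_b="+"):
        pad1 = _rand(3_000, 11)
        seg = _rand(gap, 12)
        pad2 = _rand(10_000 - 3_000 - gap - 68, 13)
        seq = pad1 + LOXP_SITE + seg + LOXP_SITE + pad2
        feats = [
            Feature("loxP", 3_000, 3_034, "+", "L1"),
            Feature("loxP", 3_034 + gap, 3_068 + gap, strand_b, "L2"),
            Feature("marker", 3_100, 3_200, "+", "inside"),
            Feature("marker", 9_000, 9_100, "+", "outside"),
        ]
        return DnaMolecule("c", seq, "circular", feats)

    def test_direct_repeat_excision_on_circle(self):
        mol = self._circle_with_sites()
        products = site_specific_recombine(mol, "loxP")
        lens = sorted(len(p) for p in products)
        assert lens == [1_034, 8_966]
        assert sum(lens) == len(mol)
        for p in products:
            assert len(p.features_of("loxP")) == 1
        small = min(products, key=len)
        assert [f.label for f in small.features_of("marker")] == ["inside"]

    def test_linear_excision_products(self):
        mol = self._circle_with_sites().copy(topology="linear")
        products = site_specific_recombine(mol, "loxP")
        assert [p.topology for p in products] == ["linear", "circular"]
        assert sum(len(p) for p in products) == len(mol)

    def test_inverted_repeats_invert_segment(self):
        mol = self._circle_with_sites(strand_b="-")
        (product,) = site_specific_recombine(mol, "loxP")
        assert len(product) == len(mol)
        assert len(product.features_of("loxP")) == 2
        inside = [f for f in product.features_of("marker") if f.label == "inside"][0]
        assert inside.strand == "-"
        # the inverted interior really is reverse-complemented
        assert product.seq[3_017 : 3_017 + 1_034] == revcomp(mol.seq[3_017 : 3_017 + 1_034])

    def test_site_count_errors(self):
        mol = self._circle_with_sites()
        lone = DnaMolecule("x", mol.seq, "circular", [mol.features[0]])
        with pytest.raises(RecombineeringError, match=">= 2"):
            site_specific_recombine(lone, "loxP")
        three = mol.copy()
        three.features.append(Feature("loxP", 8_000, 8_034, "+", "L3"))
        with pytest.raises(RecombineeringError, match="name an explicit pair"):
            site_specific_recombine(three, "loxP")
        products = site_specific_recombine(three, "loxP", pair=("L1", "L2"))
        assert sorted(len(p) for p in products) == [1_034, 8_966]

    def test_flp_then_cre_on_final_vector(self, pipeline_result):
        post_flp = pipeline_result.post_flp
        assert len(post_flp.features_of("loxP")) == 2
        assert len(post_flp.features_of("FRT")) == 1
        post_cre = pipeline_result.post_cre
        assert len(post_cre.features_of("loxP")) == 1
        assert len(post_cre.features_of("FRT")) == 0


class TestDigest:
    def test_mixed_prep_shows_three_bands(self, e2e, pipeline_result):
        assert len(pipeline_result.mixed_prep_bands) == 3
        small, mid, big = pipeline_result.mixed_prep_bands
        assert abs(small - 500) < 100   # the synthesized-insert band (~0.5 kb)
        assert abs(mid - 2_200) < 100   # the size-shifted cassette (~2.2 kb)

    def test_circular_single_cut_linearizes(self):
        seq = _rand(1_500, 21) + "GAATTC" + _rand(1_494, 22)
        mol = DnaMolecule("c", seq, "circular")
        res = digest(mol, ["EcoRI"])
        assert len(res.fragments) == 1
        assert len(res.fragments[0]) == 3_000
        assert not res.fragments[0].is_circular

    def test_linear_no_cut_is_identity(self):
        mol = DnaMolecule("l", _rand(2_000, 23))
        res = digest(mol, ["NotI"])
        assert res.fragment_lengths == [2_000]

    @pytest.mark.parametrize("topology", ["linear", "circular"])
    def test_fragment_lengths_sum_to_molecule(self, topology):
        rng = np.random.default_rng(31)
        seq = list(_rand(8_000, 31))
        for pos in rng.integers(0, 7_900, size=5):
            seq[pos : pos + 6] = list("GGATCC")
        mol = DnaMolecule("m", "".join(seq), topology)
        res = digest(mol, ["BamHI"])
        assert sum(res.fragment_lengths) == len(mol)
        n_cuts = len(res.cut_positions)
        assert len(res.fragments) == (n_cuts + 1 if topology == "linear" else max(n_cuts, 1))

    def test_rotation_invariant_fragments(self):
        seq = list(_rand(6_000, 37))
        for pos in (500, 2_200, 4_700):
            seq[pos : pos + 6] = list("ACTAGT")
        mol = DnaMolecule("m", "".join(seq), "circular")
        base = digest(mol, ["SpeI"]).fragment_lengths
        for off in (123, 2_250, 5_999):
            assert digest(rotate(mol, off), ["SpeI"]).fragment_lengths == base

    def test_unknown_enzyme(self):
        with pytest.raises(ValueError, match="unknown enzyme"):
            digest(DnaMolecule("m", "ACGT" * 100), ["HindIII"])


class TestPcr:
    def test_size_shift_after_oligo_insertion(self, locus):
        from cosbr.designer import design_screen_primers

        pp = design_screen_primers(locus, 9_000)
        oligo = design_lox_oligo(locus, 9_000)
        before = pcr(locus, pp.fwd, pp.rev)
        after = pcr(recombineer_ss(locus, oligo, 50), pp.fwd, pp.rev)
        assert after[0] - before[0] == 34

    def test_absent_primer_gives_no_product(self, locus):
        assert pcr(locus, "A" * 20, locus.seq[5_000:5_020]) == []

    def test_divergent_primers_topology_semantics(self):
        seq = _rand(3_000, 41)
        fwd = seq[1_000:1_020]
        rev_site = seq[500:520]  # upstream of fwd: divergent on a line
        rev = revcomp(rev_site)
        lin = DnaMolecule("l", seq, "linear")
        circ = DnaMolecule("c", seq, "circular")
        assert pcr(lin, fwd, rev) == []
        # around the circle: 1000 -> end -> 0 -> 520
        assert pcr(circ, fwd, rev) == [(520 - 1_000) % 3_000]

    def test_polyclonal_pool_unions_amplicons(self, e2e, pipeline_result):
        amp = pipeline_result.screen_amplicons
        assert len(amp["wild_type"]) == 1
        assert amp["cotargeted"][0] - amp["wild_type"][0] == 34
        assert amp["polyclonal_well"] == sorted(amp["wild_type"] + amp["cotargeted"])

    def test_short_primer_rejected(self, locus):
        with pytest.raises(ValueError, match=">= 15"):
            pcr(locus, "ACGTACGT", "ACGTACGTACGTACGT")


class TestFingerprint:
    def test_identical_sets_match(self):
        rep = compare_fragment_sets([3_000, 1_200, 800], [3_000, 1_200, 800])
        assert rep.is_match

    def test_five_percent_tolerance(self):
        rep = compare_fragment_sets([3_100], [3_000])
        assert rep.is_match
        rep = compare_fragment_sets([3_300], [3_000])
        assert not rep.is_match

    def test_rearranged_clone_flagged(self, locus):
        intact = make_mock_bac(locus, "T7_to_Sp6", seed=61)
        broken = make_mock_bac(locus, "T7_to_Sp6", seed=61, inject_rearrangement=True)
        d1 = digest(intact.molecule(), ["SpeI"])
        d2 = digest(broken.molecule(), ["SpeI"])
        assert d1.fragment_lengths != d2.fragment_lengths
        assert not compare_fragment_sets(d2.fragment_lengths, d1.fragment_lengths).is_match


class TestPipelineOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_pipeline_matches_string_assembly(self, seed):
        """The simulated design->prep->co-target->retrieve chain must equal
        the independently string-assembled expected vector base-for-base."""
        fx = make_end_to_end_fixture(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pipeline(
                fx.bac,
                fx.puc_plasmid,
                fx.selection_fragment,
                fx.design.lox_oligo,
                fx.retrieval_plasmid,
                fx.params,
            )
        assert molecules_equivalent(res.final_cko, fx.expected_cko)

    def test_length_conservation_through_pipeline(self, e2e, pipeline_result):
        res = pipeline_result
        assert len(res.cassette_prep_plasmid) == len(e2e.puc_plasmid) - 131 + 1_900
        assert len(res.cotargeted_bac) == len(e2e.bac.molecule()) + 2_020 + 34
        assert len(res.post_flp) + len(res.flp_excised) == len(res.final_cko)
        assert len(res.post_cre) + len(res.cre_excised) == len(res.post_flp)
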