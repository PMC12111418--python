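"""Base composition, AT/GC skews, and codon-position pooling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitochar as mc
from mitochar.genome_model import FeatureType, InputError, Strand, reverse_complement

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestBaseComposition:
    def test_uniform_sequence(self):
        p = mc.base_composition("ACGT")
        assert all(v == 25.0 for v in p.percent.values())
        assert p.at_skew == 0 and p.gc_skew == 0

    def test_degenerate_denominator_flagged(self):
        p = mc.base_composition("AAAA")
        assert p.percent["A"] == 100.0
        assert p.at_skew == 1.0
        assert p.gc_skew is None  # undefined, flagged

    def test_n_excluded_from_denominators(self):
        p = mc.base_composition("ANANGNCN")
        assert p.length == 4
        assert p.percent["A"] == 50.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            mc.base_composition("")

    def test_random_10kb_matches_generator_probabilities(self):
        # law-of-large-numbers bound at 10 kb, fixed seed
        rng = np.random.default_rng(17)
        probs = {"A": 0.314, "T": 0.251, "C": 0.274, "G": 0.161}
        seq = "".join(rng.choice(list(probs), size=10_000, p=list(probs.values())))
        p = mc.base_composition(seq)
        for b, target in probs.items():
            assert abs(p.percent[b] - 100 * target) < 1.5

    @given(SEQ)
    def test_skews_bounded_and_signed_by_counts(self, seq):
        p = mc.base_composition(seq)
        if p.at_skew is not None:
            assert -1 <= p.at_skew <= 1
            assert np.sign(p.at_skew) == np.sign(p.counts["A"] - p.counts["T"])
        if p.gc_skew is not None:
            assert -1 <= p.gc_skew <= 1

    @given(SEQ)
    def test_reverse_complement_negates_both_skews(self, seq):
        p = mc.base_composition(seq)
        q = mc.base_composition(reverse_complement(seq))
        if p.at_skew is not None:
            assert q.at_skew == pytest.approx(-p.at_skew, abs=1e-12)
        if p.gc_skew is not None:
            assert q.gc_skew == pytest.approx(-p.gc_skew, abs=1e-12)

    @given(SEQ, SEQ)
    def test_concatenation_additivity_of_counts(self, s1, s2):
        c1 = mc.base_composition(s1).counts
        c2 = mc.base_composition(s2).counts
        both = mc.base_composition(s1 + s2).counts
        assert all(both[b] == c1[b] + c2[b] for b in "TCAG")


class TestSkewFormula:
    def test_published_full_genome_skew_from_printed_percentages(self):
        assert mc.skew(31.4, 25.1) == pytest.approx(0.112, abs=5e-4)

    def test_published_rrna_skew_from_printed_percentages(self):
        assert mc.skew(34.7, 20.1) == pytest.approx(0.266, abs=5e-4)

    def test_symmetry_gives_zero(self):
        assert mc.skew(12.3, 12.3) == 0

    def test_zero_denominator_flagged(self):
        assert mc.skew(0, 0) is None


class TestCodonPositionComposition:
    def test_single_repeated_codon(self):
        p1, p2, p3 = mc.codon_position_composition(["ATGATGATG"])
        assert p1.percent["A"] == 100.0
        assert p2.percent["T"] == 100.0
        assert p3.percent["G"] == 100.0

    def test_hand_counted_two_cds(self):
        # codons ATG TAA ATG TAA: 1st position pools to 50% A, 50% T
        p1, _, _ = mc.codon_position_composition(["ATGTAA", "ATGTAA"])
        assert p1.percent["A"] == 50.0
        assert p1.percent["T"] == 50.0

    def test_incomplete_terminal_codon_trimmed(self):
        p1, _, _ = mc.codon_position_composition(["ATGTA"])
        assert p1.length == 1

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            mc.codon_position_composition([])


@pytest.fixture(scope="module")
def toy():
    # H-strand PCG at 1-12, L-strand PCG at 16-27 (written as revcomp),
    # control region at 28-33
    pcg2 = "ATGCCCAAATAA"
    seq = "ATGAAACCCTAA" + "TTT" + reverse_complement(pcg2) + "GGGGGG"
    feats = [
        mc.GeneFeature("g1", FeatureType.PCG, 1, 12, Strand.H),
        mc.GeneFeature("g2", FeatureType.PCG, 16, 27, Strand.L),
        mc.GeneFeature("D-loop", FeatureType.CONTROL, 28, 33, Strand.H),
    ]
    return mc.MitogenomeRecord("toy", sequence=seq, features=feats)


class TestRegionCompositions:

    def test_per_gene_rows_use_heavy_strand_orientation(self, toy):
        rows = {p.label: p for p in mc.region_compositions(toy)}
        # g2's genome-strand sequence is the reverse complement of its CDS
        direct = mc.base_composition(toy.sequence[15:27])
        assert rows["g2"].counts == direct.counts

    def test_codon_position_rows_use_coding_strand(self, toy):
        rows = mc.region_compositions(toy)
        p1 = next(p for p in rows if p.label == "PCGs-1st")
        # both CDSs contribute 4 codons each; first positions: A,A,C,T + A,C,A,T
        assert p1.counts["A"] == 4 and p1.counts["C"] == 2 and p1.counts["T"] == 2

    def test_profiles_equal_direct_counts(self, toy):
        rows = {p.label: p for p in mc.region_compositions(toy)}
        assert rows["Full genome"].counts == mc.base_composition(toy.sequence).counts
        assert rows["D-loop"].counts == mc.base_composition("GGGGGG").counts

    def test_expected_row_set_on_simulated_genome(self, sim_genome):
        labels = [p.label for p in mc.region_compositions(sim_genome)]
        assert labels[0] == "Full genome"
        assert "D-loop" in labels and "PCGs" in labels and "tRNAs" in labels
        assert {"PCGs-1st", "PCGs-2nd", "PCGs-3rd"} <= set(labels)
        assert len(labels) == 23  # 5 summary + 3 positions + 13 PCGs + 2 rRNAs

    def test_coordinate_only_record_rejected(self, reference):
        with pytest.raises(InputError):
            mc.region_compositions(reference)
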