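"""NG86 Ka/Ks: fractional site counts and pathway-averaged differences are
checked against exhaustive enumeration oracles, plus recovery of known
selection regimes from simulated families."""

from itertools import permutations

import numpy as np
import pytest

import mitochar as mc
from mitochar.codons import get_code
from mitochar.genome_model import InputError
from mitochar.selection import jukes_cantor

CODE = get_code()
SENSE = CODE.sense_codons


# --- independent oracles -----------------------------------------------------

def oracle_sites(codon):
    """Direct enumeration of the 9 single-base neighbors."""
    s = n = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if nb in CODE.stop_codons:
                continue
            if CODE.forward[nb] == CODE.forward[codon]:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def oracle_differences(a, b):
    """Average (syn, nonsyn) steps over all stop-free minimal pathways; falls
    back to all pathways (stop steps nonsynonymous) when every one is blocked."""
    diff = [i for i in range(3) if a[i] != b[i]]

    def walk(order, allow):
        cur, sd, nd = a, 0.0, 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in CODE.stop_codons and nxt != b:
                if not allow:
                    return None
                nd += 1
            elif cur in CODE.stop_codons or nxt in CODE.stop_codons:
                nd += 1
            elif CODE.forward[cur] == CODE.forward[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [walk(o, False) for o in permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(o, True) for o in permutations(diff)]
    return (
        sum(p[0] for p in valid) / len(valid),
        sum(p[1] for p in valid) / len(valid),
    )


# --- site counts -------------------------------------------------------------

class TestCountSites:
    def test_phenylalanine_third_position(self):
        # TTT: only TTC among the 9 neighbors is synonymous
        s, n = mc.count_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_glycine_fourfold_third_position(self):
        s, _ = mc.count_sites("GGG")
        assert s >= 1.0

    def test_stop_codon_rejected(self):
        with pytest.raises(InputError):
            mc.count_sites("TAA")

    @pytest.mark.parametrize("codon", SENSE)
    def test_all_sense_codons_match_enumeration_oracle(self, codon):
        s, n = mc.count_sites(codon)
        os_, on_ = oracle_sites(codon)
        assert s == pytest.approx(os_) and n == pytest.approx(on_)
        assert s + n <= 3 + 1e-12

    def test_site_total_is_three_without_stop_neighbors(self):
        # CCC has no stop codon among its 9 neighbors
        s, n = mc.count_sites("CCC")
        assert s + n == pytest.approx(3.0)

    def test_stop_neighbor_reduces_site_total(self):
        # GGG -> AGG (stop in the vertebrate mito code) is excluded
        s, n = mc.count_sites("GGG")
        assert s + n == pytest.approx(3.0 - 1 / 3)


# --- pairwise ----------------------------------------------------------------

class TestPairwiseKaKs:
    def test_identical_sequences(self):
        r = mc.pairwise_kaks("ATGAAACCC", "ATGAAACCC")
        assert r.sd == r.nd == 0
        assert r.ka == r.ks == 0.0
        assert r.ratio is None  # undefined, not zero-by-convention

    def test_single_synonymous_change_in_fourfold_codon(self):
        base = "ATG" + "GGA" * 99
        other = "ATG" + "GGA" * 98 + "GGC"
        r = mc.pairwise_kaks(base, other)
        assert r.nd == 0 and r.sd == pytest.approx(1.0)
        assert r.ka == 0.0 and r.ks > 0

    def test_two_position_codon_matches_pathway_oracle(self):
        # TTT vs CTC differs at two positions; both orderings averaged
        a, b = "TTTTTTATG", "CTCTTAATG"
        r = mc.pairwise_kaks(a, b)
        exp_sd = exp_nd = 0.0
        for i in range(0, len(a), 3):
            d = oracle_differences(*sorted((a[i : i + 3], b[i : i + 3])))
            exp_sd += d[0]
            exp_nd += d[1]
        assert r.sd == pytest.approx(exp_sd)
        assert r.nd == pytest.approx(exp_nd)

    def test_random_codon_pairs_match_oracle_and_conserve_differences(self):
        rng = np.random.default_rng(23)
        for _ in range(500):
            ca, cb = rng.choice(SENSE, 2)
            r = mc.pairwise_kaks(ca, cb)
            sd, nd = oracle_differences(*sorted((ca, cb)))
            assert r.sd == pytest.approx(sd)
            assert r.nd == pytest.approx(nd)
            ndiff = sum(x != y for x, y in zip(ca, cb))
            assert r.sd + r.nd == pytest.approx(ndiff)

    def test_exact_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = "".join(rng.choice(SENSE, 20))
            b = "".join(rng.choice(SENSE, 20))
            r1, r2 = mc.pairwise_kaks(a, b), mc.pairwise_kaks(b, a)
            assert (r1.sd, r1.nd, r1.s_sites, r1.n_sites) == (
                r2.sd, r2.nd, r2.s_sites, r2.n_sites
            )

    def test_gap_and_n_columns_skipped(self):
        r = mc.pairwise_kaks("ATG---AAA", "ATGCCCAAA")
        assert r.n_codons == 2

    def test_stop_containing_columns_skipped(self):
        r = mc.pairwise_kaks("ATGTAAAAA", "ATGCCCAAA")
        assert r.n_codons == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            mc.pairwise_kaks("ATGAAA", "ATG")

    def test_non_codon_length_rejected(self):
        with pytest.raises(InputError):
            mc.pairwise_kaks("ATGA", "ATGA")

    def test_jc_correction_never_shrinks_proportions(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a = "".join(rng.choice(SENSE, 40))
            b = "".join(rng.choice(SENSE, 40))
            r = mc.pairwise_kaks(a, b)
            if r.ks is not None:
                assert r.ks >= r.ps - 1e-12
            if r.ka is not None:
                assert r.ka >= r.pn - 1e-12

    def test_saturation_flagged_as_undefined(self):
        assert jukes_cantor(0.8) is None


# --- gene-wise means ---------------------------------------------------------

class TestGeneMeans:
    def test_identical_family_means_are_zero(self):
        res = mc.gene_mean_kaks({"g": ["ATGAAACCC"] * 4})
        assert res[0].mean_ka == res[0].mean_ks == 0.0

    def test_single_sequence_gene_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = mc.gene_mean_kaks({"g": ["ATGAAACCC"]})
        assert res == []

    def test_omega_ordering_preserved(self):
        # two genes evolved at omega 0.05 and 0.5 keep their rank order
        rng = np.random.default_rng(31)
        anc = "ATG" + "".join(rng.choice(SENSE, 300)) + "TAA"
        tree = "(" + ",".join(f"t{i}:0.25" for i in range(6)) + ");"
        fams = {
            "slow": list(mc.evolve_family(anc, tree, omega=0.05, seed=101).values()),
            "fast": list(mc.evolve_family(anc, tree, omega=0.5, seed=102).values()),
        }
        res = {r.gene: r for r in mc.gene_mean_kaks(fams)}
        assert res["slow"].ratio_of_means < res["fast"].ratio_of_means

    def test_purifying_regime_recovered(self):
        rng = np.random.default_rng(13)
        anc = "ATG" + "".join(rng.choice(SENSE, 400)) + "TAA"
        tree = "(" + ",".join(f"t{i}:0.25" for i in range(6)) + ");"
        tips = mc.evolve_family(anc, tree, omega=0.1, seed=41)
        r = mc.gene_mean_kaks({"g": list(tips.values())})[0]
        assert 0.4 <= r.mean_ks <= 0.7  # divergence near the calibrated range
        assert abs(r.ratio_of_means - 0.1) < 0.05
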