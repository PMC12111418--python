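"""Concatenation, JC distances, and neighbor joining (exact recovery on
additive matrices; permutation equivariance)."""

import math

import numpy as np
import pytest

import mitochar as mc
from mitochar.genome_model import FeatureType, InputError
from mitochar.phylo import DistanceMatrix, tree_path_lengths


def _records(seqs: dict[str, dict[str, str]]):
    """Build sequence records with abutting single-gene features."""
    out = []
    for taxon, genes in seqs.items():
        seq = "".join(genes.values())
        feats, pos = [], 1
        for g, s in genes.items():
            feats.append(mc.GeneFeature(g, FeatureType.PCG, pos, pos + len(s) - 1))
            pos += len(s)
        out.append(mc.MitogenomeRecord(taxon, sequence=seq, features=feats))
    return out


class TestConcatenatePCGs:
    def test_supermatrix_length_is_sum_of_gene_lengths(self):
        recs = _records(
            {t: {"a": "ATGAAA", "b": "ATGCCCGGG"} for t in ("x", "y", "z")}
        )
        labels, sm, parts = mc.concatenate_pcgs(recs, ["a", "b"])
        assert all(len(s) == 15 for s in sm)
        assert parts == {"a": (0, 6), "b": (6, 15)}

    def test_gene_order_permutation_leaves_distances_invariant(self):
        rng = np.random.default_rng(2)
        recs = _records(
            {
                t: {g: "".join(rng.choice(list("ACGT"), 60)) for g in ("a", "b", "c")}
                for t in ("x", "y", "z")
            }
        )
        _, sm1, _ = mc.concatenate_pcgs(recs, ["a", "b", "c"])
        _, sm2, _ = mc.concatenate_pcgs(recs, ["c", "a", "b"])
        d1 = mc.jc_distance_matrix(["x", "y", "z"], sm1)
        d2 = mc.jc_distance_matrix(["x", "y", "z"], sm2)
        assert np.allclose(d1.matrix, d2.matrix)

    def test_missing_gene_error_names_taxon_and_gene(self):
        recs = _records(
            {"x": {"a": "ATGAAA", "b": "ATGCCC"}, "y": {"a": "ATGAAA"}}
        )
        with pytest.raises(InputError, match="'y' is missing gene 'b'"):
            mc.concatenate_pcgs(recs, ["a", "b"])


class TestJCDistance:
    def test_identical_sequences_have_zero_distance(self):
        dm = mc.jc_distance_matrix(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert dm.matrix[0, 1] == 0.0

    def test_matches_closed_form(self):
        # 47 differences over 1000 sites
        s1 = "A" * 1000
        s2 = "C" * 47 + "A" * 953
        dm = mc.jc_distance_matrix(["a", "b"], [s1, s2])
        p = 0.047
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert dm.matrix[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_gap_sites_excluded_pairwise(self):
        dm = mc.jc_distance_matrix(["a", "b"], ["ACG-", "ACGT"])
        assert dm.matrix[0, 1] == 0.0

    def test_saturated_pair_flagged(self):
        dm = mc.jc_distance_matrix(["a", "b"], ["A" * 100, "C" * 100])
        assert ("a", "b") in dm.saturated

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(4)]
        labels = ["a", "b", "c", "d"]
        dm = mc.jc_distance_matrix(labels, seqs)
        perm = [2, 0, 3, 1]
        dm2 = mc.jc_distance_matrix([labels[i] for i in perm], [seqs[i] for i in perm])
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i != j:
                    assert dm.get(x, y) == pytest.approx(dm2.get(x, y))


def _additive_matrix_from_tree(newick: str):
    """Leaf-to-leaf path lengths of a reference tree, via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    m = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.distance(taxa[labels[i]], taxa[labels[j]])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, matrix=m)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            labels=["a", "b", "c"],
            matrix=np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.0]]),
        )
        tree = mc.neighbor_joining(dm)
        paths = tree_path_lengths(tree)
        assert paths[frozenset(("a", "b"))] == pytest.approx(3)
        assert paths[frozenset(("a", "c"))] == pytest.approx(5)
        assert paths[frozenset(("b", "c"))] == pytest.approx(6)

    @pytest.mark.parametrize(
        "newick",
        [
            "((A:2,B:3):1,C:4,D:5);",
            "(((A:1,B:2):0.5,(C:1.5,D:0.7):0.8):0.4,E:2,F:1.1);",
        ],
    )
    def test_additive_matrix_recovers_exact_path_lengths(self, newick):
        dm = _additive_matrix_from_tree(newick)
        tree = mc.neighbor_joining(dm)
        paths = tree_path_lengths(tree)
        for i, x in enumerate(dm.labels):
            for y in dm.labels[i + 1 :]:
                assert paths[frozenset((x, y))] == pytest.approx(
                    dm.get(x, y), abs=1e-9
                )

    def test_four_taxon_split_recovered(self):
        dm = _additive_matrix_from_tree("((A:2,B:3):1,(C:4,D:5):1);")
        tree = mc.neighbor_joining(dm)
        from conftest import clades_are_monophyletic

        assert clades_are_monophyletic(tree.to_newick(), {"A": 0, "B": 0, "C": 1, "D": 1}) == {
            0: True,
            1: True,
        }

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(labels=["a", "b"], matrix=np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(InputError):
            mc.neighbor_joining(dm)

    def test_newick_output_parses_with_all_leaves(self):
        dm = _additive_matrix_from_tree("((A:2,B:3):1,C:4,D:5);")
        tree = mc.neighbor_joining(dm)
        import dendropy

        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == {"A", "B", "C", "D"}


class TestCladeRecovery:
    def test_three_clade_dataset_recovered_by_nj(self):
        from conftest import clades_are_monophyletic
        from mitochar.presets import PCG_NAMES

        ds = mc.simulate_clade_dataset(6, 3, seed=7)
        labels, sm, _ = mc.concatenate_pcgs(ds.records, PCG_NAMES)
        tree = mc.neighbor_joining(mc.jc_distance_matrix(labels, sm))
        assert all(clades_are_monophyletic(tree.to_newick(), ds.clades).values())
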