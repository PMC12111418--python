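"""Shared fixtures: the published-annotation fixture, simulated genomes, and
a monophyly checker."""

from __future__ import annotations

import pytest
from hypothesis import settings

import mitochar as mc
from mitochar.presets import REFERENCE_FEATURE_ROWS

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference():
    """Coordinate-only record built from the published annotation table."""
    return mc.reference_record()


@pytest.fixture(scope="session")
def sim_genome():
    """One simulated annotated mitogenome on the published template."""
    return mc.simulate_mitogenome(seed=11)


@pytest.fixture()
def feature_table_text():
    """The published annotation rendered as a printed-style TSV, with en-dash
    locations, thousands separators, and descending light-strand rows."""
    lines = ["Number\tGenes\tLocation (bp)\tSize (bp)\tCoding Strand\tCondon"]
    for i, (name, s, e, strand, start, stop) in enumerate(REFERENCE_FEATURE_ROWS, 1):
        loc = f"{s:,}–{e:,}"
        size = abs(e - s) + 1
        lines.append(f"{i}\t{name}\t{loc}\t{size}\t{strand}\t{start} {stop}".rstrip())
    return "\n".join(lines) + "\n"


def clades_are_monophyletic(newick: str, clades: dict[str, int]) -> dict[int, bool]:
    """Which clades form a clade (or its complement) in the unrooted tree."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    biparts = [
        frozenset(x.label for x in e.bipartition.leafset_taxa(tree.taxon_namespace))
        for e in tree.bipartition_edge_map.values()
    ]
    alltaxa = frozenset(clades)
    groups: dict[int, set] = {}
    for lab, c in clades.items():
        groups.setdefault(c, set()).add(lab)
    return {
        c: any(b == frozenset(g) or (alltaxa - b) == frozenset(g) for b in biparts)
        for c, g in groups.items()
    }
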