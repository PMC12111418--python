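"""Genetic-code helpers built on Biopython's NCBI translation tables.

The default is translation table 2 (vertebrate mitochondrial): TGA = Trp,
ATA = Met, and AGA/AGG are stops, which is what the GTG start and the
T--/TA- incomplete stops of fish mitogenomes presuppose.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

BASES = "TCAG"
VERTEBRATE_MITO = 2


# eq=False keeps identity hashing: instances are lru_cache singletons per
# table id and are used as cache keys by the selection module.
@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A translation table with the derived lookups codon analyses need."""

    table_id: int
    forward: dict  # sense codon -> one-letter amino acid
    stop_codons: frozenset

    @property
    def sense_codons(self) -> list[str]:
        return sorted(self.forward)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> str:
        return self.forward[codon]

    @property
    def families(self) -> dict[str, list[str]]:
        """Synonymous families: amino acid -> sorted list of its codons."""
        fam: dict[str, list[str]] = {}
        for codon, aa in self.forward.items():
            fam.setdefault(aa, []).append(codon)
        return {aa: sorted(cs) for aa, cs in fam.items()}


@lru_cache(maxsize=None)
def get_code(table_id: int = VERTEBRATE_MITO) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    forward = dict(table.forward_table)
    # guard: forward_table must cover exactly the non-stop codons
    assert len(forward) + len(table.stop_codons) == 64
    return GeneticCode(
        table_id=table_id,
        forward=forward,
        stop_codons=frozenset(table.stop_codons),
    )


def codons_of(seq: str) -> list[str]:
    """Split a coding sequence into complete codons, dropping 1-2 trailing
    bases left by an incomplete terminal stop codon."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


ALL_CODONS = ["".join(p) for p in product(BASES, repeat=3)]

__all__ = ["GeneticCode", "get_code", "codons_of", "ALL_CODONS", "BASES", "VERTEBRATE_MITO"]
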