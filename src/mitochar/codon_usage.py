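"""Codon counting, relative synonymous codon usage (RSCU), and amino-acid
usage for mitochondrial protein-coding genes.

RSCU of a codon c in a synonymous family of size k with family total n is
``count(c) * k / n`` — the observed count relative to the expectation under
uniform usage within the family.  Values > 1 mark preferred codons; the mean
RSCU within any used family is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .codons import GeneticCode, codons_of, get_code
from .genome_model import InputError


class InternalStopWarning(UserWarning):
    """A stop codon occurred before the CDS terminus."""


def count_codons(
    cds_set: list[str], genetic_code: GeneticCode | None = None
) -> dict[str, int]:
    """Count sense codons across a set of coding-strand CDSs.

    Trailing incomplete codons (the 1-2 bases of T--/TA- stops) are dropped,
    complete terminal stop codons are excluded, and codons containing N are
    skipped.  Internal stop codons raise a warning with their position but
    are tolerated, since real mitochondrial annotations occasionally contain
    them under alternative readings.
    """
    code = genetic_code or get_code()
    counts: dict[str, int] = {}
    for idx, cds in enumerate(cds_set):
        if len(cds) < 3:
            raise InputError(f"CDS #{idx} shorter than one codon")
        codons = codons_of(cds.upper())
        for pos, codon in enumerate(codons):
            if code.is_stop(codon):
                if pos != len(codons) - 1:
                    warnings.warn(
                        f"internal stop {codon} at codon {pos + 1} of CDS #{idx}",
                        InternalStopWarning,
                        stacklevel=2,
                    )
                continue  # stop codons never enter usage counts
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return counts


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts and RSCU plus per-amino-acid totals."""

    counts: dict  # sense codon -> count
    rscu: dict  # sense codon -> RSCU (None when the family is unused)
    aa_totals: dict  # amino acid -> codon total
    total: int  # total sense codons == total encoded amino acids

    @property
    def aa_percent(self) -> dict:
        if self.total == 0:
            return {}
        return {aa: 100.0 * n / self.total for aa, n in self.aa_totals.items()}

    @property
    def preferred(self) -> list[str]:
        """Codons with RSCU > 1."""
        return sorted(c for c, v in self.rscu.items() if v is not None and v > 1)


def rscu(
    counts: dict[str, int], genetic_code: GeneticCode | None = None
) -> CodonUsageTable:
    """RSCU and amino-acid totals from raw sense-codon counts.

    Families with zero usage have undefined RSCU (``None``); single-codon
    families have RSCU identically 1 when used.  RSCU is invariant to
    duplicating the input counts.
    """
    code = genetic_code or get_code()
    rscu_vals: dict[str, float | None] = {}
    aa_totals: dict[str, int] = {}
    for aa, family in code.families.items():
        n_aa = sum(counts.get(c, 0) for c in family)
        aa_totals[aa] = n_aa
        k = len(family)
        for c in family:
            rscu_vals[c] = None if n_aa == 0 else counts.get(c, 0) * k / n_aa
    total = sum(counts.values())
    return CodonUsageTable(
        counts={c: counts.get(c, 0) for c in code.sense_codons},
        rscu=rscu_vals,
        aa_totals=aa_totals,
        total=total,
    )


def amino_acid_usage(
    counts: dict[str, int], genetic_code: GeneticCode | None = None
) -> dict[str, tuple[int, float]]:
    """Amino-acid totals and percentages of all encoded residues.

    Alternative start codons are counted as their table amino acid (GTG as
    Val), not forced to Met.
    """
    table = rscu(counts, genetic_code)
    pct = table.aa_percent
    return {
        aa: (n, pct.get(aa, 0.0)) for aa, n in table.aa_totals.items() if n > 0
    }


__all__ = [
    "count_codons",
    "rscu",
    "amino_acid_usage",
    "CodonUsageTable",
    "InternalStopWarning",
]
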