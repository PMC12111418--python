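"""Genome-structure analysis: intergenic spacers and overlaps around the
circle, strand census, start/stop-codon classification, tRNA size range, and
the light-strand replication-origin stem-loop search.

Sign convention for spacers: positive = intergenic gap, negative = overlap,
zero = abutting.  Around a circular genome the feature sizes and the signed
spacers satisfy an exact integer identity::

    sum(sizes) + sum(signed spacers) == genome length
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codons import GeneticCode
from .genome_model import (
    AdjacencyRecord,
    FeatureType,
    InputError,
    MitogenomeRecord,
    Strand,
    reverse_complement,
)

COMPLETE_STOPS = ("TAA", "TAG", "AGA", "AGG")


def compute_adjacencies(record: MitogenomeRecord) -> list[AdjacencyRecord]:
    """Signed spacer between every consecutive feature pair, including the
    wrap-around pair that closes the circle."""
    feats = record.features
    if len(feats) < 2:
        raise InputError("need at least two features for adjacency analysis")
    if record.length is None:
        raise InputError("record has no genome length")
    out = []
    for up, down in zip(feats, feats[1:]):
        out.append(
            AdjacencyRecord(up.name, down.name, down.start - up.end - 1)
        )
    last, first = feats[-1], feats[0]
    wrap = (record.length - last.end) + (first.start - 1)
    out.append(AdjacencyRecord(last.name, first.name, wrap, circular=True))
    return out


@dataclass(frozen=True)
class StemLoop:
    """An inverted-repeat hairpin: two reverse-complementary stem arms
    flanking a loop of >= 3 unpaired bases.  Positions are 0-based offsets
    into the scanned window."""

    start: int
    end: int  # exclusive, end of the 3' arm
    stem: int
    loop: int
    arm5: str
    arm3: str


def find_stem_loop(window: str, min_stem: int = 4, max_loop: int = 12) -> StemLoop | None:
    """Best hairpin in ``window`` under exact Watson-Crick arm pairing.

    Maximizes stem length; ties broken by smaller loop, then leftmost
    position.  Returns ``None`` when no hairpin with ``stem >= min_stem`` and
    ``3 <= loop <= max_loop`` exists.
    """
    if min_stem < 3:
        raise InputError("min_stem must be >= 3")
    window = window.upper()
    n = len(window)
    if n < 2 * min_stem + 3:
        return None
    best: StemLoop | None = None
    max_stem = (n - 3) // 2
    for stem in range(max_stem, min_stem - 1, -1):
        for i in range(0, n - 2 * stem - 3 + 1):
            arm5 = window[i : i + stem]
            for loop in range(3, min(max_loop, n - i - 2 * stem) + 1):
                j = i + stem + loop
                arm3 = window[j : j + stem]
                if len(arm3) < stem:
                    break
                if arm3 == reverse_complement(arm5):
                    cand = StemLoop(i, j + stem, stem, loop, arm5, arm3)
                    if best is None or (
                        (-cand.stem, cand.loop, cand.start)
                        < (-best.stem, best.loop, best.start)
                    ):
                        best = cand
        if best is not None:
            return best  # longer stems were already exhausted
    return best


@dataclass
class StructureReport:
    """Summary of the circular gene architecture of one mitogenome."""

    adjacencies: list[AdjacencyRecord]
    spacer_count: int
    overlap_count: int
    longest_spacer: tuple[int, str, str] | None
    longest_overlap: tuple[int, str, str] | None
    strand_census: dict[FeatureType, dict[Strand, int]]
    start_codons: dict[str, str] = field(default_factory=dict)
    stop_codons: dict[str, str] = field(default_factory=dict)
    trna_size_range: tuple[int, int] | None = None

    @property
    def start_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for c in self.start_codons.values():
            census[c] = census.get(c, 0) + 1
        return census

    @property
    def stop_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for c in self.stop_codons.values():
            census[c] = census.get(c, 0) + 1
        return census


def classify_stop(cds: str) -> str:
    """Classify the terminus of a coding-strand CDS.

    A CDS whose length is a multiple of 3 and ends in TAA/TAG/AGA/AGG has a
    complete stop; one trailing base T is the incomplete stop T--, two
    trailing bases TA the incomplete TA- (completed by polyadenylation of the
    mRNA).  Anything else is reported verbatim as the trailing bases.
    """
    tail = len(cds) % 3
    if tail == 0:
        last = cds[-3:]
        return last if last in COMPLETE_STOPS else last
    if tail == 1:
        return "T--" if cds[-1] == "T" else cds[-1] + "--"
    return "TA-" if cds[-2:] == "TA" else cds[-2:] + "-"


def summarize_structure(
    record: MitogenomeRecord, genetic_code: GeneticCode | None = None
) -> StructureReport:
    """Full structural summary; codon classification only when sequence is
    present.  The wrap-around adjacency is counted as a spacer or overlap
    only when nonzero (an abutting wrap leaves the printed counts untouched).
    """
    del genetic_code  # classification is table-independent; kept for API parity
    adjacencies = compute_adjacencies(record)
    gaps = [a for a in adjacencies if a.spacer > 0]
    overlaps = [a for a in adjacencies if a.spacer < 0]

    def _extreme(records, key):
        a = max(records, key=key)
        return (abs(a.spacer), a.upstream, a.downstream)

    census: dict[FeatureType, dict[Strand, int]] = {}
    for f in record.features:
        census.setdefault(f.ftype, {Strand.H: 0, Strand.L: 0})[f.strand] += 1

    trnas = record.features_of_type(FeatureType.TRNA)
    trna_range = (
        (min(f.size for f in trnas), max(f.size for f in trnas)) if trnas else None
    )

    report = StructureReport(
        adjacencies=adjacencies,
        spacer_count=len(gaps),
        overlap_count=len(overlaps),
        longest_spacer=_extreme(gaps, lambda a: a.spacer) if gaps else None,
        longest_overlap=_extreme(overlaps, lambda a: -a.spacer) if overlaps else None,
        strand_census=census,
        trna_size_range=trna_range,
    )

    if record.has_sequence:
        for pcg in record.pcgs:
            if pcg.size < 6:
                raise InputError(f"PCG {pcg.name!r} shorter than 6 bp")
            cds = record.feature_sequence(pcg, coding_strand=True)
            report.start_codons[pcg.name] = cds[:3]
            report.stop_codons[pcg.name] = classify_stop(cds)
    return report


def origin_window(record: MitogenomeRecord) -> str | None:
    """Sequence of the longest intergenic gap — in the canonical vertebrate
    order this is the WANCY-cluster gap hosting the light-strand replication
    origin (O_L)."""
    if not record.has_sequence:
        return None
    adjacencies = compute_adjacencies(record)
    gaps = [a for a in adjacencies if a.spacer > 0 and not a.circular]
    if not gaps:
        return None
    best = max(gaps, key=lambda a: a.spacer)
    up = record.get_feature(best.upstream)
    down = record.get_feature(best.downstream)
    return record.sequence[up.end : down.start - 1]


__all__ = [
    "compute_adjacencies",
    "find_stem_loop",
    "summarize_structure",
    "classify_stop",
    "origin_window",
    "StemLoop",
    "StructureReport",
    "COMPLETE_STOPS",
]
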