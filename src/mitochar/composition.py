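"""Base composition, A+T content, and strand-asymmetry skews.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed from raw
base counts (never from rounded percentages).  Positive AT-skew means an
excess of A over T on the counted strand; vertebrate mitochondrial heavy
strands typically show positive AT-skew and negative GC-skew (C > G).

Per-gene profiles are reported in heavy-strand (genome) orientation for
parity with published composition tables — including the light-strand ND6,
whose inverted skews are the published signature of strand asymmetry —
whereas codon-position pooling uses coding-strand orientation, which is what
translation requires.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codons import codons_of
from .genome_model import (
    FeatureType,
    InputError,
    MitogenomeRecord,
)


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts and derived statistics for one region."""

    label: str
    length: int  # counted bases (N excluded)
    counts: dict  # base -> count over {T, C, A, G}
    at_skew: float | None  # None when A+T == 0 (flagged undefined)
    gc_skew: float | None

    @property
    def percent(self) -> dict:
        if self.length == 0:
            return {b: float("nan") for b in "TCAG"}
        return {b: 100.0 * self.counts[b] / self.length for b in "TCAG"}

    @property
    def at_percent(self) -> float:
        p = self.percent
        return p["A"] + p["T"]


def skew(x: float, y: float) -> float | None:
    """(x - y) / (x + y); ``None`` (undefined, flagged) on a zero denominator.

    Works identically on raw counts and on percentages, so it can be applied
    directly to published percentage tables for parity checks.
    """
    if x + y == 0:
        return None
    return (x - y) / (x + y)


def base_composition(sequence: str, label: str = "") -> CompositionProfile:
    """Count bases and compute skews for one sequence; N is excluded from all
    denominators."""
    if not sequence:
        raise InputError(f"region {label!r}: empty sequence")
    sequence = sequence.upper()
    counts = {b: sequence.count(b) for b in "TCAG"}
    length = sum(counts.values())
    return CompositionProfile(
        label=label,
        length=length,
        counts=counts,
        at_skew=skew(counts["A"], counts["T"]),
        gc_skew=skew(counts["G"], counts["C"]),
    )


def _profile_from_counts(label: str, counts: dict) -> CompositionProfile:
    return CompositionProfile(
        label=label,
        length=sum(counts.values()),
        counts=dict(counts),
        at_skew=skew(counts["A"], counts["T"]),
        gc_skew=skew(counts["G"], counts["C"]),
    )


def codon_position_composition(cds_set: list[str]) -> list[CompositionProfile]:
    """Pooled composition of 1st/2nd/3rd codon positions across a CDS set.

    Each CDS must be supplied in coding-strand orientation; a 1-2 base
    incomplete terminal codon is trimmed before pooling.
    """
    if not cds_set:
        raise InputError("empty CDS set")
    counts = [dict.fromkeys("TCAG", 0) for _ in range(3)]
    for cds in cds_set:
        if len(cds) < 3:
            raise InputError("CDS shorter than one codon")
        for codon in codons_of(cds.upper()):
            for pos, base in enumerate(codon):
                if base in "TCAG":
                    counts[pos][base] += 1
    return [
        _profile_from_counts(f"PCGs-{n}", c)
        for n, c in zip(("1st", "2nd", "3rd"), counts)
    ]


def region_compositions(record: MitogenomeRecord) -> list[CompositionProfile]:
    """The standard per-region composition table for one mitogenome.

    Rows: full genome; D-loop; concatenated PCGs / tRNAs / rRNAs; the three
    pooled codon positions; each PCG; each rRNA.  Concatenated regions join
    the annotated intervals independently, so bases shared by overlapping
    genes are counted once per gene.  All rows are in heavy-strand
    orientation except the codon-position rows, which need coding strands.
    """
    if not record.has_sequence:
        raise InputError("region composition requires a sequence")
    rows = [base_composition(record.sequence, "Full genome")]

    def _concat(ftype: FeatureType) -> str:
        return "".join(
            record.feature_sequence(f, coding_strand=False)
            for f in record.features_of_type(ftype)
        )

    for f in record.features_of_type(FeatureType.CONTROL):
        rows.append(base_composition(record.feature_sequence(f, coding_strand=False), f.name))
    for label, ftype in (
        ("PCGs", FeatureType.PCG),
        ("tRNAs", FeatureType.TRNA),
        ("rRNAs", FeatureType.RRNA),
    ):
        seq = _concat(ftype)
        if seq:
            rows.append(base_composition(seq, label))
    cds_set = [record.feature_sequence(f, coding_strand=True) for f in record.pcgs]
    if cds_set:
        rows.extend(codon_position_composition(cds_set))
    for f in record.pcgs:
        rows.append(base_composition(record.feature_sequence(f, coding_strand=False), f.name))
    for f in record.features_of_type(FeatureType.RRNA):
        rows.append(base_composition(record.feature_sequence(f, coding_strand=False), f.name))
    return rows


__all__ = [
    "CompositionProfile",
    "skew",
    "base_composition",
    "codon_position_composition",
    "region_compositions",
]
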