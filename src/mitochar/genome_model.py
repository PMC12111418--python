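"""Core data model for circular annotated mitochondrial genomes.

Coordinates are 1-based and fully inclusive throughout, the convention of
published mitogenome annotation tables.  Light-strand (L) genes are stored
with ascending coordinates plus a strand flag; converters at the I/O boundary
handle dialects that print L-strand genes with descending coordinates.

Features that wrap the replication origin (start > end on the circle) are not
supported: the canonical vertebrate gene order places the D-loop flush against
the origin, so none arise in practice.  This is a documented limitation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class FeatureType(str, enum.Enum):
    """Functional class of a mitochondrial feature."""

    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"
    ORIGIN = "origin"


class Strand(str, enum.Enum):
    """Heavy (H) or light (L) strand of the mitochondrial duplex."""

    H = "H"
    L = "L"


class InputError(ValueError):
    """Raised for invalid user-supplied coordinates or sequences."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region with normalized (ascending) coordinates."""

    name: str
    ftype: FeatureType
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, start <= end
    strand: Strand = Strand.H

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise InputError(
                f"feature {self.name!r}: coordinates must be positive "
                f"(got {self.start}-{self.end})"
            )
        if self.start > self.end:
            raise InputError(
                f"feature {self.name!r}: start {self.start} > end {self.end}; "
                "normalize with normalize_feature() first"
            )

    @property
    def size(self) -> int:
        """Length in bp (inclusive of both endpoints)."""
        return self.end - self.start + 1


def normalize_feature(
    name: str,
    raw_start: int,
    raw_end: int,
    ftype: FeatureType = FeatureType.PCG,
    strand_hint: Strand | None = None,
) -> GeneFeature:
    """Build a :class:`GeneFeature` from possibly descending printed coordinates.

    Annotation tables print light-strand genes with descending coordinates
    (e.g. ``tRNA-Gln 3978–3908``).  Descending input is swapped to ascending
    and the strand set to L, unless ``strand_hint`` overrides it.  Already
    ascending input keeps ``strand_hint`` (default H).  Idempotent on
    normalized input.
    """
    if raw_start < 1 or raw_end < 1:
        raise InputError(
            f"feature {name!r}: non-positive coordinate ({raw_start}, {raw_end})"
        )
    if raw_start > raw_end:
        start, end = raw_end, raw_start
        strand = strand_hint if strand_hint is not None else Strand.L
    else:
        start, end = raw_start, raw_end
        strand = strand_hint if strand_hint is not None else Strand.H
    return GeneFeature(name=name, ftype=ftype, start=start, end=end, strand=strand)


def _sort_key(f: GeneFeature) -> tuple[int, int, str]:
    # stable tie-break for abutting features sharing a start
    return (f.start, f.end, f.name)


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: optional sequence plus ordered features.

    ``sequence`` may be ``None`` (coordinate-only mode, e.g. when built from a
    printed annotation table); sequence-dependent analyses then raise or are
    skipped.  Features are kept sorted by (start, end, name), the adjacency
    order used for intergenic-spacer computation around the circle.
    """

    identifier: str
    sequence: str | None = None
    length: int | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise InputError(
                    f"record {self.identifier!r}: invalid bases {sorted(bad)}"
                )
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise InputError(
                    f"record {self.identifier!r}: declared length {self.length} "
                    f"!= sequence length {len(self.sequence)}"
                )
        elif self.length is None and self.features:
            self.length = genome_length_from_features(self.features)
        self.features = sorted(self.features, key=_sort_key)
        if self.length is not None:
            for f in self.features:
                if f.end > self.length:
                    raise InputError(
                        f"feature {f.name!r} ends at {f.end}, beyond genome "
                        f"length {self.length}"
                    )

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None

    def features_of_type(self, ftype: FeatureType) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype is ftype]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.features_of_type(FeatureType.PCG)

    def feature_sequence(self, feature: GeneFeature, coding_strand: bool = True) -> str:
        """Extract a feature's sequence; reverse-complemented for L-strand
        features when ``coding_strand`` is true."""
        if self.sequence is None:
            raise InputError(
                f"record {self.identifier!r} has no sequence (coordinate-only)"
            )
        seq = self.sequence[feature.start - 1 : feature.end]
        if coding_strand and feature.strand is Strand.L:
            seq = reverse_complement(seq)
        return seq

    def get_feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class AdjacencyRecord:
    """Signed spacer between two consecutive features on the circle.

    Positive = intergenic gap, negative = overlap, zero = abutting.  The pair
    closing the circle (last feature back to the first) is flagged
    ``circular``.
    """

    upstream: str
    downstream: str
    spacer: int
    circular: bool = False


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def genome_length_from_features(features: Sequence[GeneFeature] | Iterable[GeneFeature]) -> int:
    """Genome length in coordinate-only mode: the maximum feature end."""
    feats = list(features)
    if not feats:
        raise InputError("cannot infer genome length from an empty feature list")
    return max(f.end for f in feats)


__all__ = [
    "FeatureType",
    "Strand",
    "InputError",
    "GeneFeature",
    "MitogenomeRecord",
    "AdjacencyRecord",
    "normalize_feature",
    "genome_length_from_features",
    "reverse_complement",
]
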