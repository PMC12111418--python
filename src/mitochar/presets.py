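"""Published reference annotation and composition targets.

The bundled template is the printed annotation of the *Onychostoma virgulatum*
mitochondrial genome (GenBase CAA104068; 16,606 bp, 13 protein-coding genes,
22 tRNAs, 2 rRNAs, one control region in the canonical vertebrate order).
Light-strand rows are kept exactly as published, i.e. with descending
coordinates, so that loading the preset exercises the same normalization path
as reading a user-supplied table.

``REGION_BASE_COMPOSITION`` holds the published per-region base percentages
(T, C, A, G, in that column order) used both as simulator sampling targets and
for skew-parity checks.
"""

from __future__ import annotations

from .genome_model import (
    FeatureType,
    GeneFeature,
    MitogenomeRecord,
    Strand,
    normalize_feature,
)

# (name, printed start, printed end, strand, start codon, stop codon)
# Descending start/end marks a light-strand gene, as printed.
REFERENCE_FEATURE_ROWS: list[tuple[str, int, int, str, str, str]] = [
    ("tRNA-Phe", 1, 69, "H", "", ""),
    ("12S rRNA", 70, 1025, "H", "", ""),
    ("tRNA-Val", 1026, 1097, "H", "", ""),
    ("16S rRNA", 1098, 2781, "H", "", ""),
    ("tRNA-Leu", 2782, 2857, "H", "", ""),
    ("ND1", 2858, 3832, "H", "ATG", "TAA"),
    ("tRNA-Ile", 3839, 3909, "H", "", ""),
    ("tRNA-Gln", 3978, 3908, "L", "", ""),
    ("tRNA-Met", 3982, 4050, "H", "", ""),
    ("ND2", 4051, 5095, "H", "ATG", "T--"),
    ("tRNA-Trp", 5096, 5165, "H", "", ""),
    ("tRNA-Ala", 5237, 5168, "L", "", ""),
    ("tRNA-Asn", 5311, 5239, "L", "", ""),
    ("tRNA-Cys", 5411, 5345, "L", "", ""),
    ("tRNA-Tyr", 5481, 5411, "L", "", ""),
    ("COX1", 5483, 7033, "H", "GTG", "TAA"),
    ("tRNA-Ser", 7104, 7034, "L", "", ""),
    ("tRNA-Asp", 7110, 7179, "H", "", ""),
    ("COX2", 7193, 7883, "H", "ATG", "T--"),
    ("tRNA-Lys", 7884, 7959, "H", "", ""),
    ("ATP8", 7961, 8125, "H", "ATG", "TAG"),
    ("ATP6", 8119, 8802, "H", "ATG", "TAA"),
    ("COX3", 8802, 9586, "H", "ATG", "TA-"),
    ("tRNA-Gly", 9587, 9659, "H", "", ""),
    ("ND3", 9660, 10008, "H", "ATG", "T--"),
    ("tRNA-Arg", 10009, 10079, "H", "", ""),
    ("ND4L", 10080, 10376, "H", "ATG", "TAA"),
    ("ND4", 10370, 11750, "H", "ATG", "T--"),
    ("tRNA-His", 11751, 11819, "H", "", ""),
    ("tRNA-Ser", 11820, 11888, "H", "", ""),
    ("tRNA-Leu", 11890, 11962, "H", "", ""),
    ("ND5", 11963, 13786, "H", "ATG", "TAA"),
    ("ND6", 14304, 13783, "L", "ATG", "TAA"),
    ("tRNA-Glu", 14373, 14305, "L", "", ""),
    ("CYTB", 14379, 15519, "H", "ATG", "T--"),
    ("tRNA-Thr", 15520, 15591, "H", "", ""),
    ("tRNA-Pro", 15661, 15591, "L", "", ""),
    ("D-loop", 15662, 16606, "H", "", ""),
]

PCG_NAMES = [
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
]

# Published per-region base percentages, columns (T, C, A, G).
REGION_BASE_COMPOSITION: dict[str, tuple[float, float, float, float]] = {
    "Full genome": (25.1, 27.4, 31.4, 16.1),
    "D-loop": (32.6, 21.1, 33.5, 12.8),
    "PCGs": (27.0, 28.1, 29.4, 15.5),
    "tRNAs": (26.8, 21.4, 28.0, 23.8),
    "rRNAs": (20.1, 24.5, 34.7, 20.7),
    "PCGs-1st": (20.9, 26.4, 27.1, 25.6),
    "PCGs-2nd": (40.4, 27.3, 18.6, 13.7),
    "PCGs-3rd": (19.7, 30.6, 42.4, 7.3),
}


def infer_feature_type(name: str) -> FeatureType:
    """Classify a feature from its conventional name.

    tRNAs are named ``tRNA-Xxx``, rRNAs ``12S/16S rRNA``, the control region
    ``D-loop``; everything else is treated as a protein-coding gene.
    """
    low = name.lower()
    if low.startswith("trna"):
        return FeatureType.TRNA
    if "rrna" in low or low in ("12s", "16s"):
        return FeatureType.RRNA
    if "d-loop" in low or "control" in low:
        return FeatureType.CONTROL
    if low in ("ol", "o_l", "rep_origin"):
        return FeatureType.ORIGIN
    return FeatureType.PCG


def dedupe_names(names: list[str]) -> list[str]:
    """Disambiguate duplicated gene names (the two tRNA-Ser / tRNA-Leu genes)
    by appending an ordinal suffix: tRNA-Ser1, tRNA-Ser2."""
    from collections import Counter

    total = Counter(names)
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if total[n] > 1:
            seen[n] = seen.get(n, 0) + 1
            out.append(f"{n}{seen[n]}")
        else:
            out.append(n)
    return out


def reference_record(identifier: str = "reference") -> MitogenomeRecord:
    """The published annotation as a coordinate-only record (no sequence)."""
    names = dedupe_names([row[0] for row in REFERENCE_FEATURE_ROWS])
    feats: list[GeneFeature] = []
    for new_name, (name, s, e, strand, _sc, _ec) in zip(names, REFERENCE_FEATURE_ROWS):
        feats.append(
            normalize_feature(
                new_name, s, e,
                ftype=infer_feature_type(name),
                strand_hint=Strand(strand),
            )
        )
    return MitogenomeRecord(identifier=identifier, features=feats)


def reference_codons() -> dict[str, tuple[str, str]]:
    """Per-PCG (start codon, stop class) of the reference annotation, keyed by
    gene name.  Stop classes: complete codons (TAA/TAG) or incomplete T--/TA-."""
    return {
        name: (sc, ec)
        for name, _s, _e, _strand, sc, ec in REFERENCE_FEATURE_ROWS
        if sc
    }


__all__ = [
    "REFERENCE_FEATURE_ROWS",
    "REGION_BASE_COMPOSITION",
    "PCG_NAMES",
    "infer_feature_type",
    "dedupe_names",
    "reference_record",
    "reference_codons",
]
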