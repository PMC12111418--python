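"""Readers and writers: GenBank flat files, FASTA, tab/comma-separated
feature tables in the dialect of published mitogenome annotation tables, and
CSV/Newick analysis reports.

The feature-table dialect: columns for gene name, location ``start–end``
(en-dash or hyphen, optional thousands separators, descending coordinates for
light-strand genes), size, intergenic spacer, coding strand, and start/stop
codons.  The spacer column is redundant with the coordinates and is treated
as derived output only: on input it is recomputed, and a mismatching provided
column triggers a validation warning, never an error.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .composition import CompositionProfile
from .genome_model import (
    FeatureType,
    GeneFeature,
    InputError,
    MitogenomeRecord,
    Strand,
    normalize_feature,
)
from .presets import dedupe_names, infer_feature_type
from .structure import compute_adjacencies

logger = logging.getLogger(__name__)

_LOCATION_RE = re.compile(r"^\s*([\d,\.]+)\s*[–—-]\s*([\d,\.]+)\s*$")


class ParseError(InputError):
    """Malformed annotation input, reporting the offending row."""


def _parse_int(text: str) -> int:
    return int(text.replace(",", "").replace(".", "").strip())


def parse_location(text: str) -> tuple[int, int]:
    m = _LOCATION_RE.match(text)
    if not m:
        raise ParseError(f"malformed location {text!r}")
    return _parse_int(m.group(1)), _parse_int(m.group(2))


def read_feature_table(path: str | Path, identifier: str | None = None) -> MitogenomeRecord:
    """Read a printed-style feature table into a coordinate-only record.

    Accepts tab- or comma-separated files.  Expected columns (header matched
    case-insensitively by prefix): gene name, location (or separate
    start/end), strand; size/spacer/codon columns are optional and never
    trusted.  Duplicate tRNA names (the two Ser/Leu isoacceptors) receive
    ordinal suffixes.  A provided spacer column is validated against the
    recomputed value.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty feature table")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = [r for r in csv.reader(text.splitlines(), delimiter=delimiter) if any(c.strip() for c in r)]

    header = [c.strip().lower() for c in rows[0]]

    def col(*prefixes: str) -> int | None:
        for i, h in enumerate(header):
            if any(h.startswith(p) for p in prefixes):
                return i
        return None

    c_name = col("gene", "name", "region")
    c_loc = col("location")
    c_start, c_end = col("start"), col("end")
    c_strand = col("coding strand", "strand")
    c_spacer = col("intergenic", "spacer")
    has_header = c_name is not None and (c_loc is not None or c_start is not None)
    data = rows[1:] if has_header else rows
    if not has_header:
        c_name, c_loc, c_strand, c_spacer = 0, 1, None, None

    parsed: list[tuple[str, int, int, str | None]] = []
    spacers: list[int | None] = []
    for lineno, row in enumerate(data, start=2 if has_header else 1):
        try:
            name = row[c_name].strip().strip("*")
            if c_loc is not None:
                s, e = parse_location(row[c_loc])
            else:
                s, e = _parse_int(row[c_start]), _parse_int(row[c_end])
            strand = None
            if c_strand is not None and len(row) > c_strand and row[c_strand].strip():
                strand = row[c_strand].strip().upper()[0]
            spacer = None
            if c_spacer is not None and len(row) > c_spacer and row[c_spacer].strip():
                try:
                    spacer = int(row[c_spacer].replace("−", "-").strip())
                except ValueError:
                    spacer = None
            parsed.append((name, s, e, strand))
            spacers.append(spacer)
        except (IndexError, ParseError, ValueError) as exc:
            raise ParseError(f"{path}, row {lineno}: {exc}") from None
    if not parsed:
        raise ParseError(f"{path}: no feature rows")

    names = dedupe_names([p[0] for p in parsed])
    features: list[GeneFeature] = []
    for new_name, (raw_name, s, e, strand) in zip(names, parsed):
        hint = Strand(strand) if strand in ("H", "L") else None
        features.append(
            normalize_feature(
                new_name, s, e, ftype=infer_feature_type(raw_name), strand_hint=hint
            )
        )
    record = MitogenomeRecord(
        identifier=identifier or path.stem, features=features
    )
    _validate_spacer_column(record, dict(zip(names, spacers)))
    return record


def _validate_spacer_column(record: MitogenomeRecord, provided: dict) -> None:
    if not any(v is not None for v in provided.values()):
        return
    recomputed = {a.upstream: a.spacer for a in compute_adjacencies(record)}
    for name, given in provided.items():
        if given is None:
            continue
        got = recomputed.get(name)
        if got is not None and got != given:
            warnings.warn(
                f"spacer column mismatch after {name!r}: table says {given}, "
                f"coordinates give {got}",
                stacklevel=3,
            )


_TABLE_HEADER = [
    "Number", "Genes", "Location", "Size (bp)",
    "Intergenic Spacer (bp)", "Coding Strand", "Start Codon", "Stop Codon",
]


def write_feature_table(
    record: MitogenomeRecord,
    path: str | Path,
    start_codons: dict | None = None,
    stop_codons: dict | None = None,
) -> None:
    """Write the annotation as a TSV feature table (spacers recomputed)."""
    spacers = {a.upstream: a.spacer for a in compute_adjacencies(record)}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TABLE_HEADER)
        for i, f in enumerate(record.features, 1):
            w.writerow([
                i, f.name, f"{f.start}-{f.end}", f.size, spacers[f.name],
                f.strand.value,
                (start_codons or {}).get(f.name, ""),
                (stop_codons or {}).get(f.name, ""),
            ])


_FTYPE_TO_GB = {
    FeatureType.PCG: "CDS",
    FeatureType.TRNA: "tRNA",
    FeatureType.RRNA: "rRNA",
    FeatureType.CONTROL: "D-loop",
    FeatureType.ORIGIN: "rep_origin",
}
_GB_TO_FTYPE = {v: k for k, v in _FTYPE_TO_GB.items()}


def to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    if not record.has_sequence:
        raise InputError("cannot export a coordinate-only record to GenBank")
    sr = SeqRecord(
        Seq(record.sequence),
        id=record.identifier,
        name=record.identifier[:16].replace(" ", "_"),
        description="simulated circular mitochondrial genome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for f in record.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=1 if f.strand is Strand.H else -1)
        sr.features.append(
            SeqFeature(loc, type=_FTYPE_TO_GB[f.ftype], qualifiers={"gene": [f.name]})
        )
    return sr


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    SeqIO.write([to_seqrecord(record)], str(path), "genbank")


def write_fasta(record: MitogenomeRecord, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(record.sequence), id=record.identifier, description="")],
        str(path),
        "fasta",
    )


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read a single-record GenBank flat file.

    ``complement(..)`` locations map to strand L.  A record without sequence
    (no ORIGIN) degrades to coordinate-only with a warning.  Multi-record
    files are rejected.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise InputError(f"{path}: expected exactly one GenBank record, found {len(records)}")
    sr = records[0]
    try:
        sequence = str(sr.seq)
    except UndefinedSequenceError:
        sequence = None
    if sequence is not None and (not sequence or set(sequence) == {"N"}):
        sequence = None
    if sequence is None:
        warnings.warn(f"{path}: no ORIGIN sequence; coordinate-only record", stacklevel=2)

    names: list[str] = []
    raw: list[tuple[str, int, int, Strand, FeatureType]] = []
    for feat in sr.features:
        if feat.type not in _GB_TO_FTYPE:
            continue
        name = (
            feat.qualifiers.get("gene", feat.qualifiers.get("product", ["?"]))[0]
        )
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = Strand.L if feat.location.strand == -1 else Strand.H
        names.append(name)
        raw.append((name, start, end, strand, _GB_TO_FTYPE[feat.type]))
    features = [
        GeneFeature(name=new_name, ftype=ftype, start=start, end=end, strand=strand)
        for new_name, (_, start, end, strand, ftype) in zip(dedupe_names(names), raw)
    ]
    return MitogenomeRecord(
        identifier=sr.id or Path(path).stem,
        sequence=sequence,
        length=len(sr) if sequence is None else None,
        features=features,
    )


def _fmt(x, nd):
    return "" if x is None else f"{x:.{nd}f}"


def write_composition_csv(profiles: list[CompositionProfile], path: str | Path) -> None:
    """Composition table: percentages to 1 decimal, skews to 3 decimals."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Region", "Size (bp)", "T", "C", "A", "G", "AT (%)", "AT-Skew", "GC-Skew"])
        for p in profiles:
            pct = p.percent
            w.writerow([
                p.label, p.length,
                *(_fmt(pct[b], 1) for b in "TCAG"),
                _fmt(p.at_percent, 1), _fmt(p.at_skew, 3), _fmt(p.gc_skew, 3),
            ])


def write_rscu_csv(table, code, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Amino acid", "Codon", "Count", "RSCU"])
        for aa, family in sorted(code.families.items()):
            for c in family:
                w.writerow([aa, c, table.counts.get(c, 0), _fmt(table.rscu.get(c), 2)])


def write_kaks_csv(results, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([
            "Gene", "Pairs", "Mean Ka", "Mean Ks",
            "Ka/Ks (ratio of means)", "Ka/Ks (mean of ratios)", "Undefined pairs",
        ])
        for r in results:
            w.writerow([
                r.gene, r.n_pairs, _fmt(r.mean_ka, 4), _fmt(r.mean_ks, 4),
                _fmt(r.ratio_of_means, 3), _fmt(r.mean_ratio, 3), r.n_undefined,
            ])


def write_reports(
    record: MitogenomeRecord,
    outdir: str | Path,
    composition: list[CompositionProfile] | None = None,
    codon_table=None,
    kaks=None,
    tree=None,
    genetic_code=None,
) -> list[Path]:
    """Write the selected analysis reports; the gene table is always written.

    Sequence-dependent reports are skipped with a logged notice on
    coordinate-only records.
    """
    from .codons import get_code
    from .structure import summarize_structure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report = summarize_structure(record)
    p = outdir / "gene_table.tsv"
    write_feature_table(record, p, report.start_codons, report.stop_codons)
    written.append(p)
    if composition is not None:
        if record.has_sequence:
            p = outdir / "composition.csv"
            write_composition_csv(composition, p)
            written.append(p)
        else:
            logger.info("composition report skipped: record has no sequence")
    if codon_table is not None:
        p = outdir / "rscu.csv"
        write_rscu_csv(codon_table, genetic_code or get_code(), p)
        written.append(p)
    if kaks is not None:
        p = outdir / "kaks.csv"
        write_kaks_csv(kaks, p)
        written.append(p)
    if tree is not None:
        p = outdir / "tree.nwk"
        p.write_text(tree.to_newick() + "\n")
        written.append(p)
    return written


__all__ = [
    "ParseError",
    "parse_location",
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "write_genbank",
    "write_fasta",
    "to_seqrecord",
    "write_reports",
    "write_composition_csv",
    "write_rscu_csv",
    "write_kaks_csv",
]
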