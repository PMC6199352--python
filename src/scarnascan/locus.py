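"""Locus reading, validation and intergenic-region extraction.

A CRISPR/Cas locus is a nucleotide sequence plus ordered feature
annotations (cas genes, the CRISPR array, flanking genes).  The small-RNA
search space is the set of intergenic regions of at least 50 bp between
consecutive features, plus the two regions flanking the outermost
features; terminator scans use each region extended 15 bp downstream on
each strand (the length of the U-score tail segment).

Coordinates are 0-based half-open internally; GFF3 I/O converts to and
from 1-based inclusive.  Feature kinds map to SO-style types: ``CDS`` for
genes and ``repeat_region`` with ``rpt_family=CRISPR`` for the array,
whose repeat travels in the ``rpt_unit_seq`` attribute.  A simple TSV
dialect (``label<TAB>kind<TAB>start<TAB>end<TAB>strand``, 1-based
inclusive) is accepted as a fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .sequences import NucleotideSequence, SequenceError, interval_ok, normalize

DEFAULT_MIN_INTERGENIC = 50
DEFAULT_TERMINATOR_EXTENSION = 15
DEFAULT_EDGE_WINDOW = 500
MIN_REPEAT_LENGTH = 20

FEATURE_KINDS = ("cas_gene", "crispr_array", "other_gene")


class LocusError(ValueError):
    pass


@dataclass(frozen=True)
class Feature:
    kind: str
    span: tuple[int, int]
    strand: str  # "+", "-", or "?" for unknown
    label: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise LocusError(f"unknown feature kind {self.kind!r}")
        if self.span[0] >= self.span[1]:
            raise LocusError(
                f"feature {self.label!r}: end ({self.span[1]}) must exceed "
                f"start ({self.span[0]})"
            )
        if self.strand not in "+-?":
            raise LocusError(f"feature {self.label!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class CrisprArray:
    span: tuple[int, int]
    repeat_forward: NucleotideSequence
    spacer_count: int | None = None
    transcription_strand: str = "ambiguous"
    min_repeat_length: int = MIN_REPEAT_LENGTH

    def __post_init__(self) -> None:
        if len(self.repeat_forward) < self.min_repeat_length:
            raise LocusError(
                f"direct repeat of {len(self.repeat_forward)} bp is shorter than "
                f"the {self.min_repeat_length} bp floor"
            )
        if self.transcription_strand not in ("+", "-", "ambiguous"):
            raise LocusError("array transcription strand must be +, - or ambiguous")


@dataclass(frozen=True)
class CrisprLocus:
    sequence: NucleotideSequence
    features: tuple[Feature, ...]
    array: CrisprArray

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for f in self.features:
            if not interval_ok(f.span[0], f.span[1], L):
                raise LocusError(
                    f"feature {f.label!r} span {f.span} outside sequence [0, {L})"
                )
        object.__setattr__(
            self, "features", tuple(sorted(self.features, key=lambda f: f.span))
        )
        arrays = [f for f in self.features if f.kind == "crispr_array"]
        if len(arrays) != 1:
            raise LocusError(
                f"locus must contain exactly one crispr_array feature, found "
                f"{len(arrays)}"
            )
        if arrays[0].span != self.array.span:
            raise LocusError("array feature span does not match array.span")
        edge_gap = min(self.array.span[0], L - self.array.span[1])
        if edge_gap < DEFAULT_MIN_INTERGENIC:
            warnings.warn(
                "CRISPR array sits within the minimum intergenic length of the "
                "sequence edge; circular genomes are not wrapped",
                stacklevel=2,
            )


@dataclass(frozen=True)
class IntergenicRegion:
    id: str
    span: tuple[int, int]
    terminator_span: tuple[int, int]
    flanking_left: str
    flanking_right: str

    def __post_init__(self) -> None:
        ts, te = self.terminator_span
        if not (ts <= self.span[0] and self.span[1] <= te):
            raise LocusError("terminator_span must contain the region span")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_features_gff3(
    path: Path, record_id: str
) -> tuple[list[Feature], tuple[int, int] | None, str | None, int | None]:
    features: list[Feature] = []
    array_span = None
    repeat = None
    spacer_count = None
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise LocusError(f"malformed GFF3 line: {line!r}")
        seqid, _src, ftype, start, end, _score, strand, _phase, attr_text = cols
        if seqid != record_id:
            continue
        attrs = _parse_gff_attributes(attr_text)
        span = (int(start) - 1, int(end))  # 1-based inclusive -> half-open
        if span[0] >= span[1]:
            raise LocusError(f"feature with end <= start in line: {line!r}")
        strand = strand if strand in "+-" else "?"
        label = attrs.get("ID") or attrs.get("Name") or ftype
        if ftype == "repeat_region" and attrs.get("rpt_family") == "CRISPR":
            features.append(Feature("crispr_array", span, strand, label))
            array_span = span
            repeat = attrs.get("rpt_unit_seq")
            if "spacer_count" in attrs:
                spacer_count = int(attrs["spacer_count"])
        elif ftype in ("CDS", "gene"):
            kind = (
                "cas_gene"
                if attrs.get("gene_kind") == "cas" or label.lower().startswith("cas")
                else "other_gene"
            )
            features.append(Feature(kind, span, strand, label))
        # other feature types are ignored
    return features, array_span, repeat, spacer_count


def _read_features_tsv(
    path: Path,
) -> tuple[list[Feature], tuple[int, int] | None, str | None, int | None]:
    features: list[Feature] = []
    array_span = None
    repeat = None
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 5:
            raise LocusError(f"TSV feature line needs 5+ columns: {line!r}")
        label, kind, start, end, strand = cols[:5]
        span = (int(start) - 1, int(end))
        if span[0] >= span[1]:
            raise LocusError(f"feature {label!r}: end <= start")
        features.append(Feature(kind, span, strand if strand in "+-" else "?", label))
        if kind == "crispr_array":
            array_span = span
            if len(cols) >= 6 and cols[5]:
                repeat = cols[5]
    return features, array_span, repeat, None


def read_locus(
    fasta_source: str | Path,
    features_source: str | Path,
    repeat_override: str | None = None,
    record_id: str | None = None,
) -> CrisprLocus:
    """Load and validate a locus from FASTA + GFF3 (or TSV) annotation.

    The FASTA must contain exactly one record unless ``record_id`` names
    one.  If the array annotation carries no ``rpt_unit_seq`` repeat,
    ``repeat_override`` must supply the direct repeat (5'->3' as written
    on the forward genomic strand).
    """
    fasta_source = Path(fasta_source)
    features_source = Path(features_source)
    records = list(SeqIO.parse(str(fasta_source), "fasta"))
    if record_id is not None:
        records = [r for r in records if r.id == record_id]
        if not records:
            raise LocusError(f"record {record_id!r} not found in {fasta_source}")
    if len(records) != 1:
        raise LocusError(
            f"expected exactly one FASTA record (or a record_id), got "
            f"{len(records)}"
        )
    rec = records[0]
    sequence = NucleotideSequence(rec.id, str(rec.seq))
    if features_source.suffix.lower() in (".gff", ".gff3"):
        features, array_span, repeat, spacer_count = _read_features_gff3(
            features_source, rec.id
        )
    else:
        features, array_span, repeat, spacer_count = _read_features_tsv(
            features_source
        )
    if array_span is None:
        raise LocusError("no crispr_array feature in the annotation")
    if repeat_override is not None:
        repeat = repeat_override
    if repeat is None:
        raise LocusError(
            "array annotation carries no repeat sequence and no repeat_override "
            "was supplied"
        )
    array_strand = next(
        f.strand for f in features if f.kind == "crispr_array"
    )
    array = CrisprArray(
        span=array_span,
        repeat_forward=NucleotideSequence("direct_repeat", normalize(repeat)),
        spacer_count=spacer_count,
        transcription_strand=array_strand if array_strand in "+-" else "ambiguous",
    )
    return CrisprLocus(sequence=sequence, features=tuple(features), array=array)


def write_locus(locus: CrisprLocus, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write a locus back to FASTA + GFF3 (round-trip safe)."""
    fasta_path = Path(fasta_path)
    gff_path = Path(gff_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{locus.sequence.id}\n")
        seq = locus.sequence.residues
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    lines = ["##gff-version 3"]
    for i, f in enumerate(locus.features):
        if f.kind == "crispr_array":
            ftype = "repeat_region"
            attrs = (
                f"ID={f.label};rpt_family=CRISPR;"
                f"rpt_unit_seq={locus.array.repeat_forward.residues}"
            )
            if locus.array.spacer_count is not None:
                attrs += f";spacer_count={locus.array.spacer_count}"
        else:
            ftype = "CDS"
            attrs = f"ID={f.label}"
            if f.kind == "cas_gene":
                attrs += ";gene_kind=cas"
        strand = f.strand if f.strand in "+-" else "."
        lines.append(
            "\t".join(
                [
                    locus.sequence.id,
                    "scarnascan",
                    ftype,
                    str(f.span[0] + 1),
                    str(f.span[1]),
                    ".",
                    strand,
                    ".",
                    attrs,
                ]
            )
        )
    gff_path.write_text("\n".join(lines) + "\n")


def extract_intergenic_regions(
    locus: CrisprLocus,
    min_len: int = DEFAULT_MIN_INTERGENIC,
    extension: int = DEFAULT_TERMINATOR_EXTENSION,
    edge_window: int = DEFAULT_EDGE_WINDOW,
) -> list[IntergenicRegion]:
    """Intergenic regions of at least ``min_len`` bp, plus edge flanks.

    Regions carry no strand: downstream promoter/terminator scans handle
    both orientations.  The two locus-edge flanks extend at most
    ``edge_window`` bp beyond the outermost features (for whole-genome
    input), clipped to the sequence.
    """
    L = len(locus.sequence)
    gaps: list[tuple[int, int, str, str]] = []
    feats = locus.features
    first, last = feats[0], feats[-1]
    left_edge = max(0, first.span[0] - edge_window)
    if first.span[0] - left_edge >= min_len:
        gaps.append((left_edge, first.span[0], "locus_edge", first.label))
    cursor_end = feats[0].span[1]
    cursor_label = feats[0].label
    for f in feats[1:]:
        if f.span[0] - cursor_end >= min_len:
            gaps.append((cursor_end, f.span[0], cursor_label, f.label))
        if f.span[1] > cursor_end:
            cursor_end = f.span[1]
            cursor_label = f.label
    right_edge = min(L, last.span[1] + edge_window)
    if right_edge - cursor_end >= min_len:
        gaps.append((cursor_end, right_edge, cursor_label, "locus_edge"))
    regions = []
    for i, (s, e, left, right) in enumerate(gaps):
        regions.append(
            IntergenicRegion(
                id=f"ig_{i:03d}",
                span=(s, e),
                terminator_span=(max(0, s - extension), min(L, e + extension)),
                flanking_left=left,
                flanking_right=right,
            )
        )
    return regions


def terminator_search_span(
    region: IntergenicRegion,
    extension: int = DEFAULT_TERMINATOR_EXTENSION,
    seq_len: int | None = None,
    strand: str = "+",
) -> tuple[int, int]:
    """Region span extended ``extension`` bp past its downstream edge.

    Downstream is the right edge on the plus strand and the left edge on
    the minus strand; the result is clipped to ``[0, seq_len)``.
    """
    s, e = region.span
    if strand == "+":
        e += extension
    elif strand == "-":
        s -= extension
    else:
        raise LocusError(f"bad strand {strand!r}")
    if seq_len is not None:
        e = min(e, seq_len)
    return (max(0, s), e)
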