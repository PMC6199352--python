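"""Transcription-unit assembly and small-RNA classification.

A predicted small RNA is a transcription unit: a repeat-homology segment
bracketed by an upstream promoter (TSS) and, usually, a downstream
intrinsic terminator on the same strand.  Classification against the
CRISPR array follows the array's own transcription orientation, inferred
from the promoter/terminator layout of its flanking regions:

* a unit whose transcript carries the repeat in the sense of the array
  transcript is a putative scaRNA;
* a unit whose transcript carries the anti-repeat (reverse complement of
  the array transcript's repeat) is a putative tracrRNA;
* a unit containing two overlapping repeat-homology segments is an
  sgRNA-like unit (a single molecule mimicking the scaRNA:tracrRNA
  duplex), and its 3' region is annotated with successive stem-loops;
* with an ambiguous array orientation the unit stays unclassified, with
  both hypotheses recorded.

A unit lacking a downstream terminator is flagged as read-through
(possibly co-transcribed with the CRISPR array, or a missed terminator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .align import AlignmentParams, local_align
from .locus import CrisprLocus, IntergenicRegion
from .promoter import TssPrediction
from .repeats import RepeatHit
from .sequences import revcomp
from .terminator import TerminatorPrediction, hairpin_chain

DEFAULT_MAX_TSS_GAP = 300
DEFAULT_MAX_TERM_GAP = 300

RNA_CLASSES = ("scaRNA", "tracrRNA", "sgRNA_like", "unclassified")


@dataclass(frozen=True)
class OrientationCall:
    strand: str  # "+", "-", or "ambiguous"
    evidence: tuple[tuple[str, int, float, str], ...]  # (kind, pos, score, orient)
    tie_break_used: bool = False

    def __post_init__(self) -> None:
        if self.strand != "ambiguous" and not self.evidence:
            raise ValueError("non-ambiguous orientation requires evidence")


@dataclass(frozen=True)
class TranscriptionUnit:
    region_id: str
    strand: str
    tss: TssPrediction
    terminator: TerminatorPrediction | None
    body_span: tuple[int, int]
    read_through: bool
    contained_hits: tuple[RepeatHit, ...]


@dataclass(frozen=True)
class SmallRnaPrediction:
    unit: TranscriptionUnit
    rna_class: str
    sense_to_array_transcript: bool | None
    structure_annotation: tuple | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class LocusReport:
    locus_id: str
    array_orientation: OrientationCall
    predictions: tuple[SmallRnaPrediction, ...]
    repeat_hits: tuple[RepeatHit, ...]
    tss_predictions: tuple[TssPrediction, ...]
    terminator_predictions: tuple[TerminatorPrediction, ...]
    rejected_hits: tuple[tuple[RepeatHit, str], ...]
    unattached_hits: tuple[RepeatHit, ...]
    config_snapshot: dict
    seed: int | None = None

    def __post_init__(self) -> None:
        tss_ids = {id(t) for t in self.tss_predictions}
        term_ids = {id(t) for t in self.terminator_predictions}
        hit_ids = {id(h) for h in self.repeat_hits}
        for p in self.predictions:
            if id(p.unit.tss) not in tss_ids:
                raise ValueError("prediction references an unknown TSS")
            if p.unit.terminator is not None and id(p.unit.terminator) not in term_ids:
                raise ValueError("prediction references an unknown terminator")
            for h in p.unit.contained_hits:
                if id(h) not in hit_ids:
                    raise ValueError("prediction references an unknown repeat hit")


def infer_array_orientation(
    locus: CrisprLocus,
    tss_predictions: list[TssPrediction],
    terminator_predictions: list[TerminatorPrediction],
    flank_window: int = 1000,
) -> OrientationCall:
    """Infer the array transcription strand from flanking signals.

    An orientation is supported when a promoter points into the array
    from its 5' flank (left flank for "+", right flank for "-"); a
    terminator in the 3' flank adds supporting evidence.  When both
    orientations have promoter support the higher promoter score wins and
    the tie-break flag is set; with no promoter support the call is
    ambiguous.
    """
    a0, a1 = locus.array.span
    evidence: dict[str, list[tuple[str, int, float, str]]] = {"+": [], "-": []}
    for t in tss_predictions:
        if t.strand == "+" and a0 - flank_window <= t.tss_position < a0:
            evidence["+"].append(("promoter", t.tss_position, t.score, "+"))
        elif t.strand == "-" and a1 <= t.tss_position < a1 + flank_window:
            evidence["-"].append(("promoter", t.tss_position, t.score, "-"))
    for term in terminator_predictions:
        s0, s1 = term.span
        if term.strand == "+" and a1 <= s0 < a1 + flank_window:
            evidence["+"].append(("terminator", s0, term.hairpin.delta_g, "+"))
        elif term.strand == "-" and a0 - flank_window <= s1 <= a0:
            evidence["-"].append(("terminator", s0, term.hairpin.delta_g, "-"))
    has_prom = {
        s: [e for e in evidence[s] if e[0] == "promoter"] for s in "+-"
    }
    if has_prom["+"] and has_prom["-"]:
        best_plus = max(e[2] for e in has_prom["+"])
        best_minus = max(e[2] for e in has_prom["-"])
        strand = "+" if best_plus >= best_minus else "-"
        return OrientationCall(strand, tuple(evidence[strand]), tie_break_used=True)
    for s in "+-":
        if has_prom[s]:
            return OrientationCall(s, tuple(evidence[s]))
    return OrientationCall("ambiguous", ())


def assemble_units(
    region: IntergenicRegion,
    repeat_hits: list[RepeatHit],
    tss_predictions: list[TssPrediction],
    terminator_predictions: list[TerminatorPrediction],
    max_tss_gap: int = DEFAULT_MAX_TSS_GAP,
    max_term_gap: int = DEFAULT_MAX_TERM_GAP,
) -> tuple[list[TranscriptionUnit], list[RepeatHit]]:
    """Attach each repeat hit to its nearest flanking transcription signals.

    For each strand, every hit (regardless of its alignment strand: a
    segment homologous to the repeat on one strand carries the complement
    homology on the other, so transcription orientation comes from the
    signals, not the alignment) gets the nearest upstream TSS within
    ``max_tss_gap`` and the nearest downstream terminator within
    ``max_term_gap`` on that strand; hits sharing both signals merge into
    one unit.  A hit with a TSS but no terminator forms a read-through
    unit bounded by the region's downstream edge; a hit attachable on
    neither strand is returned unattached.
    """
    units: dict[tuple[int, int | None, str], list[RepeatHit]] = {}
    keyed_signals: dict[tuple[int, int | None, str], tuple] = {}
    attached: set[int] = set()
    for strand in "+-":
        for hit in repeat_hits:
            h0, h1 = hit.span
            if strand == "+":
                cand_tss = [
                    t
                    for t in tss_predictions
                    if t.strand == "+" and 0 <= h0 - t.tss_position <= max_tss_gap
                ]
                tss = max(cand_tss, key=lambda t: t.tss_position, default=None)
                cand_term = [
                    t
                    for t in terminator_predictions
                    if t.strand == "+"
                    and t.span[0] >= h1
                    and t.span[0] - h1 <= max_term_gap
                ]
                term = min(cand_term, key=lambda t: t.span[0], default=None)
            else:
                cand_tss = [
                    t
                    for t in tss_predictions
                    if t.strand == "-"
                    and 0 <= t.tss_position - (h1 - 1) <= max_tss_gap
                ]
                tss = min(cand_tss, key=lambda t: t.tss_position, default=None)
                cand_term = [
                    t
                    for t in terminator_predictions
                    if t.strand == "-"
                    and t.span[1] <= h0
                    and h0 - t.span[1] <= max_term_gap
                ]
                term = max(cand_term, key=lambda t: t.span[1], default=None)
            if tss is None:
                continue
            attached.add(id(hit))
            key = (id(tss), id(term) if term is not None else None, strand)
            units.setdefault(key, []).append(hit)
            keyed_signals[key] = (tss, term, strand)
    unattached = [h for h in repeat_hits if id(h) not in attached]
    out: list[TranscriptionUnit] = []
    for key, hits in units.items():
        tss, term, strand = keyed_signals[key]
        if strand == "+":
            start = tss.tss_position
            end = term.span[1] if term is not None else region.span[1]
        else:
            end = tss.tss_position + 1
            start = term.span[0] if term is not None else region.span[0]
        out.append(
            TranscriptionUnit(
                region_id=region.id,
                strand=strand,
                tss=tss,
                terminator=term,
                body_span=(start, end),
                read_through=term is None,
                contained_hits=tuple(sorted(hits, key=lambda h: h.span)),
            )
        )
    out.sort(key=lambda u: (u.body_span, u.strand))
    return out, unattached


def classify_small_rna(
    unit: TranscriptionUnit,
    array_orientation: OrientationCall,
    repeat_forward: str,
    locus_seq: str,
    align_params: AlignmentParams | None = None,
    min_normalized: float = 0.5,
    min_columns: int = 10,
) -> SmallRnaPrediction:
    """Classify a unit as scaRNA or tracrRNA against the array transcript.

    The unit transcript (5'->3' on the unit strand) is re-aligned against
    the array transcript's repeat reading and its reverse complement; the
    better alignment at or above ``min_normalized`` per column decides
    the class.  Alignments shorter than ``min_columns`` are ignored (the
    same micro-match floor as hit detection: a chance few-column perfect
    match must not outvote a full-length anti-repeat).  Classification by
    re-alignment covers all four strand combinations with one rule.
    """
    if not unit.contained_hits:
        raise ValueError("cannot classify a unit without repeat hits")
    b0, b1 = unit.body_span
    body = locus_seq[b0:b1]
    transcript = body if unit.strand == "+" else revcomp(body)

    def best_norm(query: str) -> float:
        alns = [
            a
            for a in local_align(query, transcript, params=align_params, max_hits=2)
            if a.subject_strand == "+" and a.aligned_columns >= min_columns
        ]
        return max((a.normalized_score for a in alns), default=-1.0)

    if array_orientation.strand == "ambiguous":
        return SmallRnaPrediction(
            unit=unit,
            rna_class="unclassified",
            sense_to_array_transcript=None,
            notes=(
                "array orientation ambiguous: scaRNA if array strand matches "
                "the sense hypothesis, tracrRNA otherwise",
            ),
        )
    array_repeat_tx = (
        repeat_forward if array_orientation.strand == "+" else revcomp(repeat_forward)
    )
    sense = best_norm(array_repeat_tx)
    anti = best_norm(revcomp(array_repeat_tx))
    if max(sense, anti) < min_normalized:
        return SmallRnaPrediction(
            unit=unit,
            rna_class="unclassified",
            sense_to_array_transcript=None,
            notes=("transcript homology below the classification floor",),
        )
    if sense >= anti:
        return SmallRnaPrediction(
            unit=unit, rna_class="scaRNA", sense_to_array_transcript=True
        )
    return SmallRnaPrediction(
        unit=unit, rna_class="tracrRNA", sense_to_array_transcript=False
    )


def detect_sgrna_like(
    predictions: list[SmallRnaPrediction],
    locus_seq: str,
    min_stem: int = 4,
    min_loop: int = 3,
    max_loop: int = 13,
) -> list[SmallRnaPrediction]:
    """Re-class units with two overlapping repeat hits as sgRNA-like.

    The 3' region of such a unit (from the last repeat segment to the
    terminator, in transcript orientation) is scanned for successive
    non-overlapping stem-loops; three or more mark a tracrRNA-like 3'
    tail.
    """
    out: list[SmallRnaPrediction] = []
    for pred in predictions:
        hits = pred.unit.contained_hits
        overlapping = any(
            min(a.span[1], b.span[1]) > max(a.span[0], b.span[0])
            for i, a in enumerate(hits)
            for b in hits[i + 1 :]
        )
        if not overlapping:
            out.append(pred)
            continue
        unit = pred.unit
        if unit.strand == "+":
            t0 = max(h.span[1] for h in hits)
            t1 = unit.terminator.span[0] if unit.terminator else unit.body_span[1]
            tail = locus_seq[t0:t1]
        else:
            t1 = min(h.span[0] for h in hits)
            t0 = unit.terminator.span[1] if unit.terminator else unit.body_span[0]
            tail = revcomp(locus_seq[t0:t1])
        chain = hairpin_chain(tail, min_stem, min_loop, max_loop)
        notes = list(pred.notes)
        if len(chain) >= 3:
            notes.append("tracrRNA-like 3' tail")
        out.append(
            replace(
                pred,
                rna_class="sgRNA_like",
                structure_annotation=tuple(chain),
                notes=tuple(notes),
            )
        )
    return out


def build_report(
    locus: CrisprLocus,
    orientation: OrientationCall,
    predictions: list[SmallRnaPrediction],
    repeat_hits: list[RepeatHit],
    tss_predictions: list[TssPrediction],
    terminator_predictions: list[TerminatorPrediction],
    rejected_hits: list[tuple[RepeatHit, str]],
    unattached_hits: list[RepeatHit],
    config_snapshot: dict,
    seed: int | None = None,
) -> LocusReport:
    """Assemble the self-contained, deterministic locus report."""
    return LocusReport(
        locus_id=locus.sequence.id,
        array_orientation=orientation,
        predictions=tuple(predictions),
        repeat_hits=tuple(repeat_hits),
        tss_predictions=tuple(tss_predictions),
        terminator_predictions=tuple(terminator_predictions),
        rejected_hits=tuple(rejected_hits),
        unattached_hits=tuple(unattached_hits),
        config_snapshot=dict(config_snapshot),
        seed=seed,
    )


def report_to_tsv(report: LocusReport) -> str:
    header = (
        "locus\trna_class\tstrand\tstart\tend\ttss\tterminator_start\t"
        "read_through\tsense_to_array\tnotes\n"
    )
    rows = []
    for p in report.predictions:
        u = p.unit
        rows.append(
            "\t".join(
                [
                    report.locus_id,
                    p.rna_class,
                    u.strand,
                    str(u.body_span[0]),
                    str(u.body_span[1]),
                    str(u.tss.tss_position),
                    str(u.terminator.span[0]) if u.terminator else ".",
                    str(int(u.read_through)),
                    {True: "1", False: "0", None: "."}[p.sense_to_array_transcript],
                    ";".join(p.notes) or ".",
                ]
            )
        )
    return header + "\n".join(rows) + ("\n" if rows else "")


def report_to_gff3(report: LocusReport) -> str:
    lines = ["##gff-version 3"]
    for i, p in enumerate(report.predictions):
        u = p.unit
        attrs = (
            f"ID=small_rna_{i};rna_class={p.rna_class};"
            f"read_through={str(u.read_through).lower()};"
            f"sense_to_array_transcript="
            f"{str(p.sense_to_array_transcript).lower()}"
        )
        lines.append(
            "\t".join(
                [
                    report.locus_id,
                    "scarnascan",
                    "ncRNA",
                    str(u.body_span[0] + 1),
                    str(u.body_span[1]),
                    ".",
                    u.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def report_to_json(report: LocusReport) -> str:
    def unit_dict(p: SmallRnaPrediction) -> dict:
        u = p.unit
        return {
            "rna_class": p.rna_class,
            "region_id": u.region_id,
            "strand": u.strand,
            "body_span": list(u.body_span),
            "tss": u.tss.tss_position,
            "tss_score": round(u.tss.score, 4),
            "terminator_span": list(u.terminator.span) if u.terminator else None,
            "terminator_dg": (
                round(u.terminator.hairpin.delta_g, 3) if u.terminator else None
            ),
            "read_through": u.read_through,
            "sense_to_array_transcript": p.sense_to_array_transcript,
            "hit_spans": [list(h.span) for h in u.contained_hits],
            "hit_strands": [h.strand for h in u.contained_hits],
            "n_3prime_hairpins": (
                len(p.structure_annotation) if p.structure_annotation else None
            ),
            "notes": list(p.notes),
        }

    payload = {
        "locus": report.locus_id,
        "array_orientation": report.array_orientation.strand,
        "orientation_tie_break": report.array_orientation.tie_break_used,
        "predictions": [unit_dict(p) for p in report.predictions],
        "n_repeat_hits": len(report.repeat_hits),
        "n_tss": len(report.tss_predictions),
        "n_terminators": len(report.terminator_predictions),
        "rejected_hits": [
            {"span": list(h.span), "reason": r} for h, r in report.rejected_hits
        ],
        "config": report.config_snapshot,
        "seed": report.seed,
    }
    return json.dumps(payload, indent=1, sort_keys=True)
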