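"""Repeat-homology search inside intergenic regions.

Segments homologous to the CRISPR array direct repeat are the anchors of
every small-RNA prediction: a scaRNA carries the repeat in the sense of
the array transcript, a tracrRNA carries the anti-repeat.  Hits are local
alignments of the direct repeat against an intergenic region (both
strands), scored per alignment column so a single threshold applies to
hits of any length.

Two post-filters guard against mistaking decayed CRISPR arrays for small
RNAs: closely spaced hit pairs (gap in the size range of a spacer) are
rejected as a putative degenerate array, and a hit with another
above-threshold hit lying between it and the array is rejected as likely
array remnant context.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignmentParams, LocalAlignment, local_align

DEFAULT_MIN_COLUMNS = 10
#: Shipped fallback per-column threshold. This is a configuration choice,
#: not a published value; the calibration path replaces it when curated
#: training loci are available.
DEFAULT_REPEAT_THRESHOLD = 0.6
#: Minimum fraction of the repeat an alignment must span.  A per-column
#: score admits short high-identity windows that arise by chance in any
#: sequence; an anti-repeat by definition covers a substantial part of
#: the repeat, so hits shorter than this fraction are discarded along
#: with sub-``DEFAULT_MIN_COLUMNS`` micro-matches.
DEFAULT_MIN_QUERY_COVERAGE = 0.6


@dataclass(frozen=True)
class RepeatHit:
    region_id: str
    alignment: LocalAlignment
    normalized_score: float
    passes_primary_threshold: bool
    rescued_by_relaxation: bool

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (forward-strand) subject span of the hit."""
        return self.alignment.subject_span

    @property
    def strand(self) -> str:
        return self.alignment.subject_strand


def calibrate_repeat_threshold(curated_hits: list[RepeatHit]) -> float:
    """Lowest normalized score among curated true hits.

    This mirrors how the search threshold is set from training systems in
    which the small RNAs are experimentally known: every curated hit must
    remain above threshold, so the threshold is the minimum of their
    scores.
    """
    if not curated_hits:
        raise ValueError("calibration requires at least one curated hit")
    return min(h.normalized_score for h in curated_hits)


def select_hits(
    alignments: list[LocalAlignment],
    region_id: str,
    threshold: float,
    relax: float = 0.2,
) -> list[RepeatHit]:
    """Apply the primary threshold and the relaxation rescue rule.

    All alignments with normalized score >= ``threshold`` are hits.  When
    fewer than two alignments reach the threshold, the next
    highest-scoring alignment is additionally accepted if its score is not
    lower than the threshold by more than ``relax`` (a fraction), and is
    flagged as rescued.

    A rescue candidate whose subject span overlaps an already-accepted
    hit is skipped: one genomic segment yields one hit, and a repeat copy
    always casts a weak opposite-strand echo of itself that must not be
    re-reported as a second segment.
    """
    if threshold <= 0:
        raise ValueError("repeat threshold must be positive")
    ranked = sorted(alignments, key=lambda a: -a.normalized_score)
    hits = [
        RepeatHit(region_id, a, a.normalized_score, True, False)
        for a in ranked
        if a.normalized_score >= threshold
    ]
    if len(hits) < 2 and len(ranked) > len(hits):
        taken = [h.span for h in hits]
        for candidate in ranked[len(hits) :]:
            span = candidate.subject_span
            if any(min(span[1], t[1]) > max(span[0], t[0]) for t in taken):
                continue
            if candidate.normalized_score >= (1.0 - relax) * threshold:
                hits.append(
                    RepeatHit(
                        region_id, candidate, candidate.normalized_score, False, True
                    )
                )
            break
    return hits


def find_repeat_hits(
    region_id: str,
    region_seq: str,
    repeat: str,
    threshold: float,
    relax: float = 0.2,
    max_hits: int = 5,
    params: AlignmentParams | None = None,
    min_columns: int = DEFAULT_MIN_COLUMNS,
    min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE,
    offset: int = 0,
) -> list[RepeatHit]:
    """Repeat-homology hits in one intergenic region (both strands).

    ``offset`` shifts subject spans into genomic coordinates.  Alignments
    shorter than ``min_columns`` columns, or spanning less than
    ``min_query_coverage`` of the repeat, are ignored as spurious
    micro-matches before thresholding.
    """
    floor = max(min_columns, int(min_query_coverage * len(repeat)))
    alignments = [
        a
        for a in local_align(repeat, region_seq, params=params, max_hits=max_hits)
        if a.aligned_columns >= floor
    ]
    if offset:
        alignments = [
            LocalAlignment(
                query_span=a.query_span,
                subject_span=(a.subject_span[0] + offset, a.subject_span[1] + offset),
                subject_strand=a.subject_strand,
                raw_score=a.raw_score,
                aligned_columns=a.aligned_columns,
                cigar=a.cigar,
            )
            for a in alignments
        ]
    return select_hits(alignments, region_id, threshold, relax=relax)


def filter_array_remnants(
    hits: list[RepeatHit],
    array_span: tuple[int, int],
    spacing_window: tuple[int, int] = (20, 60),
    check_intervening: bool = True,
) -> tuple[list[RepeatHit], list[tuple[RepeatHit, str]]]:
    """Reject hits that look like remnants of a (degenerate) CRISPR array.

    Hit pairs whose mutual gap falls within ``spacing_window`` (the size
    range of a spacer) are both rejected as ``putative_degenerate_array``
    when both pass the primary threshold; when only one does, only the
    rescued partner is rejected (a below-threshold echo spaced like a
    spacer is more plausibly a decayed repeat copy than an independent
    small RNA, but it is too weak to establish a degenerate array against
    a genuine hit).  A hit is rejected as ``intervening_homology`` when
    another above-threshold hit lies strictly between it and the array
    span; that check is meaningful only for hits in a region directly
    adjacent to the array (array decay cannot reach across an
    intervening gene), so callers disable it elsewhere via
    ``check_intervening``.

    Returns ``(kept, rejected)`` where each rejected entry carries its
    reason.
    """
    lo, hi = spacing_window
    rejected: dict[int, str] = {}
    ordered = sorted(hits, key=lambda h: h.span[0])
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            gap = b.span[0] - a.span[1]
            if lo <= gap <= hi:
                for h in (a, b):
                    if (
                        a.passes_primary_threshold
                        and b.passes_primary_threshold
                    ) or not h.passes_primary_threshold:
                        rejected[id(h)] = "putative_degenerate_array"
    for a in ordered if check_intervening else []:
        if id(a) in rejected:
            continue
        if a.span[1] <= array_span[0]:
            between = (a.span[1], array_span[0])
        elif a.span[0] >= array_span[1]:
            between = (array_span[1], a.span[0])
        else:
            continue
        for b in ordered:
            if b is a or not b.passes_primary_threshold:
                continue
            if between[0] <= b.span[0] and b.span[1] <= between[1]:
                rejected[id(a)] = "intervening_homology"
                break
    kept = [h for h in ordered if id(h) not in rejected]
    dropped = [(h, rejected[id(h)]) for h in ordered if id(h) in rejected]
    return kept, dropped


def hits_to_bed(hits: list[RepeatHit], chrom: str) -> str:
    """BED6 export; score column is 1000 x normalized score, clipped."""
    lines = []
    for i, h in enumerate(hits):
        score = int(round(max(0.0, min(1.0, h.normalized_score)) * 1000))
        lines.append(
            "\t".join(
                [
                    chrom,
                    str(h.span[0]),
                    str(h.span[1]),
                    f"repeat_hit_{i}",
                    str(score),
                    h.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: list[RepeatHit]) -> str:
    header = (
        "region_id\tstart\tend\tstrand\traw_score\taligned_columns\t"
        "normalized_score\tprimary\trescued\tcigar\n"
    )
    rows = [
        "\t".join(
            [
                h.region_id,
                str(h.span[0]),
                str(h.span[1]),
                h.strand,
                f"{h.alignment.raw_score:g}",
                str(h.alignment.aligned_columns),
                f"{h.normalized_score:.4f}",
                str(int(h.passes_primary_threshold)),
                str(int(h.rescued_by_relaxation)),
                h.alignment.cigar,
            ]
        )
        for h in hits
    ]
    return header + "\n".join(rows) + ("\n" if rows else "")
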