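"""End-to-end small-RNA prediction over one CRISPR/Cas locus.

The search runs in the order the method defines: extract intergenic
regions; query each for homology to the array direct repeat; filter
putative array remnants; scan the homology-bearing regions and the two
array-flanking regions for promoters and terminators on both strands;
infer the array transcription orientation; assemble
promoter -> repeat-segment -> terminator units per region; classify each
unit as scaRNA / tracrRNA / sgRNA-like; and emit the locus report.

When the array orientation is ambiguous from flanking signals alone, the
tie is broken in favour of the orientation under which at least one unit
classifies as a tracrRNA (the molecule indispensable for system
function); if neither or both orientations do, the call stays ambiguous.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

from .assembly import (
    LocusReport,
    OrientationCall,
    assemble_units,
    build_report,
    classify_small_rna,
    detect_sgrna_like,
    infer_array_orientation,
)
from .config import PipelineConfig
from .locus import CrisprLocus, extract_intergenic_regions
from .promoter import PromoterModel, load_default_model, scan_region_for_tss
from .repeats import filter_array_remnants, find_repeat_hits
from .terminator import TerminatorConfig, find_terminators


def _terminator_cfg(cfg: PipelineConfig) -> TerminatorConfig:
    return TerminatorConfig(
        dg_cutoff=cfg.dg_cutoff,
        min_gc=cfg.min_gc_pairs,
        min_stem=cfg.min_stem,
        u_cutoff=cfg.u_cutoff,
        min_loop=cfg.min_loop,
        max_loop=cfg.max_loop,
        allow_gu=cfg.allow_gu,
    )


def predict_locus(
    locus: CrisprLocus,
    model: PromoterModel | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> LocusReport:
    """Run the full prediction pipeline on one locus."""
    cfg = config or PipelineConfig()
    model = model or load_default_model()
    if cfg.tss_threshold is not None:
        model = model.with_threshold(cfg.tss_threshold)
    seq = locus.sequence.residues
    repeat = locus.array.repeat_forward.residues
    params = cfg.alignment_params()

    regions = extract_intergenic_regions(
        locus,
        min_len=cfg.min_intergenic_len,
        extension=cfg.terminator_extension,
        edge_window=cfg.edge_window,
    )
    hits_by_region = {}
    for region in regions:
        hits = find_repeat_hits(
            region.id,
            seq[region.span[0] : region.span[1]],
            repeat,
            threshold=cfg.repeat_threshold,
            relax=cfg.relax,
            max_hits=cfg.max_hits_per_region,
            params=params,
            min_columns=cfg.min_aligned_columns,
            min_query_coverage=cfg.min_query_coverage,
            offset=region.span[0],
        )
        if hits:
            hits_by_region[region.id] = hits
    # remnant filters are scoped per region: a decayed array leaves its
    # extra repeat copies in the same intergenic region as the candidate,
    # while predictions in other regions are independent units.  The
    # intervening-homology check additionally applies only in the two
    # regions touching the array, since decay cannot span a gene.
    a0, a1 = locus.array.span
    region_by_id = {r.id: r for r in regions}
    kept_hits = []
    rejected = []
    for region_id, hits in hits_by_region.items():
        span = region_by_id[region_id].span
        adjacent = span[1] == a0 or span[0] == a1
        kept_r, rej_r = filter_array_remnants(
            hits, locus.array.span, spacing_window=cfg.spacing_window,
            check_intervening=adjacent,
        )
        kept_hits.extend(kept_r)
        rejected.extend(rej_r)
    kept_ids = {id(h) for h in kept_hits}

    # scan regions with surviving homology plus the two array flanks
    scan_regions = []
    for region in regions:
        region_hits = [
            h for h in hits_by_region.get(region.id, []) if id(h) in kept_ids
        ]
        flanks_array = region.span[1] == a0 or region.span[0] == a1
        if region_hits or flanks_array:
            scan_regions.append((region, region_hits))

    tss_all = []
    term_all = []
    tcfg = _terminator_cfg(cfg)
    for region, _ in scan_regions:
        tss_all.extend(
            scan_region_for_tss(
                seq[region.span[0] : region.span[1]],
                model,
                region_id=region.id,
                offset=region.span[0],
            )
        )
        term_all.extend(
            find_terminators(seq, region.terminator_span, region_id=region.id,
                             cfg=tcfg)
        )

    orientation = infer_array_orientation(locus, tss_all, term_all)

    units = []
    unattached = []
    for region, region_hits in scan_regions:
        if not region_hits:
            continue
        r_tss = [t for t in tss_all if t.region_id == region.id]
        r_term = [t for t in term_all if t.region_id == region.id]
        u, loose = assemble_units(
            region, region_hits, r_tss, r_term,
            max_tss_gap=cfg.max_tss_gap, max_term_gap=cfg.max_term_gap,
        )
        units.extend(u)
        unattached.extend(loose)

    classify_floor = (1.0 - cfg.relax) * cfg.repeat_threshold

    def classify_all(orient: OrientationCall):
        preds = [
            classify_small_rna(
                u, orient, repeat, seq, align_params=params,
                min_normalized=classify_floor,
                min_columns=max(cfg.min_aligned_columns,
                                int(cfg.min_query_coverage * len(repeat))),
            )
            for u in units
        ]
        return detect_sgrna_like(
            preds, seq, min_stem=cfg.min_stem, min_loop=cfg.min_loop,
            max_loop=cfg.max_loop,
        )

    if orientation.strand == "ambiguous" and units:
        # tie-break: prefer the orientation that yields a tracrRNA
        trials = {}
        for strand in "+-":
            cand = OrientationCall(
                strand,
                (("tie_break", locus.array.span[0], 0.0, strand),),
                tie_break_used=True,
            )
            trials[strand] = classify_all(cand)
        has_tracr = {
            s: any(p.rna_class == "tracrRNA" for p in trials[s]) for s in "+-"
        }
        if has_tracr["+"] != has_tracr["-"]:
            chosen = "+" if has_tracr["+"] else "-"
            orientation = OrientationCall(
                chosen,
                (("tie_break", locus.array.span[0], 0.0, chosen),),
                tie_break_used=True,
            )
            predictions = trials[chosen]
        else:
            predictions = classify_all(orientation)
    else:
        predictions = classify_all(orientation)

    # a unit abutting the array without its own terminator may be
    # co-transcribed with the array
    final = []
    for p in predictions:
        if p.unit.read_through:
            u0, u1 = p.unit.body_span
            near = (
                (p.unit.strand == "+" and 0 <= a0 - u1 <= cfg.max_term_gap)
                or (p.unit.strand == "-" and 0 <= u0 - a1 <= cfg.max_term_gap)
            )
            if near and orientation.strand == p.unit.strand:
                p = dc_replace(p, notes=p.notes + ("possible_cotranscription",))
        final.append(p)

    locus = dc_replace(
        locus,
        array=dc_replace(locus.array, transcription_strand=orientation.strand),
    )
    return build_report(
        locus,
        orientation,
        final,
        kept_hits,
        tss_all,
        term_all,
        rejected,
        unattached,
        config_snapshot=cfg.to_dict(),
        seed=seed if seed is not None else cfg.seed,
    )
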