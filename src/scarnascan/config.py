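"""Pipeline configuration and threshold calibration.

All tunable parameters live in one dataclass with their documented
defaults.  The two search thresholds (repeat homology per-column score
and promoter score) are calibratable: given training loci with curated
small-RNA units, each threshold is set to the minimum score observed over
the curated true signals, so that every curated unit is reproduced — the
same protocol used to parameterize the search on Type IIB systems with
experimental small-RNA evidence.  The shipped fallbacks
(``repeat_threshold`` 0.6/column; ``tss_threshold`` from the bundled
model file) are configuration choices, not published values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .align import AlignmentParams, local_align
from .locus import CrisprLocus, extract_intergenic_regions
from .promoter import PromoterModel, scan_region_for_tss
from .repeats import (
    DEFAULT_MIN_COLUMNS,
    DEFAULT_MIN_QUERY_COVERAGE,
    DEFAULT_REPEAT_THRESHOLD,
)

# Defaults below that quote a number in their comment are the search
# procedure's stated operating points; the rest are this package's own
# documented choices (see docs/methods.md).
MIN_INTERGENIC_LEN = 50        # minimum searched intergenic length, bp
TERMINATOR_EXTENSION = 15      # downstream extension for terminator search, bp
HAIRPIN_FRAME = (11, 50)       # stem-loop frame bounds, bp
DG_CUTOFF = -6.0               # terminator free-energy cutoff, kcal/mol
MIN_GC_PAIRS = 3               # minimum G:C pairs in the stem
MIN_STEM = 4                   # minimum stem length, pairs
U_CUTOFF = -2.3                # U-score threshold
RELAX = 0.20                   # repeat-hit rescue relaxation fraction


@dataclass
class PipelineConfig:
    min_intergenic_len: int = MIN_INTERGENIC_LEN
    terminator_extension: int = TERMINATOR_EXTENSION
    hairpin_frame: tuple[int, int] = HAIRPIN_FRAME
    dg_cutoff: float = DG_CUTOFF
    min_gc_pairs: int = MIN_GC_PAIRS
    min_stem: int = MIN_STEM
    u_cutoff: float = U_CUTOFF
    relax: float = RELAX
    repeat_threshold: float = DEFAULT_REPEAT_THRESHOLD
    tss_threshold: float | None = None  # None -> bundled model default
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_aligned_columns: int = DEFAULT_MIN_COLUMNS
    min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE
    max_hits_per_region: int = 5
    max_tss_gap: int = 300
    max_term_gap: int = 300
    edge_window: int = 500
    spacing_window: tuple[int, int] = (20, 60)
    min_loop: int = 3
    max_loop: int = 13
    allow_gu: bool = True
    seed: int = 0

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(self.match, self.mismatch, self.gap_open,
                               self.gap_extend)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hairpin_frame"] = list(self.hairpin_frame)
        d["spacing_window"] = list(self.spacing_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "hairpin_frame" in d:
            d["hairpin_frame"] = tuple(d["hairpin_frame"])
        if "spacing_window" in d:
            d["spacing_window"] = tuple(d["spacing_window"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Range checks; returns a list of violations (empty means ok).

    Departures from the documented defaults that are still legal values
    are not flagged here; they are recorded in every report's config
    snapshot instead.
    """
    v: list[str] = []
    if cfg.min_intergenic_len < 1:
        v.append("min_intergenic_len must be >= 1")
    if cfg.terminator_extension < 0:
        v.append("terminator_extension must be >= 0")
    lo, hi = cfg.hairpin_frame
    if not (0 < lo < hi):
        v.append("hairpin_frame must be an increasing positive pair")
    if cfg.dg_cutoff >= 0:
        v.append("dg_cutoff must be negative")
    if cfg.min_gc_pairs < 0:
        v.append("min_gc_pairs must be >= 0")
    if cfg.min_stem < 1:
        v.append("min_stem must be >= 1")
    if not 0.0 <= cfg.relax < 1.0:
        v.append("relax must be in [0, 1)")
    if cfg.repeat_threshold <= 0:
        v.append("repeat_threshold must be positive")
    if cfg.match <= 0 or cfg.mismatch >= 0:
        v.append("match must be positive and mismatch negative")
    if cfg.gap_open > 0 or cfg.gap_extend > 0:
        v.append("gap penalties must be <= 0")
    if not 0.0 <= cfg.min_query_coverage <= 1.0:
        v.append("min_query_coverage must be in [0, 1]")
    if cfg.max_tss_gap < 0 or cfg.max_term_gap < 0:
        v.append("assembly gaps must be >= 0")
    s0, s1 = cfg.spacing_window
    if not (0 <= s0 <= s1):
        v.append("spacing_window must be a non-decreasing non-negative pair")
    if cfg.min_loop < 1 or cfg.max_loop < cfg.min_loop:
        v.append("loop bounds must satisfy 1 <= min_loop <= max_loop")
    return v


@dataclass(frozen=True)
class CuratedUnit:
    """A curated true small-RNA unit on a training locus."""

    span: tuple[int, int]
    strand: str
    rna_class: str
    tss_position: int | None = None  # optional known start site


@dataclass(frozen=True)
class TrainingLocus:
    locus: CrisprLocus
    curated_units: tuple[CuratedUnit, ...]

    def __post_init__(self) -> None:
        L = len(self.locus.sequence)
        for u in self.curated_units:
            if not (0 <= u.span[0] < u.span[1] <= L):
                raise ValueError(f"curated unit span {u.span} outside locus")


def calibrate(
    training_loci: list[TrainingLocus],
    model: PromoterModel,
    base: PipelineConfig | None = None,
) -> tuple[PipelineConfig, dict]:
    """Set both search thresholds from curated training units.

    For each curated unit, the best repeat-homology alignment inside the
    unit span and the best promoter configuration upstream of it (same
    strand, within the assembly gap) are scored; the thresholds become
    the minima over all curated units, so every curated unit remains
    recoverable.  Raises when a curated element is undetectable.

    Returns the updated config and a per-unit score report.
    """
    if not training_loci:
        raise ValueError("calibration requires at least one training locus")
    base = base or PipelineConfig()
    params = base.alignment_params()
    hit_scores: list[float] = []
    tss_scores: list[float] = []
    details: list[dict] = []
    for tl in training_loci:
        seq = tl.locus.sequence.residues
        repeat = tl.locus.array.repeat_forward.residues
        regions = extract_intergenic_regions(
            tl.locus, min_len=base.min_intergenic_len,
            extension=base.terminator_extension, edge_window=base.edge_window,
        )
        for cu in tl.curated_units:
            u0, u1 = cu.span
            body = seq[u0:u1]
            alns = [
                a
                for a in local_align(repeat, body, params=params,
                                     max_hits=base.max_hits_per_region)
                if a.aligned_columns
                >= max(base.min_aligned_columns,
                       int(base.min_query_coverage * len(repeat)))
            ]
            if not alns:
                raise ValueError(
                    f"curated unit {cu.span} on {tl.locus.sequence.id}: no "
                    f"repeat homology detectable"
                )
            best_hit = max(a.normalized_score for a in alns)
            region = next(
                (
                    r
                    for r in regions
                    if r.span[0] <= u0 and u1 <= r.span[1]
                ),
                None,
            )
            if region is None:
                raise ValueError(
                    f"curated unit {cu.span} on {tl.locus.sequence.id} lies in "
                    f"no intergenic region"
                )
            preds = scan_region_for_tss(
                seq[region.span[0] : region.span[1]], model,
                region_id=region.id, offset=region.span[0], threshold=-1e9,
            )
            if cu.strand == "+":
                cands = [
                    p
                    for p in preds
                    if p.strand == "+"
                    and 0 <= u0 - p.tss_position <= base.max_tss_gap
                ]
            else:
                cands = [
                    p
                    for p in preds
                    if p.strand == "-"
                    and 0 <= p.tss_position - (u1 - 1) <= base.max_tss_gap
                ]
            if not cands:
                raise ValueError(
                    f"curated unit {cu.span} on {tl.locus.sequence.id}: no "
                    f"upstream promoter candidate"
                )
            best_tss = max(p.score for p in cands)
            hit_scores.append(best_hit)
            tss_scores.append(best_tss)
            details.append(
                {
                    "locus": tl.locus.sequence.id,
                    "span": list(cu.span),
                    "strand": cu.strand,
                    "rna_class": cu.rna_class,
                    "repeat_score": round(best_hit, 4),
                    "promoter_score": round(best_tss, 4),
                }
            )
    cfg = dataclasses.replace(
        base,
        repeat_threshold=min(hit_scores),
        tss_threshold=min(tss_scores),
    )
    report = {
        "repeat_threshold": cfg.repeat_threshold,
        "tss_threshold": cfg.tss_threshold,
        "curated_elements": details,
    }
    return cfg, report
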