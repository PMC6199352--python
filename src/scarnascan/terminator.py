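"""Rho-independent (intrinsic) terminator detection.

A terminator candidate is a single stem-loop whose whole span fits a
11-50 bp frame, scored by a thermodynamic nearest-neighbor free energy
(RNA parameters: termination happens on the transcript, so the DNA input
is read as RNA), plus a U-richness score over the 15 nt immediately
downstream of the hairpin.  A candidate passes when

    dG <= dg_cutoff  (default -6 kcal/mol)
    stem >= 4 pairs, with >= 3 G:C pairs (G:U pairs allowed but not counted)
    U-score >= u_cutoff (default -2.3)

Among mutually overlapping survivors on a strand only the best-dG one is
reported.

The U-score uses a geometric-decay formula (proximal U's weighted most,
symmetric around zero) kept behind a single function so an alternative
empirical equation can be dropped in; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .sequences import revcomp

MIN_FRAME = 11
MAX_FRAME = 50
DEFAULT_DG_CUTOFF = -6.0
DEFAULT_MIN_GC = 3
DEFAULT_MIN_STEM = 4
DEFAULT_U_CUTOFF = -2.3
DEFAULT_MIN_LOOP = 3
DEFAULT_MAX_LOOP = 13
U_SCORE_DECAY = 0.9
TAIL_LENGTH = 15

_PAIRS_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = {("G", "T"), ("T", "G")}


def _load_nn_params() -> dict:
    with resources.files("scarnascan.data").joinpath("nn_params.json").open() as fh:
        return json.load(fh)


_NN = _load_nn_params()
NN_STACK: dict[str, float] = _NN["stack"]
NN_HAIRPIN_LOOP: dict[int, float] = {int(k): v for k, v in _NN["hairpin_loop"].items()}
NN_VERSION: str = _NN["version"]


def pairs(a: str, b: str, allow_gu: bool = True) -> bool:
    if (a, b) in _PAIRS_WC:
        return True
    return allow_gu and (a, b) in _PAIRS_GU


@dataclass(frozen=True)
class Hairpin:
    """A single stem-loop in local window coordinates."""

    span: tuple[int, int]
    stem_pairs: tuple[tuple[int, int, str], ...]  # (i, j, "WC"|"GU")
    loop_span: tuple[int, int]
    gc_pairs: int
    delta_g: float | None = None

    @property
    def stem_length(self) -> int:
        return len(self.stem_pairs)

    @property
    def loop_length(self) -> int:
        return self.loop_span[1] - self.loop_span[0]

    def dot_bracket(self, length: int | None = None) -> str:
        n = length if length is not None else self.span[1]
        chars = ["."] * n
        for i, j, _ in self.stem_pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


@dataclass(frozen=True)
class TerminatorPrediction:
    region_id: str
    strand: str
    hairpin: Hairpin  # spans in forward genomic coordinates
    tail: str
    u_score: float
    passes: bool
    tail_truncated: bool = False
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def span(self) -> tuple[int, int]:
        return self.hairpin.span


class TerminatorError(ValueError):
    pass


def _enumerate_in(
    seq: str,
    lo: int,
    hi: int,
    min_stem: int,
    min_loop: int,
    max_loop: int,
    max_span: int,
    allow_gu: bool,
) -> list[Hairpin]:
    """Maximal single stem-loops with span inside [lo, hi).

    For every loop placement the stem is extended outward while bases
    pair, stopping at the window bounds or the frame-size cap, so each
    reported hairpin is maximal: its stem can be extended neither outward
    (within the window / frame cap) nor inward (loop ends unpaired or
    loop at minimum size).
    """
    out: list[Hairpin] = []
    for a in range(lo + 1, hi):  # loop start
        for loop_len in range(min_loop, max_loop + 1):
            b = a + loop_len  # loop end (exclusive)
            if b >= hi:
                break
            # maximality (inward): the loop ends must not pair with the
            # loop at or above the minimum size after shrinking
            if loop_len - 2 >= min_loop and pairs(seq[a], seq[b - 1], allow_gu):
                continue
            stem: list[tuple[int, int, str]] = []
            i, j = a - 1, b
            while (
                i >= lo
                and j < hi
                and (j + 1 - i) <= max_span
                and pairs(seq[i], seq[j], allow_gu)
            ):
                kind = "WC" if (seq[i], seq[j]) in _PAIRS_WC else "GU"
                stem.append((i, j, kind))
                i -= 1
                j += 1
            if len(stem) < min_stem:
                continue
            stem = stem[::-1]  # outermost pair first
            start = stem[0][0]
            end = stem[0][1] + 1
            span = end - start
            if span < MIN_FRAME:
                continue
            gc = sum(
                1
                for (pi, pj, kind) in stem
                if kind == "WC" and seq[pi] in "GC"
            )
            out.append(
                Hairpin(
                    span=(start, end),
                    stem_pairs=tuple(stem),
                    loop_span=(a, b),
                    gc_pairs=gc,
                )
            )
    out.sort(key=lambda h: (h.span, -h.stem_length))
    return out


def enumerate_hairpins(
    window_sequence: str,
    min_stem: int = DEFAULT_MIN_STEM,
    min_loop: int = DEFAULT_MIN_LOOP,
    max_loop: int = DEFAULT_MAX_LOOP,
    allow_gu: bool = True,
) -> list[Hairpin]:
    """All maximal single stem-loops within one 11-50 bp window."""
    n = len(window_sequence)
    if not MIN_FRAME <= n <= MAX_FRAME:
        raise TerminatorError(
            f"window length {n} outside the {MIN_FRAME}-{MAX_FRAME} bp frame"
        )
    return _enumerate_in(
        window_sequence, 0, n, min_stem, min_loop, max_loop, MAX_FRAME, allow_gu
    )


def hairpin_delta_g(hairpin: Hairpin, sequence: str) -> float:
    """Nearest-neighbor free energy of a stem-loop, kcal/mol.

    Sum of stack terms over adjacent stem pairs plus the hairpin-loop
    initiation penalty for the loop length, from the shipped parameter
    table.  Lower is more stable.
    """
    if hairpin.stem_length < DEFAULT_MIN_STEM:
        raise TerminatorError("stem shorter than 4 pairs is not scored")
    dg = NN_HAIRPIN_LOOP[hairpin.loop_length]
    stem = hairpin.stem_pairs
    for (i1, j1, _), (i2, j2, _) in zip(stem, stem[1:]):
        if not pairs(sequence[i1], sequence[j1]) or not pairs(
            sequence[i2], sequence[j2]
        ):
            raise TerminatorError("invalid pair in stem")
        key = f"{sequence[i1]}{sequence[i2]}/{sequence[j1]}{sequence[j2]}"
        dg += NN_STACK[key]
    return round(dg, 10)


def u_score(tail: str) -> tuple[float, bool]:
    """U-richness of a downstream tail (<= 15 nt), with empty-tail flag.

    score = sum_i delta_i * 0.9**(i-1), delta_i = +1 for T/U else -1,
    summed over the available length (at most 15).  An all-U 15-mer gives
    about +7.94, an all-non-U 15-mer about -7.94.
    """
    if not tail:
        return 0.0, True
    total = 0.0
    for i, base in enumerate(tail[:TAIL_LENGTH]):
        delta = 1.0 if base == "T" else -1.0
        total += delta * U_SCORE_DECAY**i
    return total, False


def hairpin_chain(
    seq: str,
    min_stem: int = DEFAULT_MIN_STEM,
    min_loop: int = DEFAULT_MIN_LOOP,
    max_loop: int = DEFAULT_MAX_LOOP,
) -> list[Hairpin]:
    """Successive non-overlapping stem-loops, left to right.

    Structural annotation only (no free-energy or tail constraints); used
    for the 3'-tail architecture of single-guide-like units.
    """
    hairpins = _enumerate_in(seq, 0, len(seq), min_stem, min_loop, max_loop,
                             MAX_FRAME, True)
    hairpins.sort(key=lambda h: h.span)
    chain: list[Hairpin] = []
    for hp in hairpins:
        if chain and hp.span[0] < chain[-1].span[1]:
            continue
        chain.append(hp)
    return chain


@dataclass(frozen=True)
class TerminatorConfig:
    dg_cutoff: float = DEFAULT_DG_CUTOFF
    min_gc: int = DEFAULT_MIN_GC
    min_stem: int = DEFAULT_MIN_STEM
    u_cutoff: float = DEFAULT_U_CUTOFF
    min_loop: int = DEFAULT_MIN_LOOP
    max_loop: int = DEFAULT_MAX_LOOP
    allow_gu: bool = True


def _scan_strand(
    seq: str,
    cfg: TerminatorConfig,
) -> list[tuple[Hairpin, float, str, float, bool]]:
    """Candidates on one strand of a search span (local coordinates)."""
    n = len(seq)
    if n < MIN_FRAME:
        return []
    cands = []
    hairpins = _enumerate_in(
        seq, 0, n, cfg.min_stem, cfg.min_loop, cfg.max_loop, MAX_FRAME, cfg.allow_gu
    )
    for hp in hairpins:
        if hp.gc_pairs < cfg.min_gc:
            continue
        dg = hairpin_delta_g(hp, seq)
        if dg > cfg.dg_cutoff:
            continue
        tail = seq[hp.span[1] : hp.span[1] + TAIL_LENGTH]
        score, empty = u_score(tail)
        truncated = len(tail) < TAIL_LENGTH
        if empty or score < cfg.u_cutoff:
            continue
        cands.append((hp, dg, tail, score, truncated))
    return cands


def find_terminators(
    locus_seq: str,
    search_span: tuple[int, int],
    region_id: str = "",
    cfg: TerminatorConfig | None = None,
) -> list[TerminatorPrediction]:
    """Passing terminators in a search span, both strands.

    ``search_span`` should already include the 15 bp downstream extension
    of the intergenic region.  Hairpin spans of the output are forward
    genomic coordinates; minus-strand tails read along the minus strand
    (leftward of the hairpin on the forward strand).  Overlapping
    survivors on one strand are resolved in favour of the better (lower)
    free energy.
    """
    cfg = cfg or TerminatorConfig()
    s0, s1 = search_span
    sub = locus_seq[s0:s1]
    results: list[TerminatorPrediction] = []
    for strand in "+-":
        seq = sub if strand == "+" else revcomp(sub)
        cands = _scan_strand(seq, cfg)
        mapped = []
        n = len(seq)
        for hp, dg, tail, score, truncated in cands:
            if strand == "+":
                g_span = (s0 + hp.span[0], s0 + hp.span[1])
                g_pairs = tuple(
                    (s0 + i, s0 + j, kind) for i, j, kind in hp.stem_pairs
                )
                g_loop = (s0 + hp.loop_span[0], s0 + hp.loop_span[1])
            else:
                g_span = (s0 + n - hp.span[1], s0 + n - hp.span[0])
                g_pairs = tuple(
                    sorted(
                        (s0 + n - 1 - j, s0 + n - 1 - i, kind)
                        for i, j, kind in hp.stem_pairs
                    )
                )
                g_loop = (s0 + n - hp.loop_span[1], s0 + n - hp.loop_span[0])
            mapped.append(
                (
                    Hairpin(g_span, g_pairs, g_loop, hp.gc_pairs, dg),
                    tail,
                    score,
                    truncated,
                )
            )
        # overlap resolution by best delta G, per strand
        mapped.sort(key=lambda t: (t[0].delta_g, t[0].span))
        chosen: list[tuple[Hairpin, str, float, bool]] = []
        for item in mapped:
            hp = item[0]
            if any(
                min(hp.span[1], o[0].span[1]) > max(hp.span[0], o[0].span[0])
                for o in chosen
            ):
                continue
            chosen.append(item)
        for hp, tail, score, truncated in chosen:
            results.append(
                TerminatorPrediction(
                    region_id=region_id,
                    strand=strand,
                    hairpin=hp,
                    tail=tail,
                    u_score=score,
                    passes=True,
                    tail_truncated=truncated,
                    notes=("truncated_tail",) if truncated else (),
                )
            )
    results.sort(key=lambda p: (p.span, p.strand))
    return results


def terminators_to_tsv(preds: list[TerminatorPrediction], locus_seq: str) -> str:
    header = (
        "region_id\tstart\tend\tstrand\tdelta_g\tgc_pairs\tstem\tloop\t"
        "u_score\ttail\tstructure\n"
    )
    rows = []
    for p in preds:
        s0, s1 = p.span
        local = Hairpin(
            span=(0, s1 - s0),
            stem_pairs=tuple((i - s0, j - s0, k) for i, j, k in p.hairpin.stem_pairs),
            loop_span=(p.hairpin.loop_span[0] - s0, p.hairpin.loop_span[1] - s0),
            gc_pairs=p.hairpin.gc_pairs,
        )
        rows.append(
            "\t".join(
                [
                    p.region_id,
                    str(s0),
                    str(s1),
                    p.strand,
                    f"{p.hairpin.delta_g:.2f}",
                    str(p.hairpin.gc_pairs),
                    str(p.hairpin.stem_length),
                    str(p.hairpin.loop_length),
                    f"{p.u_score:.2f}",
                    p.tail,
                    local.dot_bracket(s1 - s0),
                ]
            )
        )
    return header + "\n".join(rows) + ("\n" if rows else "")
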