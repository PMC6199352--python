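"""Seeded synthetic CRISPR/Cas loci with planted, truth-annotated signals.

Every pipeline stage is testable without downloads: loci are generated
with planted promoters sampled from the promoter model, designed
hairpin+U-tail terminators, CRISPR arrays built from real direct repeats,
and repeat-homology segments laid out in the architectures observed in
Type II systems:

``IIB_fnovicida_like``
    everything transcribed from the minus strand; a scaRNA unit (sense
    repeat copy) sits upstream of the array and a tracrRNA unit
    (anti-repeat) downstream, as in the experimentally characterised
    Type IIB locus.
``tracrRNA_only``
    a plus-oriented array and a single anti-repeat unit next to the cas
    genes, the pattern seen in several IIA/IIC systems.
``IIA_like`` / ``IIC_like``
    scaRNA:tracrRNA pair layouts with the pair split around the cas genes
    and the array on plus / minus respectively.
``sgRNA_like``
    one unit with two overlapping repeat-homology segments (possible only
    for a partially palindromic repeat) followed by a three-hairpin 3'
    tail, mimicking a fused single-guide-like molecule.

Planted elements are closed-loop verified: each promoter, terminator and
repeat segment is re-detected by the corresponding detector before the
locus is emitted.  Background sequence is i.i.d. with configurable GC
(default 0.40, typical of the AT-rich organisms carrying these systems).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentParams, local_align
from .locus import CrisprArray, CrisprLocus, Feature
from .promoter import (
    EXT10_CONTEXT,
    PromoterModel,
    PromoterError,
    score_promoter_configuration,
    scan_region_for_tss,
)
from .repeats import DEFAULT_MIN_COLUMNS, DEFAULT_REPEAT_THRESHOLD
from .sequences import NucleotideSequence, revcomp
from .terminator import (
    DEFAULT_MIN_STEM,
    TerminatorConfig,
    enumerate_hairpins,
    find_terminators,
    hairpin_chain,
    hairpin_delta_g,
    u_score,
)

#: Direct repeats (5'->3', forward genomic strand) of well-characterised
#: Type II CRISPR/Cas systems, usable as generator inputs and fixtures.
DIRECT_REPEATS: dict[str, str] = {
    "L_innocua_clip11262": "GTTTTGTTAGCATTCAAAATAACATAGCTCTAAAAC",
    "M_gallisepticum_F": "GTTTTAGCACTGTACAATACTTGTGTAAGCAATAAC",
    "S_pyogenes_M1GAS": "GTTTTAGAGCTATGCTGTTTTGAATGGTCCCAAAAC",
    "S_mutans_UA159": "GTTTTGGAACCATTCGAAACAACACAGCTCTAAAAC",
    "L_salivarius_UCC118": "GTTTCAGAAGTATGTTAAATCAATAAGGTTAAGACC",
    "L_monocytogenes_SLCC2482": "GTTTTGGTAGCATTCAAAATAACATAGCTCTAAAAC",
    "F_novicida_GA99_3548": "CTAACAGTAGTTTACCAAATAATTCAGCAACTGAAAC",
    "F_novicida_U112": "CTAACAGTAGTTTACCAAATAATTCAGCAACTGAAAC",
    "L_pneumophila_130b": "CCAATAATCCCTCATCTAAAAATCCAACCACTGAAAC",
    "W_succinogenes_DSM1740": "GCAACACTTTATAGCAAATCCGCTTAGCCTGTGAAAC",
    "N_lactamica_020_06": "ATTGTAGCACTGCGAAATGAGAAAGGGAGCTACAAC",
    "N_meningitidis_ATCC13091": "ATTGTAGCACTGCGAAATGAGAAAGGGAGCTACAAC",
    "C_jejuni_81116": "GTTTTAGTCCCTTTTTAAATTTCTTTATGGTAAAAT",
    "P_multocida_PM70": "GTTGTAGTTCCCTCTCTCATTTCGCAGTGCTACAAT",
    "H_parainfluenzae_T3T1": "ATTATAGCACTGCGAAATGAAAAAGGGAGCTACAAC",
}

TEMPLATES = (
    "IIB_fnovicida_like",
    "IIA_like",
    "IIC_like",
    "tracrRNA_only",
    "sgRNA_like",
    "custom",
)

#: 12-nt perfect palindrome used as the self-complementary core of the
#: sgRNA-like template's repeat (overlapping +/- homology segments require
#: a partially palindromic repeat).
PALINDROME_CORE = "GCGCATATGCGC"

_BASES = np.array(list("ACGT"))


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class ArchitectureSpec:
    template: str = "IIB_fnovicida_like"
    seed: int = 0
    background_gc: float = 0.40
    repeat: str | None = None  # default: the F. novicida U112 repeat
    promoter_margin: float = 4.0  # planted score above model threshold
    terminator_dg: float = -10.0  # target hairpin free energy, kcal/mol
    terminator_gc_pairs: int = 4
    tail_u_fraction: float = 1.0
    n_spacers: int = 3
    spacer_len_range: tuple[int, int] = (30, 36)
    elements: tuple | None = None  # custom template layout

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise GenerationError(f"unknown template {self.template!r}")
        if self.template == "custom" and not self.elements:
            raise GenerationError("custom template requires an element list")
        if not 0.0 < self.background_gc < 1.0:
            raise GenerationError("background_gc must be in (0, 1)")


@dataclass(frozen=True)
class PlantedElement:
    kind: str  # promoter | terminator | repeat_segment | unit | array
    span: tuple[int, int]
    strand: str
    rna_class: str | None = None
    score: float | None = None


@dataclass(frozen=True)
class GroundTruth:
    elements: tuple[PlantedElement, ...]

    def of_kind(self, kind: str) -> list[PlantedElement]:
        return [e for e in self.elements if e.kind == kind]

    @property
    def units(self) -> list[PlantedElement]:
        return self.of_kind("unit")


def _bg(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


@dataclass(frozen=True)
class PromoterDesign:
    sequence: str  # plus-sense: -35, spacer, -10 hexamer
    spacer_length: int
    score: float


def sample_promoter(
    model: PromoterModel,
    target_margin: float,
    rng: np.random.Generator,
) -> PromoterDesign:
    """A plus-sense promoter scoring >= threshold + target_margin.

    Starts from the consensus configuration and stochastically resamples
    element columns from the matrix distributions, keeping a substitution
    only while the score stays above target, so planted promoters vary
    between draws yet always satisfy the requested margin.
    """
    target = model.threshold + target_margin
    if target > model.max_score + 1e-9:
        raise PromoterError(
            f"margin {target_margin} unachievable: max score {model.max_score:.2f}"
        )
    spacer = max(model.spacer.weights, key=lambda k: model.spacer.weights[k])
    m35 = list(model.pwm35.consensus)
    ext = list(model.pwm_ext10.consensus)
    prefix = list(_bg(rng, spacer - EXT10_CONTEXT, 0.4))

    def assemble() -> str:
        return "".join(m35 + prefix + ext)

    p35 = model.pwm35.probabilities()
    pext = model.pwm_ext10.probabilities()
    columns = [("m35", i) for i in range(len(m35))] + [
        ("ext", i) for i in range(len(ext))
    ]
    for k in rng.permutation(len(columns)):
        which, i = columns[int(k)]
        store = m35 if which == "m35" else ext
        probs = p35[i] if which == "m35" else pext[i]
        old = store[i]
        store[i] = "ACGT"[int(rng.choice(4, p=probs / probs.sum()))]
        score, _ = score_promoter_configuration(assemble(), 0, spacer, model)
        if score < target:
            store[i] = old
    seq = assemble()
    score, _ = score_promoter_configuration(seq, 0, spacer, model)
    return PromoterDesign(sequence=seq, spacer_length=spacer, score=score)


@dataclass(frozen=True)
class TerminatorDesign:
    sequence: str  # plus-sense hairpin followed by the 15-nt tail
    hairpin_span: tuple[int, int]  # within `sequence`
    delta_g: float
    gc_pairs: int
    u_score: float


def design_terminator(
    target_dg: float,
    gc_pairs: int = 4,
    tail_u_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
    max_stem: int = 12,
    loop: str = "AACA",
) -> TerminatorDesign:
    """A hairpin + tail whose free energy reaches ``target_dg``.

    The stem holds exactly ``gc_pairs`` G:C pairs; A:T pairs are appended
    (never more G:C, so the stated G:C count is preserved) until the
    scored free energy meets the target, failing beyond ``max_stem``
    pairs.  The design is round-tripped through the detector's own
    enumerator and scorer.
    """
    if target_dg >= 0:
        raise GenerationError("target_dg must be negative")
    rng = rng if rng is not None else np.random.default_rng(0)
    n_at = max(0, DEFAULT_MIN_STEM - gc_pairs)
    while True:
        bases = [rng.choice(list("GC")) for _ in range(gc_pairs)]
        bases += [rng.choice(list("AT")) for _ in range(n_at)]
        side5 = "".join(np.asarray(bases)[rng.permutation(len(bases))])
        hairpin_seq = side5 + loop + revcomp(side5)
        found = enumerate_hairpins(hairpin_seq, min_stem=DEFAULT_MIN_STEM)
        full = [h for h in found if h.span == (0, len(hairpin_seq))]
        if not full:
            raise GenerationError("designed stem failed re-detection")
        dg = hairpin_delta_g(full[0], hairpin_seq)
        if dg <= target_dg:
            break
        if len(bases) >= max_stem:
            raise GenerationError(
                f"target {target_dg} kcal/mol unachievable with {gc_pairs} G:C "
                f"pairs and a <= {max_stem}-pair stem"
            )
        n_at += 1
    u_count = int(round(15 * tail_u_fraction))
    filler = "".join(rng.choice(np.array(list("AC")), size=15 - u_count))
    tail = "T" * u_count + filler
    score, _ = u_score(tail)
    return TerminatorDesign(
        sequence=hairpin_seq + tail,
        hairpin_span=(0, len(hairpin_seq)),
        delta_g=dg,
        gc_pairs=full[0].gc_pairs,
        u_score=score,
    )


def generate_array(
    repeat: str,
    n_spacers: int,
    spacer_len_range: tuple[int, int] = (30, 36),
    rng: np.random.Generator | None = None,
    threshold: float = DEFAULT_REPEAT_THRESHOLD,
    params: AlignmentParams | None = None,
    gc: float = 0.40,
    max_tries: int = 100,
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """(repeat + spacer) x n_spacers + trailing repeat, with truth spans.

    Spacers are rejection-sampled so their best repeat alignment stays
    below half the hit threshold: a planted array must not seed
    accidental repeat-homology hits outside the truth annotation.
    """
    if n_spacers < 1:
        raise GenerationError("n_spacers must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    lo, hi = spacer_len_range
    parts: list[str] = [repeat]
    repeat_spans = [(0, len(repeat))]
    spacer_spans: list[tuple[int, int]] = []
    cursor = len(repeat)
    for _ in range(n_spacers):
        length = int(rng.integers(lo, hi + 1))
        for attempt in range(max_tries):
            spacer = _bg(rng, length, gc)
            alns = [
                a
                for a in local_align(repeat, spacer, params=params)
                if a.aligned_columns >= DEFAULT_MIN_COLUMNS
            ]
            best = max((a.normalized_score for a in alns), default=-1.0)
            if best < 0.5 * threshold:
                break
        else:
            raise GenerationError("could not sample a repeat-unlike spacer")
        parts.append(spacer)
        spacer_spans.append((cursor, cursor + length))
        cursor += length
        parts.append(repeat)
        repeat_spans.append((cursor, cursor + len(repeat)))
        cursor += len(repeat)
    return "".join(parts), repeat_spans, spacer_spans


def degrade_signal(
    sequence: str,
    element_span: tuple[int, int],
    n_mutations: int,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Exactly ``n_mutations`` substitutions placed uniformly in the span."""
    s, e = element_span
    if not (0 <= s <= e <= len(sequence)):
        raise GenerationError("element span out of bounds")
    if n_mutations > e - s:
        raise GenerationError("more mutations than span positions")
    positions = sorted(
        int(p) for p in rng.choice(np.arange(s, e), size=n_mutations, replace=False)
    )
    chars = list(sequence)
    for p in positions:
        others = [b for b in "ACGT" if b != chars[p]]
        chars[p] = others[int(rng.integers(3))]
    return "".join(chars), positions


class _Builder:
    """Accumulates sequence parts, features and truth annotations."""

    def __init__(self, rng: np.random.Generator, gc: float):
        self.rng = rng
        self.gc = gc
        self.parts: list[str] = []
        self.cursor = 0
        self.features: list[Feature] = []
        self.truth: list[PlantedElement] = []

    def add(self, seq: str) -> tuple[int, int]:
        span = (self.cursor, self.cursor + len(seq))
        self.parts.append(seq)
        self.cursor = span[1]
        return span

    def pad(self, lo: int, hi: int) -> tuple[int, int]:
        return self.add(_bg(self.rng, int(self.rng.integers(lo, hi + 1)), self.gc))

    def gene(self, label: str, kind: str, length: int, strand: str = "+") -> None:
        span = self.add(_bg(self.rng, length, self.gc))
        self.features.append(Feature(kind, span, strand, label))

    def sequence(self) -> str:
        return "".join(self.parts)


def _plant_unit(
    b: _Builder,
    strand: str,
    segment_fwd: str,
    rna_class: str,
    model: PromoterModel,
    spec: ArchitectureSpec,
    tail_sequences: list[str] | None = None,
    pre_terminator_pad: str | None = None,
) -> None:
    """Plant promoter -> segment [-> 3' tail parts] -> terminator.

    ``segment_fwd`` is the repeat-homology segment as written on the
    forward strand; ``tail_sequences`` (plus-sense, transcript order) go
    between the segment and the terminator.  ``pre_terminator_pad``
    replaces the random pad before the terminator with a fixed spacer
    (used when the 3' structure must be deterministic).
    """
    rng = b.rng
    prom = sample_promoter(model, spec.promoter_margin, rng)
    term = design_terminator(
        spec.terminator_dg,
        spec.terminator_gc_pairs,
        spec.tail_u_fraction,
        rng,
    )
    tails = tail_sequences or []
    if strand == "+":
        p_span = b.add(prom.sequence)
        tss = p_span[1] - 1 + model.tss_offset
        b.pad(15, 40)
        seg_span = b.add(segment_fwd)
        for t in tails:
            b.add(t)
        if pre_terminator_pad is not None:
            b.add(pre_terminator_pad)
        else:
            b.pad(10, 25)
        b.add("C")  # guard: blocks outward stem extension into the pad
        t_span = b.add(term.sequence)
        hairpin = (t_span[0], t_span[0] + term.hairpin_span[1])
        unit = (tss, hairpin[1])
    else:
        t_span = b.add(revcomp("C" + term.sequence))
        # guard base is the last base of the insert on the forward strand
        hp_len = term.hairpin_span[1]
        hairpin = (t_span[1] - 1 - hp_len, t_span[1] - 1)
        b.pad(10, 25)
        for t in reversed(tails):
            b.add(revcomp(t))
        seg_span = b.add(segment_fwd)
        b.pad(15, 40)
        p_span = b.add(revcomp(prom.sequence))
        tss = p_span[0] - model.tss_offset
        b.pad(15, 30)
        unit = (hairpin[0], tss + 1)
    b.truth.extend(
        [
            PlantedElement("promoter", p_span, strand, score=prom.score),
            PlantedElement("repeat_segment", seg_span, strand),
            PlantedElement("terminator", hairpin, strand, score=term.delta_g),
            PlantedElement("unit", unit, strand, rna_class=rna_class),
        ]
    )


def _plant_array_signals(
    b: _Builder, strand: str, which: str, model: PromoterModel, spec: ArchitectureSpec
) -> None:
    """Plant the array's own promoter or terminator (orientation evidence)."""
    rng = b.rng
    if which == "promoter":
        prom = sample_promoter(model, spec.promoter_margin, rng)
        if strand == "+":
            span = b.add(prom.sequence)
            b.pad(10, 14)
        else:
            b.pad(10, 14)
            span = b.add(revcomp(prom.sequence))
        b.truth.append(PlantedElement("promoter", span, strand, score=prom.score))
    else:
        term = design_terminator(
            spec.terminator_dg, spec.terminator_gc_pairs, spec.tail_u_fraction, rng
        )
        if strand == "+":
            b.add("C")
            span = b.add(term.sequence)
            hairpin = (span[0], span[0] + term.hairpin_span[1])
        else:
            span = b.add(revcomp("C" + term.sequence))
            hairpin = (span[1] - 1 - term.hairpin_span[1], span[1] - 1)
        b.truth.append(
            PlantedElement("terminator", hairpin, strand, score=term.delta_g)
        )


def _add_array(b: _Builder, spec: ArchitectureSpec, repeat: str) -> tuple[int, int]:
    arr_seq, _, _ = generate_array(
        repeat,
        spec.n_spacers,
        spec.spacer_len_range,
        b.rng,
        gc=spec.background_gc,
    )
    span = b.add(arr_seq)
    b.features.append(Feature("crispr_array", span, "?", "crispr_array"))
    b.truth.append(PlantedElement("array", span, "?"))
    return span


def _sgrna_segment(repeat: str) -> str:
    """Two overlapping repeat-homology segments sharing the palindrome core.

    For a repeat R = X + P with palindromic P, the segment X + P + rc(X)
    matches R fully on the plus strand over its first |R| bases and on
    the minus strand over its last |R| bases; the two alignments overlap
    across P, the base-pairing 5'/3' ends of a single-guide-like fold.
    """
    if not repeat.endswith(PALINDROME_CORE):
        raise GenerationError("sgRNA-like template needs a palindrome-cored repeat")
    x = repeat[: -len(PALINDROME_CORE)]
    return repeat + revcomp(x)


def _annotation_hairpins(rng: np.random.Generator, n: int = 3) -> list[str]:
    """Weak stem-loops for 3'-structure annotation (not terminators)."""
    out = []
    for _ in range(n):
        bases = [rng.choice(list("GC")) for _ in range(2)]
        bases += [rng.choice(list("AT")) for _ in range(3)]
        side5 = "".join(np.asarray(bases)[rng.permutation(len(bases))])
        out.append("CA" + side5 + "AACA" + revcomp(side5) + "AC")
    return out


def generate_locus(
    spec: ArchitectureSpec,
    model: PromoterModel,
    rng: np.random.Generator | None = None,
    verify: bool = True,
) -> tuple[CrisprLocus, GroundTruth]:
    """Emit a locus in the requested architecture, with ground truth.

    With ``verify`` (default), every planted promoter, terminator and
    repeat segment is re-detected by the corresponding detector before
    the locus is returned.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    template = spec.template
    if template == "sgRNA_like":
        x = _bg(rng, 15, 0.4)
        repeat = spec.repeat or (x + PALINDROME_CORE)
    else:
        repeat = spec.repeat or DIRECT_REPEATS["F_novicida_U112"]
    b = _Builder(rng, spec.background_gc)

    if template == "IIB_fnovicida_like" or template == "IIC_like":
        # all components on the minus strand
        b.add(_bg(rng, 60, spec.background_gc))
        b.gene("flank_left", "other_gene", 300)
        b.pad(20, 30)
        _plant_unit(b, "-", revcomp(repeat), "tracrRNA", model, spec)
        if template == "IIC_like":
            b.pad(15, 25)
            b.gene("cas9", "cas_gene", 500, "-")
            b.pad(30, 40)
            _plant_array_signals(b, "-", "terminator", model, spec)
            b.pad(10, 16)
            _add_array(b, spec, repeat)
        else:
            b.pad(15, 25)
            _plant_array_signals(b, "-", "terminator", model, spec)
            b.pad(10, 16)
            _add_array(b, spec, repeat)
        b.pad(10, 14)
        _plant_array_signals(b, "-", "promoter", model, spec)
        b.pad(12, 20)
        _plant_unit(b, "-", repeat, "scaRNA", model, spec)
        b.pad(15, 25)
        if template == "IIB_fnovicida_like":
            b.gene("cas9", "cas_gene", 500, "-")
            b.add(_bg(rng, 80, spec.background_gc))
        b.gene("flank_right", "other_gene", 300)
        b.add(_bg(rng, 60, spec.background_gc))
    elif template == "tracrRNA_only":
        b.add(_bg(rng, 60, spec.background_gc))
        b.gene("flank_left", "other_gene", 300)
        b.pad(20, 30)
        _plant_unit(b, "-", repeat, "tracrRNA", model, spec)
        b.pad(15, 25)
        b.gene("cas9", "cas_gene", 500)
        b.pad(20, 30)
        _plant_array_signals(b, "+", "promoter", model, spec)
        _add_array(b, spec, repeat)
        b.pad(10, 16)
        _plant_array_signals(b, "+", "terminator", model, spec)
        b.pad(40, 50)
        b.gene("flank_right", "other_gene", 300)
        b.add(_bg(rng, 60, spec.background_gc))
    elif template == "IIA_like":
        b.add(_bg(rng, 60, spec.background_gc))
        b.gene("flank_left", "other_gene", 300)
        b.pad(20, 30)
        _plant_unit(b, "-", repeat, "tracrRNA", model, spec)
        b.pad(15, 25)
        b.gene("cas9", "cas_gene", 500)
        b.pad(15, 25)
        _plant_unit(b, "+", repeat, "scaRNA", model, spec)
        b.pad(12, 18)
        _plant_array_signals(b, "+", "promoter", model, spec)
        _add_array(b, spec, repeat)
        b.pad(10, 16)
        _plant_array_signals(b, "+", "terminator", model, spec)
        b.pad(40, 50)
        b.gene("flank_right", "other_gene", 300)
        b.add(_bg(rng, 60, spec.background_gc))
    elif template == "sgRNA_like":
        segment = _sgrna_segment(repeat)
        b.add(_bg(rng, 60, spec.background_gc))
        b.gene("flank_left", "other_gene", 300)
        b.pad(20, 30)
        # closed loop: the emitted 3' region must annotate as exactly three
        # successive stem-loops (adjacent random stems can chance-pair into
        # one larger structure, so resample until the chain is clean)
        ac_pad, fixed_pad = "ACCACAACCACACCA", "ACACACACAC"
        for _ in range(100):
            three = _annotation_hairpins(rng)
            region_3p = ac_pad + "".join(three) + fixed_pad + "C"
            if len(hairpin_chain(region_3p)) == 3:
                break
        else:
            raise GenerationError("could not design a clean three-hairpin tail")
        tails = [ac_pad] + three
        _plant_unit(b, "+", segment, "sgRNA_like", model, spec,
                    tail_sequences=tails, pre_terminator_pad=fixed_pad)
        b.pad(15, 25)
        b.gene("cas9", "cas_gene", 500)
        b.pad(20, 30)
        _plant_array_signals(b, "+", "promoter", model, spec)
        _add_array(b, spec, repeat)
        b.pad(10, 16)
        _plant_array_signals(b, "+", "terminator", model, spec)
        b.pad(40, 50)
        b.gene("flank_right", "other_gene", 300)
        b.add(_bg(rng, 60, spec.background_gc))
    elif template == "custom":
        for element in spec.elements:
            kind = element["kind"]
            if kind == "background":
                b.add(_bg(rng, element["length"], spec.background_gc))
            elif kind == "gene":
                b.gene(
                    element.get("label", "gene"),
                    element.get("feature_kind", "other_gene"),
                    element["length"],
                    element.get("strand", "+"),
                )
            elif kind == "array":
                _add_array(b, spec, repeat)
            elif kind == "array_promoter":
                _plant_array_signals(b, element["strand"], "promoter", model, spec)
            elif kind == "array_terminator":
                _plant_array_signals(b, element["strand"], "terminator", model, spec)
            elif kind == "unit":
                seg = element.get("segment_fwd")
                if seg is None:
                    seg = (
                        repeat if element["rna_class"] == "scaRNA"
                        else revcomp(repeat)
                    )
                _plant_unit(
                    b, element["strand"], seg, element["rna_class"], model, spec
                )
            else:
                raise GenerationError(f"unknown custom element kind {kind!r}")

    sequence = b.sequence()
    array_feature = next(f for f in b.features if f.kind == "crispr_array")
    locus = CrisprLocus(
        sequence=NucleotideSequence(f"synthetic_{template}_{spec.seed}", sequence),
        features=tuple(b.features),
        array=CrisprArray(
            span=array_feature.span,
            repeat_forward=NucleotideSequence("direct_repeat", repeat),
            spacer_count=spec.n_spacers,
        ),
    )
    truth = GroundTruth(tuple(b.truth))
    if verify:
        _verify_truth(locus, truth, model)
    return locus, truth


def _verify_truth(
    locus: CrisprLocus, truth: GroundTruth, model: PromoterModel
) -> None:
    """Re-detect every planted element before the locus is emitted."""
    seq = locus.sequence.residues
    repeat = locus.array.repeat_forward.residues
    for el in truth.elements:
        s, e = el.span
        if el.kind == "promoter":
            lo, hi = max(0, s - 30), min(len(seq), e + 30)
            preds = scan_region_for_tss(seq[lo:hi], model, offset=lo)
            tss = e - 1 + model.tss_offset if el.strand == "+" else s - model.tss_offset
            if not any(
                p.strand == el.strand and abs(p.tss_position - tss) <= 5
                for p in preds
            ):
                raise GenerationError(f"planted promoter at {el.span} not re-detected")
        elif el.kind == "terminator":
            lo, hi = max(0, s - 20), min(len(seq), e + 25)
            preds = find_terminators(seq, (lo, hi), cfg=TerminatorConfig())
            if not any(
                p.strand == el.strand
                and min(p.span[1], e) - max(p.span[0], s) > 0
                for p in preds
            ):
                raise GenerationError(
                    f"planted terminator at {el.span} not re-detected"
                )
        elif el.kind == "repeat_segment":
            alns = [
                a
                for a in local_align(repeat, seq[s:e])
                if a.aligned_columns >= DEFAULT_MIN_COLUMNS
            ]
            best = max((a.normalized_score for a in alns), default=-1.0)
            if best < DEFAULT_REPEAT_THRESHOLD:
                raise GenerationError(
                    f"planted repeat segment at {el.span} not re-detected"
                )


def truth_to_gff3(locus: CrisprLocus, truth: GroundTruth) -> str:
    """Truth annotation as GFF3 with a ``truth_class`` attribute."""
    type_map = {
        "promoter": "promoter",
        "terminator": "terminator",
        "repeat_segment": "repeat_region",
        "unit": "ncRNA",
        "array": "repeat_region",
    }
    lines = ["##gff-version 3"]
    for i, el in enumerate(truth.elements):
        attrs = f"ID=truth_{i};truth_kind={el.kind}"
        if el.rna_class:
            attrs += f";truth_class={el.rna_class}"
        if el.score is not None:
            attrs += f";planted_score={el.score:.3f}"
        strand = el.strand if el.strand in "+-" else "."
        lines.append(
            "\t".join(
                [
                    locus.sequence.id,
                    "scarnascan_synthetic",
                    type_map[el.kind],
                    str(el.span[0] + 1),
                    str(el.span[1]),
                    ".",
                    strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"
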