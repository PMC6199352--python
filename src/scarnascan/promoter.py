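"""Sigma-70 (RpoD) promoter model: weight matrices and TSS scanning.

A promoter configuration is a -35 hexamer, a spacer of 15-19 bp, and a
-10 element.  The -10 element is scored with a 15-column extended matrix
whose 3'-terminal six columns are the -10 hexamer and whose nine 5'
columns capture the TG-extension context upstream of it; a short 6-column
-10 matrix substitutes when the extended window cannot fit.  Spacer
lengths carry additive log-frequency weights.  The total score is the sum
of the -35 score, the spacer weight and the (extended) -10 score; the
transcription start site is placed a fixed offset downstream of the -10
hexamer.

Matrices are positional log-odds:
    weight[c][b] = log2( (count(b,c) + pc) / (N + 4*pc) / background[b] )
with pseudocount pc > 0 so all weights are finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .sequences import revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

WIDTH_MINUS35 = 6
WIDTH_MINUS10 = 6
WIDTH_EXT10 = 15
EXT10_CONTEXT = WIDTH_EXT10 - WIDTH_MINUS10  # 9 nt of upstream context
DEFAULT_TSS_OFFSET = 7
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_SPACER_RANGE = (15, 19)
COLLAPSE_DISTANCE = 5

#: Background of the shipped default model: AT-rich composition typical of
#: the organisms this tool targets (GC fraction 0.40).  Rebuild the PWMs
#: with a measured composition for other backgrounds.
DEFAULT_BACKGROUND = (0.30, 0.20, 0.20, 0.30)


class PromoterError(ValueError):
    pass


@dataclass(frozen=True)
class PositionWeightMatrix:
    element: str  # minus35 | extended_minus10 | minus10
    width: int
    weights: np.ndarray = field(repr=False)  # (width, 4) log2-odds
    background: tuple[float, float, float, float]
    counts: np.ndarray = field(repr=False)  # (width, 4) site counts

    def __post_init__(self) -> None:
        if self.weights.shape != (self.width, 4):
            raise PromoterError("weight matrix shape mismatch")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise PromoterError("background must sum to 1")
        if not np.isfinite(self.weights).all():
            raise PromoterError("non-finite weights (pseudocount required)")

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def probabilities(self) -> np.ndarray:
        """Per-column base probabilities implied by counts + pseudocount."""
        n = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + DEFAULT_PSEUDOCOUNT) / (n + 4 * DEFAULT_PSEUDOCOUNT)


def build_pwm(
    element: str,
    aligned_sites: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND,
    on_invalid: str = "error",
) -> PositionWeightMatrix:
    """Build a log-odds matrix from equal-length aligned sites.

    ``on_invalid`` controls sites containing non-ACGT characters:
    ``"error"`` raises, ``"drop"`` skips them with the count reduced.
    """
    if pseudocount <= 0:
        raise PromoterError("pseudocount must be > 0")
    sites = []
    for s in aligned_sites:
        s = s.upper().replace("U", "T")
        if set(s) - set(BASES):
            if on_invalid == "drop":
                continue
            raise PromoterError(f"site {s!r} contains non-ACGT characters")
        sites.append(s)
    if len(sites) < 2:
        raise PromoterError("need at least two valid aligned sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise PromoterError("aligned sites must have equal length")
    counts = np.zeros((width, 4), dtype=np.float64)
    for s in sites:
        for c, b in enumerate(s):
            counts[c, _BASE_INDEX[b]] += 1
    n = len(sites)
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    weights = np.log2(freqs / np.asarray(background))
    return PositionWeightMatrix(element, width, weights, tuple(background), counts)


def score_window(pwm: PositionWeightMatrix, window: str) -> float:
    """Sum of per-column weights for one window."""
    if len(window) != pwm.width:
        raise PromoterError(
            f"window length {len(window)} != matrix width {pwm.width}"
        )
    try:
        idx = [_BASE_INDEX[b] for b in window]
    except KeyError as exc:
        raise PromoterError(f"invalid base {exc} in window") from exc
    return float(sum(pwm.weights[c, i] for c, i in enumerate(idx)))


@dataclass(frozen=True)
class SpacerWeights:
    """Additive weights per -35 to -10 spacer length (bp)."""

    weights: dict[int, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise PromoterError("at least one allowed spacer length required")
        ls = sorted(self.weights)
        if ls != list(range(ls[0], ls[-1] + 1)):
            raise PromoterError("allowed spacer lengths must be contiguous")

    @property
    def allowed(self) -> range:
        ls = sorted(self.weights)
        return range(ls[0], ls[-1] + 1)

    def weight(self, length: int) -> float:
        if length not in self.weights:
            raise PromoterError(f"spacer length {length} outside allowed range")
        return self.weights[length]

    @classmethod
    def from_lengths(
        cls, lengths: list[int], pseudocount: float = DEFAULT_PSEUDOCOUNT
    ) -> "SpacerWeights":
        """log2 empirical spacer-length frequencies with a pseudocount."""
        lo, hi = min(lengths), max(lengths)
        n = len(lengths)
        k = hi - lo + 1
        w = {
            length: math.log2(
                (lengths.count(length) + pseudocount) / (n + k * pseudocount)
            )
            for length in range(lo, hi + 1)
        }
        return cls(w)


@dataclass(frozen=True)
class PromoterModel:
    pwm35: PositionWeightMatrix
    pwm_ext10: PositionWeightMatrix
    pwm10: PositionWeightMatrix
    spacer: SpacerWeights
    threshold: float
    tss_offset: int = DEFAULT_TSS_OFFSET

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise PromoterError("threshold must be finite")
        if self.tss_offset < 0:
            raise PromoterError("tss_offset must be >= 0")

    @property
    def max_score(self) -> float:
        return (
            self.pwm35.max_score
            + max(self.spacer.weights.values())
            + self.pwm_ext10.max_score
        )

    def min_footprint(self, spacer_length: int) -> int:
        return WIDTH_MINUS35 + spacer_length + WIDTH_MINUS10

    def with_threshold(self, threshold: float) -> "PromoterModel":
        return PromoterModel(
            self.pwm35, self.pwm_ext10, self.pwm10, self.spacer,
            threshold, self.tss_offset,
        )


@dataclass(frozen=True)
class TssPrediction:
    region_id: str
    strand: str
    tss_position: int  # 0-based genomic coordinate of the start site
    minus35_span: tuple[int, int]  # forward genomic coordinates
    minus10_span: tuple[int, int]
    spacer_length: int
    score: float
    used_short_minus10: bool = False


def score_promoter_configuration(
    seq: str,
    pos35: int,
    spacer_length: int,
    model: PromoterModel,
) -> tuple[float, bool]:
    """Total score of one configuration on a plus-sense sequence.

    Returns ``(score, used_short_minus10)``.  The extended -10 window is
    the 15-mer ending at the -10 hexamer's 3' end; when that window does
    not fit the sequence while the hexamer itself does, the short -10
    matrix is substituted over the hexamer only.
    """
    if spacer_length not in model.spacer.allowed:
        raise PromoterError(f"spacer length {spacer_length} outside allowed range")
    h = pos35 + WIDTH_MINUS35 + spacer_length
    if pos35 < 0 or h + WIDTH_MINUS10 > len(seq):
        raise PromoterError("configuration out of bounds")
    total = score_window(model.pwm35, seq[pos35 : pos35 + WIDTH_MINUS35])
    total += model.spacer.weight(spacer_length)
    ext_start = h - EXT10_CONTEXT
    if ext_start >= 0 and h + WIDTH_MINUS10 <= len(seq):
        total += score_window(model.pwm_ext10, seq[ext_start : h + WIDTH_MINUS10])
        return total, False
    total += score_window(model.pwm10, seq[h : h + WIDTH_MINUS10])
    return total, True


def _element_track(pwm: PositionWeightMatrix, codes: np.ndarray) -> np.ndarray:
    """Window score at every start position (vectorized sliding sum)."""
    n = len(codes) - pwm.width + 1
    if n <= 0:
        return np.empty(0)
    acc = np.zeros(n)
    for c in range(pwm.width):
        acc += pwm.weights[c, codes[c : c + n]]
    return acc


def _scan_plus(
    seq: str, model: PromoterModel
) -> list[tuple[int, int, float, bool]]:
    """All above-threshold configurations: (pos35, spacer, score, short)."""
    codes = np.array([_BASE_INDEX[b] for b in seq], dtype=np.intp)
    s35 = _element_track(model.pwm35, codes)
    sext = _element_track(model.pwm_ext10, codes)
    out: list[tuple[int, int, float, bool]] = []
    for spacer in model.spacer.allowed:
        sw = model.spacer.weight(spacer)
        # extended window start = pos35 + 6 + spacer - 9
        shift = WIDTH_MINUS35 + spacer - EXT10_CONTEXT
        n = min(len(s35), len(sext) - shift)
        if n <= 0:
            continue
        lo = max(0, -shift)
        if lo >= n:
            continue
        totals = s35[lo:n] + sw + sext[lo + shift : n + shift]
        for k in np.flatnonzero(totals >= model.threshold):
            out.append((int(lo + k), spacer, float(totals[k]), False))
    return out


def scan_region_for_tss(
    region_seq: str,
    model: PromoterModel,
    region_id: str = "",
    offset: int = 0,
    threshold: float | None = None,
) -> list[TssPrediction]:
    """TSS predictions on both strands of an intergenic region.

    Overlapping same-strand predictions whose start sites lie within 5 bp
    of each other collapse to the best-scoring one.  Coordinates are
    forward genomic (``offset`` + local); the TSS sits ``tss_offset`` bp
    downstream of the -10 hexamer on the prediction strand.
    """
    if threshold is not None:
        model = model.with_threshold(threshold)
    L = len(region_seq)
    preds: list[TssPrediction] = []
    for strand in "+-":
        seq = region_seq if strand == "+" else revcomp(region_seq)
        for pos35, spacer, score, short in _scan_plus(seq, model):
            h = pos35 + WIDTH_MINUS35 + spacer
            tss_local = h + WIDTH_MINUS10 - 1 + model.tss_offset
            m35_local = (pos35, pos35 + WIDTH_MINUS35)
            m10_local = (h, h + WIDTH_MINUS10)
            if strand == "+":
                tss = offset + tss_local
                m35 = (offset + m35_local[0], offset + m35_local[1])
                m10 = (offset + m10_local[0], offset + m10_local[1])
            else:
                tss = offset + L - 1 - tss_local
                m35 = (offset + L - m35_local[1], offset + L - m35_local[0])
                m10 = (offset + L - m10_local[1], offset + L - m10_local[0])
            preds.append(
                TssPrediction(
                    region_id=region_id,
                    strand=strand,
                    tss_position=tss,
                    minus35_span=m35,
                    minus10_span=m10,
                    spacer_length=spacer,
                    score=score,
                    used_short_minus10=short,
                )
            )
    # collapse near-duplicate configurations per strand
    preds.sort(key=lambda p: (-p.score, p.tss_position, p.strand))
    kept: list[TssPrediction] = []
    for p in preds:
        if any(
            q.strand == p.strand
            and abs(q.tss_position - p.tss_position) <= COLLAPSE_DISTANCE
            for q in kept
        ):
            continue
        kept.append(p)
    kept.sort(key=lambda p: (p.tss_position, p.strand))
    return kept


def calibrate_tss_threshold(
    training: list[tuple[str, int, list[tuple[int, str]]]],
    model: PromoterModel,
    tolerance: int = 3,
) -> float:
    """Largest threshold keeping every curated promoter predicted.

    ``training`` holds ``(region_seq, offset, curated)`` triples where
    ``curated`` lists (tss_position, strand) of true promoters.  Returns
    the minimum score over matched curated configurations; raises if any
    curated promoter is absent from an unthresholded scan.
    """
    scores: list[float] = []
    missing: list[tuple[int, str]] = []
    for region_seq, offset, curated in training:
        preds = scan_region_for_tss(
            region_seq, model, offset=offset, threshold=-1e9
        )
        for tss, strand in curated:
            matches = [
                p.score
                for p in preds
                if p.strand == strand and abs(p.tss_position - tss) <= tolerance
            ]
            if matches:
                scores.append(max(matches))
            else:
                missing.append((tss, strand))
    if missing:
        raise PromoterError(f"curated promoters not recoverable: {missing}")
    if not scores:
        raise PromoterError("no curated promoters supplied")
    return min(scores)


def realign_sites(
    sites: list[str],
    element: str,
    shift: int = 2,
    max_iterations: int = 10,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND,
) -> list[str]:
    """Greedy one-round realignment of element sites (optional utility).

    Each site may shift up to ``shift`` columns against the current
    matrix, iterating to a fixed point.  Sites must be wide enough to
    allow the shift; the returned sites are trimmed to the central window.
    """
    width = len(sites[0]) - 2 * shift
    if width < 1:
        raise PromoterError("sites too short for the requested shift")
    offsets = [shift] * len(sites)
    for _ in range(max_iterations):
        windows = [s[o : o + width] for s, o in zip(sites, offsets)]
        pwm = build_pwm(element, windows, pseudocount, background)
        changed = False
        for i, s in enumerate(sites):
            best_o, best_score = offsets[i], score_window(
                pwm, s[offsets[i] : offsets[i] + width]
            )
            for o in range(0, 2 * shift + 1):
                sc = score_window(pwm, s[o : o + width])
                if sc > best_score + 1e-12:
                    best_o, best_score = o, sc
            if best_o != offsets[i]:
                offsets[i] = best_o
                changed = True
        if not changed:
            break
    return [s[o : o + width] for s, o in zip(sites, offsets)]


def pwm_to_jaspar(pwm: PositionWeightMatrix, name: str) -> str:
    """JASPAR-style count matrix block."""
    lines = [f">{name} {pwm.element}"]
    for i, b in enumerate(BASES):
        vals = " ".join(f"{int(v):4d}" for v in pwm.counts[:, i])
        lines.append(f"{b}  [ {vals} ]")
    return "\n".join(lines) + "\n"


def _parse_site_file(text: str) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            current = line[1:].strip()
            blocks[current] = []
        elif current is not None:
            blocks[current].append(line)
    return blocks


def load_default_model(
    threshold: float | None = None,
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND,
    tss_offset: int = DEFAULT_TSS_OFFSET,
) -> PromoterModel:
    """Promoter model built from the bundled synthetic site fixture.

    The fixture ships 50 aligned -35 and extended -10 sites plus spacer
    lengths so the model builds without any download; importing a real
    curated promoter collection is the documented alternative (build the
    matrices with :func:`build_pwm` from your own aligned sites).
    """
    text = (
        resources.files("scarnascan.data")
        .joinpath("synthetic_promoter_sites.txt")
        .read_text()
    )
    blocks = _parse_site_file(text)
    pwm35 = build_pwm("minus35", blocks["minus35"], background=background)
    pwm_ext10 = build_pwm("extended_minus10", blocks["extended_minus10"],
                          background=background)
    pwm10 = build_pwm(
        "minus10",
        [s[-WIDTH_MINUS10:] for s in blocks["extended_minus10"]],
        background=background,
    )
    spacer = SpacerWeights.from_lengths([int(x) for x in blocks["spacer_lengths"]])
    if threshold is None:
        threshold = float(blocks["default_threshold"][0])
    return PromoterModel(pwm35, pwm_ext10, pwm10, spacer, threshold, tss_offset)
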