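"""Local pairwise alignment with suboptimal, non-overlapping hits.

Anti-repeat detection needs more than the single best local alignment: one
intergenic region can encode several repeat-homology segments, so after the
best Smith-Waterman hit is reported its subject span is masked and the
search repeats, up to ``max_hits`` per strand.  Scores use an affine gap
model (Gotoh); a gap of length L costs ``gap_open + L * gap_extend``.

The per-column normalized score (raw score divided by the number of
alignment columns) makes hits of different lengths comparable under a
single threshold, which is how the repeat-homology search is thresholded
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import revcomp

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    """Column scores for local alignment.

    Defaults (+1/-1, gap open -2, extend -1) keep the normalized score in
    [-1, +1] so it reads as a per-column identity-like score.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise AlignmentError("match score must be positive")
        if self.mismatch >= 0:
            raise AlignmentError("mismatch score must be negative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("gap penalties must be <= 0")


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a query against a subject.

    ``subject_span`` is always expressed in forward-strand coordinates of
    the subject, regardless of ``subject_strand``; minus-strand CIGARs read
    along the minus strand.
    """

    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    subject_strand: str
    raw_score: float
    aligned_columns: int
    cigar: str

    @property
    def normalized_score(self) -> float:
        return self.raw_score / self.aligned_columns


def _sw_fill(q, s, mask, match, mismatch, go, ge, H, E, F, PH, PE, PF):
    n = q.shape[0]
    m = s.shape[0]
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if mask[j - 1]:
                H[i, j] = 0.0
                E[i, j] = -1e30
                F[i, j] = -1e30
                PH[i, j] = 0
                continue
            e_open = H[i, j - 1] + go + ge
            e_ext = E[i, j - 1] + ge
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                PE[i, j] = 1
            f_open = H[i - 1, j] + go + ge
            f_ext = F[i - 1, j] + ge
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                PF[i, j] = 1
            sub = match if q[i - 1] == s[j - 1] else mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _sw_fill_fast = njit(cache=True)(_sw_fill)
except Exception:  # pragma: no cover
    _sw_fill_fast = _sw_fill


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _smith_waterman(
    query: str,
    subject: str,
    params: AlignmentParams,
    mask: np.ndarray,
) -> LocalAlignment | None:
    """Best local alignment avoiding masked subject positions, or None."""
    n, m = len(query), len(subject)
    q = _encode(query)
    s = _encode(subject)
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), -1e30, dtype=np.float64)
    F = np.full((n + 1, m + 1), -1e30, dtype=np.float64)
    PH = np.zeros((n + 1, m + 1), dtype=np.int8)
    PE = np.zeros((n + 1, m + 1), dtype=np.int8)
    PF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best, bi, bj = _sw_fill_fast(
        q, s, mask, params.match, params.mismatch,
        params.gap_open, params.gap_extend, H, E, F, PH, PE, PF,
    )
    if best <= 0.0:
        return None
    # Traceback through the three Gotoh state matrices.
    ops: list[str] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                ops.append("M")
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("I")
            from_open = PE[i, j] == 0
            j -= 1
            if from_open:
                state = "H"
        else:  # F
            ops.append("D")
            from_open = PF[i, j] == 0
            i -= 1
            if from_open:
                state = "H"
    ops.reverse()
    cigar_parts: list[str] = []
    run_op = ops[0]
    run_len = 0
    for op in ops:
        if op == run_op:
            run_len += 1
        else:
            cigar_parts.append(f"{run_len}{run_op}")
            run_op = op
            run_len = 1
    cigar_parts.append(f"{run_len}{run_op}")
    return LocalAlignment(
        query_span=(i, bi),
        subject_span=(j, bj),
        subject_strand="+",
        raw_score=float(best),
        aligned_columns=len(ops),
        cigar="".join(cigar_parts),
    )


def _strand_hits(
    query: str,
    subject: str,
    params: AlignmentParams,
    max_hits: int,
) -> list[LocalAlignment]:
    mask = np.zeros(len(subject), dtype=np.uint8)
    hits: list[LocalAlignment] = []
    for _ in range(max_hits):
        aln = _smith_waterman(query, subject, params, mask)
        if aln is None:
            break
        hits.append(aln)
        ss, se = aln.subject_span
        mask[ss:se] = 1
    return hits


def local_align(
    query: str,
    subject: str,
    params: AlignmentParams | None = None,
    max_hits: int = 5,
) -> list[LocalAlignment]:
    """Best plus suboptimal local alignments on both subject strands.

    Suboptimal hits are found by masking each reported subject span and
    re-running, so reported spans never overlap on the same strand.
    Minus-strand hits are mapped back to forward subject coordinates.
    Results are sorted by raw score, descending (ties: leftmost, + first).

    Parameters
    ----------
    query, subject : str
        Non-empty DNA sequences.
    params : AlignmentParams, optional
    max_hits : int
        Maximum hits reported per strand.
    """
    if not query or not subject:
        raise AlignmentError("empty sequence in local alignment")
    params = params or AlignmentParams()
    m = len(subject)
    hits = _strand_hits(query, subject, params, max_hits)
    for aln in _strand_hits(query, revcomp(subject), params, max_hits):
        ss, se = aln.subject_span
        hits.append(
            LocalAlignment(
                query_span=aln.query_span,
                subject_span=(m - se, m - ss),
                subject_strand="-",
                raw_score=aln.raw_score,
                aligned_columns=aln.aligned_columns,
                cigar=aln.cigar,
            )
        )
    hits.sort(key=lambda a: (-a.raw_score, a.subject_span[0], a.subject_strand))
    return hits
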