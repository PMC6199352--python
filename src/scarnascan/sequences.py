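"""Nucleotide sequence primitives shared by all modules.

All internal work uses the DNA alphabet {A, C, G, T}; RNA input (U) is
normalized to T at load time, and transcript sequences are derived on
demand.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
VALID_BASES = frozenset("ACGT")


class SequenceError(ValueError):
    """Raised for alphabet or coordinate violations."""


def normalize(raw: str) -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceError(f"invalid residues {sorted(bad)} in sequence")
    return seq


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence with a text label."""

    id: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        norm = normalize(self.residues)
        if not norm:
            raise SequenceError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(id=self.id + "_rc", residues=revcomp(self.residues))


def interval_ok(start: int, end: int, length: int) -> bool:
    return 0 <= start < end <= length


def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the overlap of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
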