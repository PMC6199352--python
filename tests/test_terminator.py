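"""Hairpin enumeration, nearest-neighbor scoring and terminator calls."""

import json
from importlib import resources

import numpy as np
import pytest

from scarnascan.sequences import revcomp
from scarnascan.terminator import (
    Hairpin,
    TerminatorConfig,
    TerminatorError,
    _enumerate_in,
    enumerate_hairpins,
    find_terminators,
    hairpin_delta_g,
    u_score,
)
from scarnascan.synthetic import design_terminator

from conftest import random_dna

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}


def _pairs(a, b):
    return (a, b) in WC or (a, b) in GU


def oracle_hairpins(seq, min_stem=4, min_loop=3, max_loop=13, max_span=50):
    """Exhaustive (position, stem, loop) partition enumeration oracle."""
    n = len(seq)
    found = set()
    for i in range(n):
        for stem in range(min_stem, n // 2 + 1):
            for loop in range(min_loop, max_loop + 1):
                span = 2 * stem + loop
                j = i + span
                if j > n or span > max_span or span < 11:
                    continue
                if not all(_pairs(seq[i + k], seq[j - 1 - k]) for k in range(stem)):
                    continue
                # maximal inward: loop cannot shrink further
                if loop - 2 >= min_loop and _pairs(seq[i + stem], seq[j - 1 - stem]):
                    continue
                # maximal outward: no extension within bounds and frame cap
                if (
                    i - 1 >= 0
                    and j < n
                    and span + 2 <= max_span
                    and _pairs(seq[i - 1], seq[j])
                ):
                    continue
                found.add((i, j, stem, loop))
    return found


def oracle_delta_g(hairpin: Hairpin, seq: str) -> float:
    """Hand-summation of the shipped parameter table, read directly."""
    params = json.loads(
        resources.files("scarnascan.data").joinpath("nn_params.json").read_text()
    )
    total = params["hairpin_loop"][str(hairpin.loop_length)]
    stem = list(hairpin.stem_pairs)
    for (i1, j1, _), (i2, j2, _) in zip(stem, stem[1:]):
        total += params["stack"][f"{seq[i1]}{seq[i2]}/{seq[j1]}{seq[j2]}"]
    return total


class TestEnumeration:
    def test_designed_stem_loop_found_exactly(self):
        hits = enumerate_hairpins("GGGGCAAAAGCCCC")
        assert len(hits) == 1
        (hp,) = hits
        assert hp.span == (0, 14)
        assert hp.stem_length == 5
        assert hp.loop_span == (5, 9)
        assert hp.gc_pairs == 5

    def test_unstructured_sequence_yields_nothing(self):
        assert enumerate_hairpins("AAAAAAAAAAAAAAA") == []

    def test_window_length_outside_frame_rejected(self):
        with pytest.raises(TerminatorError):
            enumerate_hairpins("ACGTACGTAC")  # 10 < 11
        with pytest.raises(TerminatorError):
            enumerate_hairpins("A" * 51)

    def test_matches_exhaustive_partition_oracle_on_random_sequences(self):
        rng = np.random.default_rng(55)
        for _ in range(500):
            n = int(rng.integers(11, 31))
            seq = random_dna(rng, n, gc=0.5)
            ours = {
                (h.span[0], h.span[1], h.stem_length, h.loop_length)
                for h in _enumerate_in(seq, 0, n, 4, 3, 13, 50, True)
            }
            assert ours == oracle_hairpins(seq)


class TestDeltaG:
    def test_matches_hand_summation_oracle(self):
        rng = np.random.default_rng(60)
        checked = 0
        while checked < 60:
            seq = random_dna(rng, 30, gc=0.6)
            for hp in _enumerate_in(seq, 0, 30, 4, 3, 13, 50, True):
                assert hairpin_delta_g(hp, seq) == pytest.approx(
                    oracle_delta_g(hp, seq)
                )
                checked += 1

    def test_scoring_is_deterministic(self):
        hits = enumerate_hairpins("GGGGCAAAAGCCCC")
        a = hairpin_delta_g(hits[0], "GGGGCAAAAGCCCC")
        b = hairpin_delta_g(hits[0], "GGGGCAAAAGCCCC")
        assert a == b < 0

    def test_three_pair_stem_is_rejected_before_scoring(self):
        bogus = Hairpin(
            span=(0, 11),
            stem_pairs=((0, 10, "WC"), (1, 9, "WC"), (2, 8, "WC")),
            loop_span=(3, 8),
            gc_pairs=3,
        )
        with pytest.raises(TerminatorError):
            hairpin_delta_g(bogus, "GGGAAAAATCCC")

    def test_replacing_at_pair_with_gc_never_destabilizes(self):
        rng = np.random.default_rng(61)
        tested = 0
        while tested < 40:
            seq = random_dna(rng, 24, gc=0.5)
            for hp in _enumerate_in(seq, 0, 24, 4, 3, 13, 50, True):
                at_pairs = [
                    (i, j) for i, j, kind in hp.stem_pairs
                    if kind == "WC" and seq[i] in "AT"
                ]
                for i, j in at_pairs:
                    chars = list(seq)
                    chars[i] = "G" if seq[i] == "A" else "C"
                    chars[j] = "C" if chars[i] == "G" else "G"
                    stabilized = "".join(chars)
                    assert hairpin_delta_g(hp, stabilized) <= hairpin_delta_g(
                        hp, seq
                    ) + 1e-9
                    tested += 1


class TestUScore:
    def test_all_u_tail_maximizes_and_all_a_negates(self):
        expected = sum(0.9**i for i in range(15))
        assert u_score("T" * 15)[0] == pytest.approx(expected)
        assert u_score("A" * 15)[0] == pytest.approx(-expected)
        assert expected == pytest.approx(7.941, abs=1e-3)

    def test_empty_tail_scores_zero_with_flag(self):
        score, empty = u_score("")
        assert score == 0.0 and empty

    def test_equals_position_by_position_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            tail = random_dna(rng, int(rng.integers(1, 16)))
            expected = sum(
                (1 if b == "T" else -1) * 0.9**i for i, b in enumerate(tail)
            )
            assert u_score(tail)[0] == pytest.approx(expected)


class TestFindTerminators:
    def _planted(self, rng, dg=-10.0, u_frac=1.0):
        design = design_terminator(dg, 4, u_frac, rng)
        seq = random_dna(rng, 60) + "C" + design.sequence + random_dna(rng, 60)
        start = 61
        hairpin_span = (start, start + design.hairpin_span[1])
        return seq, hairpin_span, design

    def test_planted_canonical_terminator_found_once(self):
        rng = np.random.default_rng(83)
        seq, span, design = self._planted(rng)
        preds = find_terminators(seq, (0, len(seq)))
        plus = [p for p in preds if p.strand == "+"]
        assert len(plus) == 1
        assert plus[0].span == span
        assert plus[0].hairpin.delta_g == pytest.approx(design.delta_g)
        assert plus[0].u_score == pytest.approx(design.u_score)

    def test_marginal_hairpin_fails_the_free_energy_cutoff(self):
        rng = np.random.default_rng(89)
        # 4 G:C pairs over a 4-nt loop: stable, but above the -6 cutoff
        hairpin = "GCGCAACAGCGC"
        (hp,) = enumerate_hairpins(hairpin)
        dg = hairpin_delta_g(hp, hairpin)
        assert -6.0 < dg < 0
        seq = random_dna(rng, 50) + "C" + hairpin + "T" * 15 + random_dna(rng, 50)
        span = (51, 51 + len(hairpin))
        strict = find_terminators(seq, (0, len(seq)))
        assert all(p.span != span for p in strict)
        relaxed = find_terminators(
            seq, (0, len(seq)), cfg=TerminatorConfig(dg_cutoff=dg)
        )
        assert any(p.span == span for p in relaxed)

    def test_u_poor_tail_fails_the_u_score_cutoff(self):
        rng = np.random.default_rng(97)
        seq, span, design = self._planted(rng, u_frac=0.0)
        assert design.u_score < -2.3
        preds = find_terminators(seq, (0, len(seq)))
        assert all(p.span != span for p in preds)

    def test_overlapping_candidates_resolved_by_better_delta_g(self):
        from scarnascan.terminator import _scan_strand

        rng = np.random.default_rng(101)
        cfg = TerminatorConfig()
        for _ in range(20):
            seq = random_dna(rng, 300, gc=0.6)
            reported = [
                p for p in find_terminators(seq, (0, 300), cfg=cfg)
                if p.strand == "+"
            ]
            spans = sorted(p.span for p in reported)
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                assert e0 <= s1  # pairwise non-overlapping on a strand
            # every passing candidate is either reported or overlapped by a
            # reported terminator with an equal-or-better free energy
            for hp, dg, _tail, _score, _tr in _scan_strand(seq, cfg):
                covered = [
                    p for p in reported
                    if min(p.span[1], hp.span[1]) > max(p.span[0], hp.span[0])
                ]
                assert covered
                assert min(p.hairpin.delta_g for p in covered) <= dg + 1e-9

    def test_strand_symmetry_is_exact(self):
        rng = np.random.default_rng(103)
        seq, _, _ = self._planted(rng)
        fwd = find_terminators(seq, (0, len(seq)))
        rev = find_terminators(revcomp(seq), (0, len(seq)))
        n = len(seq)
        fwd_set = {
            (p.strand, p.span, round(p.hairpin.delta_g, 6), round(p.u_score, 6))
            for p in fwd
        }
        mirrored = {
            ("-" if p.strand == "+" else "+", (n - p.span[1], n - p.span[0]),
             round(p.hairpin.delta_g, 6), round(p.u_score, 6))
            for p in rev
        }
        assert fwd_set == mirrored

    @pytest.mark.parametrize(
        "loose",
        [
            {"dg_cutoff": -4.0},
            {"u_cutoff": -4.0},
            {"min_gc": 2},
        ],
    )
    def test_relaxing_any_cutoff_yields_a_superset(self, loose):
        rng = np.random.default_rng(107)
        seq = random_dna(rng, 400, gc=0.55)
        strict = {
            (p.span, p.strand) for p in find_terminators(seq, (0, 400))
        }
        relaxed = {
            (p.span, p.strand)
            for p in find_terminators(seq, (0, 400), cfg=TerminatorConfig(**loose))
        }
        assert strict <= relaxed
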