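"""Weight matrices, configuration scoring, scanning and calibration."""

import math

import numpy as np
import pytest

from scarnascan.promoter import (
    EXT10_CONTEXT,
    WIDTH_MINUS35,
    WIDTH_MINUS10,
    PromoterError,
    SpacerWeights,
    build_pwm,
    calibrate_tss_threshold,
    load_default_model,
    pwm_to_jaspar,
    realign_sites,
    scan_region_for_tss,
    score_promoter_configuration,
    score_window,
)
from scarnascan.sequences import revcomp
from scarnascan.synthetic import sample_promoter

from conftest import random_dna

UNIFORM = (0.25, 0.25, 0.25, 0.25)


class TestBuildPwm:
    def test_identical_sites_give_log2_3_at_consensus(self):
        pwm = build_pwm("minus35", ["TTGACA"] * 4, pseudocount=0.5,
                        background=UNIFORM)
        # (4 + 0.5) / (4 + 4*0.5) / 0.25 = 3
        for c, base in enumerate("TTGACA"):
            i = "ACGT".index(base)
            assert pwm.weights[c, i] == pytest.approx(math.log2(3))

    def test_site_with_ambiguous_base_rejected_or_dropped(self):
        with pytest.raises(PromoterError):
            build_pwm("minus35", ["TTGACA", "TTGNCA", "TTGACA"])
        pwm = build_pwm("minus35", ["TTGACA", "TTGNCA", "TTGACA"],
                        on_invalid="drop")
        assert pwm.counts.sum() == 2 * 6

    def test_unequal_site_lengths_rejected(self):
        with pytest.raises(PromoterError):
            build_pwm("minus35", ["TTGACA", "TTGAC"])


def test_score_window_equals_per_column_summation_oracle(model):
    rng = np.random.default_rng(8)
    for pwm in (model.pwm35, model.pwm_ext10, model.pwm10):
        for _ in range(20):
            window = random_dna(rng, pwm.width, gc=0.5)
            expected = sum(
                pwm.weights[c, "ACGT".index(b)] for c, b in enumerate(window)
            )
            assert score_window(pwm, window) == pytest.approx(expected)


def test_consensus_attains_the_maximum_and_substitutions_never_help(model):
    for pwm in (model.pwm35, model.pwm_ext10, model.pwm10):
        consensus = pwm.consensus
        top = score_window(pwm, consensus)
        assert top == pytest.approx(pwm.max_score)
        for c in range(pwm.width):
            for b in "ACGT":
                if b == consensus[c]:
                    continue
                mutated = consensus[:c] + b + consensus[c + 1 :]
                assert score_window(pwm, mutated) <= top + 1e-12


def test_spacer_weights_require_contiguous_lengths():
    with pytest.raises(PromoterError):
        SpacerWeights({15: -1.0, 18: -2.0})
    sw = SpacerWeights.from_lengths([17, 17, 17, 16, 18])
    assert set(sw.allowed) == {16, 17, 18}
    assert sw.weight(17) > sw.weight(16)


class TestConfigurationScoring:
    def test_consensus_configuration_sums_the_three_maxima(self, model):
        spacer = max(model.spacer.weights, key=lambda k: model.spacer.weights[k])
        seq = (
            model.pwm35.consensus
            + "A" * (spacer - EXT10_CONTEXT)
            + model.pwm_ext10.consensus
        )
        total, short = score_promoter_configuration(seq, 0, spacer, model)
        assert not short
        assert total == pytest.approx(model.max_score)

    def test_out_of_range_spacer_rejected(self, model):
        seq = "A" * 60
        bad = max(model.spacer.allowed) + 1
        with pytest.raises(PromoterError):
            score_promoter_configuration(seq, 0, bad, model)

    def test_all_configurations_match_exhaustive_enumeration_oracle(self, model):
        rng = np.random.default_rng(13)
        seq = random_dna(rng, 120)
        for pos35 in range(0, 60):
            for spacer in model.spacer.allowed:
                h = pos35 + WIDTH_MINUS35 + spacer
                if h + WIDTH_MINUS10 > len(seq):
                    continue
                expected = (
                    score_window(model.pwm35, seq[pos35 : pos35 + WIDTH_MINUS35])
                    + model.spacer.weight(spacer)
                    + score_window(
                        model.pwm_ext10,
                        seq[h - EXT10_CONTEXT : h + WIDTH_MINUS10],
                    )
                )
                got, _ = score_promoter_configuration(seq, pos35, spacer, model)
                assert got == pytest.approx(expected)


class TestScan:
    def test_planted_minus_strand_promoter_recovered_at_its_tss(self, model):
        rng = np.random.default_rng(17)
        design = sample_promoter(model, 3.0, rng)
        region = (
            random_dna(rng, 80) + revcomp(design.sequence) + random_dna(rng, 80)
        )
        preds = scan_region_for_tss(region, model, offset=500)
        minus = [p for p in preds if p.strand == "-"]
        assert len(minus) >= 1
        expected_tss = 500 + 80 - model.tss_offset
        assert any(p.tss_position == expected_tss for p in minus)

    def test_unreachable_threshold_gives_empty_scan(self, model):
        rng = np.random.default_rng(19)
        region = random_dna(rng, 300)
        assert scan_region_for_tss(region, model, threshold=1e6) == []

    def test_scan_of_reverse_complement_mirrors_predictions(self, model):
        rng = np.random.default_rng(23)
        for _ in range(10):
            region = random_dna(rng, 250)
            fwd = scan_region_for_tss(region, model, threshold=8.0)
            rev = scan_region_for_tss(revcomp(region), model, threshold=8.0)
            n = len(region)
            fwd_set = {
                (p.strand, p.tss_position, round(p.score, 6)) for p in fwd
            }
            mirrored = {
                ("-" if p.strand == "+" else "+", n - 1 - p.tss_position,
                 round(p.score, 6))
                for p in rev
            }
            assert fwd_set == mirrored

    def test_higher_threshold_predictions_are_a_subset(self, model):
        rng = np.random.default_rng(29)
        region = random_dna(rng, 400)
        low = scan_region_for_tss(region, model, threshold=6.0)
        high = scan_region_for_tss(region, model, threshold=10.0)
        low_keys = {(p.strand, p.tss_position) for p in low}
        high_keys = {(p.strand, p.tss_position) for p in high}
        assert high_keys <= low_keys


class TestCalibration:
    def _training_region(self, model, rng, margin):
        design = sample_promoter(model, margin, rng)
        region = random_dna(rng, 60) + design.sequence + random_dna(rng, 60)
        tss = 60 + len(design.sequence) - 1 + model.tss_offset
        return region, tss

    def test_threshold_is_minimum_over_curated_promoters(self, model):
        rng = np.random.default_rng(31)
        training = []
        scores = []
        for margin in (5.0, 2.0, 3.5):
            region, tss = self._training_region(model, rng, margin)
            preds = scan_region_for_tss(region, model, threshold=-1e9)
            scores.append(
                max(p.score for p in preds
                    if p.strand == "+" and abs(p.tss_position - tss) <= 3)
            )
            training.append((region, 0, [(tss, "+")]))
        assert calibrate_tss_threshold(training, model) == pytest.approx(
            min(scores)
        )
        # single training locus: that locus' own minimum
        assert calibrate_tss_threshold(training[:1], model) == pytest.approx(
            scores[0]
        )

    def test_unrecoverable_curated_promoter_raises(self, model):
        rng = np.random.default_rng(37)
        region = random_dna(rng, 200)
        with pytest.raises(PromoterError, match="not recoverable"):
            calibrate_tss_threshold([(region, 0, [(5000, "+")])], model)


def test_realign_sites_recovers_shifted_consensus():
    rng = np.random.default_rng(41)
    core = "TTGACA"
    sites = []
    for _ in range(30):
        shift = int(rng.integers(0, 5))
        flanked = random_dna(rng, shift) + core + random_dna(rng, 4 - shift)
        sites.append(flanked)
    realigned = realign_sites(sites, "minus35", shift=2)
    # at least the central columns should be strongly enriched after realignment
    pwm = build_pwm("minus35", realigned, background=UNIFORM)
    assert score_window(pwm, pwm.consensus) > 6.0


def test_jaspar_export_contains_count_rows(model):
    text = pwm_to_jaspar(model.pwm35, "M35")
    assert text.startswith(">M35 minus35")
    assert sum(line.startswith(("A", "C", "G", "T")) for line in text.splitlines()) == 4
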