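"""Unit assembly, array orientation, classification and reports."""

import numpy as np
import pytest

from scarnascan.align import LocalAlignment
from scarnascan.assembly import (
    OrientationCall,
    assemble_units,
    build_report,
    classify_small_rna,
    detect_sgrna_like,
    infer_array_orientation,
    report_to_json,
    report_to_tsv,
)
from scarnascan.locus import IntergenicRegion
from scarnascan.pipeline import predict_locus
from scarnascan.promoter import TssPrediction
from scarnascan.repeats import RepeatHit
from scarnascan.sequences import revcomp
from scarnascan.terminator import Hairpin, TerminatorPrediction

from conftest import random_dna


def tss(pos, strand, score=18.0, region="ig"):
    return TssPrediction(region, strand, pos, (pos - 30, pos - 24),
                         (pos - 13, pos - 7), 17, score)


def term(start, end, strand, dg=-9.0, region="ig"):
    hp = Hairpin(span=(start, end), stem_pairs=(), loop_span=(start, end),
                 gc_pairs=4, delta_g=dg)
    return TerminatorPrediction(region, strand, hp, "T" * 15, 7.0, True)


def hit(span, strand="+", norm=0.9, region="ig"):
    cols = span[1] - span[0]
    aln = LocalAlignment((0, cols), span, strand, norm * cols, cols, f"{cols}M")
    return RepeatHit(region, aln, norm, True, False)


REGION = IntergenicRegion("ig", (0, 600), (0, 615), "a", "b")


class TestAssembleUnits:
    def test_hit_between_signals_forms_one_unit(self):
        units, loose = assemble_units(
            REGION, [hit((150, 185))], [tss(100, "+")], [term(220, 240, "+")]
        )
        assert not loose
        (u,) = units
        assert u.strand == "+"
        assert u.body_span == (100, 240)
        assert not u.read_through

    def test_missing_terminator_gives_read_through_to_region_edge(self):
        units, _ = assemble_units(REGION, [hit((150, 185))], [tss(100, "+")], [])
        (u,) = units
        assert u.read_through
        assert u.body_span == (100, 600)

    def test_terminator_only_upstream_leaves_hit_unattached(self):
        units, loose = assemble_units(
            REGION, [hit((150, 185))], [], [term(50, 80, "+")]
        )
        assert units == [] and len(loose) == 1

    def test_hits_sharing_signals_merge_into_one_unit(self):
        units, _ = assemble_units(
            REGION,
            [hit((150, 185)), hit((200, 235), strand="-")],
            [tss(100, "+")],
            [term(280, 300, "+")],
        )
        (u,) = units
        assert len(u.contained_hits) == 2

    def test_minus_strand_geometry_mirrors(self):
        units, _ = assemble_units(
            REGION, [hit((300, 335))], [tss(420, "-")], [term(200, 230, "-")]
        )
        (u,) = units
        assert u.strand == "-"
        assert u.body_span == (200, 421)

    def test_signals_beyond_the_gap_limits_do_not_attach(self):
        units, loose = assemble_units(
            REGION, [hit((500, 535))], [tss(100, "+")], [],
            max_tss_gap=300,
        )
        assert units == [] and len(loose) == 1


class TestOrientation:
    def _locus(self, make_locus):
        locus, _ = make_locus("IIB_fnovicida_like", 7)
        return locus

    def test_minus_promoter_downstream_of_array_supports_minus(self, make_locus):
        locus = self._locus(make_locus)
        a1 = locus.array.span[1]
        call = infer_array_orientation(locus, [tss(a1 + 40, "-")], [])
        assert call.strand == "-"
        assert not call.tie_break_used

    def test_no_flanking_signals_is_ambiguous(self, make_locus):
        locus = self._locus(make_locus)
        call = infer_array_orientation(locus, [], [])
        assert call.strand == "ambiguous"

    def test_double_support_resolved_by_promoter_score(self, make_locus):
        locus = self._locus(make_locus)
        a0, a1 = locus.array.span
        call = infer_array_orientation(
            locus,
            [tss(a0 - 50, "+", score=15.0), tss(a1 + 50, "-", score=19.0)],
            [],
        )
        assert call.strand == "-"
        assert call.tie_break_used


class TestClassification:
    def _unit_for(self, make_locus, template, seed, cls):
        locus, truth = make_locus(template, seed)
        report = predict_locus(locus)
        match = [p for p in report.predictions if p.rna_class == cls]
        assert match, f"no {cls} predicted"
        return locus, report, match[0]

    def test_iib_layout_gives_sense_scarna_and_antisense_tracrrna(
        self, make_locus
    ):
        locus, report, sca = self._unit_for(
            make_locus, "IIB_fnovicida_like", 19, "scaRNA"
        )
        assert sca.sense_to_array_transcript is True
        tracr = next(
            p for p in report.predictions if p.rna_class == "tracrRNA"
        )
        assert tracr.sense_to_array_transcript is False
        # scaRNA upstream of the array in the minus reading (right side)
        assert sca.unit.body_span[0] >= locus.array.span[1]
        assert tracr.unit.body_span[1] <= locus.array.span[0]

    def test_ambiguous_orientation_leaves_units_unclassified(self, make_locus):
        locus, _ = make_locus("IIB_fnovicida_like", 19)
        report = predict_locus(locus)
        unit = report.predictions[0].unit
        pred = classify_small_rna(
            unit,
            OrientationCall("ambiguous", ()),
            locus.array.repeat_forward.residues,
            locus.sequence.residues,
        )
        assert pred.rna_class == "unclassified"
        assert pred.sense_to_array_transcript is None

    def test_unit_without_hits_cannot_be_classified(self, make_locus):
        locus, _ = make_locus("IIB_fnovicida_like", 19)
        report = predict_locus(locus)
        from dataclasses import replace

        unit = replace(report.predictions[0].unit, contained_hits=())
        with pytest.raises(ValueError):
            classify_small_rna(
                unit,
                report.array_orientation,
                locus.array.repeat_forward.residues,
                locus.sequence.residues,
            )


class TestSgRnaDetection:
    def test_overlapping_hits_reclass_to_sgrna_like(self, make_locus):
        locus, truth = make_locus("sgRNA_like", 23)
        report = predict_locus(locus)
        sg = [p for p in report.predictions if p.rna_class == "sgRNA_like"]
        assert len(sg) == 1
        spans = [h.span for h in sg[0].unit.contained_hits]
        assert len(spans) == 2
        assert min(s[1] for s in spans) > max(s[0] for s in spans)  # overlap

    def test_three_prime_tail_annotated_with_three_hairpins(self, make_locus):
        locus, _ = make_locus("sgRNA_like", 23)
        report = predict_locus(locus)
        (sg,) = [p for p in report.predictions if p.rna_class == "sgRNA_like"]
        assert sg.structure_annotation is not None
        assert len(sg.structure_annotation) >= 3
        assert "tracrRNA-like 3' tail" in sg.notes

    def test_single_hit_units_keep_their_class(self, make_locus):
        locus, _ = make_locus("IIB_fnovicida_like", 23)
        report = predict_locus(locus)
        classes = {p.rna_class for p in report.predictions}
        assert classes == {"scaRNA", "tracrRNA"}


class TestReport:
    def test_two_runs_are_byte_identical(self, make_locus):
        locus, _ = make_locus("IIB_fnovicida_like", 29)
        r1 = predict_locus(locus, seed=5)
        r2 = predict_locus(locus, seed=5)
        assert report_to_tsv(r1) == report_to_tsv(r2)
        assert report_to_json(r1) == report_to_json(r2)

    def test_empty_prediction_set_is_a_valid_report(self, make_locus):
        locus, _ = make_locus("IIB_fnovicida_like", 29)
        report = build_report(locus, OrientationCall("ambiguous", ()), [], [],
                              [], [], [], [], {})
        assert report.predictions == ()
        assert report_to_tsv(report).count("\n") == 1  # header only

    def test_report_referencing_foreign_signals_is_rejected(self, make_locus):
        locus, _ = make_locus("IIB_fnovicida_like", 29)
        report = predict_locus(locus)
        with pytest.raises(ValueError, match="unknown TSS"):
            build_report(
                locus,
                report.array_orientation,
                list(report.predictions),
                list(report.repeat_hits),
                [],  # drop the TSS list the predictions reference
                list(report.terminator_predictions),
                [],
                [],
                {},
            )
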