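# scarnascan

Ab initio prediction of CRISPR/Cas-associated small regulatory RNAs —
scaRNA, tracrRNA and sgRNA-like units — inside Type II CRISPR/Cas loci,
directly from genome sequence.

## The problem

Type II CRISPR/Cas systems require small RNAs encoded outside the CRISPR
array. The tracrRNA carries an *anti-repeat* (complementary to the array
transcript's repeat) and scaffolds Cas9 recruitment; the scaRNA carries
repeat sequence in the *same* sense as the array transcript and, paired
with tracrRNA, can redirect Cas9 to endogenous mRNAs — a non-canonical
activity linked to bacterial virulence. RNA-Seq coverage across bacteria
is far too sparse to find these molecules systematically, but they leave
a recognizable genomic signature: a segment homologous to the array
direct repeat, bracketed by a sigma-70 promoter upstream and a
Rho-independent terminator downstream. `scarnascan` detects that
signature and classifies the resulting transcription units.

## The method

For a locus (sequence + annotations of cas genes, the CRISPR array and
flanking genes), the search runs over intergenic regions of ≥ 50 bp
(both strands), with each region extended 15 bp downstream for the
terminator scan:

1. **Repeat homology.** Smith–Waterman local alignment (affine gaps,
   Gotoh) of the array direct repeat against each region, on both
   strands, reporting suboptimal non-overlapping hits. Scores are
   normalized per alignment column (match +1, mismatch −1, gaps
   −2 − L), so one threshold applies to hits of any length. When fewer
   than two alignments reach the threshold *t*, the next-best distinct
   alignment is rescued if it scores ≥ 0.8 *t*. Closely spaced hit pairs
   (gap 20–60 bp, the size of a spacer) and hits with further homology
   between themselves and the array are rejected as putative degenerate
   array remnants.
2. **Promoters.** Position weight matrices for the −35 element and an
   extended −10 element (15 columns: 9 nt of TG-extension context + the
   −10 hexamer), with additive log-frequency weights for the 15–19 bp
   spacer: score = S₋₃₅ + w(spacer) + S₋₁₀ᵉˣᵗ, TSS placed 7 nt
   downstream of the −10 hexamer.
3. **Terminators.** All maximal single stem-loops within 11–50 bp
   frames, scored with nearest-neighbor RNA free energies; a terminator
   requires ΔG ≤ −6 kcal/mol, a stem of ≥ 4 pairs with ≥ 3 G:C pairs,
   and a U-score ≥ −2.3 over the 15 nt downstream tail. Overlapping
   candidates resolve to the better ΔG.
4. **Assembly and classification.** The array's transcription
   orientation is inferred from the promoter/terminator layout of its
   flanking regions. Each repeat-homology segment is attached to its
   nearest same-strand upstream TSS and downstream terminator; a unit
   whose transcript aligns to the array transcript's repeat is a
   **scaRNA**, to its reverse complement a **tracrRNA**; a unit with two
   overlapping repeat segments is **sgRNA-like** and its 3' tail is
   annotated with successive stem-loops. Units lacking a terminator are
   flagged read-through (possible co-transcription with the array).

Both search thresholds are calibratable: given training loci with
curated units, each threshold is set to the minimum score over the
curated true signals, so every curated unit is reproduced.

A seeded synthetic-locus generator (`scarnascan.synthetic`) plants
promoters sampled from the promoter model, designed hairpin+U-tail
terminators, CRISPR arrays built from real direct repeats, and
repeat-homology segments in the canonical Type II locus architectures,
with ground-truth annotations — so the entire pipeline is testable
without downloads.

## Worked example

Simulate a Type IIB-architecture locus (everything on the minus strand,
scaRNA upstream and tracrRNA downstream of the array) and run the
predictor on it:

```bash
$ scarnascan simulate --template IIB_fnovicida_like --seed 7 --out sim
synthetic_IIB_fnovicida_like_7 (2078 bp) -> sim

$ scarnascan predict --fasta sim/locus.fasta --features sim/locus.gff3 \
      --seed 7 --out pred
synthetic_IIB_fnovicida_like_7: array orientation -, 2 small RNA unit(s) -> pred

$ cat pred/predictions.tsv
locus	rna_class	strand	start	end	tss	terminator_start	read_through	sense_to_array	notes
synthetic_IIB_fnovicida_like_7	tracrRNA	-	404	500	499	404	0	0	.
synthetic_IIB_fnovicida_like_7	scaRNA	-	959	1056	1055	959	0	1	.
```

The array (at 628–871 here) is called minus-oriented from its flanking
promoter; the unit downstream of it in that reading (404–500, anti-repeat,
`sense_to_array = 0`) is the tracrRNA, and the unit upstream (959–1056,
repeat in the array-transcript sense, `sense_to_array = 1`) is the
scaRNA. Each row's `tss` and `terminator_start` give the unit's
boundaries; `pred/report.json` additionally carries every raw signal
(promoter scores, terminator ΔG and U-scores, alignment hits) and the
full configuration snapshot.

Calibration from loci with known (truth-annotated) units:

```bash
scarnascan calibrate --training sim/locus.fasta,sim/locus.gff3,sim/truth.gff3 \
    --out calibrated.yaml
scarnascan predict --fasta ... --config calibrated.yaml --out ...
```

## Scope

The tool predicts transcription units and their scaRNA / tracrRNA /
sgRNA-like classification. It does not discover CRISPR arrays de novo
(supply the array annotation, e.g. from a CRISPR-detection tool), does
not search for Cas proteins, and does not predict the mRNA targets of
scaRNA:tracrRNA:Cas9 complexes. See `docs/methods.md` for the model
details, parameter defaults and known limitations.
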