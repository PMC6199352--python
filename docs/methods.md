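# Methods

`scarnascan` predicts small CRISPR/Cas-associated regulatory RNAs in
Type II loci by jointly detecting three signals in intergenic sequence —
homology to the array direct repeat, sigma-70 (RpoD) core promoters, and
Rho-independent terminators — and assembling them into oriented
transcription units. This note records the model, every tunable that
matters, the numerical choices, what the synthetic benchmark does and
does not emulate, and the known limitations.

## Search space

The locus is a linear sequence with ordered features (cas genes, the
CRISPR array, flanking genes). Intergenic regions are the gaps of at
least `min_intergenic_len` (default **50 bp**, matching the footprint of
the shortest informative signal) between consecutive features, plus the
two flanks outside the outermost features. When a whole genome is
supplied the flanks are capped at `edge_window` (default 500 bp — a
choice, since no principled outer boundary exists without a neighboring
gene). For terminator scans each region is extended
`terminator_extension` (default **15 bp**) past its downstream edge on
each strand, the length of the U-score tail segment, so a hairpin at a
region boundary still has its tail visible. Regions carry no strand;
every scan runs on both. Circular genomes are not wrapped; an array
within 50 bp of the sequence edge triggers a warning.

Coordinates are 0-based half-open internally; GFF3 I/O converts to
1-based inclusive. All internal work uses the DNA alphabet (U→T on
input); transcript sequences are derived on demand, which keeps strand
arithmetic in one place.

## Repeat homology

Local pairwise alignment (Smith–Waterman with affine gaps, Gotoh
recursion) of the direct repeat — as written 5'→3' on the forward
genomic strand — against each region, on both strands. Suboptimal hits
are found by masking the subject span of each reported alignment and
re-running, up to `max_hits_per_region` (5) per strand, so one genomic
segment yields one hit per strand.

Scoring defaults: match **+1**, mismatch **−1**, gap of length L
**−2 − L**. With these values the per-column normalized score
(raw / aligned columns) lies in [−1, +1] and reads as an identity-like
score, which is what lets a single threshold apply to hits of any
length. The shipped fallback threshold is **0.6 per column** — a
configuration choice, not a measured constant; the calibration path
below replaces it.

Two micro-match guards: alignments shorter than `min_aligned_columns`
(10) are ignored, and alignments spanning less than `min_query_coverage`
(0.6) of the repeat are ignored. The coverage guard exists because a
per-column score alone admits short high-identity windows that occur by
chance in any sequence (an 8/10-identity window scores 0.6/column and is
expected several times per region); an anti-repeat by definition covers
a substantial fraction of the repeat, so requiring ≥ 60 % of it is a
biological constraint, not a tuning knob.

**Relaxation rule.** When fewer than two alignments in a region reach
the threshold *t*, the next highest-scoring alignment is additionally
accepted iff its normalized score ≥ (1 − `relax`) · *t*, with `relax` =
**0.20**, and is flagged `rescued_by_relaxation`. The rule is applied
per region (each region judged independently). A rescue candidate whose
span overlaps an already-accepted hit is skipped: every repeat copy
casts a weak opposite-strand echo of itself (partial palindromicity),
and re-reporting that echo would fabricate a second overlapping segment.

**Degenerate-array filters.** Within each region, pairs of hits whose
mutual gap falls in `spacing_window` (20–60 bp, the size range of a
spacer) are rejected as a putative degenerate array — when both pass the
primary threshold; in a mixed pair only the rescued partner is dropped,
since a sub-threshold echo cannot establish a degenerate array against a
genuine hit but is itself better explained as a decayed copy. A hit with
another above-threshold hit strictly between it and the array is
rejected as remnant context; this intervening-homology check applies
only in the two regions directly adjacent to the array, because array
decay cannot reach across an intervening gene. Both filters are scoped
per region: remnants of a decayed array necessarily share the
candidate's region, whereas predictions in other regions (often
separated by cas genes) are independent units and must not veto each
other.

## Promoter model

Three positional log-odds matrices: −35 (6 columns), extended −10
(15 columns) and short −10 (6 columns), built as

    weight[c][b] = log2( (count(b,c) + pc) / (N + 4·pc) / background[b] )

with pseudocount `pc` = 0.5. The extended −10 window is the 15-mer
ending at the −10 hexamer's 3' end: its 5' nine columns carry the
TG-extension context, its 3' six columns are the hexamer. A promoter
configuration is scored additively:

    S = S₋₃₅(pos) + w(spacer) + S₋₁₀ᵉˣᵗ(pos + 6 + spacer − 9)

where the spacer (15–19 bp) is the true −35→−10 gap and w(·) is the
log2 empirical spacer-length frequency in the training set
(pseudocount 0.5). With this geometry the extended window always fits
whenever the hexamer does; the short −10 matrix remains as a defensive
substitute for direct configuration scoring with out-of-bounds extended
windows. The additive combination is a declared design choice, isolated
in one function (`score_promoter_configuration`) so an alternative
functional form can be swapped in.

The TSS is placed `tss_offset` = **7 nt** downstream of the −10
hexamer's 3' end (canonical sigma-70 geometry). Scans cover both
strands; same-strand predictions whose start sites lie within 5 bp
collapse to the best-scoring one.

**Training data.** The builder accepts any aligned site collection. The
repo ships a bundled fixture of 50 *synthetic* aligned −35 and extended
−10 sites plus spacer lengths (generated once from fixed per-column base
distributions and versioned), so the model builds with no download;
importing a curated promoter collection is the supported alternative. A
greedy ±2-column realignment utility (`realign_sites`, max 10
iterations) is provided for raw site sets. The default background is an
AT-rich composition (A=T=0.30, C=G=0.20), matching the organisms this
tool targets and the synthetic generator's default; matrices are
rebuildable against any measured composition, which is how a
region-local background would be used.

**Default threshold.** The fixture file carries a fallback score
threshold set, at fixture-generation time, to the 99.9th percentile of
per-region-strand best scores on random AT-rich sequence — i.e. roughly
one spurious promoter call per thousand region-strand scans. This is
deliberately conservative: the method's real operating point comes from
calibration, and without a manual-curation step a permissive fallback
would flood locus reports with false units.

## Terminator model

Candidates are single stem-loops whose whole span fits an 11–50 bp
frame. Enumeration is by loop placement: for every loop of 3–13 nt the
stem is extended outward while bases pair (Watson–Crick plus G:U), so
each reported hairpin is maximal — extendable neither inward nor outward
within the window and frame cap. The pipeline enumerates maximal
stem-loops over the whole search span directly (span capped at 50 bp)
rather than literally sliding every 11–50 bp frame: the union over
frames of frame-maximal hairpins adds only truncated sub-stems of larger
stems, which the best-ΔG overlap resolution would discard anyway.

Free energy is a nearest-neighbor sum: stack terms over adjacent stem
pairs plus a hairpin-loop initiation penalty for the loop length, from a
Turner-2004-style RNA parameter table shipped as versioned JSON
(`data/nn_params.json`). RNA parameters are used although the input is
DNA, because termination happens on the transcript. The table is
symmetric under reading the duplex from the other end, and satisfies the
monotonicity property that replacing an A:U pair by G:C never
destabilizes a stem. Terminal-pair penalties and dangling ends are not
modelled. Bulged stems are not enumerated: natural
terminators with imperfect stems will be missed (a read-through flag
rather than a terminator), and the parameter file reserves a bulge
penalty (+3.0 kcal/mol) for a future bulge-tolerant mode.

A candidate passes iff ΔG ≤ `dg_cutoff` (**−6 kcal/mol**), stem ≥
`min_stem` (**4 pairs**) with ≥ `min_gc_pairs` (**3**) G:C pairs (G:U
pairs may occur in the stem but never count toward the G:C quota), and
the 15-nt downstream tail scores ≥ `u_cutoff` (**−2.3**). The U-score is

    U = Σᵢ δᵢ · 0.9^(i−1),  δᵢ = +1 if position i is U, else −1

over at most 15 tail positions — a geometric-decay form (proximal U's
weighted most, symmetric about zero, extremes ±7.94) standing in for the
original empirical equation, which this package does not reproduce; it
is isolated behind `u_score` and one config key so an alternative can be
dropped in. Tails truncated by the sequence end are scored over the
available length and flagged, never auto-failed. Among mutually
overlapping survivors on a strand, only the best-ΔG candidate is
reported.

## Orientation, assembly, classification

The array's transcription orientation is inferred from its flanking
regions: an orientation is supported by a promoter pointing into the
array from its 5' flank (within 1000 bp), with terminators in the 3'
flank as secondary evidence. Both orientations supported → the higher
promoter score wins (tie-break flagged); neither → ambiguous. If
ambiguity remains and exactly one orientation would let some unit
classify as a tracrRNA — the molecule required for any Type II function
— that orientation is adopted, flagged as a tie-break.

Each hit is attached, per strand, to the nearest upstream TSS within
`max_tss_gap` (300 bp) and nearest downstream terminator within
`max_term_gap` (300 bp) on that strand. The unit strand is the *signal*
strand, not the alignment strand: homology to the repeat on one strand
implies homology to its complement on the other, so only the
transcription signals can orient the unit (loci exist with the repeat
segment on the direct strand and all signals in the reverse
orientation). Hits sharing both signals merge into one unit; a hit with
a TSS but no terminator forms a read-through unit bounded by the region
edge; a hit attachable on neither strand is reported unattached. A
read-through unit abutting the array on the array's strand is annotated
`possible_cotranscription` and kept as a separate unit rather than
merged with the array.

Classification re-aligns the unit transcript (5'→3' on the unit strand)
against the array transcript's repeat reading and its reverse
complement: the better alignment decides scaRNA (sense) vs tracrRNA
(anti-sense). One rule covers all four strand combinations. The
alignment floor is (1 − relax) · repeat_threshold — consistent with
rescued hits remaining classifiable — with the same minimum-column /
coverage guard as hit detection, so a chance few-column perfect match
cannot outvote a full-length anti-repeat. Units with two overlapping
repeat segments re-class as sgRNA-like; their 3' region (last segment to
terminator) is annotated with successive non-overlapping stem-loops, and
three or more add a `tracrRNA-like 3' tail` note.

## Calibration

Given training loci with curated true units, the repeat threshold and
the TSS threshold are each set to the *minimum* score over the curated
signals (best in-unit alignment; best upstream same-strand promoter), so
that every curated unit remains recoverable — reproducing the curated
set is the thresholds' defining property, and the operation is
idempotent. A curated element with no detectable signal raises an error
naming it. The shipped fallbacks let the tool run uncalibrated, at the
conservative operating point described above.

## Synthetic benchmark

The generator emulates the canonical Type II locus architectures with
planted, truth-annotated elements: `IIB_fnovicida_like` (all components
minus-oriented; scaRNA unit upstream and tracrRNA unit downstream of the
array), `tracrRNA_only` (plus-oriented array, one anti-repeat unit near
the cas genes), `IIA_like`/`IIC_like` (scaRNA:tracrRNA pairs split
around the cas genes), `sgRNA_like` (two overlapping repeat segments —
constructed from a partially palindromic repeat, since overlap of
plus/minus homology requires self-complementarity — plus a three-hairpin
3' tail), and `custom` (caller-supplied element list). Defaults: i.i.d.
background at GC 0.40, promoters planted at 4.0 score units above
threshold, terminators designed to −10 kcal/mol with 4 G:C pairs and
all-U tails, arrays of 3 spacers of 30–36 nt. Spacers are
rejection-sampled to score below half the hit threshold against the
repeat, so arrays seed no accidental hits. Every planted promoter,
terminator and repeat segment is re-detected by the corresponding
detector before a locus is emitted, and the sgRNA-like 3' tail is
resampled until it annotates as exactly three stem-loops (adjacent
random stems can chance-pair into one larger structure). Generation is
fully deterministic under a seed.

What the benchmark does *not* emulate — and hence what passing tests do
not show about real data: compositional heterogeneity and repeats of
real genomes (background is i.i.d.), promoters not drawn from the
scanning model itself (real sensitivity depends on how well the trained
matrices match the organism's sigma-70 sites), non-L-shaped or
bulged-stem terminators, overlapping genes and mis-annotated feature
boundaries, and degenerate arrays with realistic decay patterns (the
remnant filters are exercised only by constructed cases). Recovery
statistics on synthetic loci are a correctness check of the machinery,
not an accuracy estimate for real loci.

## Numerical choices and degenerate inputs

Alignment ties resolve deterministically (first-encountered cell in
row-major order; diagonal preferred over gaps). TSS collapse keeps the
best-scoring configuration, ties broken by position. Terminator overlap
resolution sorts by (ΔG, span). Empty tails score 0 with a warning flag.
Empty intergenic-region lists, empty prediction sets and ambiguous
orientations all produce valid (possibly empty) reports; reports are
validated to reference only signals present in their raw lists, and
identical inputs yield byte-identical outputs. Seeds derived from the
user seed stay below 2³¹.

Problem sizes in the shipped verification suite — 200 random pairs for
the alignment oracle, 500 sequences ≤ 30 nt for the hairpin oracle, 100
regions for scan symmetry, 100 synthetic loci per architecture (plus 25
per degradation level) for recovery — were chosen so the whole suite
completes in well under a minute while keeping counting noise far below
the effects being checked.

## Known limitations

* The promoter and repeat thresholds shipped as fallbacks are
  configuration choices; meaningful absolute scores require calibration
  on loci with known units or a trained site collection.
* Only single stem-loop (L-shaped) intrinsic terminators are modelled;
  loci terminated by other mechanisms will show read-through flags
  rather than terminators.
* Units are assembled within one intergenic region; a unit spanning a
  feature boundary (e.g. a promoter inside an annotated gene) is not
  representable.
* Array orientation inference depends entirely on flanking signal
  predictions; weak or cryptic array promoters leave it ambiguous, and
  then classification relies on the tracrRNA tie-break or stays
  unclassified.
* mRNA-target prediction for scaRNA:tracrRNA:Cas9 complexes is out of
  scope.
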