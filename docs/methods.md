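# Methods

## Panel and reference-allele model

A locus is modelled as `primer_fwd + flank5 + repeat array + flank3 +
revcomp(primer_rev)`. The repeat array is an ordered list of blocks;
exactly one block is *variable* and its copy number is what the allele
label counts, the others are *fixed* (compound patterns such as
`TCTA (TCTG)₃ (TCTA)ₙ`). Labels are strings, never floats — `"9.3"` is
not the number 9.3 — so `10` and `10.0` can never collide.

Partial-repeat placement is not standardised across loci, so it is
configurable per locus: the partial unit is the motif's prefix or suffix
of length *y*, inserted after a configurable number of full units
(default: motif prefix after all full units). The built-in TH01 pins the
9.3 allele to six full `AATG` units + `ATG` + three full units; under
run-length encoding this is identical to allele 10, which is the
property the collision diagnostics must reproduce. The collision itself
holds wherever the partial sits, because RLE(`AATG`) = `ATG` regardless
of its neighbours.

The built-in panel covers 14 STRs + amelogenin with real repeat motifs
and population allele ranges (TPOX 8–12 … SE33 12–34). Primers and most
flanks are synthetic stand-ins (the original assay's primer sequences
are not public); the D18S51 5' flank and the D21S11 repeat-adjacent
sequence are the published sequences that resemble their repeat units.
The two built-in contributor profiles are likewise synthetic stand-ins
for laboratory reference samples, constrained to the panel's ranges.
`complexity_class` (Low/Medium/High) is declared input — there is no
agreed formula — and a structural heuristic (`classify_complexity`) is
provided for exploration but never used in scoring.

## Simulator

The simulator works at the molecule level, not per PCR cycle: for each
locus, `depth × bias` molecules draw a contributor (mixture weight), a
parent allele (uniform over the genotype's 1–2 alleles), and a product
category over {parent: 1−ρ₋−ρ₊, n−1: ρ₋, n+1: ρ₊}. Stutter products
outside the locus's allele range are clamped out (the molecule stays a
parent copy), keeping per-locus depth exact; at range-edge alleles the
observed stutter fraction is therefore slightly below ρ. An optional
linear `repeat_scaling` above a pivot repeat number emulates the higher
stutter of long repeats.

Sequencing errors are applied per position in a fixed order —
insertion before the position, substitution of it, deletion of it — with
independent probabilities. Deletion probability inside a homopolymer run
of length L is `p_del · (1 + h·(min(L, L_cap) − 1))`. This order and the
linear run-length scaling were chosen for testability: the expected
deletion count has a closed form (`expected_deletions`), which the test
suite checks against simulation. Defaults: `short-accurate`
p_sub = 0.002, p_ins = p_del = 10⁻⁴, h = 1; `long-noisy` p_sub = 0.03,
p_ins = 0.02, p_del = 0.025, h = 1.5, L_cap = 8 — typical published
magnitudes for the two platform classes, all overridable. Half the reads
are emitted reverse-complemented by default (both amplicon strands are
sequenced). Quality strings are constant placeholders; the pipeline
never reads them.

What the simulator does **not** emulate: per-cycle PCR branching and
polymerase-specific stutter spectra, signal-level artefacts (the error
process is i.i.d. given the run-length profile, while real base-caller
errors are bursty and sequence-context dependent), chimeric reads,
barcode cross-talk, and quality-value information. Passing tests
therefore show that the pipeline's logic is correct under the stated
noise model, not that real-platform accuracy numbers are reproduced.

## Pipeline semantics

*Demultiplexing.* "Two mismatches per primer" is interpreted as edit
distance ≤ 2 (indels are the dominant long-read error); a
substitution-only Hamming mode is available behind `allow_indels=False`.
The search is restricted to a window of primer length + k at each read
end, in both orientations. Reads matching more than one locus are
dropped — no tiebreak is defined, and discarding mirrors the
ambiguity-discard used at the allele level.

*Alignment.* Exhaustive global alignment (unit-cost edit distance via
edlib, verified against an independent full-matrix DP oracle in the
tests) against every allele of the read's locus replaces a heuristic
read mapper: databases are ≤ ~30 alleles of ≤ ~200 nt, so exhaustive
scoring is exact, deterministic, and makes "ambiguous" crisp — an exact
score tie, the analogue of a multi-mapping (XA-tagged) read. Integer
edit distances make the tie test exact. Reads are compared full length,
primers included (primer bases anchor the alignment).
`min_score_frac = 0.4` marks a read unaligned when even the best allele
is > 0.4 × read length edits away — generous for 5–10%-error reads,
while random sequence sits near ~0.5–0.6 × length from everything.

*Calling.* The second-ranked allele is called only when its count
**strictly** exceeds `threshold × max` (default 0.5): a runner-up at
exactly half the maximum reads out as homozygous. A count tie at the
top calls both tied alleles (each exceeds the threshold relative to the
other); in a >2-way top tie the two numerically smallest labels are
reported, deterministically. "Correct-complicated" — correct, but some
allele outside the truth set collected more than `complication_frac`
(default 0.4) × the top count — operationalises a status that has no
published formal definition, and the fraction is exposed as a
parameter. Mixture correctness (contributor proportions unknown, so the
50% rule does not apply) is defined as: the top-m ranked alleles equal
the m-allele union of the contributors' genotypes.

## Diagnostics

* Repeat homopolymer length is computed on a **two-copy tandem array**
  of each block motif, so runs spanning the unit junction count
  (`AGAA|AGAA` → `AAA` → 3; `AAAAG|AAAAG` → 4); the maximum over blocks
  is reported. A single unit would miss junction runs. For loci whose
  repeat array has no run ≥ 2 the statistic is 1 (a single base is a
  run of length 1); characteristic tables elsewhere may print 0 for
  "no homopolymer".
* RLE collisions compare the run-length-encoded **repeat-region insert**
  of every allele pair within a locus; flanks are locus-constant and
  cannot disambiguate alleles, so they are excluded.
* Flank–repeat identity aligns each non-empty flank globally against an
  idealized tandem array of the variable motif tiled to the flank's
  length, takes identity = 1 − distance/length, and maximises over the
  motif's rotations and over both flanks. Maximising over rotations
  makes the statistic phase-free: a flank that is itself a perfect
  tandem array scores exactly 1.0 in any phase. There is no published
  formula for this similarity; identity against a matched-length ideal
  array, compared to a random-flank baseline, is this package's
  operationalization.

## Problem sizes and numerical choices

The test suite exercises the full 15-locus design at depth 200/locus
for the exact end-to-end identity check, 10 seeds × depth 300 for the
locus-degradation ordering, and 100 replicates × depth 500 for genotype
recovery — sizes at which the binomial standard errors the assertions
use are small relative to the tested margins. All randomness flows
through one seeded NumPy generator per run; fixed seeds give
byte-identical FASTQ and TSV outputs. Score ties are exact integer
comparisons; ranking ties break by numeric allele label.

## Known limitations

* The aligner's unique/ambiguous/unaligned trade-off is that of exact
  edit distance, not of any specific heuristic mapper's scoring; real
  mappers' percentages will differ in detail.
* Stutter magnitudes are placeholders for sensitivity analysis, not
  estimates of any particular assay.
* Allele frequencies are not modelled; the panel enumerates population
  ranges uniformly.
* Amelogenin is modelled with short synthetic X/Y inserts; dosage-based
  sex inference beyond allele presence is out of scope.
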