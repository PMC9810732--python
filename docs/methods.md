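# Methods

`riboscreen` implements a ribosome-profiling (Ribo-seq) translatome screen
for small open reading frames (sORFs) in long intergenic non-coding RNAs
(lincRNAs). This note documents the model behind each stage, the parameters
that matter, what the synthetic data generator does and does not emulate,
and the design choices made where the design was genuinely open.

## Coordinate conventions and input contract

The pipeline operates entirely in transcript space: positions are 0-based,
intervals half-open, strand always `+`. Upstream processing (adapter
trimming, rRNA depletion, alignment to a transcript FASTA) is assumed done;
the contract starts at per-read alignments reduced to a 5′ position and a
read length. Ribosome-protected fragments (RPFs) shorter than 18 nt are
discarded, reflecting the size selection of RPF libraries; the retention
window defaults to [18, 40] nt and is configurable.

## P-site assignment

Each RPF is collapsed to a single estimated P-site position at
`five_prime_pos + offset(read_length)`. The default offset is the classic
constant 5′+12 nt rule appropriate for ~28-nt footprints; a per-length
offset table can be supplied, and offset 0 reproduces raw 5′-end counting.
Offsets are *not* auto-calibrated from metagene periodicity — that is out of
scope, and for the synthetic data the emission and counting conventions
match by construction. Reads whose P-site falls outside the transcript or
whose length is outside the window are dropped and tallied, so
`n_assigned + n_dropped` always equals the input read count.

## ORF enumeration

Candidate sORFs run from an allowed start codon (default ATG only;
near-cognate CTG/GTG/TTG behind a config flag) to the first in-frame stop,
with no internal in-frame stop. Length bounds default to 10–150 encoded
amino acids; `aa_length` excludes the stop codon, so a "108 aa" peptide has
`aa_length = 108`. Under the default `longest_per_stop` policy only the
most 5′ qualifying start is kept per stop codon, avoiding multiple counting
of nested starts; `all_starts` is retained for sensitivity analyses.
Enumeration is deterministic and is tested against an independent
brute-force oracle. Main ORFs (mORFs) of protein-coding transcripts come
straight from the annotation; non-canonical start/stop codons are flagged,
not rejected. Candidates with zero pooled P-site counts are dropped before
scoring (`min_reads = 1`).

## Translation statistics

**ORF score.** In-ORF P-sites are split by codon sub-position relative to
the ORF start (stop codon excluded; the first codon optionally excluded for
initiation-inhibitor pileups). With frame counts (F0, F1, F2) and
m = (F0+F1+F2)/3, the score is

    s = log2(1 + Σᵢ (Fᵢ − m)² / m)

taken positive only when F0 strictly dominates both other frames, negative
otherwise, and defined as exactly 0 for zero total counts. Elongating
ribosomes step 3 nt at a time, so genuinely translated ORFs pile counts
into frame 0 and score high positive; frameless background scores near 0
and off-frame overlaps score negative. The magnitude grows roughly as
log2 of the count total at fixed frame composition, which is why the
statistic is thresholded against a reference distribution rather than an
absolute cutoff.

**Ribosome release score (RRS).** With R = RPF P-site counts and N = RNA-seq
5′-end counts in the ORF and in the downstream region [stop, transcript
end), and pseudocount ψ = 1 on all four counts:

    RRS = ((R_orf + ψ) / (R_down + ψ)) × ((N_down + ψ) / (N_orf + ψ))

Termination releases ribosomes at the stop codon, so translated ORFs show a
sharp footprint drop downstream and a high RRS; the RNA term cancels
coverage trends. When the ORF ends at the transcript's last base the RRS is
undefined and flagged (`no_downstream_region`); such ORFs are never called
active. Without matched RNA-seq the fallback is the length-normalized RPF
density ratio alone, flagged `zero_rna`. The pseudocount keeps the score
finite for the empty downstream regions that genuine translation produces.

## Screen logic

Scores for thresholding are computed once per ORF on counts pooled across
all samples (one point per ORF, as in the score scatter); per-sample
calling remains available through the per-sample scoring path. Thresholds
are the nearest-rank 95th percentiles (1-based index ⌈p/100·n⌉ of the
ascending list — no interpolation, for exact reproducibility) of the mORF
ORF-score and log10 RRS distributions, requiring at least 20 usable mORFs.
A lincORF is *actively translated* only when it strictly exceeds both
thresholds — it must look more convincingly translated than 95% of
annotated coding ORFs. This literal reading of the calibration is extremely
stringent by design (it matches a regime where only tens of candidates
survive from thousands); a lower percentile can be configured for
sensitivity analyses.

Differential translation is a deterministic fold-change rule, not a
replicate-based test (no replicates per condition are modeled): for each
case sample, `log2fc = log2((d_case + ψ·d0_case) / (d_ctrl + ψ·d0_ctrl))`
where d is RPKM-style P-site density and d0 the density equivalent of one
read in that ORF and sample. A sample is flagged when |log2fc| ≥ 1 and
either sample has ≥ 10 reads in the ORF; a candidate is *shared
differential* when every case sample flags it with a consistent direction.
Candidates are ranked by mean |log2fc| across case samples, ties broken by
total RPF count and then lexicographic ORF id, so output order is fully
deterministic. No p-values are produced; the rule and all parameters are
recorded in output provenance comments.

## Synthetic data generator

The generator emulates the screen's study design — one normal control and
three tumor case samples, each with an RPF and an RNA-seq library — at the
alignment level. Defaults: 400 protein-coding transcripts and 100 lincRNAs
of 300–1500 nt; log-normal expression across transcripts (sdlog 1.0) with a
small per-sample log-normal jitter (sdlog 0.05, modest library-to-library
variability); 20% of lincRNAs carry one planted sORF; RPF lengths 26–32 nt
peaked at 28; 2×10⁵ reads per library.

RNA totals per transcript are multinomial in expression; RPF totals are
proportional to expression × (sum of ORF translation efficiencies + a
background TE of 0.05). Reads on a translated ORF put their P-site on a
uniformly chosen coding codon with sub-codon position drawn from the frame
fidelity vector (0.85/0.10/0.05), except a 2% leakage fraction placed
uniformly downstream of the stop; background reads are uniform and
frameless. An optional start-codon spike emulates initiation-inhibitor
pileup for robustness tests of `exclude_first_codon`.

Three generator choices deserve explanation:

* **Translated lincORF TE ∈ [2, 6] relative to mORF TE = 1, and planted
  transcripts draw expression at or above the distribution median.** The
  screen's calibration only passes lincORFs that beat the 95th percentile
  of mORFs on both statistics, so detectable planted signals must sit in
  the upper tail of the footprint-count distribution; a real screen's hits
  are expression- and TE-biased in exactly this way (what is not expressed
  cannot be recovered). Early designs with much larger TE multipliers made
  the planted ORFs consume over half the case footprint library, which
  compositionally diluted every other transcript by ~2× and produced
  artifactual "down" calls — a biologically absurd regime the defaults
  deliberately avoid.
* **Differential fold changes: one standout 16× effect plus a geometric
  4×–8× ladder across the 10 planted ORFs (all "up" in cases).** A spread
  of effect sizes with a single dominant hit mirrors a screen whose
  top-ranked candidate stands clearly apart, and makes "the strongest
  planted effect" well defined for recovery testing.
* **Per-(sample, assay) random streams** derived from the seed plus stable
  string hashes, so adding a sample never perturbs the reads of existing
  samples and every fixture is byte-reproducible.

What the generator does **not** emulate: sequence-composition biases,
ligation/PCR duplication and UMIs, rRNA contamination, spliced or
genome-space alignment, sequencing error (reads are emitted as perfect
transcript-space alignments), nucleotide-resolution ramps or pause sites,
and replicate structure within a condition. Passing the recovery tests
therefore demonstrates that the statistics and calibration behave correctly
under the assumed signal model — not that the pipeline is robust to every
artifact of real libraries.

## Numerical choices and degenerate inputs

Zero frame counts give ORF score 0 by definition; undefined RRS is carried
as NaN in tables and excluded from percentile lists; sign ties in the ORF
score (F0 not strictly maximal) are negative by convention. Percentiles are
nearest-rank. Codons containing N never match start or stop patterns.
Duplicate read ids are allowed across samples and assays (files are
concatenated); alignment row order never affects any result. Empty
downstream regions, empty alignment tables, and transcripts with no reads
in a sample are all well-defined (flags or zero profiles, never
exceptions).

## Problem sizes

Default verification runs use the full default fixture (500 transcripts,
four samples, 2×10⁵ RPF + 2×10⁵ RNA reads each); the recovery properties
are checked across 20 seeds. Unit and property tests use a scaled-down
design (120 transcripts, 3×10⁴ reads per library) that preserves every
structural property at a fraction of the cost.

## Known limitations

The "modified" variant of the ORF score used in some published screens is
not precisely specified in the literature this design follows; the standard
chi-square/log2 form is implemented, with `exclude_first_codon` and the
stop-codon exclusion as the plausible modification axes. P-site offsets are
not calibrated from data. The differential rule is intentionally simple and
has no error control; with replicates available, a count-model test would
be preferable. Genome-space coordinates, overlapping-frame translation, and
stop-codon readthrough are out of scope.
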