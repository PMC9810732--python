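# riboscreen

Ribo-seq translatome screening of small ORFs in lincRNAs: enumerate
candidate sORFs, score them for active translation, and call candidates
differentially translated between tumor and normal samples.

## The problem

Long intergenic non-coding RNAs (lincRNAs) occasionally hide short open
reading frames (sORFs) that are genuinely translated into micropeptides or
small proteins, some of them functional drivers in cancer. Ribosome
profiling (Ribo-seq) can reveal them: ribosome-protected fragments (RPFs)
mapped onto a candidate ORF show a 3-nt periodic footprint pattern while
the ribosome elongates, and a sharp footprint drop after the stop codon
when it releases. `riboscreen` packages this logic as a tested, fully
deterministic pipeline for anyone screening lincRNA translation from
transcript-space Ribo-seq (and optionally RNA-seq) alignments — plus a
synthetic data generator so every stage can be verified end to end without
any external download.

## The statistics

For an ORF with P-site counts F₀, F₁, F₂ in the three codon sub-positions
(stop codon excluded) and m = (F₀+F₁+F₂)/3, the **ORF score** is

    s = ± log2(1 + Σᵢ (Fᵢ − m)² / m)

positive iff frame 0 strictly dominates, and 0 for zero counts. The
**ribosome release score** compares footprint density inside the ORF with
the region downstream of its stop, normalized by RNA-seq coverage, with
pseudocount ψ = 1:

    RRS = (R_orf + ψ)/(R_down + ψ) × (N_down + ψ)/(N_orf + ψ)

Active-translation thresholds are calibrated from the annotated main ORFs
(mORFs) of protein-coding transcripts: a lincORF is called actively
translated only when it strictly exceeds the 95th nearest-rank percentile
of the mORF distribution on *both* statistics. Active lincORFs are then
tested for differential translation against the control sample (RPF
density log2 fold change ≥ 1 with ≥ 10 supporting reads, consistent
direction in every case sample) and ranked by mean |log2FC|. See
`docs/methods.md` for the full model, parameter defaults, and design
rationale.

## Worked example

Simulate the default study design — one control and three case samples,
400 coding transcripts and 100 lincRNAs, 2×10⁵ RPF and RNA reads per
library, 10 planted differentially translated sORFs — and run the screen:

```python
from riboscreen import make_screen_dataset, run_screen

ds = make_screen_dataset(seed=1)
res = run_screen(ds.transcripts, ds.rpf_alignments, ds.manifest, ds.rna_alignments)
print(f"candidate sORFs:      {res.n_candidate_sorfs}")
print(f"detected (>=1 read):  {res.n_detected_sorfs}")
print(f"thresholds: ORF score > {res.thresholds.orfscore_threshold:.2f}, "
      f"log10 RRS > {res.thresholds.rrs_threshold:.2f} "
      f"(p{res.thresholds.percentile:.0f} of {res.thresholds.n_morfs} mORFs)")
print(f"active lincORFs:      {len(res.active)}")
print(f"shared differential:  {len(res.ranking)}")
print(f"top candidate:        {res.ranking[0]}")
```

prints

```
candidate sORFs:      650
detected (>=1 read):  546
thresholds: ORF score > 11.71, log10 RRS > 1.32 (p95 of 400 mORFs)
active lincORFs:      19
shared differential:  10
top candidate:        linc0014:90-450
```

Reading the numbers: 650 ATG-initiated sORF candidates (10–150 aa) exist in
the 100 simulated lincRNAs, 546 of them covered by at least one pooled
P-site. Only 19 exceed both mORF-calibrated thresholds — the calibration is
deliberately stringent — and 10 of those are differentially translated in
all three case samples with a consistent direction. The top-ranked
candidate `linc0014:90-450` (transcript id, ORF interval in transcript
coordinates) is the planted strongest-effect sORF, recovered with mean
|log2FC| ≈ 3.2 across case samples. Against the emitted ground truth
(`ds.truth`) this run recovers the planted differential set with recall
and precision 1.0.

The same workflow is available from the shell:

```bash
riboscreen simulate --seed 1 --out fixture/
riboscreen screen --fasta fixture/transcripts.fasta --annotation fixture/annotation.tsv \
    --manifest fixture/manifest.tsv --out screen.tsv
riboscreen find-orfs --fasta fixture/transcripts.fasta --annotation fixture/annotation.tsv \
    --out orfs        # BED6 + sidecar TSV
```

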