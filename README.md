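# osteotag

Spike-in calibrated CUT&Tag / CUT&RUN enhancer analysis for osteogenic
differentiation studies.

## The problem

Chromatin readers such as BRD4 bind acetylated enhancers to drive lineage
programmes — in cranial neural crest cells, the osteoblast programme
executed by the transcription factor RUNX2.  Quantifying what happens to
such a factor's occupancy in a knockout is treacherous: when binding
collapses *genome-wide*, per-library normalisation (CPM and friends)
silently rescales the smaller signal back up, and the loss disappears.
The accepted remedy is an exogenous-genome spike-in: foreign chromatin
(e.g. *Drosophila*) added at a fixed ratio per cell, whose mapped reads
anchor an absolute scale.  `osteotag` implements the full analysis built
on that idea:

1. **Spike-in scaling factors** per sample,
   `factor = ((primary_reads / genome_bp) / spike_reads) x 10^4`,
   whose reciprocal serves as the effective library size in differential
   tests.
2. **Differential occupancy and expression** by a sum-conditional
   negative-binomial exact test with common dispersion φ: group sums are
   modelled as `Y_g ~ NB(n_g μ, φ/n_g)`; conditional on the total the law
   is μ-free and the two-sided p-value is computed by enumeration
   (at φ = 0 it reduces to the conditional binomial test).  BH-FDR and
   DESeq2-style independent filtering sit on top.
3. **The classification ladder**: pooled peaks are validated (WT RPKM > 1
   and either wild-type-specific or significant knockout loss at
   FDR < 0.05), split into promoters (TSS ± 500 bp) versus enhancers
   (H3K27ac overlap, non-TSS), ranked into super-enhancers by the
   tangent (slope = 1) rule on the rank-ordered acetylation-density
   curve, linked to target genes that lose expression in both knockout
   lines within 50 kb, and classified temporally: stem-cell enhancers
   (bound in the undifferentiated state, target gene flat across
   differentiation) versus early/late osteogenic enhancers (bound at day
   3/6 with the target gene induced in wild type).
4. **Co-occupancy statistics**: Fisher's exact test for BRD4-RUNX2
   co-binding over the enhancer universe, NB-exact RUNX2-loss calls in
   the knockout, and per-class unpaired Student *t* comparisons of
   enhancer RUNX2 signal.
5. **Motif enrichment**: log2-odds PWM scanning (both strands,
   pseudocount 10⁻³, threshold 80% of the maximal score) and
   presence/absence Fisher enrichment in bound versus unbound enhancers.

Everything runs on synthetic data with planted ground truth: the
`simulate` module generates a toy genome whose geometry provably
satisfies the 50-kb target rule, draws NB fragment counts with a global
knockout collapse that only the spike channel can reveal, plants a
heavy-tailed super-enhancer subset, RUNX2 co-binding and a RUNX-like
sequence motif, and scores every pipeline stage against the truth.

## Worked example

```sh
osteotag demo --seed 0 --out demo_out
```

simulates the default study (two 10.5-Mb chromosomes, 620 genes, 300
enhancers + 20 bound promoters, BRD4/H3K27ac/RUNX2 occupancy at D0/D3/D6
plus RNA counts for WT and two knockout lines), runs the pipeline and
prints the planted-truth scorecard.  With seed 0 it reports, among
others:

* `validated_peaks`: precision 1.00 / recall 1.00 at each timepoint —
  all 60 planted BRD4-bound elements per timepoint are retained, no
  false peaks survive validation;
* `super_enhancers`: 31 called vs 30 planted, Jaccard 0.97;
* `target_links` (peak-gene pairs within 50 kb of a gene down in both
  knockouts): precision 1.00, recall 0.94-1.00 across timepoints;
* `temporal_classes`: stem / early / late recovered at precision 1.00,
  recall 0.93-1.00;
* `fisher_cooccupancy`: odds ratio 13.9, p = 5.0e-20 — RUNX2 peaks
  concentrate on BRD4-bound enhancers (planted rates 0.6 vs 0.1);
* `motif_enrichment`: motif in 56% of bound osteogenic enhancers vs 11%
  of unbound enhancers, p = 1.9e-13;
* `runx2_loss`: 82/82 planted knockout-sensitive RUNX2 peaks flagged
  (recall 0.99).

The same `demo_out/` directory contains the master peak tables
(`brd4_peaks_*.tsv`), BED exports per enhancer class, the RUNX2 tables,
`summary.json` (promoter/enhancer counts, super-enhancer frequencies at
bound vs unbound enhancers, Fisher and motif statistics) and
`metrics.json` (the scorecard).  `osteotag simulate --write-tracks` and
`osteotag run` operate on on-disk bundles (BED / bedGraph / TSV / FASTA)
for file-based workflows.

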