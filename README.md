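# gbsmap

Linkage mapping for an F2 interspecific cross genotyped by GBS
(genotyping-by-sequencing), built as a reusable, tested Python library.  It
covers the full analysis chain for low-depth GBS data from two inbred parents
and their F2 progeny:

1. **SNP filtering and phasing** — a six-step cascade (MAF ≥ 40 %, genotype
   depth ≥ 7, ≤ 10 % missing, 1:2:1 segregation at p ≥ 0.01, one SNP per
   64-base tag locus) followed by recoding each progeny genotype by parental
   origin (A / H / B / U).
2. **Linkage-map construction** — pairwise recombination fractions by EM,
   single-linkage grouping at an independence p-value cutoff of 1e-12,
   within-group ordering (exact dynamic programming for small groups,
   nearest-neighbour seeding with 2-opt/Or-opt refinement for large ones) and
   cumulative **Kosambi** centimorgan positions, d = 25·ln((1+2r)/(1−2r)).
3. **Crossover QC** — individuals with > 66 minimal crossovers and SNPs with
   > 15 double crossovers (singletons) are removed and the map rebuilt.
4. **HMM error correction** — per-individual 3-state forward–backward
   (max-marginal) smoothing with posterior threshold 0.8; map distances are
   re-estimated on the corrected genotypes.
5. **Dominant tag mapping** — a 64-base GBS tag observed in a subset of
   progeny (its *carriers*) is placed on the map by the recombination rate
   min(n₁, n₂)/(n₁ + n₂), where n₁/n₂ count carriers homozygous for either
   parent at a SNP; a tag maps when the minimum rate is < 5 % with ≥ 30
   informative homozygotes (two-tailed binomial P < 6e-8).
6. **Contig tag haplotypes** — the concordant mapped tags of a contig
   (same LG, within 50 SNP indices of the sample-size-weighted consensus)
   are merged by summing counts; presence requires ≥ 5 % of the mean non-zero
   count, and the haplotype is re-mapped at a relaxed 10 % threshold.
7. **Pseudomolecule assembly** — SNP-anchored contigs keep map order and are
   quasi-oriented from their first/last physical SNP; tag-only contigs are
   inserted after the contig hosting their GeneticMean SNP; contigs are
   joined with 100 N's and emitted as FASTA + AGP 2.1.

Because raw GBS data for this study design are generally unavailable, the
package ships a first-class synthetic-data generator (`gbsmap.simdata`) that
simulates the whole observation process — Poisson crossovers, depth-dependent
heterozygote undercalling, site-level coverage heterogeneity, dominant tag
counts, high-crossover outlier individuals — with full ground truth, so every
stage is verifiable end to end.

## Worked example

`examples/` holds one short script per capability.  Building a map on a small
simulated cross (2 LGs, 100 F2, depth 10):

```bash
$ python examples/03_build_linkage_map.py
individuals retained: 100 (dropped 0 high-crossover outliers)
SNPs dropped for double crossovers: 0

linkage groups: 2
  LG-1: 42 SNPs spanning 49.3 cM (0.9 SNPs/cM)
  LG-2: 23 SNPs spanning 59.7 cM (0.4 SNPs/cM)
total map length: 109.0 cM (simulated genome: 140 cM; mapped SNPs span
slightly less than the full genome)
```

The two recovered linkage groups correspond to the two simulated
chromosomes; the mapped SNPs span less than the simulated 140 cM because the
outermost simulated SNPs do not all survive filtering.  The same flow at
study scale (375 F2, 8 LGs, ~881 cM, mean depth 7) is what the acceptance
script below runs.

From Python, the one-call entry points are:

```python
from gbsmap import SimConfig, PipelineConfig, run_simulated_pipeline

result, truth = run_simulated_pipeline(SimConfig(seed=1), PipelineConfig())
result.map_final.total_length_cm   # estimated Kosambi map length
result.summary                     # per-LG counts, spans, tag/haplotype totals
```

or `run_pipeline(vcf, parent1, parent2, tags_path=..., contigs_path=...)` for
data on disk (VCF with GT/DP, tag TSV, contig FASTA).

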