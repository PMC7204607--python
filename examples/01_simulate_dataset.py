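"""Simulate a small F2 GBS dataset and write it in standard formats.

Builds a ground-truthed cross (two inbred parents, F2 progeny, low-depth GBS
genotype calls, dominant presence/absence tags, contig sequences) and writes
VCF / TSV / FASTA plus the ground-truth tables used for recovery checks.
"""

from pathlib import Path

from gbsmap import formats, simdata

cfg = simdata.SimConfig(
    n_individuals=100, n_linkage_groups=2, lg_lengths_cm=(80.0, 60.0),
    contigs_per_lg=25, snps_per_contig=6, mean_depth=10.0, depth_shape=None,
    outlier_individuals=2, seed=42,
)
true_map = simdata.simulate_true_map(cfg)
pop = simdata.simulate_f2(true_map, cfg)
calls = simdata.simulate_snp_calls(pop, true_map, cfg)
tags = simdata.simulate_tag_counts(pop, true_map, cfg)
contigs = simdata.simulate_contig_sequences(true_map, cfg)

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)
formats.write_vcf(calls, out / "calls.vcf")
formats.write_tag_matrix(
    formats.TagCountMatrix(tags=tags.tags.drop(columns=["donor"]),
                           samples=tags.samples, counts=tags.counts),
    out / "tags.tsv",
)
formats.write_fasta(contigs.sequences, out / "contigs.fasta")
simdata.write_ground_truth(true_map, pop, out / "truth")

het = pop.snp_het.mean()
print(f"simulated {cfg.n_individuals} F2 + 2 parents at {true_map.n_snps} SNPs "
      f"on {cfg.n_linkage_groups} LGs ({sum(cfg.lg_lengths_cm):.0f} cM)")
print(f"true mean F2 heterozygosity: {het:.3f}  (expectation 0.5)")
print(f"mean crossovers per F2: {pop.crossovers.mean():.1f} "
      f"(expectation {2 * sum(cfg.lg_lengths_cm) / 100:.1f} for two gametes)")
print(f"wrote VCF, tag TSV, contig FASTA and truth tables under {out}/")
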