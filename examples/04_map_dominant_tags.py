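"""Map dominant presence/absence tags and contig tag haplotypes.

A tag's carriers are compared with the map: at each SNP, the recombination
rate is min(n1, n2)/(n1 + n2) over carrier homozygotes.  A tag maps when the
minimum rate is < 5% with >= 30 informative homozygotes (two-tailed binomial
P < 6e-8); a contig's concordant tags are then merged into a tag haplotype
and re-mapped at a relaxed 10% threshold, which is what rescues contigs whose
individual tags are too shallow.
"""

from gbsmap import contighap, pipeline, simdata, tagmap

cfg = simdata.SimConfig(
    n_individuals=200, n_linkage_groups=2, lg_lengths_cm=(80.0, 60.0),
    contigs_per_lg=25, snps_per_contig=6, mean_depth=10.0, depth_shape=None,
    dominant_tags_per_contig=3, tag_depth_mean=3.0, outlier_individuals=0,
    seed=42,
)
result, truth = pipeline.run_simulated_pipeline(
    cfg, pipeline.PipelineConfig(), with_assembly=False
)

df = tagmap.tag_mappings_frame(result.tag_mappings)
print(f"segregating tags tested: {len(df)}; mapped: {(df.status == 'mapped').sum()}")
print("\nfirst mapped tags (GeneticStart..End in consecutive SNP indices):")
cols = ["tag_id", "lg", "n_hom_par1", "n_hom_par2", "min_rec_rate",
        "p_binomial", "genetic_start", "genetic_end", "genetic_mean"]
print(df[df.status == "mapped"][cols].head(5).to_string(index=False))

hap = contighap.haplotypes_frame(result.haplotypes)
print(f"\ncontig tag haplotypes: {len(hap)}; mapped: {(hap.status == 'mapped').sum()}; "
      f"discordant member tags: {hap['n_discordant'].sum()}")
print("a 0 recombination rate means every informative carrier is homozygous "
      "for the donor parent at the best SNP: perfect linkage.")
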