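"""End-to-end orchestration: simulate -> filter/phase -> map -> QC -> impute
-> tag map -> haplotype map -> assemble, with per-stage attrition reporting.

The stage order follows the analysis it re-implements:

1. the six-step SNP filter cascade and parental phasing,
2. a first linkage map on all progeny,
3. removal of individuals with more than 66 minimal crossovers, map rebuilt,
4. removal of SNPs with more than 15 double crossovers, final map rebuilt,
5. HMM max-marginal error correction / imputation (min posterior 0.8),
   after which adjacent map distances are re-estimated on the corrected
   genotypes (so residual genotyping error does not inflate the map),
6. dominant tag mapping against the final map,
7. contig tag-haplotype consensus mapping,
8. rule-based pseudomolecule assembly (FASTA + AGP).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats, simdata, snpfilter, mapbuild, tagmap, contighap, assembly


@dataclass
class PipelineConfig:
    """All stage thresholds, at the study's defaults."""

    min_maf: float = 0.40
    min_depth: int = 7
    max_missing: float = 0.10
    seg_p: float = 0.01
    thin_bp: int = 65
    p_cutoff: float = 1e-12
    map_missing: float = 0.15
    max_xo: int = 66
    max_dxo: int = 15
    min_prob: float = 0.8
    hmm_error_rate: float = 0.01
    tag_min_present: int = 30
    tag_max_present: int | None = None  # None: 256 at N=366, else floor(0.80 N)
    tag_max_rec: float = 0.05
    tag_min_sample: int = 30
    window: int = 50
    presence_fraction: float = 0.05
    hap_max_rec: float = 0.10
    gap_length: int = 100


@dataclass
class PipelineResult:
    filter_report: snpfilter.FilterReport
    phased: snpfilter.PhasedGenotypeMatrix          # all progeny
    map_initial: mapbuild.LinkageMap
    retained_individuals: list
    dropped_individuals: list
    phased_retained: snpfilter.PhasedGenotypeMatrix
    map_rebuilt: mapbuild.LinkageMap
    retained_snps: list
    dropped_snps: list
    phased_final: snpfilter.PhasedGenotypeMatrix
    map_final: mapbuild.LinkageMap                  # respaced after imputation
    imputed: snpfilter.PhasedGenotypeMatrix
    tag_matrix: formats.TagCountMatrix | None = None
    tag_mappings: list = field(default_factory=list)
    haplotypes: list = field(default_factory=list)
    layout: assembly.PseudomoleculeLayout | None = None
    sequences: dict | None = None
    agp: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def run_snp_stages(calls: formats.SnpCallSet, config: PipelineConfig):
    """Stages 1-5: cascade, map, crossover QC, double-crossover QC, imputation."""
    phased, report = snpfilter.run_filter_cascade(
        calls, min_maf=config.min_maf, min_depth=config.min_depth,
        max_missing=config.max_missing, seg_p=config.seg_p,
        thin_bp=config.thin_bp,
    )
    map1 = mapbuild.build_linkage_map(
        phased, p_cutoff=config.p_cutoff, missing_threshold=config.map_missing
    )
    xo1 = mapbuild.count_crossovers(phased, map1)
    retained_ind = mapbuild.drop_outlier_individuals(xo1, config.max_xo)
    dropped_ind = [p for p in phased.progeny if p not in set(retained_ind)]

    phased_r = phased.subset_progeny(retained_ind)
    map2 = mapbuild.build_linkage_map(
        phased_r, p_cutoff=config.p_cutoff, missing_threshold=config.map_missing
    )
    xo2 = mapbuild.count_crossovers(phased_r, map2)
    retained_snps = mapbuild.drop_outlier_snps(xo2, config.max_dxo)
    dropped_snps = [
        s for s in map2.table["snp_id"] if s not in set(retained_snps)
    ]
    keep_mask = phased_r.sites["snp_id"].isin(retained_snps).to_numpy()
    phased_f = phased_r.subset_snps(keep_mask)
    map3 = mapbuild.build_linkage_map(
        phased_f, p_cutoff=config.p_cutoff, missing_threshold=config.map_missing
    )
    imputed = mapbuild.impute_genotypes(
        phased_f, map3, min_prob=config.min_prob, error_rate=config.hmm_error_rate
    )
    map_final = mapbuild.respace_map(imputed, map3)
    return PipelineResult(
        filter_report=report,
        phased=phased,
        map_initial=map1,
        retained_individuals=retained_ind,
        dropped_individuals=dropped_ind,
        phased_retained=phased_r,
        map_rebuilt=map2,
        retained_snps=retained_snps,
        dropped_snps=dropped_snps,
        phased_final=phased_f,
        map_final=map_final,
        imputed=imputed,
    )


def run_tag_stages(result: PipelineResult, matrix: formats.TagCountMatrix,
                   config: PipelineConfig) -> None:
    """Stages 6-7: dominant tag mapping and contig tag-haplotype mapping."""
    unique = formats.filter_tags_unique(matrix)
    segregating = tagmap.filter_segregating_tags(
        unique, result.retained_individuals,
        min_present=config.tag_min_present, max_present=config.tag_max_present,
    )
    result.tag_matrix = segregating
    result.tag_mappings = tagmap.map_all_tags(
        segregating, result.imputed, result.map_final,
        max_rec_rate=config.tag_max_rec, min_sample=config.tag_min_sample,
    )
    result.haplotypes = contighap.build_contig_haplotypes(
        segregating, result.tag_mappings, result.imputed, result.map_final,
        window=config.window, presence_fraction=config.presence_fraction,
        max_rec_rate=config.hap_max_rec, min_sample=config.tag_min_sample,
    )


def run_assembly_stage(result: PipelineResult, contigs: formats.ContigSet,
                       config: PipelineConfig) -> None:
    """Stage 8: pseudomolecule layout and sequence emission."""
    snp_meta = result.phased_final.sites[["snp_id", "contig", "pos"]]
    snp_entries, removed = assembly.order_snp_contigs(result.map_final, snp_meta)
    snp_contigs = {e.contig_id for items in snp_entries.values() for e in items}
    hap_rows = []
    hap_mapped = set()
    for h in result.haplotypes:
        if h.mapping is not None and h.mapping.mapped:
            hap_mapped.add(h.contig_id)
            if h.contig_id not in snp_contigs and h.contig_id not in removed:
                m = h.mapping
                hap_rows.append(
                    {"contig_id": h.contig_id, "lg": m.lg,
                     "genetic_start": m.genetic_start,
                     "genetic_end": m.genetic_end,
                     "genetic_mean": m.genetic_mean}
                )
    tag_only = pd.DataFrame(
        hap_rows,
        columns=["contig_id", "lg", "genetic_start", "genetic_end", "genetic_mean"],
    )
    layout = assembly.place_tag_contigs(snp_entries, removed, tag_only,
                                        result.map_final, snp_meta)
    layout.gap_length = config.gap_length
    assembly.mark_dual_source(layout, hap_mapped)
    result.layout = layout
    result.sequences, result.agp = assembly.build_pseudomolecules(layout, contigs)


def summarize_map(result: PipelineResult) -> dict:
    """Results-style summary: per-LG counts/spans/densities, contig cM-span
    distribution, contigs by mapping source, assembly totals."""
    lmap = result.map_final
    per_lg = []
    for lg in lmap.lg_names:
        sub = lmap.lg_table(lg)
        span = float(sub["cm"].iloc[-1])
        per_lg.append(
            {"lg": lg, "n_snps": len(sub), "span_cm": round(span, 1),
             "snps_per_cm": round(len(sub) / span, 1) if span > 0 else np.nan}
        )
    per_lg = pd.DataFrame(per_lg)

    meta = result.phased_final.sites[["snp_id", "contig"]]
    t = lmap.table.merge(meta, on="snp_id")
    spans = t.groupby("contig")["cm"].agg(["min", "max", "count"])
    multi = spans[spans["count"] > 1]
    contig_spans = (multi["max"] - multi["min"]).to_numpy()
    span_classes = {
        "within_1_cm": float((contig_spans <= 1.0).mean()) if len(contig_spans) else np.nan,
        "within_5_cm": float((contig_spans <= 5.0).mean()) if len(contig_spans) else np.nan,
        "within_10_cm": float((contig_spans <= 10.0).mean()) if len(contig_spans) else np.nan,
    }

    sources = {"snp": 0, "both": 0, "tag": 0}
    if result.layout is not None:
        for items in result.layout.entries.values():
            for e in items:
                sources[e.source] += 1

    summary = {
        "n_linkage_groups": len(lmap.lg_names),
        "n_mapped_snps": int(lmap.n_snps),
        "total_length_cm": round(lmap.total_length_cm, 1),
        "n_mapped_contigs_snp_anchored": int(len(spans)),
        "n_multi_snp_contigs": int(len(multi)),
        "contig_span_fractions": span_classes,
        "contigs_by_source": sources,
        "per_lg": per_lg.to_dict(orient="records"),
        "n_individuals_retained": len(result.retained_individuals),
        "n_individuals_dropped": len(result.dropped_individuals),
        "n_snps_dropped_double_crossover": len(result.dropped_snps),
        "n_tags_mapped": sum(1 for m in result.tag_mappings if m.mapped),
        "n_tags_total": len(result.tag_mappings),
        "n_haplotypes_mapped": sum(
            1 for h in result.haplotypes
            if h.mapping is not None and h.mapping.mapped
        ),
    }
    if result.sequences is not None:
        total = sum(len(s) for s in result.sequences.values())
        non_n = sum(len(s) - s.count("N") for s in result.sequences.values())
        summary["pseudomolecule_total_bp"] = int(total)
        summary["pseudomolecule_non_n_fraction"] = non_n / total if total else np.nan
    result.summary = summary
    return summary


def run_simulated_pipeline(sim_config: simdata.SimConfig,
                           config: PipelineConfig | None = None,
                           out_dir=None, with_tags: bool = True,
                           with_assembly: bool = True):
    """Simulate a dataset and run every stage; returns (result, truth bundle).

    The truth bundle carries the TrueMap, TruePopulation and simulated tag
    donor assignments, for recovery checks against ground truth.
    """
    config = config or PipelineConfig()
    true_map = simdata.simulate_true_map(sim_config)
    pop = simdata.simulate_f2(true_map, sim_config)
    calls = simdata.simulate_snp_calls(pop, true_map, sim_config)
    result = run_snp_stages(calls, config)
    tag_matrix = None
    if with_tags:
        tag_matrix = simdata.simulate_tag_counts(pop, true_map, sim_config)
        run_tag_stages(result, tag_matrix, config)
    if with_assembly and with_tags:
        contigs = simdata.simulate_contig_sequences(true_map, sim_config)
        run_assembly_stage(result, contigs, config)
    summarize_map(result)
    if out_dir is not None:
        write_outputs(result, out_dir)
    truth = {"true_map": true_map, "population": pop, "calls": calls,
             "tag_matrix": tag_matrix}
    return result, truth


def run_pipeline(vcf_path, parent1: str, parent2: str,
                 tags_path=None, contigs_path=None,
                 config: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """File-based entry point: VCF in, optional tag TSV and contig FASTA."""
    config = config or PipelineConfig()
    calls = formats.read_vcf(vcf_path, parent1=parent1, parent2=parent2)
    result = run_snp_stages(calls, config)
    if tags_path is not None:
        matrix = formats.read_tag_matrix(tags_path)
        run_tag_stages(result, matrix, config)
        if contigs_path is not None:
            contigs = formats.read_fasta(contigs_path)
            run_assembly_stage(result, contigs, config)
    summarize_map(result)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write every stage product as plain text files under ``out_dir``."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.filter_report.to_frame().to_csv(out / "filter_attrition.tsv",
                                           sep="\t", index=False)
    lmap = result.map_final
    lmap.write_tsv(out / "linkage_map.tsv")
    order = lmap.table["row"].to_numpy()
    formats.write_csvr(
        lmap.table["snp_id"], lmap.table["lg"], lmap.table["cm"],
        result.imputed.codes[order], result.imputed.progeny,
        out / "genotypes_imputed.csvr",
    )
    if result.tag_mappings:
        tagmap.tag_mappings_frame(result.tag_mappings).to_csv(
            out / "tag_mappings.tsv", sep="\t", index=False
        )
    if result.haplotypes:
        contighap.haplotypes_frame(result.haplotypes).to_csv(
            out / "contig_haplotypes.tsv", sep="\t", index=False
        )
    if result.layout is not None:
        result.layout.to_frame().to_csv(out / "layout.tsv", sep="\t", index=False)
    if result.sequences is not None:
        formats.write_fasta(result.sequences, out / "pseudomolecules.fasta")
        assembly.write_agp(result.agp, out / "pseudomolecules.agp")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
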