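"""Contig tag haplotypes: pooling concordant mapped tags of a contig.

At low GBS depth a single tag's carrier set is incomplete, so the mapped tags
of a contig are combined into one dominant marker.  The consensus LG is a
majority rule weighted by each tag's informative sample size; the consensus
position is the sample-size-weighted mean of the tags' GeneticMean values.
Tags on the consensus LG within 50 SNP indices of the consensus position are
merged by summing their counts per individual; the haplotype's presence in an
individual requires a count of at least 5% of the mean non-zero count (to
suppress occasional sequencing-error counts), and the merged marker is mapped
like a single tag but with a relaxed 10% recombination-rate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import TagCountMatrix
from .snpfilter import PhasedGenotypeMatrix
from .mapbuild import LinkageMap
from .tagmap import TagMapping, map_all_tags, map_tag, tag_recombination_profile


@dataclass
class ContigHaplotype:
    """Merged tag haplotype for one contig."""

    contig_id: str
    member_tags: list
    discordant_tags: list
    consensus_lg: str | None
    consensus_position: float | None  # SNP-index units
    merged_counts: np.ndarray | None = None
    presence: np.ndarray | None = None
    mapping: TagMapping | None = None

    @property
    def has_consensus(self) -> bool:
        return self.consensus_lg is not None


def contig_consensus(mapped_tags: list):
    """Weighted-majority consensus (LG, position) over one contig's mapped tags.

    LG weight is the sum of tag sample sizes; an exact tie between the top
    LGs gives no consensus (returns (None, None)).  The position is the
    sample-size-weighted mean GeneticMean over tags on the winning LG.
    """
    if not mapped_tags:
        raise ValueError("no mapped tags for contig")
    weights = {}
    for t in mapped_tags:
        weights[t.lg] = weights.get(t.lg, 0) + t.sample_size
    ranked = sorted(weights.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None, None
    lg = ranked[0][0]
    members = [t for t in mapped_tags if t.lg == lg]
    wsum = sum(t.sample_size for t in members)
    pos = sum(t.sample_size * t.genetic_mean for t in members) / wsum
    return lg, pos


def merge_concordant_tags(contig_id: str, mapped_tags: list, consensus,
                          matrix: TagCountMatrix, window: int = 50) -> ContigHaplotype:
    """Merge tags agreeing with the consensus (same LG, within ``window`` SNP
    indices, inclusive) by summing their counts per individual."""
    lg, pos = consensus
    if lg is None:
        return ContigHaplotype(
            contig_id=contig_id, member_tags=[],
            discordant_tags=[t.tag_id for t in mapped_tags],
            consensus_lg=None, consensus_position=None,
        )
    members, discordant = [], []
    for t in mapped_tags:
        if t.lg == lg and abs(t.genetic_mean - pos) <= window:
            members.append(t.tag_id)
        else:
            discordant.append(t.tag_id)
    tag_index = {tid: i for i, tid in enumerate(matrix.tags["tag_id"])}
    rows = [tag_index[tid] for tid in members]
    merged = matrix.counts[rows].sum(axis=0)
    return ContigHaplotype(
        contig_id=contig_id, member_tags=members, discordant_tags=discordant,
        consensus_lg=lg, consensus_position=pos, merged_counts=merged,
    )


def call_presence(merged_counts: np.ndarray, min_fraction: float = 0.05) -> np.ndarray:
    """Presence flags: count >= min_fraction x mean of the non-zero counts."""
    counts = np.asarray(merged_counts)
    nz = counts[counts > 0]
    if nz.size == 0:
        raise ValueError("all merged counts are zero")
    threshold = min_fraction * nz.mean()
    return counts >= threshold


def map_haplotype(presence: np.ndarray, phased: PhasedGenotypeMatrix,
                  lmap: LinkageMap, contig_id: str = "",
                  max_rec_rate: float = 0.10, min_sample: int = 30) -> TagMapping:
    """Map a contig tag haplotype exactly like a tag, at the relaxed threshold."""
    profile = tag_recombination_profile(presence, phased, lmap)
    return map_tag(profile, tag_id=contig_id,
                   max_rec_rate=max_rec_rate, min_sample=min_sample)


def build_contig_haplotypes(matrix: TagCountMatrix, tag_mappings: list,
                            phased: PhasedGenotypeMatrix, lmap: LinkageMap,
                            window: int = 50, presence_fraction: float = 0.05,
                            max_rec_rate: float = 0.10,
                            min_sample: int = 30) -> list:
    """Consensus, merge, presence-call and map every contig with mapped tags.

    ``tag_mappings`` must be parallel to ``matrix`` rows.  Contigs whose every
    tag is individually unmapped get no haplotype.
    """
    by_contig = {}
    contig_of = dict(zip(matrix.tags["tag_id"], matrix.tags["contig"]))
    for m in tag_mappings:
        if m.mapped:
            by_contig.setdefault(contig_of[m.tag_id], []).append(m)
    haplotypes = []
    for contig_id in sorted(by_contig):
        mapped = by_contig[contig_id]
        consensus = contig_consensus(mapped)
        hap = merge_concordant_tags(contig_id, mapped, consensus, matrix, window)
        if hap.has_consensus and hap.merged_counts is not None and hap.merged_counts.sum() > 0:
            hap.presence = call_presence(hap.merged_counts, presence_fraction)
            hap.mapping = map_haplotype(
                hap.presence, phased, lmap, contig_id=contig_id,
                max_rec_rate=max_rec_rate, min_sample=min_sample,
            )
        haplotypes.append(hap)
    return haplotypes


def haplotypes_frame(haplotypes: list) -> pd.DataFrame:
    """Per-contig TSV-shaped summary of haplotype construction and mapping."""
    rows = []
    for h in haplotypes:
        m = h.mapping
        rows.append(
            {
                "contig_id": h.contig_id,
                "n_tags": len(h.member_tags) + len(h.discordant_tags),
                "n_discordant": len(h.discordant_tags),
                "consensus_lg": h.consensus_lg,
                "consensus_position": h.consensus_position,
                "status": m.status if m is not None else "no-consensus",
                "lg": m.lg if m is not None else None,
                "min_rec_rate": m.min_rec_rate if m is not None else np.nan,
                "genetic_start": m.genetic_start if m is not None else None,
                "genetic_end": m.genetic_end if m is not None else None,
                "genetic_mean": m.genetic_mean if m is not None else None,
            }
        )
    return pd.DataFrame(rows)
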