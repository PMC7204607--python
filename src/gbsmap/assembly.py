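"""Rule-based assembly of genetically mapped contigs into pseudomolecules.

Ordering rules:

1. Contigs placed on the map via segregating SNPs keep their relative map
   order.  (a) A contig with multiple mapped SNPs is quasi-oriented when the
   cM position differs between its first and last SNP by physical position
   (minus strand when the first physical SNP sits at the higher cM).  (b)
   Comingled contigs are ordered by the map position of their first SNP.
   (c) A contig whose SNPs split across LGs is resolved by majority SNP vote;
   an exact tie removes the contig from the assembly, and minority SNPs are
   dropped.
2. Contigs mapped only by tag haplotype are inserted immediately after the
   contig containing their GeneticMean SNP (floor of a fractional mean), tied
   insertions sorted by (GeneticStart, GeneticEnd, contig type with scaffold
   before contig, contig name); they stay unoriented.
3. Ordered contigs on a pseudomolecule are separated by exactly 100 N's.
4. Pseudomolecules are named after their linkage groups (LG-1, LG-2, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .formats import ContigSet, contig_type
from .mapbuild import LinkageMap

logger = logging.getLogger(__name__)

GAP_LENGTH = 100


@dataclass
class LayoutEntry:
    contig_id: str
    source: str  # snp | tag | both
    orientation: str  # + | - | ?
    anchor: tuple = ()


@dataclass
class PseudomoleculeLayout:
    """Ordered, quasi-oriented contigs per LG (AGP-representable)."""

    entries: dict  # lg name -> list of LayoutEntry
    removed_contigs: list = field(default_factory=list)
    gap_length: int = GAP_LENGTH

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lg, items in self.entries.items():
            for rank, e in enumerate(items, start=1):
                rows.append((lg, rank, e.contig_id, e.source, e.orientation,
                             ";".join(str(a) for a in e.anchor)))
        return pd.DataFrame(
            rows, columns=["lg", "rank", "contig_id", "source", "orientation",
                           "anchor"]
        )


def order_snp_contigs(lmap: LinkageMap, snp_meta: pd.DataFrame):
    """Rule 1: order and quasi-orient SNP-anchored contigs per LG.

    ``snp_meta`` maps snp_id -> contig, pos (physical, 1-based).  Returns
    (entries, removed): entries is {lg: [LayoutEntry(source='snp')]} and
    removed lists contigs dropped for an exact cross-LG SNP tie.
    """
    t = lmap.table.merge(snp_meta[["snp_id", "contig", "pos"]], on="snp_id",
                         how="left")
    if t["contig"].isna().any():
        missing = t.loc[t["contig"].isna(), "snp_id"].tolist()
        raise ValueError(f"no contig metadata for SNPs: {missing[:5]}")
    removed = []
    keep_rows = []
    for contig, sub in t.groupby("contig", sort=False):
        votes = sub["lg"].value_counts()
        if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
            removed.append(str(contig))
            logger.info("contig %s removed: equal SNP votes across LGs", contig)
            continue
        winner = votes.index[0]
        dropped = int((sub["lg"] != winner).sum())
        if dropped:
            logger.info("contig %s: %d minority SNP(s) on other LGs dropped",
                        contig, dropped)
        keep_rows.append(sub[sub["lg"] == winner])
    kept = pd.concat(keep_rows, ignore_index=True) if keep_rows else t.iloc[0:0]

    entries = {}
    for lg in lmap.lg_names:
        sub = kept[kept["lg"] == lg]
        if sub.empty:
            entries[lg] = []
            continue
        per_contig = []
        for contig, grp in sub.groupby("contig", sort=False):
            first_cm = grp["cm"].min()
            first_idx = int(grp["lg_index"].min())
            by_phys = grp.sort_values("pos", kind="stable")
            cm_first_phys = float(by_phys["cm"].iloc[0])
            cm_last_phys = float(by_phys["cm"].iloc[-1])
            if cm_first_phys < cm_last_phys:
                orient = "+"
            elif cm_first_phys > cm_last_phys:
                orient = "-"
            else:
                orient = "?"
            per_contig.append(
                (first_cm, first_idx, str(contig),
                 LayoutEntry(contig_id=str(contig), source="snp",
                             orientation=orient,
                             anchor=(round(float(grp["cm"].min()), 6),
                                     round(float(grp["cm"].max()), 6))))
            )
        per_contig.sort(key=lambda x: (x[0], x[1], x[2]))
        entries[lg] = [e for _, _, _, e in per_contig]
    return entries, removed


def place_tag_contigs(snp_entries: dict, removed: list, tag_only: pd.DataFrame,
                      lmap: LinkageMap, snp_meta: pd.DataFrame) -> PseudomoleculeLayout:
    """Rule 2: insert tag-haplotype-only contigs after their GeneticMean host.

    ``tag_only`` rows: contig_id, lg, genetic_start, genetic_end,
    genetic_mean (SNP-index units on the LG).  A fractional GeneticMean is
    floored to pick the host SNP; when the host contig was removed under rule
    1c, the nearest retained preceding host is used (logged).
    """
    contig_of_snp = dict(zip(snp_meta["snp_id"], snp_meta["contig"]))
    idx_to_contig = {}  # (lg, lg_index) -> host contig id
    for _, r in lmap.table.iterrows():
        idx_to_contig[(r["lg"], int(r["lg_index"]))] = str(contig_of_snp[r["snp_id"]])

    entries = {lg: list(items) for lg, items in snp_entries.items()}
    pending = {}  # (lg, host contig) -> list of sort-keyed entries
    for _, row in tag_only.iterrows():
        lg = row["lg"]
        if lg not in entries:
            continue
        retained = {e.contig_id for e in entries[lg]}
        host_idx = int(np.floor(row["genetic_mean"]))
        host = idx_to_contig.get((lg, host_idx))
        # walk toward the start until a retained SNP-anchored host is found
        probe = host_idx
        while probe >= 1 and (host is None or host not in retained):
            probe -= 1
            host = idx_to_contig.get((lg, probe))
        if host is None or host not in retained:
            logger.info("tag contig %s: no retained preceding host on %s; "
                        "placed first", row["contig_id"], lg)
            host = None
        elif idx_to_contig.get((lg, host_idx)) != host:
            logger.info("tag contig %s: host of SNP %d removed; using %s",
                        row["contig_id"], host_idx, host)
        key = (
            row["genetic_start"], row["genetic_end"],
            0 if contig_type(str(row["contig_id"])) == "scaffold" else 1,
            str(row["contig_id"]),
        )
        pending.setdefault((lg, host), []).append(
            (key, LayoutEntry(contig_id=str(row["contig_id"]), source="tag",
                              orientation="?",
                              anchor=(row["genetic_start"], row["genetic_end"],
                                      row["genetic_mean"])))
        )

    out = {}
    for lg, items in entries.items():
        new_items = [
            e for _, e in sorted(pending.get((lg, None), []), key=lambda x: x[0])
        ]
        for e in items:
            new_items.append(e)
            inserts = pending.get((lg, e.contig_id), [])
            new_items.extend(ins for _, ins in sorted(inserts, key=lambda x: x[0]))
        out[lg] = new_items
    return PseudomoleculeLayout(entries=out, removed_contigs=list(removed))


def mark_dual_source(layout: PseudomoleculeLayout, haplotype_mapped: set) -> None:
    """Relabel SNP-anchored contigs that also carry a mapped tag haplotype."""
    for items in layout.entries.values():
        for e in items:
            if e.source == "snp" and e.contig_id in haplotype_mapped:
                e.source = "both"


def build_pseudomolecules(layout: PseudomoleculeLayout, contigs: ContigSet):
    """Rule 3+4: emit per-LG sequences joined by 100 N's, plus AGP 2.1 rows.

    Returns (sequences: {lg: str}, agp: DataFrame).  Minus-strand contigs are
    reverse-complemented; unoriented contigs are emitted forward with AGP
    orientation '?'.  Output is deterministic given identical inputs.
    """
    sequences = {}
    agp_rows = []
    gap = "N" * layout.gap_length
    for lg, items in layout.entries.items():
        parts = []
        pos = 0
        part_no = 0
        for i, e in enumerate(items):
            if e.contig_id not in contigs:
                raise ValueError(f"contig {e.contig_id} missing from sequence set")
            if i > 0:
                part_no += 1
                agp_rows.append((lg, pos + 1, pos + layout.gap_length, part_no,
                                 "U", layout.gap_length, "scaffold", "yes", "map"))
                parts.append(gap)
                pos += layout.gap_length
            seq = contigs[e.contig_id]
            if e.orientation == "-":
                seq = str(Seq(seq).reverse_complement())
            part_no += 1
            agp_rows.append((lg, pos + 1, pos + len(seq), part_no, "W",
                             e.contig_id, 1, len(seq), e.orientation))
            parts.append(seq)
            pos += len(seq)
        sequences[lg] = "".join(parts)
    agp = pd.DataFrame(
        agp_rows,
        columns=["object", "object_beg", "object_end", "part_number",
                 "component_type", "component_id_or_gap_length",
                 "component_beg_or_gap_type", "component_end_or_linkage",
                 "orientation_or_evidence"],
    )
    return sequences, agp


def write_agp(agp: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)
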