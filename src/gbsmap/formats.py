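"""Readers and writers for the external representations shared by the pipeline.

Genotype calls are held in a :class:`SnpCallSet` (integer-coded calls plus
per-call read depths), dominant GBS tag counts in a :class:`TagCountMatrix`
(tag metadata plus a tag x sample count matrix), and nucleotide sequences in a
:class:`ContigSet`.  All external coordinates are 1-based (VCF convention).

Call codes used throughout the package::

    0  homozygous reference
    1  heterozygous
    2  homozygous alternate
   -1  missing

VCF is read with :mod:`cyvcf2`; multiallelic records are skipped (the analysis
is biallelic throughout) and the skipped count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class SnpCallSet:
    """Genotype calls + depths for parents and progeny at contig-anchored sites.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers.  ``parent1``/``parent2`` name the two
        designated parents; every other sample is progeny.
    sites : pandas.DataFrame
        One row per site with columns ``contig``, ``pos`` (1-based bp),
        ``ref``, ``alt``.  (contig, pos) pairs are unique.
    calls : numpy.ndarray, int8, shape (n_sites, n_samples)
    depth : numpy.ndarray, int32, shape (n_sites, n_samples)
    """

    samples: list
    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray
    parent1: str | None = None
    parent2: str | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError("calls shape does not match sites x samples")
        if self.depth.shape != self.calls.shape:
            raise ValueError("depth shape does not match calls")
        key = self.sites[["contig", "pos"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("duplicate (contig, pos) site")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def progeny_indices(self) -> np.ndarray:
        par = {self.parent1, self.parent2}
        return np.array([i for i, s in enumerate(self.samples) if s not in par])

    @property
    def progeny(self) -> list:
        par = {self.parent1, self.parent2}
        return [s for s in self.samples if s not in par]

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def subset_sites(self, mask: np.ndarray) -> "SnpCallSet":
        mask = np.asarray(mask)
        return SnpCallSet(
            samples=list(self.samples),
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[mask],
            depth=self.depth[mask],
            parent1=self.parent1,
            parent2=self.parent2,
        )


@dataclass
class TagCountMatrix:
    """Dominant 64-base GBS tags with alignment metadata and per-sample counts.

    ``tags`` has one row per tag: ``tag_id``, ``sequence``, ``contig``, ``pos``
    (1-based), ``strand``, ``unique`` (uniquely aligned flag), ``divergent``.
    ``counts`` is (n_tags, n_samples) non-negative int.
    """

    tags: pd.DataFrame
    samples: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.tags), len(self.samples)):
            raise ValueError("counts shape does not match tags x samples")
        if self.tags["tag_id"].duplicated().any():
            raise ValueError("duplicated tag id")
        if (self.counts < 0).any():
            raise ValueError("negative tag count")

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def subset_tags(self, mask: np.ndarray) -> "TagCountMatrix":
        mask = np.asarray(mask)
        return TagCountMatrix(
            tags=self.tags.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            counts=self.counts[mask],
        )

    def subset_samples(self, names: list) -> "TagCountMatrix":
        idx = [self.samples.index(n) for n in names]
        return TagCountMatrix(
            tags=self.tags.copy(), samples=list(names), counts=self.counts[:, idx]
        )


def contig_type(contig_id: str) -> str:
    """Classify a contig id as ``scaffold`` or ``contig`` from its name prefix."""
    return "scaffold" if contig_id.lower().startswith("scaffold") else "contig"


@dataclass
class ContigSet:
    """Mapping from contig id to nucleotide sequence (plain str)."""

    sequences: dict = field(default_factory=dict)

    def __post_init__(self):
        for cid, seq in self.sequences.items():
            if len(seq) == 0:
                raise ValueError(f"empty sequence for contig {cid}")

    def __getitem__(self, cid: str) -> str:
        return self.sequences[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def type_of(self, cid: str) -> str:
        return contig_type(cid)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(callset: SnpCallSet, path) -> None:
    """Write a minimal VCF 4.2 with GT and DP per sample."""
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for contig in pd.unique(callset.sites["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(callset.samples)
            + "\n"
        )
        sites = callset.sites
        for i in range(callset.n_sites):
            row = sites.iloc[i]
            fields = [
                str(row["contig"]),
                str(int(row["pos"])),
                ".",
                str(row["ref"]),
                str(row["alt"]),
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for j in range(len(callset.samples)):
                fields.append(
                    f"{gt_str[int(callset.calls[i, j])]}:{int(callset.depth[i, j])}"
                )
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, parent1: str | None = None, parent2: str | None = None) -> SnpCallSet:
    """Read a VCF with GT and DP into a :class:`SnpCallSet`.

    Multiallelic sites are skipped (count logged).  A record without a DP
    value raises an error naming the site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    contigs, poss, refs, alts = [], [], [], []
    calls_rows, depth_rows = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        dp = var.format("DP")
        if dp is None:
            raise ValueError(f"missing DP field at {var.CHROM}:{var.POS}")
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = var.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        d = dp.reshape(-1).astype(np.int64)
        d[d < 0] = 0  # cyvcf2 encodes missing DP as a negative sentinel
        contigs.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        calls_rows.append(gt)
        depth_rows.append(d)
    vcf.close()
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic sites", n_multi)
    sites = pd.DataFrame({"contig": contigs, "pos": poss, "ref": refs, "alt": alts})
    calls = np.array(calls_rows, dtype=np.int8).reshape(len(sites), len(samples))
    depth = np.array(depth_rows, dtype=np.int32).reshape(len(sites), len(samples))
    return SnpCallSet(
        samples=samples, sites=sites, calls=calls, depth=depth,
        parent1=parent1, parent2=parent2,
    )


# ---------------------------------------------------------------------------
# Tag count matrix (TSV)
# ---------------------------------------------------------------------------

_TAG_META_COLS = ["tag_id", "sequence", "contig", "pos", "strand", "unique", "divergent"]


def write_tag_matrix(matrix: TagCountMatrix, path) -> None:
    df = matrix.tags[_TAG_META_COLS].copy()
    df["unique"] = df["unique"].astype(int)
    df["divergent"] = df["divergent"].astype(int)
    counts = pd.DataFrame(matrix.counts, columns=matrix.samples)
    pd.concat([df.reset_index(drop=True), counts], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_tag_matrix(path) -> TagCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"tag_id": str, "contig": str})
    missing_cols = [c for c in _TAG_META_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"tag matrix header missing columns: {missing_cols}")
    sample_cols = [c for c in df.columns if c not in _TAG_META_COLS]
    if not sample_cols:
        raise ValueError("tag matrix has no sample columns")
    counts = df[sample_cols]
    if counts.isna().any().any():
        raise ValueError("empty count cell in tag matrix (counts must be explicit)")
    counts = counts.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        as_int = counts.astype(np.int64)
        if not np.array_equal(as_int, counts):
            raise ValueError("non-integer tag count")
        counts = as_int
    if (counts < 0).any():
        raise ValueError("negative tag count")
    tags = df[_TAG_META_COLS].copy()
    tags["unique"] = tags["unique"].astype(bool)
    tags["divergent"] = tags["divergent"].astype(bool)
    return TagCountMatrix(tags=tags, samples=sample_cols, counts=counts)


def filter_tags_unique(matrix: TagCountMatrix) -> TagCountMatrix:
    """Retain only uniquely aligned, non-divergent tags."""
    keep = (matrix.tags["unique"] & ~matrix.tags["divergent"]).to_numpy()
    return matrix.subset_tags(keep)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> ContigSet:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return ContigSet(sequences=seqs)


# ---------------------------------------------------------------------------
# csvr genotype table (markers as rows: id, LG, cM, genotype codes A/H/B/-)
# ---------------------------------------------------------------------------

_CSVR_CODE = {0: "A", 1: "H", 2: "B", -1: "-"}
_CSVR_DECODE = {v: k for k, v in _CSVR_CODE.items()}


def write_csvr(marker_ids, lgs, cms, codes: np.ndarray, progeny: list, path) -> None:
    """Write a rotated genotype table: one marker per row.

    Columns: marker id, linkage group, cM position, then one A/H/B/- code per
    progeny individual.  The first row carries the progeny ids in the genotype
    columns (lg/cM blank), so the file round-trips.
    """
    with open(path, "w") as fh:
        fh.write("id,,," + ",".join(progeny) + "\n")
        for mid, lg, cm, row in zip(marker_ids, lgs, cms, codes):
            genos = ",".join(_CSVR_CODE[int(c)] for c in row)
            fh.write(f"{mid},{lg},{cm:.4f},{genos}\n")


def read_csvr(path):
    """Read a rotated genotype table written by :func:`write_csvr`.

    Returns (marker_ids, lgs, cms, codes, progeny).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        progeny = header[3:]
        ids, lgs, cms, rows = [], [], [], []
        for line in fh:
            parts = line.rstrip("\n").split(",")
            ids.append(parts[0])
            lgs.append(parts[1])
            cms.append(float(parts[2]) if parts[2] else np.nan)
            rows.append([_CSVR_DECODE[c] for c in parts[3:]])
    codes = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(progeny)), np.int8)
    return ids, lgs, np.array(cms), codes, progeny
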