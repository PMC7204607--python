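"""SNP filtering cascade, parental phasing, and per-individual heterozygosity.

The cascade, applied in this fixed order, prepares biallelic GBS SNPs for F2
linkage mapping:

1. minor allele frequency >= 0.40 over progeny,
2. genotypes below read depth 7 set to missing,
3. sites with > 10% missing progeny genotypes discarded,
4. sites deviating from 1:2:1 segregation at p < 0.01 discarded,
5. greedy thinning so no two kept SNPs on a contig are < 65 bp apart
   (one SNP per 64-base tag locus),
6. phasing on the two inbred parents into A/H/B/U codes.

MAF and missingness are computed over progeny only; the filters serve the F2
segregation analysis, and the parents are used solely for phasing.
Each filter returns a subset of its input sites and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import SnpCallSet, HOM_REF, HET, HOM_ALT, MISSING

A, H, B, U = 0, 1, 2, -1


@dataclass
class PhasedGenotypeMatrix:
    """F2 genotypes recoded by parental origin.

    ``codes`` is (n_snps, n_progeny) int8 with A=0 (homozygous parent-1),
    H=1, B=2 (homozygous parent-2), U=-1 (missing).  ``sites`` carries the
    retained (contig, pos) rows in input order with a ``snp_id`` column.
    """

    progeny: list
    sites: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sites), len(self.progeny)):
            raise ValueError("codes shape does not match sites x progeny")

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    def subset_snps(self, mask) -> "PhasedGenotypeMatrix":
        mask = np.asarray(mask)
        return PhasedGenotypeMatrix(
            progeny=list(self.progeny),
            sites=self.sites.loc[mask].reset_index(drop=True),
            codes=self.codes[mask],
        )

    def subset_progeny(self, names) -> "PhasedGenotypeMatrix":
        idx = [self.progeny.index(n) for n in names]
        return PhasedGenotypeMatrix(
            progeny=list(names), sites=self.sites.copy(), codes=self.codes[:, idx]
        )


def _progeny_calls(calls: SnpCallSet) -> np.ndarray:
    return calls.calls[:, calls.progeny_indices]


def filter_maf(calls: SnpCallSet, min_maf: float = 0.40) -> SnpCallSet:
    """Retain sites with minor allele frequency >= ``min_maf`` over progeny.

    Allele frequency counts two copies for a homozygote and one of each for a
    heterozygote, over non-missing progeny calls.  Sites with zero non-missing
    progeny calls are removed.
    """
    g = _progeny_calls(calls)
    n_called = (g != MISSING).sum(axis=1)
    alt_copies = (g == HET).sum(axis=1) + 2 * (g == HOM_ALT).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt_copies / (2.0 * n_called), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep = (n_called > 0) & (maf >= min_maf)
    return calls.subset_sites(keep)


def mask_low_depth(calls: SnpCallSet, min_depth: int = 7) -> SnpCallSet:
    """Set any genotype supported by fewer than ``min_depth`` reads to missing."""
    new_calls = calls.calls.copy()
    new_calls[calls.depth < min_depth] = MISSING
    return SnpCallSet(
        samples=list(calls.samples), sites=calls.sites.copy(),
        calls=new_calls, depth=calls.depth.copy(),
        parent1=calls.parent1, parent2=calls.parent2,
    )


def filter_missing(calls: SnpCallSet, max_missing: float = 0.10) -> SnpCallSet:
    """Discard sites with more than ``max_missing`` missing progeny genotypes."""
    g = _progeny_calls(calls)
    frac = (g == MISSING).mean(axis=1)
    return calls.subset_sites(frac <= max_missing)


def test_segregation_121(n_a: int, n_h: int, n_b: int) -> float:
    """Chi-square goodness-of-fit p-value against 1:2:1 (df = 2)."""
    n = n_a + n_h + n_b
    if n == 0:
        raise ValueError("all-zero genotype counts")
    expected = np.array([n / 4.0, n / 2.0, n / 4.0])
    observed = np.array([n_a, n_h, n_b], dtype=float)
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(stat, df=2))


def filter_segregation(calls: SnpCallSet, min_p: float = 0.01) -> SnpCallSet:
    """Discard sites deviating from 1:2:1 segregation at p < ``min_p``.

    Counts are homRef : het : homAlt over non-missing progeny calls; sites
    with zero non-missing calls are removed.
    """
    g = _progeny_calls(calls)
    n_a = (g == HOM_REF).sum(axis=1)
    n_h = (g == HET).sum(axis=1)
    n_b = (g == HOM_ALT).sum(axis=1)
    n = n_a + n_h + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (
            (n_a - n / 4.0) ** 2 / (n / 4.0)
            + (n_h - n / 2.0) ** 2 / (n / 2.0)
            + (n_b - n / 4.0) ** 2 / (n / 4.0)
        )
    p = stats.chi2.sf(stat, df=2)
    keep = (n > 0) & (p >= min_p)
    return calls.subset_sites(keep)


def thin_snps(calls: SnpCallSet, min_spacing: int = 65) -> SnpCallSet:
    """Greedy per-contig thinning: keep a SNP only if it is >= ``min_spacing``
    bases after the last kept SNP on the same contig (lowest position first).
    """
    keep = np.zeros(calls.n_sites, dtype=bool)
    sites = calls.sites
    for _, idx in sites.groupby("contig", sort=False).groups.items():
        idx = np.asarray(idx)
        order = idx[np.argsort(sites.loc[idx, "pos"].to_numpy(), kind="stable")]
        last = None
        for i in order:
            pos = int(sites.at[i, "pos"])
            if last is None or pos - last >= min_spacing:
                keep[i] = True
                last = pos
    return calls.subset_sites(keep)


def phase_by_parents(calls: SnpCallSet) -> PhasedGenotypeMatrix:
    """Recode progeny genotypes by parental origin.

    Only sites where both parents are called homozygous for different alleles
    are informative; progeny homozygous for the parent-1 allele become A,
    heterozygotes H, homozygous parent-2 B, missing U.  Polarity follows the
    parents, not ref/alt.  Sites with a heterozygous, missing, or identical
    parent call are dropped.
    """
    if calls.parent1 is None or calls.parent2 is None:
        raise ValueError("both parent samples must be designated")
    p1 = calls.calls[:, calls.sample_index(calls.parent1)]
    p2 = calls.calls[:, calls.sample_index(calls.parent2)]
    hom = np.isin(p1, (HOM_REF, HOM_ALT)) & np.isin(p2, (HOM_REF, HOM_ALT))
    informative = hom & (p1 != p2)
    g = _progeny_calls(calls)[informative]
    p1_i = p1[informative]
    codes = np.full(g.shape, U, dtype=np.int8)
    codes[g == HET] = H
    # progeny call equals parent-1's homozygous call -> A, the other hom -> B
    codes[(g == p1_i[:, None]) & (g != MISSING) & (g != HET)] = A
    other = (2 - p1_i)[:, None]  # HOM_REF <-> HOM_ALT
    codes[(g == other) & (g != MISSING) & (g != HET)] = B
    sites = calls.sites.loc[informative].reset_index(drop=True).copy()
    sites.insert(0, "snp_id", sites["contig"].astype(str) + "_" + sites["pos"].astype(str))
    return PhasedGenotypeMatrix(progeny=calls.progeny, sites=sites, codes=codes)


@dataclass
class FilterReport:
    """Per-step attrition of the cascade."""

    steps: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "sites_in", "sites_out"])


def run_filter_cascade(
    calls: SnpCallSet,
    min_maf: float = 0.40,
    min_depth: int = 7,
    max_missing: float = 0.10,
    seg_p: float = 0.01,
    thin_bp: int = 65,
):
    """Apply filters (1)-(6) in the fixed order; returns (phased, report)."""
    steps = []
    stage = filter_maf(calls, min_maf)
    steps.append(("maf", calls.n_sites, stage.n_sites))
    stage2 = mask_low_depth(stage, min_depth)
    steps.append(("depth_mask", stage.n_sites, stage2.n_sites))
    stage3 = filter_missing(stage2, max_missing)
    steps.append(("missing", stage2.n_sites, stage3.n_sites))
    stage4 = filter_segregation(stage3, seg_p)
    steps.append(("segregation_121", stage3.n_sites, stage4.n_sites))
    stage5 = thin_snps(stage4, thin_bp)
    steps.append(("thin", stage4.n_sites, stage5.n_sites))
    phased = phase_by_parents(stage5)
    steps.append(("phase", stage5.n_sites, phased.n_snps))
    return phased, FilterReport(steps=steps)


# ---------------------------------------------------------------------------
# Heterozygosity / inbreeding statistics
# ---------------------------------------------------------------------------

def het_summary_from_counts(nl: int, nho: int, nhe: float):
    """(PHo, F) from per-individual locus counts: PHo = NHo/NL, F = 1 - NHo/NHe."""
    pho = nho / nl if nl > 0 else np.nan
    f = 1.0 - nho / nhe if nhe > 0 else np.nan
    return pho, f


def het_stats(calls: SnpCallSet) -> pd.DataFrame:
    """Per-sample observed/expected heterozygosity and inbreeding coefficient.

    For each sample, over its non-missing loci: NL = locus count, NHo =
    heterozygous calls, NHe = sum over loci of 2p(1-p) * n/(n-1) with p the
    alternate allele frequency over all samples and n the number of observed
    alleles at the locus (the finite-sample correction of the usual
    ``--het``-style expected heterozygosity).  PHo = NHo/NL, F = 1 - NHo/NHe.
    """
    g = calls.calls
    called = g != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt_copies = (g == HET).sum(axis=1) + 2 * (g == HOM_ALT).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_copies / n_alleles
        exp_het = 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0)
    exp_het = np.where(n_alleles > 1, exp_het, 0.0)
    rows = []
    for j, sample in enumerate(calls.samples):
        m = called[:, j]
        nl = int(m.sum())
        nho = int((g[:, j] == HET).sum())
        nhe = float(exp_het[m].sum())
        pho, f = het_summary_from_counts(nl, nho, nhe)
        rows.append((sample, nl, nho, nhe, pho, f))
    return pd.DataFrame(rows, columns=["sample", "NL", "NHo", "NHe", "PHo", "F"])
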