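"""Genetic mapping of dominant presence/absence GBS tags against a linkage map.

At low sequencing depth the absence of a tag is uninformative, so only the
progeny in which a tag was observed (its carriers) are used.  For every SNP on
the map, among carriers homozygous at that SNP (heterozygotes are excluded as
non-informative), the recombination rate between tag and SNP is::

    min( nHomPar2 / (nHomPar1 + nHomPar2), nHomPar1 / (nHomPar1 + nHomPar2) )

A tag is genetically mapped when the global minimum of this rate is below 5%
with at least 30 informative homozygotes at an achieving SNP; the two-tailed
binomial tail for that threshold configuration (n = 30, k <= 1) is below
6e-8, which is what makes the single-tag gate trustworthy.  The mapped span
(GeneticStart..GeneticEnd) runs from the first to the last SNP on the linkage
group achieving the same minimum rate (compared exactly, by
cross-multiplication of the integer counts), and GeneticMean is the midpoint
of the span, in consecutive SNP-index units.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .formats import TagCountMatrix
from .snpfilter import PhasedGenotypeMatrix, A, B
from .mapbuild import LinkageMap


@dataclass
class TagMapping:
    """Anchoring result for one dominant tag (or contig tag haplotype)."""

    tag_id: str
    status: str  # mapped | unlinked | ambiguous | no-data
    lg: str | None = None
    n_hom_par1: int = 0
    n_hom_par2: int = 0
    min_rec_rate: float = np.nan
    p_binomial: float = np.nan
    genetic_start: int | None = None
    genetic_end: int | None = None
    genetic_mean: float | None = None

    @property
    def sample_size(self) -> int:
        return self.n_hom_par1 + self.n_hom_par2

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"


def filter_segregating_tags(matrix: TagCountMatrix, retained_individuals: list,
                            min_present: int = 30,
                            max_present: int | None = None) -> TagCountMatrix:
    """Restrict to retained F2 individuals and keep segregating tags.

    A tag is kept when present (count > 0) in at least ``min_present`` and at
    most ``max_present`` of the retained individuals.  ``max_present``
    defaults to the literal 256 when exactly 366 individuals are retained and
    to floor(0.80 * N) otherwise.
    """
    sub = matrix.subset_samples(retained_individuals)
    n = len(retained_individuals)
    if max_present is None:
        max_present = 256 if n == 366 else int(np.floor(0.80 * n))
    present = (sub.counts > 0).sum(axis=1)
    return sub.subset_tags((present >= min_present) & (present <= max_present))


def tag_recombination_profile(tag_presence: np.ndarray,
                              phased: PhasedGenotypeMatrix,
                              lmap: LinkageMap):
    """Per-map-SNP (recRate, n1, n2) for one tag.

    ``tag_presence``: boolean per progeny (carrier flags).  Returns a
    DataFrame aligned with ``lmap.table``: columns n1, n2, rec_rate (NaN where
    n1 + n2 = 0).
    """
    carriers = np.asarray(tag_presence, dtype=bool)
    rows = lmap.table["row"].to_numpy()
    codes = phased.codes[np.ix_(rows, np.flatnonzero(carriers))]
    n1 = (codes == A).sum(axis=1)
    n2 = (codes == B).sum(axis=1)
    tot = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(tot > 0, np.minimum(n1, n2) / np.maximum(tot, 1), np.nan)
    return pd.DataFrame(
        {"snp_id": lmap.table["snp_id"].to_numpy(),
         "lg": lmap.table["lg"].to_numpy(),
         "lg_index": lmap.table["lg_index"].to_numpy(),
         "n1": n1, "n2": n2, "rec_rate": rate}
    )


def binomial_two_tailed_p(k: int, n: int) -> float:
    """Two-tailed tail probability min(1, 2 P(X <= min(k, n-k))) for
    X ~ Binomial(n, 1/2).

    ``k`` is folded onto the smaller tail, so the result is symmetric in
    k <-> n-k.  Computed in exact rational arithmetic (the gate operates at
    probabilities around 1e-8 where floating-point summation error would
    matter).
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    k = min(k, n - k)
    total = 0
    c = 1
    for i in range(k + 1):
        total += c
        c = c * (n - i) // (i + 1)
    p = 2 * Fraction(total, 2**n)
    return float(min(p, Fraction(1)))


def _min_rate_spans(profile: pd.DataFrame):
    """Exact-minimum SNPs by cross-multiplied rational comparison.

    Returns (achieving mask, k_star, m_star) where the minimum rate is
    k_star/m_star; mask is all-False when no rate is defined.
    """
    n1 = profile["n1"].to_numpy(dtype=np.int64)
    n2 = profile["n2"].to_numpy(dtype=np.int64)
    tot = n1 + n2
    k = np.minimum(n1, n2)
    defined = tot > 0
    if not defined.any():
        return np.zeros(len(profile), dtype=bool), 0, 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(defined, k / np.maximum(tot, 1), np.inf)
    i_star = int(np.argmin(rate))
    k_star, m_star = int(k[i_star]), int(tot[i_star])
    achieving = defined & (k * m_star == k_star * tot)
    return achieving, k_star, m_star


def map_tag(profile: pd.DataFrame, tag_id: str = "",
            max_rec_rate: float = 0.05, min_sample: int = 30) -> TagMapping:
    """Decide whether a tag is genetically mapped and locate its span.

    The global minimum recombination rate must be below ``max_rec_rate`` and
    the sample size at an achieving SNP at least ``min_sample``.  A minimum
    achieved on more than one LG is ambiguous (unmapped).
    """
    achieving, k_star, m_star = _min_rate_spans(profile)
    if not achieving.any():
        return TagMapping(tag_id=tag_id, status="no-data")
    r_star = k_star / m_star
    ach = profile.loc[achieving]
    lgs = ach["lg"].unique()
    if r_star >= max_rec_rate:
        return TagMapping(tag_id=tag_id, status="unlinked", min_rec_rate=r_star)
    if len(lgs) > 1:
        return TagMapping(tag_id=tag_id, status="ambiguous", min_rec_rate=r_star)
    best = ach.loc[ach["n1"] + ach["n2"] == (ach["n1"] + ach["n2"]).max()].iloc[0]
    sample = int(best["n1"] + best["n2"])
    if sample < min_sample:
        return TagMapping(tag_id=tag_id, status="unlinked", min_rec_rate=r_star)
    start = int(ach["lg_index"].min())
    end = int(ach["lg_index"].max())
    return TagMapping(
        tag_id=tag_id,
        status="mapped",
        lg=str(lgs[0]),
        n_hom_par1=int(best["n1"]),
        n_hom_par2=int(best["n2"]),
        min_rec_rate=r_star,
        p_binomial=binomial_two_tailed_p(min(int(best["n1"]), int(best["n2"])), sample),
        genetic_start=start,
        genetic_end=end,
        genetic_mean=(start + end) / 2.0,
    )


def map_all_tags(matrix: TagCountMatrix, phased: PhasedGenotypeMatrix,
                 lmap: LinkageMap, max_rec_rate: float = 0.05,
                 min_sample: int = 30) -> list:
    """Map every tag in the matrix; progeny order must match ``phased``.

    Vectorised over tags: informative homozygote counts for all tags at all
    map SNPs come from two indicator matrix products.
    """
    if list(matrix.samples) != list(phased.progeny):
        raise ValueError("tag matrix samples must match phased progeny order")
    rows = lmap.table["row"].to_numpy()
    codes = phased.codes[rows]  # (n_snps, n_ind)
    isA = (codes == A).astype(np.float32)
    isB = (codes == B).astype(np.float32)
    P = (matrix.counts > 0).astype(np.float32)  # (n_tags, n_ind)
    N1 = np.rint(P @ isA.T).astype(np.int64)  # (n_tags, n_snps)
    N2 = np.rint(P @ isB.T).astype(np.int64)
    base = lmap.table[["snp_id", "lg", "lg_index"]].reset_index(drop=True)
    results = []
    for t in range(matrix.n_tags):
        profile = base.copy()
        profile["n1"] = N1[t]
        profile["n2"] = N2[t]
        tot = N1[t] + N2[t]
        with np.errstate(invalid="ignore", divide="ignore"):
            profile["rec_rate"] = np.where(
                tot > 0, np.minimum(N1[t], N2[t]) / np.maximum(tot, 1), np.nan
            )
        results.append(
            map_tag(profile, tag_id=str(matrix.tags["tag_id"].iloc[t]),
                    max_rec_rate=max_rec_rate, min_sample=min_sample)
        )
    return results


def tag_mappings_frame(mappings: list) -> pd.DataFrame:
    """Tabulate TagMapping results (one row per tag)."""
    return pd.DataFrame(
        [
            {
                "tag_id": m.tag_id, "status": m.status, "lg": m.lg,
                "n_hom_par1": m.n_hom_par1, "n_hom_par2": m.n_hom_par2,
                "min_rec_rate": m.min_rec_rate, "p_binomial": m.p_binomial,
                "genetic_start": m.genetic_start, "genetic_end": m.genetic_end,
                "genetic_mean": m.genetic_mean,
            }
            for m in mappings
        ]
    )
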