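"""Ground-truthed synthetic F2 GBS datasets.

The generator emulates the data this pipeline consumes: an interspecific F2
cross of two inbred parents genotyped by GBS at low, heterogeneous depth.

Model
-----
* A true genetic map: eight linkage groups by default, tiled with contigs;
  each contig occupies a short cM interval and carries several SNPs at random
  physical offsets, with a random orientation relative to the map.
* F2 individuals: two independent F1 gametes per individual; crossovers per
  gamete per LG are a no-interference Poisson process with mean equal to the
  LG length in Morgans.  The expected per-locus heterozygote fraction is 1/2
  and genotype frequencies converge to 1:2:1.
* SNP calls: per-cell read depth ~ Poisson(mean_depth x s_site) where s_site
  is an optional per-site Gamma(shape, mean 1) coverage multiplier (GBS tag
  loci have strongly heterogeneous coverage; shape=None gives a homogeneous
  Poisson).  Reads at true heterozygotes are Binomial(depth, 1/2) per allele,
  so shallow heterozygotes are undercalled as homozygotes; depth 0 is a
  missing call.  Calls are flipped to a random wrong genotype at
  ``genotype_error_rate`` (elevated to ``outlier_error_rate`` for a configured
  number of outlier individuals, reproducing the high-crossover QC signature).
  Parents are emitted as two extra samples at 10x depth.
* Dominant tags: each contig carries tags donated by one parent; an
  individual's tag count is Poisson(tag_depth_mean x donor dosage / 2), so
  non-carriers have count 0 and donor homozygotes average twice the
  heterozygote count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import SnpCallSet, TagCountMatrix, ContigSet, HOM_REF, HET, HOM_ALT, MISSING

P1, P2 = 0, 1

#: Per-LG genetic lengths (cM).  The eight printed per-LG spans of the study
#: map, scaled proportionally so the total equals the study's 881 cM map length.
DEFAULT_LG_LENGTHS_CM = (94.0, 65.6, 129.2, 137.5, 134.4, 127.4, 64.1, 128.9)


@dataclass
class SimConfig:
    """Free parameters of the simulation.

    Defaults mirror the study scale: 375 F2 plants of which 9 are
    high-crossover outliers, eight linkage groups totalling ~881 cM, mean GBS
    depth 7 reads/site/individual, and enough simulated SNPs that roughly
    2,300 survive the filter cascade.
    """

    n_individuals: int = 375
    n_linkage_groups: int = 8
    lg_lengths_cm: tuple = DEFAULT_LG_LENGTHS_CM
    contigs_per_lg: int = 140
    snps_per_contig: int = 10
    contig_length_bp: int = 5000
    mean_depth: float = 7.0
    depth_shape: float | None = 1.0  # per-site Gamma coverage multiplier; None = homogeneous
    genotype_error_rate: float = 0.001
    dominant_tags_per_contig: int = 3
    tag_depth_mean: float = 4.0
    outlier_individuals: int = 9
    outlier_error_rate: float = 0.2
    parent_depth_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        self.lg_lengths_cm = tuple(float(x) for x in self.lg_lengths_cm)
        if len(self.lg_lengths_cm) != self.n_linkage_groups:
            raise ValueError("lg_lengths_cm length must equal n_linkage_groups")
        for name in ("n_individuals", "n_linkage_groups", "contigs_per_lg",
                     "snps_per_contig", "contig_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.outlier_individuals < 0:
            raise ValueError("outlier_individuals must be >= 0")
        if self.outlier_individuals > self.n_individuals:
            raise ValueError("more outliers than individuals")
        for name in ("genotype_error_rate", "outlier_error_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(l <= 0 for l in self.lg_lengths_cm):
            raise ValueError("lg lengths must be > 0")
        if self.mean_depth <= 0 or self.tag_depth_mean <= 0:
            raise ValueError("depth means must be > 0")

    @property
    def individual_ids(self) -> list:
        return [f"F2_{i + 1:03d}" for i in range(self.n_individuals)]


@dataclass
class TrueMap:
    """Ground-truth map: contig tiling and true per-SNP genetic positions.

    ``snps`` rows are in true map order: snp_id, lg (1-based), cm, contig,
    pos_bp (1-based).  ``contigs``: contig_id, lg, rank (order within LG),
    start_cm, end_cm, mid_cm, orient (+1/-1), length_bp.
    """

    snps: pd.DataFrame
    contigs: pd.DataFrame
    lg_lengths_cm: tuple

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class TruePopulation:
    """Realized parental origins for every individual at every locus.

    ``snp_origins``/``contig_origins``: int8 arrays (n_individuals, n_loci, 2)
    with values P1=0 / P2=1, rows of loci matching ``TrueMap.snps`` /
    ``TrueMap.contigs``.  ``crossovers``: realized crossover events per
    individual summed over both gametes and all LGs.
    """

    snp_origins: np.ndarray
    contig_origins: np.ndarray
    crossovers: np.ndarray
    individuals: list = field(default_factory=list)

    @property
    def snp_het(self) -> np.ndarray:
        return self.snp_origins[:, :, 0] != self.snp_origins[:, :, 1]

    def snp_dosage(self, parent: int) -> np.ndarray:
        """Copies of ``parent``'s allele per individual x SNP (0, 1 or 2)."""
        return (self.snp_origins == parent).sum(axis=2).astype(np.int8)

    def contig_dosage(self, parent: int) -> np.ndarray:
        return (self.contig_origins == parent).sum(axis=2).astype(np.int8)


def simulate_true_map(config: SimConfig) -> TrueMap:
    """Tile contigs along each LG and place SNPs with true cM positions."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    contig_rows, snp_rows = [], []
    n_contig_global = 0
    for lg in range(1, config.n_linkage_groups + 1):
        length = config.lg_lengths_cm[lg - 1]
        span = length / config.contigs_per_lg
        for rank in range(config.contigs_per_lg):
            n_contig_global += 1
            prefix = "scaffold" if rng.random() < 0.5 else "c"
            cid = f"{prefix}{n_contig_global:05d}"
            start = rank * span
            orient = 1 if rng.random() < 0.5 else -1
            # distinct physical offsets, ascending
            pos = np.sort(
                rng.choice(config.contig_length_bp, size=config.snps_per_contig,
                           replace=False) + 1
            )
            frac = (pos - 1) / max(config.contig_length_bp - 1, 1)
            if orient < 0:
                frac = 1.0 - frac
            cms = start + frac * span
            contig_rows.append(
                (cid, lg, rank, start, start + span, start + span / 2, orient,
                 config.contig_length_bp)
            )
            for p, cm in zip(pos, cms):
                snp_rows.append((f"{cid}_{p}", lg, cm, cid, int(p)))
    contigs = pd.DataFrame(
        contig_rows,
        columns=["contig_id", "lg", "rank", "start_cm", "end_cm", "mid_cm",
                 "orient", "length_bp"],
    )
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "lg", "cm", "contig", "pos_bp"])
    snps = snps.sort_values(["lg", "cm", "snp_id"], kind="stable").reset_index(drop=True)
    return TrueMap(snps=snps, contigs=contigs, lg_lengths_cm=config.lg_lengths_cm)


def _gamete_origin(rng, length_cm: float, eval_cm: np.ndarray):
    """One F1 gamete on one LG: Poisson crossovers, uniform positions.

    Returns (origins at eval_cm, number of crossover events).
    """
    k = rng.poisson(length_cm / 100.0)
    start = rng.integers(0, 2)
    if k == 0:
        return np.full(eval_cm.shape, start, dtype=np.int8), 0
    points = np.sort(rng.uniform(0.0, length_cm, size=k))
    switches = np.searchsorted(points, eval_cm, side="right")
    return ((start + switches) % 2).astype(np.int8), k


def simulate_f2(true_map: TrueMap, config: SimConfig) -> TruePopulation:
    """Draw F2 individuals as pairs of independent F1 gametes per LG."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_individuals
    snp_lg = true_map.snps["lg"].to_numpy()
    snp_cm = true_map.snps["cm"].to_numpy()
    ctg_lg = true_map.contigs["lg"].to_numpy()
    ctg_cm = true_map.contigs["mid_cm"].to_numpy()
    snp_origins = np.empty((n, true_map.n_snps, 2), dtype=np.int8)
    contig_origins = np.empty((n, len(true_map.contigs), 2), dtype=np.int8)
    crossovers = np.zeros(n, dtype=np.int64)
    for lg in range(1, config.n_linkage_groups + 1):
        length = config.lg_lengths_cm[lg - 1]
        s_idx = np.flatnonzero(snp_lg == lg)
        c_idx = np.flatnonzero(ctg_lg == lg)
        eval_cm = np.concatenate([snp_cm[s_idx], ctg_cm[c_idx]])
        for i in range(n):
            for g in range(2):
                origin, k = _gamete_origin(rng, length, eval_cm)
                snp_origins[i, s_idx, g] = origin[: len(s_idx)]
                contig_origins[i, c_idx, g] = origin[len(s_idx):]
                crossovers[i] += k
    return TruePopulation(
        snp_origins=snp_origins,
        contig_origins=contig_origins,
        crossovers=crossovers,
        individuals=config.individual_ids,
    )


def outlier_mask(config: SimConfig) -> np.ndarray:
    """Boolean mask of the configured outlier individuals (the first k)."""
    mask = np.zeros(config.n_individuals, dtype=bool)
    mask[: config.outlier_individuals] = True
    return mask


def simulate_snp_calls(pop: TruePopulation, true_map: TrueMap,
                       config: SimConfig) -> SnpCallSet:
    """Low-depth GBS genotype calls, with the two parents as extra samples."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n_sites = true_map.n_snps
    n_prog = config.n_individuals

    # per-site coverage multiplier (tag-locus amplification heterogeneity)
    if config.depth_shape is None:
        s_site = np.ones(n_sites)
    else:
        s_site = rng.gamma(config.depth_shape, 1.0 / config.depth_shape, size=n_sites)

    # ref/alt polarity: ref allele is parent-1's for a random half of sites
    ref_is_p1 = rng.random(n_sites) < 0.5
    bases = np.array(list("ACGT"))
    ref_base = bases[rng.integers(0, 4, size=n_sites)]
    alt_base = bases[(np.char.find("ACGT", ref_base) + rng.integers(1, 4, size=n_sites)) % 4]

    dosage_p1 = pop.snp_dosage(P1).T  # (n_sites, n_prog)
    # true genotype in ref/alt space: dosage of alt allele
    alt_dosage = np.where(ref_is_p1[:, None], 2 - dosage_p1, dosage_p1)
    true_code = np.empty((n_sites, n_prog), dtype=np.int8)
    true_code[alt_dosage == 0] = HOM_REF
    true_code[alt_dosage == 1] = HET
    true_code[alt_dosage == 2] = HOM_ALT

    depth = rng.poisson(config.mean_depth * s_site[:, None], size=(n_sites, n_prog))
    calls = true_code.copy()
    het = true_code == HET
    alt_reads = np.zeros_like(depth)
    alt_reads[het] = rng.binomial(depth[het], 0.5)
    calls[het & (alt_reads == 0) & (depth > 0)] = HOM_REF
    calls[het & (alt_reads == depth) & (depth > 0)] = HOM_ALT
    calls[depth == 0] = MISSING

    err = np.full(n_prog, config.genotype_error_rate)
    err[outlier_mask(config)] = config.outlier_error_rate
    flip = (rng.random((n_sites, n_prog)) < err[None, :]) & (calls != MISSING)
    shift = rng.integers(1, 3, size=(n_sites, n_prog)).astype(np.int8)
    calls[flip] = (calls[flip] + shift[flip]) % 3

    # parents: inbred homozygotes at 10x depth
    par_depth = rng.poisson(
        config.parent_depth_factor * config.mean_depth * s_site[:, None],
        size=(n_sites, 2),
    )
    par_code = np.empty((n_sites, 2), dtype=np.int8)
    par_code[:, 0] = np.where(ref_is_p1, HOM_REF, HOM_ALT)  # parent 1
    par_code[:, 1] = np.where(ref_is_p1, HOM_ALT, HOM_REF)  # parent 2
    par_calls = par_code.copy()
    par_flip = (rng.random((n_sites, 2)) < config.genotype_error_rate) & (par_depth > 0)
    par_shift = rng.integers(1, 3, size=(n_sites, 2)).astype(np.int8)
    par_calls[par_flip] = (par_calls[par_flip] + par_shift[par_flip]) % 3
    par_calls[par_depth == 0] = MISSING

    samples = ["Par_1", "Par_2"] + config.individual_ids
    sites = pd.DataFrame(
        {
            "contig": true_map.snps["contig"].to_numpy(),
            "pos": true_map.snps["pos_bp"].to_numpy(),
            "ref": ref_base,
            "alt": alt_base,
        }
    )
    return SnpCallSet(
        samples=samples,
        sites=sites,
        calls=np.concatenate([par_calls, calls], axis=1),
        depth=np.concatenate([par_depth, depth], axis=1).astype(np.int32),
        parent1="Par_1",
        parent2="Par_2",
    )


def _random_tag_seq(rng) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=64)])


def simulate_tag_counts(pop: TruePopulation, true_map: TrueMap,
                        config: SimConfig) -> TagCountMatrix:
    """Dominant presence/absence tags: counts follow donor-parent dosage."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n_prog = config.n_individuals
    dos = {P1: pop.contig_dosage(P1), P2: pop.contig_dosage(P2)}  # (n_prog, n_ctg)
    rows, counts = [], []
    tag_no = 0
    for ci, ctg in true_map.contigs.iterrows():
        # one donor per contig: retained tags mark the reference-matching
        # haplotype, which is locally a single parent's
        donor = P1 if rng.random() < 0.5 else P2
        for _ in range(config.dominant_tags_per_contig):
            tag_no += 1
            lam = config.tag_depth_mean * dos[donor][:, ci] / 2.0
            counts.append(rng.poisson(lam))
            rows.append(
                (f"tag{tag_no:06d}", _random_tag_seq(rng), ctg["contig_id"],
                 int(rng.integers(1, config.contig_length_bp + 1)),
                 "+" if rng.random() < 0.5 else "-", True, False, donor)
            )
    tags = pd.DataFrame(
        rows,
        columns=["tag_id", "sequence", "contig", "pos", "strand", "unique",
                 "divergent", "donor"],
    )
    return TagCountMatrix(
        tags=tags, samples=config.individual_ids,
        counts=np.array(counts, dtype=np.int64),
    )


def simulate_unlinked_tags(n_tags: int, config: SimConfig,
                           seed_stream: int = 5) -> TagCountMatrix:
    """Tags whose presence is independent of the map (negative controls).

    Each tag gets an i.i.d. 1:2:1 pseudo-dosage per individual, so the counts
    segregate like a dominant marker but carry no linkage signal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_stream]))
    n_prog = config.n_individuals
    rows, counts = [], []
    for t in range(n_tags):
        dosage = rng.choice([0, 1, 2], size=n_prog, p=[0.25, 0.5, 0.25])
        counts.append(rng.poisson(config.tag_depth_mean * dosage / 2.0))
        rows.append(
            (f"utag{t + 1:06d}", _random_tag_seq(rng), f"unplaced{t + 1:05d}",
             1, "+", True, False, -1)
        )
    tags = pd.DataFrame(
        rows,
        columns=["tag_id", "sequence", "contig", "pos", "strand", "unique",
                 "divergent", "donor"],
    )
    return TagCountMatrix(
        tags=tags, samples=config.individual_ids,
        counts=np.array(counts, dtype=np.int64),
    )


def simulate_contig_sequences(true_map: TrueMap, config: SimConfig) -> ContigSet:
    """Random nucleotide sequences for every contig in the true map."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    bases = np.array(list("ACGT"))
    seqs = {
        cid: "".join(bases[rng.integers(0, 4, size=length)])
        for cid, length in zip(
            true_map.contigs["contig_id"], true_map.contigs["length_bp"]
        )
    }
    return ContigSet(sequences=seqs)


def write_ground_truth(true_map: TrueMap, pop: TruePopulation, out_dir) -> None:
    """Ground truth as TSV: SNP->LG,cM; contig->LG,cM; individual->crossovers."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    true_map.snps.to_csv(out / "true_snps.tsv", sep="\t", index=False)
    true_map.contigs.to_csv(out / "true_contigs.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"individual": pop.individuals, "true_crossovers": pop.crossovers}
    ).to_csv(out / "true_crossovers.tsv", sep="\t", index=False)
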