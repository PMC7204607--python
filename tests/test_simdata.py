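"""The synthetic F2 GBS generator: segregation structure, depth model, tags."""

import numpy as np
import pytest
from scipy import stats

from gbsmap import simdata
from gbsmap.formats import HET, MISSING
from gbsmap.simdata import SimConfig, P1, P2


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_linkage_groups=2)  # default lengths are for 8 LGs
    with pytest.raises(ValueError):
        SimConfig(n_linkage_groups=1, lg_lengths_cm=(0.0,))
    with pytest.raises(ValueError):
        SimConfig(genotype_error_rate=1.5)
    with pytest.raises(ValueError):
        SimConfig(outlier_individuals=-1)


def test_true_map_structure():
    cfg = SimConfig(n_linkage_groups=8, seed=3, contigs_per_lg=5, snps_per_contig=4)
    tm = simdata.simulate_true_map(cfg)
    assert tm.snps["lg"].nunique() == 8
    for lg in range(1, 9):
        sub = tm.snps[tm.snps["lg"] == lg]
        assert sub["cm"].max() <= cfg.lg_lengths_cm[lg - 1]
        assert (np.diff(sub["cm"]) >= 0).all()
    # every SNP belongs to exactly one known contig; offsets within bounds
    assert tm.snps["contig"].isin(tm.contigs["contig_id"]).all()
    assert tm.snps["pos_bp"].between(1, cfg.contig_length_bp).all()


def test_seed_determinism():
    cfg = SimConfig(n_individuals=20, n_linkage_groups=1, lg_lengths_cm=(50.0,),
                    contigs_per_lg=4, snps_per_contig=3, outlier_individuals=0,
                    seed=5)
    outs = []
    for _ in range(2):
        tm = simdata.simulate_true_map(cfg)
        pop = simdata.simulate_f2(tm, cfg)
        calls = simdata.simulate_snp_calls(pop, tm, cfg)
        tags = simdata.simulate_tag_counts(pop, tm, cfg)
        outs.append((tm, pop, calls, tags))
    a, b = outs
    assert a[0].snps.equals(b[0].snps)
    assert np.array_equal(a[1].snp_origins, b[1].snp_origins)
    assert np.array_equal(a[2].calls, b[2].calls)
    assert np.array_equal(a[2].depth, b[2].depth)
    assert np.array_equal(a[3].counts, b[3].counts)


@pytest.fixture(scope="module")
def big_pop():
    cfg = SimConfig(
        n_individuals=500, n_linkage_groups=8, contigs_per_lg=125,
        snps_per_contig=10, outlier_individuals=0, seed=17,
    )
    tm = simdata.simulate_true_map(cfg)
    return cfg, tm, simdata.simulate_f2(tm, cfg)


class TestF2Segregation:
    def test_mean_heterozygosity_is_half(self, big_pop):
        _, tm, pop = big_pop
        assert tm.n_snps == 10000
        assert pop.snp_het.mean() == pytest.approx(0.5, abs=0.01)

    def test_crossovers_match_poisson_expectation(self, big_pop):
        cfg, _, pop = big_pop
        expected = 2.0 * sum(cfg.lg_lengths_cm) / 100.0
        se = np.sqrt(expected / cfg.n_individuals)  # Poisson variance
        assert abs(pop.crossovers.mean() - expected) < 3 * se

    def test_locus_genotypes_fit_1_2_1(self):
        cfg = SimConfig(
            n_individuals=1000, n_linkage_groups=2, lg_lengths_cm=(90.0, 70.0),
            contigs_per_lg=25, snps_per_contig=4, outlier_individuals=0, seed=23,
        )
        tm = simdata.simulate_true_map(cfg)
        pop = simdata.simulate_f2(tm, cfg)
        dos = pop.snp_dosage(P1)  # (n_ind, n_loci): 0,1,2
        pvals = []
        for j in range(dos.shape[1]):
            counts = np.bincount(dos[:, j], minlength=3)
            stat = (((counts - [250, 500, 250]) ** 2) / [250.0, 500.0, 250.0]).sum()
            pvals.append(stats.chi2.sf(stat, df=2))
        assert np.mean(np.array(pvals) > 0.001) >= 0.99


class TestSnpCalls:
    def test_depth_zero_missing_and_depth_one_hom(self):
        cfg = SimConfig(
            n_individuals=300, n_linkage_groups=1, lg_lengths_cm=(50.0,),
            contigs_per_lg=10, snps_per_contig=5, mean_depth=1.5,
            depth_shape=None, genotype_error_rate=0.0, outlier_individuals=0,
            seed=31,
        )
        tm = simdata.simulate_true_map(cfg)
        pop = simdata.simulate_f2(tm, cfg)
        calls = simdata.simulate_snp_calls(pop, tm, cfg)
        prog = calls.calls[:, 2:]
        depth = calls.depth[:, 2:]
        assert (prog[depth == 0] == MISSING).all()
        het = pop.snp_het.T
        assert not (prog[(depth == 1) & het] == HET).any()

    def test_het_undercall_rate_matches_closed_form(self):
        cfg = SimConfig(
            n_individuals=100, n_linkage_groups=1, lg_lengths_cm=(100.0,),
            contigs_per_lg=100, snps_per_contig=10, mean_depth=7.0,
            depth_shape=None, genotype_error_rate=0.0, outlier_individuals=0,
            seed=37,
        )
        tm = simdata.simulate_true_map(cfg)
        pop = simdata.simulate_f2(tm, cfg)
        calls = simdata.simulate_snp_calls(pop, tm, cfg)
        het = pop.snp_het.T
        prog = calls.calls[:, 2:]
        called = het & (prog != MISSING)
        observed = (prog[called] != HET).mean()
        # closed form: P(all reads one allele | het, depth d>=1) = 2 (1/2)^d
        d = np.arange(1, 60)
        pd_ = stats.poisson.pmf(d, 7.0)
        expected = (pd_ * 2 * 0.5**d).sum() / stats.poisson.sf(0, 7.0)
        assert observed == pytest.approx(expected, abs=0.02)

    def test_parents_deeply_homozygous(self):
        cfg = SimConfig(
            n_individuals=30, n_linkage_groups=1, lg_lengths_cm=(40.0,),
            contigs_per_lg=10, snps_per_contig=4, genotype_error_rate=0.0,
            outlier_individuals=0, seed=41,
        )
        tm = simdata.simulate_true_map(cfg)
        pop = simdata.simulate_f2(tm, cfg)
        calls = simdata.simulate_snp_calls(pop, tm, cfg)
        p1 = calls.calls[:, calls.sample_index("Par_1")]
        p2 = calls.calls[:, calls.sample_index("Par_2")]
        ok = (p1 != MISSING) & (p2 != MISSING)
        assert (p1[ok] != p2[ok]).all()
        assert not (p1[ok] == HET).any() and not (p2[ok] == HET).any()
        assert calls.depth[:, :2].mean() > 5 * calls.depth[:, 2:].mean()


@pytest.fixture(scope="module")
def tag_sim():
    cfg = SimConfig(
        n_individuals=1000, n_linkage_groups=1, lg_lengths_cm=(60.0,),
        contigs_per_lg=30, snps_per_contig=2, dominant_tags_per_contig=2,
        tag_depth_mean=6.0, outlier_individuals=0, seed=43,
    )
    tm = simdata.simulate_true_map(cfg)
    pop = simdata.simulate_f2(tm, cfg)
    return cfg, tm, pop, simdata.simulate_tag_counts(pop, tm, cfg)


class TestTags:
    def test_non_carriers_have_zero_counts(self, tag_sim):
        cfg, tm, pop, tags = tag_sim
        ctg_index = {c: i for i, c in enumerate(tm.contigs["contig_id"])}
        dos = {P1: pop.contig_dosage(P1), P2: pop.contig_dosage(P2)}
        for t in range(tags.n_tags):
            donor = int(tags.tags["donor"].iloc[t])
            ci = ctg_index[tags.tags["contig"].iloc[t]]
            non_carrier = dos[donor][:, ci] == 0
            assert (tags.counts[t][non_carrier] == 0).all()

    def test_hom_het_count_ratio_two_to_one(self, tag_sim):
        cfg, tm, pop, tags = tag_sim
        ctg_index = {c: i for i, c in enumerate(tm.contigs["contig_id"])}
        dos = {P1: pop.contig_dosage(P1), P2: pop.contig_dosage(P2)}
        hom_means, het_means = [], []
        for t in range(tags.n_tags):
            donor = int(tags.tags["donor"].iloc[t])
            ci = ctg_index[tags.tags["contig"].iloc[t]]
            d = dos[donor][:, ci]
            hom_means.append(tags.counts[t][d == 2].mean())
            het_means.append(tags.counts[t][d == 1].mean())
        ratio = np.mean(hom_means) / np.mean(het_means)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_carrier_fraction_three_quarters(self, tag_sim):
        cfg, tm, pop, tags = tag_sim
        # carriers of the donor haplotype (>= 1 donor allele) per tag
        ctg_index = {c: i for i, c in enumerate(tm.contigs["contig_id"])}
        dos = {P1: pop.contig_dosage(P1), P2: pop.contig_dosage(P2)}
        fracs = [
            (dos[int(tags.tags["donor"].iloc[t])][:, ctg_index[tags.tags["contig"].iloc[t]]] > 0).mean()
            for t in range(tags.n_tags)
        ]
        se = np.sqrt(0.75 * 0.25 / (cfg.n_individuals * tags.n_tags))
        assert abs(np.mean(fracs) - 0.75) < 3 * se


def test_unlinked_tags_independent_of_map():
    cfg = SimConfig(n_individuals=400, n_linkage_groups=1, lg_lengths_cm=(50.0,),
                    contigs_per_lg=5, snps_per_contig=2, outlier_individuals=0,
                    seed=47)
    tags = simdata.simulate_unlinked_tags(50, cfg)
    assert tags.n_tags == 50
    present = (tags.counts > 0).mean(axis=1)
    assert 0.4 < present.mean() < 0.9
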