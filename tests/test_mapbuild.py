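"""Map construction: Kosambi, pairwise r-hat, grouping, ordering, QC, HMM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gbsmap import mapbuild, simdata
from gbsmap.mapbuild import (CrossoverReport, LinkageMap, PairwiseLinkage,
                             count_crossovers, drop_outlier_individuals,
                             drop_outlier_snps, estimate_rf_pair,
                             group_markers, hmm_posteriors, impute_genotypes,
                             kosambi_cm, kosambi_r, map_positions,
                             order_markers, pairwise_linkage)
from gbsmap.snpfilter import A, H, B, U, PhasedGenotypeMatrix


def make_phased(codes):
    codes = np.asarray(codes, dtype=np.int8)
    m, n = codes.shape
    sites = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m)],
        "contig": [f"c{i}" for i in range(m)],
        "pos": [100] * m,
    })
    return PhasedGenotypeMatrix(progeny=[f"i{j}" for j in range(n)],
                                sites=sites, codes=codes)


class TestKosambi:
    def test_zero(self):
        assert kosambi_cm(0.0) == 0.0

    def test_quarter(self):
        assert kosambi_cm(0.25) == pytest.approx(25.0 * np.log(3.0), rel=1e-12)
        assert kosambi_cm(0.25) == pytest.approx(27.465, abs=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)
        with pytest.raises(ValueError):
            kosambi_r(-1.0)

    @given(st.floats(0.0, 0.49))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, r):
        assert kosambi_r(kosambi_cm(r)) == pytest.approx(r, abs=1e-12)


def _simulate_pair(r, n, rng):
    """Independent two-locus F2 oracle: gametes recombine with probability r."""
    g1a = rng.integers(0, 2, n)
    g1b = rng.integers(0, 2, n)
    rec_a = rng.random(n) < r
    rec_b = rng.random(n) < r
    g2a = np.where(rec_a, 1 - g1a, g1a)
    g2b = np.where(rec_b, 1 - g1b, g1b)
    return (g1a + g1b).astype(np.int8), (g2a + g2b).astype(np.int8)


class TestPairwise:
    def test_identical_vectors_rf_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 200).astype(np.int8)
        assert estimate_rf_pair(x, x) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("r_true", [0.01, 0.05, 0.1, 0.2, 0.3, 0.4])
    def test_recovers_true_r(self, r_true):
        rng = np.random.default_rng(int(r_true * 1000))
        x, y = _simulate_pair(r_true, 1000, rng)
        assert estimate_rf_pair(x, y) == pytest.approx(r_true, abs=0.02)

    def test_independent_pair_rf_half_p_large(self):
        rng = np.random.default_rng(3)
        x, _ = _simulate_pair(0.5, 366, rng)
        y, _ = _simulate_pair(0.5, 366, np.random.default_rng(4))
        phased = make_phased(np.vstack([x, y]))
        pw = pairwise_linkage(phased)
        assert pw.rhat[0, 1] == pytest.approx(0.5, abs=0.06)
        assert pw.pvalue[0, 1] > 1e-12

    def test_few_joint_progeny_p_one(self):
        codes = np.array([[0, 1, 2, 0] + [-1] * 30,
                          [-1] * 30 + [0, 1, 2, 0]], dtype=np.int8)
        pw = pairwise_linkage(make_phased(codes))
        assert pw.pvalue[0, 1] == 1.0

    def test_monomorphic_rejected(self):
        codes = np.array([[0, 0, 0, 0], [0, 1, 2, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_linkage(make_phased(codes))


class TestGrouping:
    def test_zero_cutoff_all_unplaced(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, (5, 50)).astype(np.int8)
        pw = pairwise_linkage(make_phased(codes))
        groups, unplaced = group_markers(pw, p_cutoff=0.0)
        assert groups == [] and len(unplaced) == 5

    def test_two_simulated_groups_recovered(self):
        def chain(rng, n, m, r):
            g = [rng.integers(0, 2, n), rng.integers(0, 2, n)]
            rows = [g[0] + g[1]]
            for _ in range(m - 1):
                g = [np.where(rng.random(n) < r, 1 - x, x) for x in g]
                rows.append(g[0] + g[1])
            return rows

        rng = np.random.default_rng(5)
        n = 200
        codes = np.array(chain(rng, n, 6, 0.05) + chain(rng, n, 6, 0.05),
                         dtype=np.int8)
        pw = pairwise_linkage(make_phased(codes))
        groups, unplaced = group_markers(pw, 1e-12)
        assert len(groups) == 2 and not unplaced
        assert sorted(map(len, groups)) == [6, 6]
        assert set(groups[0]) in ({0, 1, 2, 3, 4, 5}, {6, 7, 8, 9, 10, 11})


def _random_linkage(k, rng):
    R = rng.uniform(0.05, 0.45, (k, k))
    R = (R + R.T) / 2
    np.fill_diagonal(R, 0.0)
    return PairwiseLinkage(rhat=R, pvalue=np.zeros((k, k)),
                           n_joint=np.full((k, k), 100, dtype=np.int32))


class TestOrdering:
    @pytest.mark.parametrize("k", [2, 4, 6, 8])
    def test_matches_exhaustive_search(self, k):
        # independent oracle: full permutation enumeration of the path cost
        for trial in range(8):
            rng = np.random.default_rng(100 * k + trial)
            pw = _random_linkage(k, rng)
            order = order_markers(np.arange(k), pw)
            got = pw.rhat[order[:-1], order[1:]].sum()
            best = min(
                sum(pw.rhat[p[i], p[i + 1]] for i in range(k - 1))
                for p in itertools.permutations(range(k))
            )
            assert got == pytest.approx(best, abs=1e-12)

    def test_two_markers(self):
        pw = _random_linkage(2, np.random.default_rng(0))
        order = order_markers(np.array([0, 1]), pw)
        assert sorted(order.tolist()) == [0, 1]

    def test_single_marker_returned_as_is(self):
        pw = _random_linkage(1, np.random.default_rng(0))
        assert order_markers(np.array([4]), pw).tolist() == [4]

    def test_chain_recovery_50_markers(self):
        # markers on a chain, r between adjacent = 0.03: recover the chain order
        from scipy.stats import kendalltau

        rng = np.random.default_rng(9)
        n, m = 1000, 50
        g = [rng.integers(0, 2, n), rng.integers(0, 2, n)]
        codes = [g[0] + g[1]]
        for _ in range(m - 1):
            g = [np.where(rng.random(n) < 0.03, 1 - x, x) for x in g]
            codes.append(g[0] + g[1])
        codes = np.array(codes, dtype=np.int8)
        perm = rng.permutation(m)
        pw = pairwise_linkage(make_phased(codes[perm]))
        order = order_markers(np.arange(m), pw)
        tau = abs(kendalltau(perm[order], np.arange(m)).statistic)
        assert tau >= 0.95


class TestPositions:
    def test_closed_form_adjacent_tenth(self):
        # construct exact r-hat 0.1 between consecutive hom-coded markers
        base = np.array([A] * 50 + [B] * 50, dtype=np.int8)
        x1 = base.copy()
        x2 = base.copy(); x2[:5] = B; x2[50:55] = A   # 10 recombinants
        x3 = x2.copy(); x3[5:10] = B; x3[55:60] = A
        cms = map_positions(make_phased(np.vstack([x1, x2, x3])), np.arange(3))
        assert cms[0] == 0.0
        assert cms[1] == pytest.approx(10.137, abs=1e-3)
        assert cms[2] == pytest.approx(20.273, abs=1e-3)

    def test_zero_rf_coincident(self):
        x = np.array([A, H, B, A, B, H] * 10, dtype=np.int8)
        cms = map_positions(make_phased(np.vstack([x, x])), np.arange(2))
        assert cms[1] == pytest.approx(0.0, abs=1e-4)

    def test_total_span_telescopes_and_reversal_invariant(self):
        rng = np.random.default_rng(2)
        codes = np.vstack(_simulate_pair(0.1, 500, rng)
                          + _simulate_pair(0.2, 500, rng)).astype(np.int8)
        fwd = map_positions(make_phased(codes), np.arange(4))
        rev = map_positions(make_phased(codes), np.arange(4)[::-1])
        assert fwd[-1] == pytest.approx(np.diff(fwd).sum())
        assert fwd[-1] == pytest.approx(rev[-1], rel=1e-9)


def _map_for(phased):
    m = phased.n_snps
    table = pd.DataFrame({
        "snp_id": phased.sites["snp_id"],
        "lg": ["LG-1"] * m,
        "lg_index": np.arange(1, m + 1),
        "cm": np.arange(m, dtype=float),
        "row": np.arange(m),
    })
    return LinkageMap(table=table)


class TestCrossoverQc:
    def test_minimal_crossover_counting(self):
        codes = np.array([[A], [A], [H], [H], [B], [B]], dtype=np.int8)
        phased = make_phased(codes)
        rep = count_crossovers(phased, _map_for(phased))
        assert rep.individual_crossovers.iloc[0] == 2

    def test_a_to_b_counts_two(self):
        phased = make_phased(np.array([[A], [B]], dtype=np.int8))
        rep = count_crossovers(phased, _map_for(phased))
        assert rep.individual_crossovers.iloc[0] == 2

    def test_singleton_double_crossover(self):
        codes = np.array([[A], [A], [B], [A], [A]], dtype=np.int8)
        phased = make_phased(codes)
        rep = count_crossovers(phased, _map_for(phased))
        assert rep.snp_double_crossovers["s2"] == 1
        assert rep.snp_double_crossovers.drop("s2").sum() == 0

    def test_missing_flanks_bridge(self):
        codes = np.array([[A], [U], [B], [U], [A]], dtype=np.int8)
        phased = make_phased(codes)
        rep = count_crossovers(phased, _map_for(phased))
        assert rep.individual_crossovers.iloc[0] == 4
        assert rep.snp_double_crossovers["s2"] == 1

    def test_outlier_thresholds(self):
        rep = CrossoverReport(
            individual_crossovers=pd.Series({"a": 66, "b": 67, "c": 5}),
            snp_double_crossovers=pd.Series({"s1": 15, "s2": 16, "s3": 0}),
        )
        assert drop_outlier_individuals(rep, 66) == ["a", "c"]
        assert drop_outlier_snps(rep, 15) == ["s1", "s3"]


def _brute_posteriors(codes, cms, error_rate):
    m, n = codes.shape
    prior = np.array([0.25, 0.5, 0.25])
    Ts = [mapbuild._transition(float(kosambi_r(cms[i + 1] - cms[i])))
          for i in range(m - 1)]

    def emis(obs, s):
        if obs == U:
            return 1.0
        return 1.0 - error_rate if obs == s else error_rate / 2.0

    post = np.zeros((m, n, 3))
    for j in range(n):
        for path in itertools.product(range(3), repeat=m):
            p = prior[path[0]] * emis(codes[0, j], path[0])
            for i in range(1, m):
                p *= Ts[i - 1][path[i - 1], path[i]] * emis(codes[i, j], path[i])
            for i in range(m):
                post[i, j, path[i]] += p
        post[:, j] /= post[:, j].sum(axis=1, keepdims=True)
    return post


class TestHmm:
    def test_posteriors_match_enumeration(self):
        rng = np.random.default_rng(21)
        for m in (2, 4, 6):
            codes = rng.integers(-1, 3, (m, 3)).astype(np.int8)
            # avoid all-missing columns producing the trivial case only
            codes[0] = rng.integers(0, 3, 3)
            cms = np.sort(rng.uniform(0, 20, m))
            got = hmm_posteriors(codes, cms, 0.02)
            want = _brute_posteriors(codes, cms, 0.02)
            assert np.allclose(got, want, atol=1e-10)

    def test_singleton_error_corrected(self):
        codes = np.array([[A]] * 3 + [[B]] + [[A]] * 3, dtype=np.int8)
        phased = make_phased(codes)
        table = _map_for(phased).table
        table["cm"] = np.arange(7, dtype=float)  # 1 cM spacing
        lmap = LinkageMap(table=table)
        out = impute_genotypes(phased, lmap, min_prob=0.8, error_rate=0.01)
        assert out.codes[3, 0] == A

    def test_all_missing_gives_all_u(self):
        codes = np.full((5, 2), U, dtype=np.int8)
        phased = make_phased(codes)
        out = impute_genotypes(phased, _map_for(phased), min_prob=0.8)
        assert (out.codes == U).all()

    def test_tie_prefers_h(self):
        # a single marker with missing observation: posterior = prior (max 1/2 at H)
        codes = np.full((1, 1), U, dtype=np.int8)
        phased = make_phased(codes)
        out = impute_genotypes(phased, _map_for(phased), min_prob=0.5)
        assert out.codes[0, 0] == H

    def test_imputation_never_hurts_on_clean_simulation(self, small_run):
        result, truth = small_run
        tm = truth["true_map"]
        pop = truth["population"]
        snp_idx = {s: i for i, s in enumerate(tm.snps["snp_id"])}
        rows = result.map_final.table["row"].to_numpy()
        ids = result.phased_final.sites["snp_id"].to_numpy()[rows]
        keep_ind = [i for i, p in enumerate(pop.individuals)
                    if p in set(result.retained_individuals)]
        truth_codes = pop.snp_dosage(simdata.P2)[np.ix_(
            keep_ind, [snp_idx[s] for s in ids])].T
        raw = result.phased_final.codes[rows]
        imputed = result.imputed.codes[rows]
        correct_raw = (raw == truth_codes).sum()
        correct_imp = (imputed == truth_codes).sum()
        assert correct_imp >= correct_raw
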