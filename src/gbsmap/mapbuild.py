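"""Linkage-map construction from phased F2 genotypes.

Stages (a functional re-implementation of the classic group / order / space
workflow for an F2 intercross):

* pairwise recombination fractions by maximum likelihood (EM over the
  double-heterozygote ambiguity) plus a chi-square independence test,
* single-linkage grouping at an independence p-value cutoff (1e-12),
* ordering within a group by minimising the sum of adjacent recombination
  fractions: zero-recombination bins are collapsed, small groups are solved
  exactly (Held-Karp path DP), larger ones by a nearest-neighbour seed from
  the two most distant markers followed by 2-opt refinement,
* cumulative Kosambi centimorgan positions from re-estimated adjacent
  recombination fractions,
* crossover-based QC (per-individual minimal crossover counts, per-SNP
  double-crossover counts) and the corresponding outlier-removal rules,
* per-individual 3-state HMM max-marginal error correction / imputation
  (posterior >= min_prob keeps the argmax state, otherwise missing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .snpfilter import PhasedGenotypeMatrix, A, H, B, U

# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------

def kosambi_cm(r) -> np.ndarray | float:
    """Kosambi distance d = 25 ln((1+2r)/(1-2r)) in cM, for r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(d) -> np.ndarray | float:
    """Inverse Kosambi: r = tanh(d/50)/2 for d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Pairwise linkage
# ---------------------------------------------------------------------------

@dataclass
class PairwiseLinkage:
    """Pairwise recombination fractions and independence p-values.

    ``rhat``: (m, m) ML recombination fraction (0 on the diagonal; 0.5 where
    undefined).  ``pvalue``: chi-square (df 4) independence p-values, set to 1
    for pairs with fewer than ``min_joint`` jointly non-missing progeny.
    ``n_joint``: jointly non-missing counts.
    """

    rhat: np.ndarray
    pvalue: np.ndarray
    n_joint: np.ndarray


_REC_WEIGHT = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)


def _em_rf(S, nHH, N, iters: int = 200):
    """Vectorised EM for the F2 recombination fraction.

    S = recombinant gametes observed outside the double-het class, nHH =
    double-het count, N = jointly typed progeny.  All arrays broadcastable.
    """
    S = np.asarray(S, dtype=float)
    nHH = np.asarray(nHH, dtype=float)
    N = np.asarray(N, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(N > 0, np.clip(S / np.maximum(2.0 * N, 1e-300), 1e-6, 0.49), 0.5)
        for _ in range(iters):
            denom = (1.0 - r) ** 2 + r**2
            e_hh = 2.0 * r**2 / denom
            r_new = (S + nHH * e_hh) / np.maximum(2.0 * N, 1e-300)
            r_new = np.where(N > 0, np.clip(r_new, 0.0, 0.4999), 0.5)
            delta = np.max(np.abs(r_new - r)) if r.size else 0.0
            r = r_new
            if delta < 1e-9:
                break
    return r


def estimate_rf_pair(x: np.ndarray, y: np.ndarray) -> float:
    """ML recombination fraction between two phased code vectors."""
    ok = (x != U) & (y != U)
    if not ok.any():
        return 0.5
    xo, yo = x[ok].astype(int), y[ok].astype(int)
    S = _REC_WEIGHT[xo, yo].sum() - 0  # |code difference|; HH contributes 0
    nHH = int(((xo == H) & (yo == H)).sum())
    return float(_em_rf(S, nHH, len(xo)))


def pairwise_linkage(phased: PhasedGenotypeMatrix, min_joint: int = 20,
                     em_iters: int = 200) -> PairwiseLinkage:
    """All-pairs recombination fractions and independence tests.

    Raises on a monomorphic SNP (a single observed code): its recombination
    fraction is undefined.
    """
    codes = phased.codes
    m, n = codes.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 SNPs and 2 progeny")
    X = [(codes == c).astype(np.float32) for c in (A, H, B)]
    observed = [(codes == c).any(axis=1) for c in (A, H, B)]
    if np.any(np.sum(observed, axis=0) < 2):
        bad = np.flatnonzero(np.sum(observed, axis=0) < 2)
        raise ValueError(f"monomorphic SNP(s) at rows {bad.tolist()}")

    # joint genotype count matrices C[i][j][a, b] = #progeny with codes (i, j)
    C = {}
    for i in range(3):
        for j in range(i, 3):
            C[(i, j)] = X[i] @ X[j].T
    for i in range(3):
        for j in range(i):
            C[(i, j)] = C[(j, i)].T

    N = sum(C[(i, j)] for i in range(3) for j in range(3))
    nHH = C[(1, 1)]
    S = (C[(0, 1)] + C[(1, 0)] + C[(1, 2)] + C[(2, 1)]
         + 2.0 * (C[(0, 2)] + C[(2, 0)]))

    # chi-square independence on the 3x3 table, df 4
    row = [sum(C[(i, j)] for j in range(3)) for i in range(3)]
    col = [sum(C[(i, j)] for i in range(3)) for j in range(3)]
    stat = np.zeros((m, m))
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(3):
            for j in range(3):
                E = row[i] * col[j] / np.maximum(N, 1.0)
                term = (C[(i, j)] - E) ** 2 / np.where(E > 0, E, 1.0)
                stat += np.where(E > 0, term, 0.0)
    pvalue = stats.chi2.sf(stat, df=4)
    pvalue[N < min_joint] = 1.0
    np.fill_diagonal(pvalue, 0.0)

    rhat = _em_rf(S, nHH, N, iters=em_iters)
    np.fill_diagonal(rhat, 0.0)
    return PairwiseLinkage(rhat=rhat.astype(np.float64), pvalue=pvalue,
                           n_joint=N.astype(np.int32))


def group_markers(pw: PairwiseLinkage, p_cutoff: float = 1e-12):
    """Single-linkage components of the graph with edges at p < cutoff.

    Returns (groups, unplaced): groups are marker-index arrays sorted by
    descending size (ties by smallest member); singletons are unplaced.
    """
    m = pw.pvalue.shape[0]
    adj = pw.pvalue < p_cutoff
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(sparse.csr_matrix(adj), directed=False)
    comps = [np.flatnonzero(labels == k) for k in range(n_comp)]
    comps.sort(key=lambda idx: (-len(idx), idx[0]))
    groups = [c for c in comps if len(c) > 1]
    unplaced = [int(c[0]) for c in comps if len(c) == 1]
    return groups, unplaced


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------

def _path_cost(D: np.ndarray, order) -> float:
    order = np.asarray(order)
    return float(D[order[:-1], order[1:]].sum())


def _held_karp_path(D: np.ndarray) -> list:
    """Exact minimum Hamiltonian path by bitmask DP (small instances)."""
    k = D.shape[0]
    full = 1 << k
    INF = np.inf
    cost = np.full((full, k), INF)
    parent = np.full((full, k), -1, dtype=int)
    for v in range(k):
        cost[1 << v, v] = 0.0
    for mask in range(full):
        for v in range(k):
            c = cost[mask, v]
            if not np.isfinite(c) or not (mask >> v) & 1:
                continue
            for w in range(k):
                if (mask >> w) & 1:
                    continue
                nm = mask | (1 << w)
                nc = c + D[v, w]
                if nc < cost[nm, w]:
                    cost[nm, w] = nc
                    parent[nm, w] = v
    end = int(np.argmin(cost[full - 1]))
    order = [end]
    mask = full - 1
    while parent[mask, order[-1]] >= 0:
        prev = parent[mask, order[-1]]
        mask ^= 1 << order[-1]
        order.append(int(prev))
    return order[::-1]


def _two_opt(D: np.ndarray, order: list, max_rounds: int = 60) -> list:
    """2-opt segment-reversal refinement of a path to local optimality."""
    order = list(order)
    k = len(order)
    for _ in range(max_rounds):
        improved = False
        pos = np.array(order)
        for a in range(k - 1):
            # reverse segment [a, b] for all b > a; vectorised delta
            b = np.arange(a + 1, k)
            left = D[pos[a - 1], pos[b]] if a > 0 else np.zeros(len(b))
            right = np.where(b < k - 1, D[pos[a], pos[np.minimum(b + 1, k - 1)]], 0.0)
            old_left = D[pos[a - 1], pos[a]] if a > 0 else 0.0
            old_right = np.where(b < k - 1, D[pos[b], pos[np.minimum(b + 1, k - 1)]], 0.0)
            delta = left + right - old_left - old_right
            best = int(np.argmin(delta))
            if delta[best] < -1e-12:
                bb = a + 1 + best
                order[a: bb + 1] = order[a: bb + 1][::-1]
                pos = np.array(order)
                improved = True
        if not improved:
            break
    return order


def _or_opt(D: np.ndarray, order: list, max_seg: int = 40,
            max_rounds: int = 30) -> list:
    """Or-opt refinement: relocate contiguous segments (either orientation).

    Complements 2-opt: a block stranded far from its true neighbours cannot
    be repaired by reversals alone (distances saturate at 0.5), but segment
    relocation moves it in one step.
    """
    order = list(order)
    k = len(order)
    if k < 3:
        return order
    for _ in range(max_rounds):
        improved = False
        for seg_len in range(1, min(max_seg, k - 1) + 1):
            i = 0
            while i + seg_len <= len(order):
                p = np.array(order)
                j = i + seg_len - 1
                left = p[i - 1] if i > 0 else -1
                right = p[j + 1] if j < k - 1 else -1
                removed = (
                    (D[left, p[i]] if left >= 0 else 0.0)
                    + (D[p[j], right] if right >= 0 else 0.0)
                    - (D[left, right] if (left >= 0 and right >= 0) else 0.0)
                )
                # candidate insertion gaps (t, t+1) in the path without the segment
                rest = np.concatenate([p[:i], p[j + 1:]])
                m = len(rest)
                ends_a = np.concatenate([[-1], rest])   # left node of each gap
                ends_b = np.concatenate([rest, [-1]])   # right node of each gap
                da = np.where(ends_a >= 0, D[np.maximum(ends_a, 0), p[i]], 0.0)
                db = np.where(ends_b >= 0, D[p[j], np.maximum(ends_b, 0)], 0.0)
                da_r = np.where(ends_a >= 0, D[np.maximum(ends_a, 0), p[j]], 0.0)
                db_r = np.where(ends_b >= 0, D[p[i], np.maximum(ends_b, 0)], 0.0)
                dgap = np.where((ends_a >= 0) & (ends_b >= 0),
                                D[np.maximum(ends_a, 0), np.maximum(ends_b, 0)], 0.0)
                add_f = da + db - dgap
                add_r = da_r + db_r - dgap
                add = np.minimum(add_f, add_r)
                deltas = add - removed
                # skip re-inserting into the original gap (index i)
                deltas[i] = np.inf
                t = int(np.argmin(deltas))
                if deltas[t] < -1e-12:
                    seg = order[i: j + 1]
                    if add_r[t] < add_f[t]:
                        seg = seg[::-1]
                    rest_list = order[:i] + order[j + 1:]
                    order = rest_list[:t] + seg + rest_list[t:]
                    improved = True
                else:
                    i += 1
        if not improved:
            break
    return order


def order_markers(group: np.ndarray, pw: PairwiseLinkage,
                  exact_max: int = 12, zero_tol: float = 1e-6) -> np.ndarray:
    """Order one linkage group minimising the sum of adjacent r-hat.

    Markers at zero observed recombination are collapsed into bins (input
    order preserved within a bin); bins are ordered exactly for <= exact_max
    bins, else by nearest-neighbour seeding from the most distant pair plus
    2-opt.  The returned order is normalised so the first marker's original
    index is smaller than the last's (order and reversal are equivalent).
    """
    group = np.asarray(group)
    if len(group) == 1:
        return group.copy()
    R = pw.rhat[np.ix_(group, group)]

    # collapse zero-recombination bins (union-find on r < zero_tol)
    k = len(group)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ii, jj = np.nonzero(R < zero_tol)
    for i, j in zip(ii, jj):
        if i < j:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    roots = sorted({find(i) for i in range(k)})
    bins = {r: [] for r in roots}
    for i in range(k):
        bins[find(i)].append(i)
    bin_members = [bins[r] for r in roots]
    nb = len(bin_members)
    if nb == 1:
        return group.copy()

    # inter-bin distance: mean r-hat between members
    D = np.zeros((nb, nb))
    for a in range(nb):
        for b in range(a + 1, nb):
            D[a, b] = D[b, a] = R[np.ix_(bin_members[a], bin_members[b])].mean()

    if nb <= exact_max:
        bin_order = _held_karp_path(D)
    else:
        start = int(np.unravel_index(np.argmax(D), D.shape)[0])
        todo = set(range(nb)) - {start}
        bin_order = [start]
        while todo:
            last = bin_order[-1]
            nxt = min(todo, key=lambda j: D[last, j])
            bin_order.append(nxt)
            todo.remove(nxt)
        cost = _path_cost(D, bin_order)
        for _ in range(10):
            bin_order = _two_opt(D, bin_order)
            bin_order = _or_opt(D, bin_order)
            new_cost = _path_cost(D, bin_order)
            if new_cost > cost - 1e-12:
                break
            cost = new_cost

    order = [i for b in bin_order for i in sorted(bin_members[b])]
    if order[0] > order[-1]:
        order = order[::-1]
    return group[np.array(order)]


def adjacent_rf(phased: PhasedGenotypeMatrix, ordered_rows: np.ndarray) -> np.ndarray:
    """Re-estimated recombination fractions between consecutive ordered SNPs."""
    codes = phased.codes[np.asarray(ordered_rows)]
    x, y = codes[:-1], codes[1:]
    ok = (x != U) & (y != U)
    xi = np.where(ok, x, 0).astype(int)
    yi = np.where(ok, y, 0).astype(int)
    S = np.where(ok, _REC_WEIGHT[xi, yi], 0.0).sum(axis=1)
    nHH = ((x == H) & (y == H) & ok).sum(axis=1)
    N = ok.sum(axis=1)
    return np.minimum(_em_rf(S, nHH, N), 0.4999)


def map_positions(phased: PhasedGenotypeMatrix, ordered_rows: np.ndarray) -> np.ndarray:
    """Cumulative Kosambi cM positions (starting at 0) along an ordered group."""
    ordered_rows = np.asarray(ordered_rows)
    if len(ordered_rows) == 1:
        return np.zeros(1)
    r = adjacent_rf(phased, ordered_rows)
    d = kosambi_cm(np.minimum(r, 0.49989999))
    return np.concatenate([[0.0], np.cumsum(d)])


# ---------------------------------------------------------------------------
# LinkageMap
# ---------------------------------------------------------------------------

@dataclass
class LinkageMap:
    """Ordered SNPs per linkage group with cumulative Kosambi cM positions.

    ``table`` rows (one per mapped SNP, LG blocks in order): snp_id, lg
    (LG-1...), lg_index (consecutive 1..n within the LG), cm, row (row of the
    SNP in the phased matrix the map was built from).
    """

    table: pd.DataFrame
    unplaced: list = field(default_factory=list)

    @property
    def lg_names(self) -> list:
        return list(dict.fromkeys(self.table["lg"]))

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def lg_table(self, lg: str) -> pd.DataFrame:
        return self.table[self.table["lg"] == lg]

    def lg_rows(self, lg: str) -> np.ndarray:
        return self.lg_table(lg)["row"].to_numpy()

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.lg_table(lg)["cm"].iloc[-1] for lg in self.lg_names))

    def write_tsv(self, path) -> None:
        self.table.drop(columns=["row"]).to_csv(path, sep="\t", index=False)


def build_linkage_map(phased: PhasedGenotypeMatrix, p_cutoff: float = 1e-12,
                      missing_threshold: float = 0.15,
                      min_joint: int = 20) -> LinkageMap:
    """Group, order and space the phased SNPs into a linkage map.

    SNPs with more than ``missing_threshold`` missing genotypes among the
    current progeny are excluded from map construction.  LGs are named
    LG-1..LG-k by descending SNP count.
    """
    miss = (phased.codes == U).mean(axis=1)
    usable = np.flatnonzero(miss <= missing_threshold)
    sub = phased.subset_snps(usable)
    pw = pairwise_linkage(sub, min_joint=min_joint)
    groups, unplaced = group_markers(pw, p_cutoff)
    records = []
    for g_no, group in enumerate(groups, start=1):
        ordered = order_markers(group, pw)
        cms = map_positions(sub, ordered)
        rows = usable[ordered]
        ids = sub.sites["snp_id"].to_numpy()[ordered]
        for idx, (sid, cm, row) in enumerate(zip(ids, cms, rows), start=1):
            records.append((sid, f"LG-{g_no}", idx, float(cm), int(row)))
    table = pd.DataFrame(records, columns=["snp_id", "lg", "lg_index", "cm", "row"])
    unplaced_ids = [str(sub.sites["snp_id"].iloc[i]) for i in unplaced]
    return LinkageMap(table=table, unplaced=unplaced_ids)


# ---------------------------------------------------------------------------
# Crossover QC
# ---------------------------------------------------------------------------

@dataclass
class CrossoverReport:
    """Minimal crossover counts per individual; double crossovers per SNP."""

    individual_crossovers: pd.Series  # index: progeny id
    snp_double_crossovers: pd.Series  # index: snp_id


def count_crossovers(phased: PhasedGenotypeMatrix, lmap: LinkageMap) -> CrossoverReport:
    """Crossovers per individual across LGs and double crossovers per SNP.

    Per individual and LG, the minimal crossover count is the sum of
    |code_i - code_j| over consecutive non-missing calls (A=0, H=1, B=2).
    A SNP's double-crossover count is the number of individuals whose call
    differs from both nearest non-missing flanking calls when those agree.
    """
    n_ind = len(phased.progeny)
    xo = np.zeros(n_ind, dtype=np.int64)
    dxo = {sid: 0 for sid in lmap.table["snp_id"]}
    for lg in lmap.lg_names:
        sub = lmap.lg_table(lg)
        rows = sub["row"].to_numpy()
        ids = sub["snp_id"].to_numpy()
        codes = phased.codes[rows]  # (m, n_ind)
        for j in range(n_ind):
            col = codes[:, j]
            nz = np.flatnonzero(col != U)
            if len(nz) < 2:
                continue
            vals = col[nz].astype(int)
            d = np.abs(np.diff(vals))
            xo[j] += int(d.sum())
            if len(nz) >= 3:
                mid = vals[1:-1]
                single = (vals[:-2] == vals[2:]) & (mid != vals[:-2])
                for k in np.flatnonzero(single):
                    dxo[ids[nz[k + 1]]] += 1
    return CrossoverReport(
        individual_crossovers=pd.Series(xo, index=phased.progeny),
        snp_double_crossovers=pd.Series(dxo),
    )


def drop_outlier_individuals(report: CrossoverReport, max_xo: int = 66) -> list:
    """Progeny retained after removing individuals with > max_xo crossovers."""
    s = report.individual_crossovers
    return list(s.index[s <= max_xo])


def drop_outlier_snps(report: CrossoverReport, max_dxo: int = 15) -> list:
    """SNP ids retained after removing SNPs with > max_dxo double crossovers."""
    s = report.snp_double_crossovers
    return list(s.index[s <= max_dxo])


# ---------------------------------------------------------------------------
# HMM max-marginal error correction / imputation
# ---------------------------------------------------------------------------

def _transition(r: float) -> np.ndarray:
    q = 1.0 - r
    return np.array(
        [
            [q * q, 2 * r * q, r * r],
            [r * q, q * q + r * r, r * q],
            [r * r, 2 * r * q, q * q],
        ]
    )


#: argmax preference at exact posterior ties: H over A over B (maximises the
#: 1/4:1/2:1/4 prior).
_TIE_ORDER = np.array([H, A, B])


def hmm_posteriors(codes: np.ndarray, cms: np.ndarray,
                   error_rate: float = 0.01) -> np.ndarray:
    """Forward-backward state posteriors for one LG.

    ``codes``: (m, n_ind) observed A/H/B/U; ``cms``: (m,) map positions.
    States A, H, B with prior (1/4, 1/2, 1/4); transitions from the Kosambi
    inverse of adjacent distances; emission 1-e for the observed code, e/2
    for each other code, uniform for missing.  Returns (m, n_ind, 3).
    """
    m, n = codes.shape
    e = error_rate
    emis_lookup = np.full((4, 3), 1.0)  # row 3 = missing
    for obs in range(3):
        emis_lookup[obs] = e / 2.0
        emis_lookup[obs, obs] = 1.0 - e
    obs_idx = np.where(codes == U, 3, codes).astype(int)
    E = emis_lookup[obs_idx]  # (m, n, 3)

    Ts = [_transition(float(kosambi_r(max(cms[i + 1] - cms[i], 0.0))))
          for i in range(m - 1)]
    prior = np.array([0.25, 0.5, 0.25])

    alpha = np.empty((m, n, 3))
    scale = np.empty((m, n))
    a = prior[None, :] * E[0]
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for i in range(1, m):
        a = (alpha[i - 1] @ Ts[i - 1]) * E[i]
        scale[i] = a.sum(axis=1)
        alpha[i] = a / scale[i][:, None]

    beta = np.empty((m, n, 3))
    beta[m - 1] = 1.0
    for i in range(m - 2, -1, -1):
        b = (beta[i + 1] * E[i + 1]) @ Ts[i].T
        beta[i] = b / scale[i + 1][:, None]

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def impute_genotypes(phased: PhasedGenotypeMatrix, lmap: LinkageMap,
                     min_prob: float = 0.8,
                     error_rate: float = 0.01) -> PhasedGenotypeMatrix:
    """Max-marginal error correction and imputation along the map.

    Each mapped SNP's code becomes the argmax posterior state when that
    posterior reaches ``min_prob`` (observed calls may be overwritten), else
    U.  SNPs not on the map are left unchanged.
    """
    new_codes = phased.codes.copy()
    for lg in lmap.lg_names:
        sub = lmap.lg_table(lg)
        rows = sub["row"].to_numpy()
        cms = sub["cm"].to_numpy()
        post = hmm_posteriors(phased.codes[rows], cms, error_rate)
        perm = post[:, :, _TIE_ORDER]
        best = _TIE_ORDER[np.argmax(perm, axis=2)]
        pmax = perm.max(axis=2)
        out = np.where(pmax >= min_prob, best, U).astype(np.int8)
        new_codes[rows] = out
    return PhasedGenotypeMatrix(
        progeny=list(phased.progeny), sites=phased.sites.copy(), codes=new_codes
    )


def respace_map(phased: PhasedGenotypeMatrix, lmap: LinkageMap) -> LinkageMap:
    """Recompute cM positions (order unchanged) from the given genotype matrix.

    Used after HMM error correction so final map distances are not inflated
    by residual genotyping error.
    """
    parts = []
    for lg in lmap.lg_names:
        sub = lmap.lg_table(lg).copy()
        sub["cm"] = map_positions(phased, sub["row"].to_numpy())
        parts.append(sub)
    return LinkageMap(table=pd.concat(parts, ignore_index=True),
                      unplaced=list(lmap.unplaced))
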