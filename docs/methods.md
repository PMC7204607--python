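# Methods

This note documents the models, parameter choices and numerical details
behind `gbsmap`, in the order the pipeline runs them.

## The experimental design being modelled

Two inbred parental lines from closely related species are crossed; one F1 is
selfed to give an F2 mapping population.  Every F2 locus is a pair of
parental origins, so codominant markers segregate 1:2:1 (A : H : B) and the
expected per-locus heterozygote fraction is 1/2.  Genotyping is by GBS:
restriction-anchored 64-base tags sequenced at low depth, yielding (a) SNP
calls with depth-dependent quality and (b) tag presence/absence counts that
behave as dominant markers.

## Synthetic data generator (`simdata`)

The generator's defaults are the study conditions the pipeline is designed
for: 375 F2 individuals of which 9 are high-crossover outliers, eight linkage
groups, mean depth 7 reads/site/individual, and enough simulated SNPs
(8 LGs × 140 contigs × 10 SNPs = 11,200) that roughly 2,300–2,400 survive the
filter cascade — the scale of the final study map.  Default LG lengths are
the eight printed per-LG spans scaled proportionally to a total of 881 cM
(the printed per-LG spans and the printed total differ in the source; the
total was kept and the relative spans preserved).

* **Meiosis.**  Each F2 individual is two independent F1 gametes.  Crossovers
  per gamete per LG are Poisson with mean equal to the LG length in Morgans,
  positions uniform — i.e. *no interference*.  Estimation uses the Kosambi
  map function (which allows for interference); the simulation deliberately
  uses the simplest generative model and leaves the map-function choice to
  the estimation side.  The "true" length compared against in recovery
  checks is the realized true cM span of the mapped SNPs.
* **Contigs.**  Each LG is tiled by contigs of 5,000 bp occupying equal cM
  intervals, with random orientation relative to the map; SNPs sit at random
  distinct physical offsets.  This gives multi-SNP contigs whose SNPs map
  within < 1 cM of each other, matching the observed tight within-contig
  spans, and exercises the orientation logic.
* **Depth model.**  Read depth is Poisson(mean_depth × s_site) with
  s_site ~ Gamma(shape = 1, mean 1) per site (`depth_shape=None` gives a
  homogeneous Poisson).  The site-level multiplier models the strongly
  heterogeneous amplification of GBS tag loci, and it is what makes the
  filter cascade meaningful at mean depth 7: with homogeneous Poisson(7)
  every site has ~45 % of genotypes below the depth-7 mask and the 10 %
  missingness filter would discard *all* sites, whereas with site-level
  variation the well-covered minority survives — reproducing the drastic
  site attrition (here 11,200 → ~2,400) that the real cascade shows.
* **Calls.**  True heterozygotes emit Binomial(depth, 1/2) allele reads and
  are called homozygous when all reads agree (probability 2·(1/2)^d), missing
  at depth 0.  Calls are flipped to a random wrong genotype at rate 0.001
  (a typical residual GBS error), or 0.2 for outlier individuals — outliers
  are modelled as elevated genotype error, which produces the spurious-
  crossover QC signature without simulating extra meioses.  Parents are
  emitted at 10× depth so phasing is rarely blocked by parental missingness.
* **Tags.**  Each contig carries 3 dominant tags with a *single donor parent
  per contig*; a tag's count is Poisson(tag_depth_mean × donor dosage / 2),
  so non-carriers are 0 and donor homozygotes average twice the heterozygote
  count.  The per-contig donor reflects what survives the real tag filters:
  only tags matching the reference assembly without divergence are kept, and
  the reference locally matches one parental haplotype; merging tags with
  opposite donors would otherwise produce a near-monomorphic haplotype.
  `tag_depth_mean` defaults to 4, which puts tag presence at ~68 % of
  individuals — under the 256/366 segregating-filter cap, as in the data the
  cap was designed for.  `simulate_unlinked_tags` draws an i.i.d. 1:2:1
  pseudo-dosage per individual as a negative control.

What the generator does **not** emulate: read-level errors and allele bias,
linked restriction-site polymorphism between neighbouring tags, segregation
distortion, residual heterozygosity in the parents, missing parental
genotypes, and reference mis-assembly (chimeric contigs).  Passing recovery
tests therefore demonstrate the correctness of the statistical machinery
under the stated model, not robustness to every artefact of real GBS data.

## Filter cascade and phasing (`snpfilter`)

The six steps run in the fixed printed order; MAF is computed *before* depth
masking, and MAF/missingness are computed over progeny only (the filters
serve the F2 segregation analysis; parents are used solely for phasing).
The 1:2:1 test is a Pearson chi-square with 2 df, no continuity correction.
Thinning is a greedy per-contig scan keeping the lowest-position SNP of each
run closer than 65 bp.  Phasing keeps only sites where both parents are
homozygous for different alleles; polarity follows the parents, not ref/alt.
Sites with a heterozygous or missing parent are dropped rather than imputed.

Expected heterozygosity per individual uses the finite-sample correction
2p(1−p)·n/(n−1) with p the alternate allele frequency over all samples and n
the observed allele count at the locus; F = 1 − NHo/NHe then reproduces the
published per-individual values from their count columns.

## Map construction (`mapbuild`)

* **Pairwise r̂** is the F2 maximum-likelihood estimate via EM: all joint
  genotype classes except the double heterozygote carry a known recombinant
  gamete count (|code difference|); the double-het class contributes
  2r²/((1−r)²+r²) expected recombinants.  The EM runs vectorised over all
  pairs until the largest update is < 1e-9 (≤ 200 iterations); undefined
  pairs (no joint data) report r̂ = 0.5.  Independence is a chi-square test
  on the 3×3 joint table (4 df); pairs with < 20 jointly typed progeny get
  p = 1 so sparse overlap can never create an edge.
* **Grouping** is single linkage (connected components) over edges with
  p < 1e-12; singleton components are reported unplaced.  SNPs with > 15 %
  missing genotypes among current progeny are excluded before grouping.
* **Ordering** minimises the sum of adjacent r̂.  Markers at zero observed
  recombination are collapsed into bins (input order preserved inside a
  bin — a deterministic tie-break; bins are unresolvable by the data).
  ≤ 12 bins are solved exactly by Held–Karp path DP; larger groups use a
  nearest-neighbour seed from the most distant pair, then alternating 2-opt
  (segment reversal) and Or-opt (segment relocation, both orientations)
  passes to joint local optimality.  Or-opt matters: with distances saturating
  at r = 0.5, a block stranded at the wrong end of the path is invisible to
  reversals but fixed by relocation.  An order and its reversal are
  equivalent; output is normalised so the first marker's input index is the
  smaller.
* **Positions** re-estimate r̂ between consecutive ordered markers and
  cumulate Kosambi distances from 0.
* **Crossover QC** uses minimal crossover counts (sum of |code_i − code_j|
  over consecutive non-missing calls, A=0 H=1 B=2) per individual, and
  per-SNP singleton counts (call differing from both equal nearest flanks).
  Thresholds: individuals > 66 crossovers, SNPs > 15 double crossovers; the
  map is rebuilt after each removal.  The thresholds are calibrated to the
  study scale (~2,300 SNPs); at other scales they should be rescaled (the
  examples do).  Crossovers are counted on the raw phased data, before any
  imputation, matching the stated order of operations.
* **HMM error correction** is per-individual forward–backward over states
  (A, H, B) with prior (1/4, 1/2, 1/4), transitions from the Kosambi inverse
  of adjacent distances ((1−r)², 2r(1−r), r² pattern), emissions 1−e for the
  observed code and e/2 for the others (e = 0.01 by default; the simulated
  residual error after depth masking is a few per mil, and the correction is
  insensitive to e within a factor of a few), uniform for missing.  The
  output code is the argmax posterior when it reaches 0.8, else missing;
  exact posterior ties prefer H over A over B (the prior-maximising state).
  Observed calls can be overwritten (error correction, not just imputation).
* **Final distances** are re-estimated on the corrected genotypes.  This is
  a deliberate design choice: at ~0.4 cM marker spacing, even a few per-mil
  genotyping error inflates raw adjacent r̂ several-fold, and the corrected
  re-estimate brings the total length within ~5 % of the realized truth
  (slightly *under*, because smoothing also removes a small number of
  genuine tight double crossovers).

## Tag and haplotype mapping (`tagmap`, `contighap`)

Only carriers are informative (absence at low depth is not evidence), and
heterozygous carriers are excluded at each SNP.  The "same minimum rate" span
is determined by exact integer cross-multiplication (k·m* = k*·m), never by
floating-point equality, so span endpoints cannot be inflated by rounding.
GeneticMean is the midpoint of (GeneticStart, GeneticEnd) in consecutive
SNP-index units.  A minimum achieved on more than one LG leaves the tag
unmapped (status `ambiguous`).  The two-tailed binomial gate folds k onto the
smaller tail and is evaluated in exact rational arithmetic; the threshold
configuration (n = 30, k ≤ 1) gives 62/2³⁰ ≈ 5.77e-8.  The reported sample
size and counts come from the achieving SNP with the largest sample.

The segregating-tag filter keeps tags present in ≥ 30 and ≤ 256 of 366
retained individuals; with a different number retained the cap generalises to
floor(0.80·N).  Consensus per contig is a sample-size-weighted LG majority
(exact ties → no consensus); the merge window |GeneticMean − consensus| ≤ 50
is inclusive.  Contigs whose every tag is individually unmapped get no
haplotype.  Haplotype presence needs ≥ 5 % of the mean non-zero merged count;
haplotype mapping reuses the tag machinery at a 10 % rate threshold.

## Assembly (`assembly`)

Rule 1 (SNP-anchored contigs): majority SNP vote resolves cross-LG contigs,
an exact tie removes the contig; order within an LG is by the map position of
each contig's first SNP (ties by SNP index, then name); orientation is − when
the first physical SNP sits at higher cM than the last, + when lower,
unoriented when equal or single-SNP.  Rule 2 (tag-only contigs): host SNP =
floor(GeneticMean); if the host contig was removed, the nearest preceding
retained host is used (placed first on the LG if none); insertions at one
host sort by (GeneticStart, GeneticEnd, scaffold-before-contig, lexicographic
name — embedded numbers are compared lexicographically, a documented choice).
Rules 3–4: exactly 100 N's between neighbours; pseudomolecules named after
their LGs.  Minus-strand contigs are reverse-complemented; unoriented contigs
are emitted forward with AGP orientation "?", and gap rows are AGP 2.1 "U"
rows (100 bp, linkage evidence "map").  The layout is a deterministic
function of its inputs; repeated builds are byte-identical.

## Problem sizes used in verification

The test suite exercises small crosses (2 LGs, 80–200 individuals) for unit
behaviour and one study-scale simulation (375 F2 / 366 retained, 8 LGs,
~2,400 mapped SNPs, mean depth 7) for end-to-end recovery; the acceptance
script runs the same study-scale configuration plus a 500 × 10,000-locus
population for the F2 heterozygosity expectation and 2,000 unlinked tags as
negative controls.  Exhaustive oracles (permutation search for ordering, path
enumeration for the HMM, rational arithmetic for the binomial tail) are run
at the sizes where enumeration is exact (≤ 8 markers, n ≤ 64).

## Known limitations

* The grouping/ordering and error-correction stages are functionally
  equivalent re-implementations of the classic MSTMap-style and
  fill.geno-style workflows, not bit-for-bit reproductions of those tools;
  they are validated by recovery and by exhaustive oracles on small
  instances.
* Ordering within zero-recombination bins is taken from input order; no
  data-driven resolution exists at that resolution.
* The map-length estimate is biased slightly low (a few per cent) by the
  HMM smoothing of genuine tight double crossovers.
* Tag mapping searches all LGs globally; with dense maps and very low
  carrier counts the span can touch neighbouring SNPs with identical rational
  rates, which is the intended exact-equality semantics.
* The pipeline assumes biallelic SNPs and fully inbred parents; residual
  parental heterozygosity silently shrinks the phasable site set.
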