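# Methods

This note documents the models, estimators, null models and numerical
choices implemented in `ecoassembly`, in the spirit of the methods
documentation that accompanies simulation and statistics packages.

## Data model

All stages consume an `OtuTable`: a non-negative integer count matrix with
samples as rows and OTUs as columns, optional taxonomy strings per OTU and an
optional sample → habitat mapping. Counts are kept as integers; relative
abundances (row-stochastic `RelAbundanceTable`) are derived lazily and never
persisted. Sample and OTU id matching is exact and case-sensitive — silent
case-folding hides upstream errors. The loader accepts either orientation of
a TSV table; detection prefers label evidence (ids starting with "OTU") and
otherwise assumes the longer axis is OTUs, falling back to the conventional
OTUs-as-rows layout for near-square tables. OTUs with fewer than `min_count`
reads in total (default 2, i.e. singleton removal) are dropped at load.

Trees are rooted newicks with non-negative branch lengths whose tips are OTU
ids (dendropy-backed); patristic distances are computed once and cached.
Environmental tables are CSVs of per-sample variables; non-numeric cells
become missing values with a warning, and all downstream handling is
pairwise-complete — never imputation.

## Abundant/rare partitioning and diversity

An OTU is *abundant* when its mean relative abundance across the samples
under consideration is ≥ 1e-4 (0.01%), otherwise *rare*; the boundary is
abundant. The threshold scope is a parameter (`mean` default,
`per_sample_max` optional) because surveys are not consistent about it; the
pipeline applies the partition within each habitat group separately.

Alpha diversity per sample: observed richness; Shannon `H = −Σ p ln p`
(natural log); Pielou `J = H / ln S` (undefined at S = 1); Chao1 in the
classic form `S + F1²/(2 F2)` with the bias-corrected form
`S + F1(F1−1)/(2(F2+1))` when doubletons are absent (so Chao1 = S when there
are no singletons); ACE with rare-abundance cutoff 10 (configurable). These
delegate to scikit-bio's estimators; when every rare taxon is a singleton —
where ACE's coverage estimate is undefined — the bias-corrected Chao1 is
reported instead, following the EstimateS recommendation. Group comparisons
use one-way ANOVA with Tukey HSD compact letters at α = 0.05 (letters are
the maximal cliques of the non-significance graph, ordered by group mean);
two groups degrade to Welch's t-test.

Beta diversity is classical metric MDS (PCoA) of the Bray–Curtis matrix
`Σ|x−y| / Σ(x+y)`. Bray–Curtis is non-Euclidean, so negative eigenvalues of
the Gower-centered matrix can occur; they are clipped to zero with a logged
note and axis signs are canonicalized (largest-|score| coordinate positive).
The implementation is cross-checked against scikit-bio's PCoA in the tests.

## Levins' niche breadth and habitat specialization

For OTU *j* with relative abundance `P_ij` in community *i*, let
`q_i = P_ij / Σ_i P_ij`. Levins' niche breadth is `B_j = 1 / Σ_i q_i²`, the
inverse Simpson concentration of the OTU's distribution over communities:
B = 1 for a single-community OTU, B = N for a perfectly even one. The
across-community normalization of P is essential — without it B is not
bounded by N. The community mean `B_m` is the unweighted mean over OTUs with
a bootstrap sd over 100 OTU resamples (seeded).

Generalists and specialists are called against a permutation null. The
default null (`count_swap`) randomizes the integer count matrix while
preserving every row and column sum exactly, via repeated 2×2 checkerboard
moves (`[[a,b],[c,d]] → [[a−1,b+1],[c+1,d−1]]` where legal), the
quantitative analogue of quasiswap; the chain runs 5× the number of
non-zero cells of successful moves per sample. When the matrix admits fewer
than two checkerboard units the chain cannot mix and the code falls back,
with a warning, to a `row_proportion` null (each sample's total
redistributed multinomially using pooled metacommunity proportions). With
1000 permutations (default) and a 95% two-sided envelope per OTU: observed
B above the upper quantile ⇒ generalist, below the lower ⇒ specialist,
otherwise neutral. OTUs absent from the subset under analysis are excluded
rather than scored B = 0. Note that a margin-preserving null allocates each
OTU roughly proportionally to sample depths — i.e. toward proportional
evenness — so generalist calls are intrinsically conservative and
specialists are the commonly detected class; this matches field experience
with these nulls.

## Assembly null models

**βMNTD** between samples A and B is the abundance-weighted mean of each
present OTU's patristic distance to its nearest relative in the other
sample:

    βMNTD = ½ [ Σ_j p_jA · min_{k∈B} d(j,k) + Σ_j p_jB · min_{k∈A} d(j,k) ]

with p the within-sample relative abundances; shared OTUs contribute zero.
**βNTI** standardizes the observed value against a null built by shuffling
tip labels across the whole phylogeny (equivalently, permuting the rows and
columns of the patristic matrix), independently per replicate, 999
replicates by default. The tree is pruned to the OTUs of the subset under
analysis before the shuffle. When the null is effectively constant (e.g. an
equidistant star tree) βNTI is undefined; such pairs are flagged, excluded
from process fractions, and counted in the result metadata. The degeneracy
test is `sd ≤ 1e-10 · max(1, |mean|)` to absorb float accumulation. βNTI is
invariant to uniform scaling of branch lengths (observed and null scale
together).

**RC_Bray** compares each pair's observed Bray–Curtis dissimilarity with a
null distribution in which both communities are reassembled preserving their
observed richness and total abundance: species enter the null community with
probability proportional to their occurrence frequency across samples (one
individual each), and the remaining individuals are assigned multinomially
with probability proportional to metacommunity relative abundance. With
`n_null` replicates,

    RC = 2 · [ (#(null < obs) + ½ · #(null = obs)) / n_null ] − 1  ∈ [−1, 1].

**Process classification** (per unordered pair): βNTI ≥ 2 heterogeneous
selection; βNTI ≤ −2 homogeneous selection; otherwise RC > 0.95 dispersal
limitation, RC < −0.95 homogenizing dispersal, |RC| ≤ 0.95 undominated. The
deterministic boundary is inclusive (|βNTI| = 2 is selection); the RC
boundary is strict. Fractions are reported per habitat × abundance-class
subset; the two null models consume independent seeded streams derived from
one master seed.

## Co-occurrence networks

OTUs present in at least ⌈2/3 · n⌉ samples are correlated all-against-all
with Spearman rank correlation (average-rank ties, t-approximation p).
Edges require |r| > 0.8 AND p < 0.01, strict; Benjamini–Hochberg correction
is available but off by default, since the raw-p filter is the convention
this analysis follows. Correlation is computed on counts (ranks are
depth-invariant; an option switches to relative abundances). Zero-variance
OTUs are excluded with a warning, and OTUs without any retained edge do not
appear as nodes. Topology: AD = 2E/V; ACC = mean local clustering (degree <
2 contributes 0); APD = mean shortest path on the largest connected
component (its coverage is reported — global APD is undefined for
disconnected graphs); GD = 2E/(V(V−1)); modularity via seeded Louvain on the
unweighted graph, repeated 20 times (mean ± sd) with the best partition's
module labels stored on the nodes. Node annotation attaches abundance class,
niche category and phylum (parsed from `p__` fields of lineage strings).

## Mantel association

The Mantel statistic is the Spearman correlation of the lower-triangle
entries of a βNTI matrix and a single-variable Euclidean distance matrix
|x_i − x_k|. The null permutes sample labels of the second matrix; the
p-value is two-sided, `(1 + #(|r_null| ≥ |r_obs|)) / (n_perm + 1)` with 999
permutations by default, so its resolution is 1/(n_perm+1). A βNTI matrix is
not a metric distance (negative entries, no triangle inequality); the
rank-based permutation machinery does not require metricity, but the caveat
stands. Samples with missing values are dropped from both matrices
(pairwise-complete). Per-variable tests run over the whole environmental
table with no multiplicity correction by default (BH optional).

## Synthetic-data generator

The generator emulates a 12-sample, two-habitat amplicon survey:

- **Metacommunity**: 300 OTUs with log-normal relative abundances
  (sd-log 4.0). At the default depth of 50,000 reads per sample this yields
  the qualitative structure of real surveys — rare OTUs (< 0.01% mean
  relative abundance) are the majority of observed richness yet carry well
  under 20% of reads. Both parameters are realistic for soil-associated 16S
  data, where a handful of OTUs dominate reads and most taxa are rare.
- **Phylogeny**: pure-birth tree (birth rate 1) with total depth normalized
  to 1. The simulator stops at the n-th speciation, which leaves zero-length
  terminal cherries, so one extra exponential waiting time is appended to
  every terminal branch before normalization.
- **Traits**: Brownian motion along the tree (rate 1), giving
  phylogenetically conserved niche optima — the signal βNTI needs.
- **Regimes**: `neutral` draws every sample multinomially from the shared
  metacommunity; `selection` places six samples at each end of a ±1
  environmental contrast (plus N(0, 0.05) noise) and weights the
  metacommunity by the Gaussian kernel `exp(−(trait − env)²/(2σ²))` with
  filter width σ = 0.35 — narrow enough that the two environments select
  different clades; `dispersal_limitation` assigns OTUs at random to
  disjoint source pools (2 by default) and samples draw only from their
  pool, so the split is random with respect to the phylogeny (RC saturates,
  βNTI does not).
- **Environment table**: the true gradient plus three pure-noise N(0,1)
  variables for Mantel type-I checks.

All randomness flows from one master seed through spawned sub-streams,
recorded in the dataset's ground-truth metadata.

### What passing tests do and do not show

The generator produces multinomial sampling noise on smooth expected
profiles. Real amplicon data add compositional artefacts, PCR/primer bias,
overdispersion, contamination and uneven sequencing depth, none of which are
emulated. Ground-truth recovery on these simulations therefore validates
the statistical machinery (the null models do detect the processes that
generated the data, at the stated problem sizes), not robustness to
real-world measurement error. One further caveat: a single Brownian trait
realization can place the selection split off-clade, weakening the βNTI
signal for that draw; validation therefore pools replicate communities
rather than relying on one tree.

## Problem sizes and defaults used in validation

Validation and the acceptance script run at the emulated survey's design
size — 12 samples × 300 OTUs, 66 sample pairs — with 199 null replicates for
βNTI/RC and 199 permutations for niche-breadth and Mantel nulls (999 remain
the library defaults; the estimates at 199 are within the Monte-Carlo error
the classification thresholds tolerate). The exhaustive cross-checks
(tip-permutation βNTI, margin enumeration for the niche null) run at 3–4
tips/samples where complete enumeration is possible.

## Known limitations

- The count-swap chain is a heuristic sampler of the fixed-margin space; it
  is not guaranteed to sample the space uniformly (a known property of swap
  algorithms on quantitative matrices). The tests bound its envelope by the
  exact enumeration support on tiny matrices.
- RC_Bray follows the occurrence-weighted, abundance-proportional null; other
  weightings in the literature (richness-only, equal-probability) are not
  offered.
- βNTI's tip shuffle is the full-tree taxa shuffle; within-group or
  within-habitat restricted shuffles are not implemented.
- Quantitative process estimation beyond the two-metric five-way scheme
  (phylogenetic-bin decompositions) is out of scope.
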