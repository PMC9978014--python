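# ecoassembly

Community-assembly inference for microbiome OTU tables.

Microbial surveys routinely ask not just *who is there* but *why*: are
communities shaped by deterministic environmental selection, by limits on
dispersal, or by drift? `ecoassembly` implements the standard inference chain
used to answer this for amplicon (16S) count data — for example the abundant
and rare bacteria of a fungal fruiting body and its surrounding mycosphere
soil — as a tested, reusable Python library with a thin CLI:

- **Abundant/rare partitioning** at the 0.01% mean relative-abundance
  threshold, with alpha diversity (richness, Shannon *H*, Pielou *J*, Chao1,
  ACE) and Bray–Curtis PCoA.
- **Levins' niche breadth** per OTU,
  *B_j* = 1 / Σᵢ qᵢ² with qᵢ the OTU's proportional distribution over the
  *N* communities (1 ≤ *B* ≤ *N*), community means with bootstrap spread, and
  generalist / specialist / neutral calls against a count-preserving
  permutation null (fixed row and column sums).
- **Assembly-process attribution** per sample pair:
  βMNTD (abundance-weighted between-sample mean nearest-taxon distance),
  βNTI = (βMNTD_obs − mean_null) / sd_null from a tip-shuffle null
  (999 randomizations by default), and Raup–Crick on Bray–Curtis (RC_Bray ∈
  [−1, 1]). The five-way scheme: βNTI ≥ 2 heterogeneous selection,
  βNTI ≤ −2 homogeneous selection; otherwise RC_Bray > 0.95 dispersal
  limitation, RC_Bray < −0.95 homogenizing dispersal, |RC_Bray| ≤ 0.95
  undominated.
- **Co-occurrence networks**: Spearman |r| > 0.8 and p < 0.01 after a ≥ 2/3
  prevalence filter, with the usual topology summary (average degree,
  clustering coefficient, path distance, density, modularity mean ± sd over
  restarts).
- **Mantel tests** (Spearman, permutation p) relating βNTI matrices to
  per-variable Euclidean environmental distances.
- A **synthetic-data generator** producing communities with known assembly
  regime (neutral / selection / dispersal limitation), a pure-birth phylogeny
  with Brownian niche traits, and an environmental table — the ground truth
  every stage is validated against.

## Worked example

Generate a 8-sample community filtered by a two-level environmental gradient,
then attribute assembly processes:

```bash
ecoassembly simulate --regime selection --n-otus 80 --n-samples 8 \
    --depth 3000 --seed 7 --out demo/
ecoassembly assembly --otu demo/table.tsv --tree demo/tree.nwk \
    --n-null 199 --seed 42 --min-count 0 --out demo/pairs.tsv
```

which prints the per-pair process fractions:

```json
{
  "heterogeneous_selection": 0.6428571428571429,
  "homogeneous_selection": 0.0,
  "dispersal_limitation": 0.0,
  "homogenizing_dispersal": 0.2857142857142857,
  "undominated": 0.07142857142857142
}
```

64% of sample pairs — essentially all pairs that straddle the two
environments — are called heterogeneous selection (βNTI > 2): communities at
opposite ends of the gradient are phylogenetically more distinct than the
tip-shuffle null expects, exactly what Gaussian niche filtering of
phylogenetically conserved traits should produce. The within-environment
pairs land in the stochastic classes. `demo/pairs.tsv` holds the per-pair
βMNTD, βNTI, RC_Bray and labels.

The same analyses are available as library calls (`ecoassembly.beta_nti`,
`ecoassembly.rc_bray`, `ecoassembly.classify_specialists`, ...), and
`ecoassembly pipeline` runs every stage over habitat × abundance-class
subsets from one config, writing per-stage TSV/JSON/GraphML outputs and a
deterministic `report.json`.

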