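# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `microlake`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Normalization

Sequencing depth differs between samples, so all downstream statistics run
on a table rarefied to even depth: subsampling **without replacement**
(multivariate hypergeometric per sample), default depth = the minimum sample
sum, seed recorded in the run log. Rarefaction without replacement keeps
Shannon and Bray–Curtis comparable across samples and can never invent a
taxon that was absent. Relative abundances are per-sample proportions.

## Abundance classes

Dual thresholds on the pooled table: abundant (AT) = local relative
abundance > 1% in **at least one** sample and mean ≥ 0.1%; rare (RT) = local
< 0.01% in **every** sample and mean < 0.001%; intermediate (IT) otherwise.
The "at least one sample" reading of the local condition is the one that
makes AT and RT disjoint; boundaries are strict `>`/`<` except the AT mean
(`≥`), exactly as the thresholds are conventionally printed. Classification
is computed once on the pooled table; per-region membership intersects the
labels with regional presence (pooled count > 0).

Venn accounting reports shared/region-specific fractions against **two
denominators** — the union of regional OTU sets and the sum of per-region
richnesses — because published Venn percentages mix both conventions and
only the union-based shared fraction is internally consistent.

## Diversity and group statistics

* Shannon H′ = −Σ p ln p (natural log), per sample.
* Bray–Curtis on relative abundances; PCoA by Gower double-centering of
  −d²/2 with `eigh`; negative eigenvalues are reported but excluded from the
  explained-variance denominator (sum of positive eigenvalues).
* PERMANOVA: pseudo-F from the within/between squared-distance
  decomposition; p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) with
  whole-sample label permutation under a fixed seed; 999 permutations by
  default. PERMANOVA (not ANOSIM) is the companion test to PCoA here because
  it tests location differences on the same dissimilarity.
* Kruskal–Wallis per taxon with scipy's tie correction; constant taxa get
  H = 0, p = 1 instead of an error. BH (step-up) adjustment across taxa;
  both raw p and q are emitted, significance flags use raw p < 0.05 as the
  field prints them.
* One-way ANOVA with Tukey–Kramer HSD (studentized range; Kramer correction
  for unequal n) and a compact letter display built by splitting the
  all-groups set on each significant pair and absorbing subset letters.
* Spearman taxon–environment correlation with average ranks for ties;
  constant variables yield missing ρ rather than an error.

## Co-occurrence networks

Nodes are the top-100 taxa by mean relative abundance (configurable); edges
are Spearman correlations with |ρ| ≥ 0.6 and BH-adjusted p ≤ 0.05 — the
usual amplicon-network defaults, since no single canonical threshold exists.
Modularity uses deterministic greedy (CNM) agglomeration on the unweighted
graph, preferred over stochastic Louvain for reproducibility; exhaustive
search over all partitions bounds it on small graphs in the tests.

Robustness: remove ⌊f·n⌋ uniformly random nodes (f = 0.5 by default), then
delete any node left without a neighbour (one isolation cascade); R is the
surviving fraction of the original nodes, averaged over 500 seeded
iterations with its SE. The no-cascade variant would equal 1 − f identically
and could not differ between regions, so the cascade reading is the
meaningful one. Class-level robustness runs on the induced AT/IT/RT
subgraphs; classes with fewer than 4 nodes are skipped with a warning.

## Indicator species

Dufrêne–Legendre IndVal with the group-mean form of specificity
(A = mean abundance in the group / sum of group means), which corrects for
the unbalanced 18/12/18 design; fidelity B is the fraction of the group's
samples with the taxon present (> 0 after normalization). Permutations
shuffle whole samples, preserving taxon covariance; n_perm = 999 by default.
Strong indicators: IndVal > 0.7 and raw p < 0.05; BH-adjusted q is emitted
alongside but the flag uses raw p as printed in the field.

## Assembly null models

Patristic distances are computed once per tree and cached; the βNTI null
permutes the row/column labels of that matrix, which is mathematically
identical to relabelling tips but much cheaper. Tip shuffling randomizes
across the whole tree. Abundance-weighted βMNTD is the default (unweighted
mode retained for testing). Pairs whose null distribution has zero spread
(e.g., a star phylogeny) are flagged degenerate; their βNTI is undefined and
they fall through to the RC_bray rules, so the five process fractions always
sum to 1. RC_bray nulls draw presence ∝ occupancy and fill reads ∝ pooled
relative abundance from the whole-survey pool by default (per-region pools
available); ties in the null Bray–Curtis count half. n_null defaults to 999;
the acceptance checks run 299 for speed.

Communities without a usable phylogeny (the normal situation for ITS fungal
data) skip the βNTI stage: the partition then distinguishes only dispersal
limitation, homogenizing dispersal and drift, and says so in the report —
selection is never inferred without a tree.

## Synthetic communities

The generator emulates a 48-sample survey (three regions, 18/12/18 samples =
(3 + 2 + 3) plots × 3 replicates × 2 dates), default depth 20,000 reads.

* **Metacommunity**: log-normal(0, sdlog 2) by default (strong dominance);
  `metacommunity="logseries"` (p = 0.9999) gives the singleton-heavy
  distribution that best shows the richness/abundance decoupling.
* **Phylogeny**: Yule pure-birth tree with exponential waiting times,
  ultrametric by construction. Niche optima evolve by Brownian motion
  (variance ∝ branch length); `signal=False` shuffles optima across tips to
  destroy the signal while preserving the marginal distribution.
* **Regimes**: `neutral` samples every community from the metacommunity;
  `filtering_*` multiplies the metacommunity by a Gaussian niche kernel
  exp(−(optimum − E)²/2σ²) around the sample's environment, with region
  environments at ±1.5 trait-SD offsets (heterogeneous) or a common value
  (homogeneous) and niche breadth σ = 0.25 trait-SD — a strong filter, as
  the regime's name promises; `dispersal_limited` gives each region a
  private permutation of the metacommunity (optionally disjoint taxon
  sets); `mixed` assigns one regime per region.
* **Drift**: every sample's weights pass through a Dirichlet with
  concentration θ·w (θ = 200) before the multinomial read draw. A pure
  multinomial re-draw of one fixed metacommunity would be technical
  replication, not ecological drift — sample pairs would be far more similar
  than any pool-based null expects. The Dirichlet layer adds the
  between-sample compositional variance drift actually denotes, and its
  variance profile (small CV for dominant taxa, large for rare ones) matches
  the occupancy-driven variance of the Raup–Crick null, which is why neutral
  simulations calibrate: the acceptance checks measure ≥ 90% |βNTI| < 2 and
  ≥ 85% |RC_bray| ≤ 0.95 on those runs.
* **Environment**: the 12 water-chemistry variables are drawn per region as
  Normal(mean, SE·√n) around published per-region means (total nitrogen,
  dissolved oxygen, chlorophyll-a, etc.); an optional rank-coupling ties one
  variable to a chosen taxon at a target Spearman ρ for recovery tests.
* **Planted networks**: block-diagonal latent Gaussian correlation,
  exponentiated and multinomially sampled; 60 uncorrelated background taxa
  absorb the compositional budget so simplex closure does not induce
  spurious negative edges between blocks.

**What the generator does not emulate** — and therefore what passing tests
do not show about field data: chimeras and PCR/sequencing error; taxonomy
(genus aggregation is exercised only through user-supplied tables);
temporal autocorrelation between the two sampling dates; and genuinely
conditionally-rare dynamics — under the default drift layer a taxon that is
rare on average can blip above the 0.01% local threshold in one sample,
which is why the richness-decoupling demonstration uses the log-series
metacommunity without drift.

## Problem sizes and seeds

Null-model checks run at 64 taxa × 12 samples (neutral and dispersal) and
128 taxa (filtering, where clade structure carries the signal), 299 nulls,
three seeds — sizes at which every acceptance computation finishes in a few
minutes on one CPU while the measured rates are stable across seeds. Every
random stage in the pipeline consumes a child seed derived by hashing the
stage name with the master seed, so adding a stage never perturbs earlier
stages' randomness.

## Known limitations

* RC_bray is intrinsically sensitive to single-taxon dominance: when one
  taxon holds most reads, the occupancy-based null is right-skewed and RC
  drifts negative even for null data. The calibration holds at the
  generator's default dominance; extreme (>70% single-taxon) communities
  should be interpreted with care.
* The compact-letter display is the greedy insert–absorb construction; like
  all letter displays it is a summary of the pairwise tests, not a new test.
* Greedy modularity is a lower bound on the optimal Q (verified against
  exhaustive search on ≤ 8 nodes in the tests).
* The βNTI ±2 convention treats the null as approximately Gaussian; with
  very few taxa per sample the null can be skewed and coverage slightly
  below nominal.
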