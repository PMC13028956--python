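# microlake

Community ecology of lake microbiomes: a tested, reusable pipeline for the
analyses a eutrophic-lake amplicon survey runs downstream of OTU clustering —
rare-biosphere abundance classes, diversity and ordination statistics,
bacterial–fungal co-occurrence network robustness, indicator-species
screening, and null-model partitioning of community assembly processes. A
ground-truthed synthetic-community generator makes every stage verifiable
without any field sequences.

## Who it is for

Microbial ecologists analysing taxa × sample count tables from multi-region
freshwater surveys (e.g., a polluted basin, a bloom zone, and a macrophyte
remnant zone of one lake), who need the standard battery of community
statistics with explicit seeds, nulls, and tests.

## The statistics at its core

**Abundance classes.** An OTU is *abundant* (AT) if its within-sample relative
abundance exceeds 1% in at least one sample and its mean across samples is
≥ 0.1%; *rare* (RT) if it never reaches 0.01% locally and its mean is
< 0.001%; otherwise *intermediate* (IT).

**Assembly null models.** For sample pair (k, l), the abundance-weighted
β-mean nearest taxon distance is

    βMNTD = ½ [ Σ_{i∈k} f_ik · min_{j∈l} d_ij + Σ_{j∈l} f_jl · min_{i∈k} d_ji ]

with f relative abundances and d patristic distances. βNTI standardizes the
observed βMNTD against a null that shuffles taxa across the tips of the
phylogeny: βNTI = (βMNTD_obs − μ_null)/σ_null. RC_bray compares the observed
Bray–Curtis dissimilarity to communities reassembled from the species pool
(presence ∝ occupancy, abundance fill ∝ pool relative abundance), rescaled
to [−1, 1]. Each pair is assigned a process: βNTI > 2 heterogeneous
selection; βNTI < −2 homogeneous selection; otherwise RC_bray > 0.95
dispersal limitation, RC_bray < −0.95 homogenizing dispersal, else drift.

**Networks.** Spearman co-occurrence among the top taxa (|ρ| ≥ 0.6, BH-adjusted
p ≤ 0.05), greedy modularity Q, and robustness R = mean fraction of nodes
surviving random removal of 50% of nodes plus the isolation cascade.

**Indicator species.** IndVal = A·B with A the group-mean specificity and B
the occurrence fidelity; significance by whole-sample label permutation;
strong indicators have IndVal > 0.7 and p < 0.05.

Also included: Shannon diversity, Bray–Curtis PCoA, PERMANOVA,
Kruskal–Wallis differential abundance with BH correction, Tukey–Kramer
compact letters, and Spearman taxon–environment correlation.

## Worked example

`examples/05_assembly_processes.py` simulates one neutral and one
environmentally filtered survey and partitions the between-region sample
pairs:

```
neutral (between-region pairs):
     heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  drift  deterministic  stochastic  n_pairs
all                    0.042                    0.0                   0.0                     0.0  0.958          0.042       0.958     48.0

filtering_heterogeneous (between-region pairs):
     heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  drift  deterministic  stochastic  n_pairs
all                    0.688                    0.0                 0.312                     0.0    0.0          0.688       0.312     48.0
```

Under neutral assembly 96% of pairs fall to ecological drift (|βNTI| < 2,
|RC_bray| ≤ 0.95), while region-distinct environmental filtering on a
phylogenetically conserved niche trait moves 69% of between-region pairs into
heterogeneous selection — the generator's planted regime is recovered by the
null models. The other scripts in `examples/` cover abundance classes,
diversity/ordination, networks, indicator species, and the full pipeline;
each prints the numbers it computes and one line on what they mean.

A thin CLI wraps the library for shell use:

```sh
microlake simulate --n-taxa 500 --regime mixed --seed 1 --outdir survey/
microlake run --config run.yaml --outdir out/
```

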