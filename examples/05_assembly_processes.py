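"""Null-model partition of community assembly processes.

Runs betaNTI (phylogenetic turnover vs tip-shuffling null) and RCbray
(taxonomic turnover vs species-pool null) on two simulated surveys — one
neutral, one with region-distinct environmental filtering — and prints the
five-process breakdown for between-region sample pairs.
"""

from microlake import (
    SimulationConfig, beta_nti, partition_processes, process_fractions,
    rc_bray, simulate_communities, simulate_tree,
)

for regime in ("neutral", "filtering_heterogeneous"):
    n_taxa = 64 if regime == "neutral" else 128
    cfg = SimulationConfig(n_taxa=n_taxa, depth=20000, regime=regime,
                           samples_per_region=(4, 4, 4), seed=1)
    table, meta, truth = simulate_communities(cfg)
    tree = truth["tree"] or simulate_tree(n_taxa, seed=51)
    bnti = beta_nti(table, tree, n_null=299, seed=1).betanti
    rc = rc_bray(table, n_null=299, seed=1)
    pairs = partition_processes(bnti, rc, groups=meta["region"])
    frac = process_fractions(pairs[pairs["scope"] == "between_region"])
    print(f"\n{regime} (between-region pairs):")
    print(frac.round(3).to_string())
print("\n-> filtering pushes pairs into heterogeneous selection (betaNTI > 2);"
      "\n   neutral assembly leaves most pairs in the stochastic processes.")
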