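"""Delimit floristic districts: NMDS ordination plus MRPP confirmation.

NMDS embeds the dissimilarity matrix in two dimensions while preserving
rank order (Kruskal stress-1 measures the distortion).  MRPP then asks
whether a grouping of plots is tighter than random relabelings: A > 0
with small p confirms the districts.  Without analyst-supplied groups,
k-medoids provides provisional labels.
"""

from phylodistricts import (
    SimulationConfig,
    align_tree_matrix,
    k_medoids,
    mrpp,
    nmds,
    sorenson_matrix,
)
from phylodistricts.simulate import simulate_communities, simulate_tree

config = SimulationConfig(
    seed=42, n_species=300, n_plots=24, n_districts=3,
    clade_bias=0.9, fisher_alpha=60.0, n_individuals=300,
)
tree = simulate_tree(config.n_species, config.birth_rate, seed=config.seed)
bundle = simulate_communities(tree, config)
tree, cm, _ = align_tree_matrix(bundle.tree, bundle.community)
truth = bundle.districts.loc[cm.plot_ids]

tbd = sorenson_matrix(cm)

ordination = nmds(tbd, n_starts=16, seed=0)
print(f"NMDS stress-1: {ordination.stress:.4f} "
      f"({ordination.n_starts} starts, converged={ordination.converged})")
print(ordination.coordinates.head(6).round(3))

derived = k_medoids(tbd, k=3)
agreement = (
    truth.groupby(derived).agg(lambda s: s.value_counts().iloc[0]).sum()
    / len(truth)
)
print(f"\nk-medoids vs true districts: {agreement:.0%} agreement")

res = mrpp(tbd, truth.to_dict(), n_perm=999, seed=0)
print(f"MRPP on true districts: delta_obs={res.delta_obs:.4f} "
      f"delta_exp={res.delta_exp:.4f} A={res.a_statistic:.4f} "
      f"p={res.p_value:.3f}")
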