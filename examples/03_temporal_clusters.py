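"""Soft clustering of temporal expression profiles.

Every gene is reduced to its standardized vector of group means across the
ordered conditions, then partitioned by fuzzy c-means; cluster centroids
are labelled by trend shape (monotone up, monotone down, up-then-down).
1,000 genes are simulated, 240 of which carry three planted trends
(80 genes each); the rest are unstructured background.
"""

from collections import Counter

from sklearn.metrics import adjusted_rand_score

from tipdnb import ProfileSpec, SimulationConfig, simulate_timecourse
from tipdnb.clustering import (
    assign_clusters, fuzzy_cmeans, label_cluster_shape, standardize_profiles,
)
from tipdnb.deg import normalize_log_cpm

config = SimulationConfig(
    n_genes=1000, replicates=3, de_fraction=0.0,
    profile_clusters=(
        ProfileSpec("mono_up", 80, amplitude=2.5),
        ProfileSpec("mono_down", 80, amplitude=2.5),
        ProfileSpec("up_down", 80, amplitude=2.5),
    ),
    seed=11,
)
matrix, truth = simulate_timecourse(config)

profiles = standardize_profiles(normalize_log_cpm(matrix))
fc = fuzzy_cmeans(profiles, c=4, m=1.25, seed=0)
print(f"converged: {fc.converged} after {fc.n_iter} iterations, "
      f"objective {fc.objective:.1f}")

assignments = assign_clusters(fc)
shape_of_gene = {g: s for s, genes in truth.profile_members.items() for g in genes}
for j in range(fc.c):
    members = [g for g, c in assignments.items() if c == j]
    planted = Counter(shape_of_gene.get(g, "background") for g in members)
    label = label_cluster_shape(fc.centroids[j], fc.group_order)
    detail = ", ".join(f"{k}={v}" for k, v in planted.most_common())
    print(f"cluster {j + 1}: {len(members):3d} genes  centroid shape={label:9s}  ({detail})")

planted_genes = sorted(shape_of_gene)
ari = adjusted_rand_score(
    [shape_of_gene[g] for g in planted_genes],
    [assignments[g] for g in planted_genes],
)
print(f"\nadjusted Rand index on the 240 planted genes: {ari:.3f}")
# Three clusters should each collect one planted trend (about 80 genes,
# matching centroid shape label); the fourth absorbs the unstructured
# background, whose noise profiles scatter across all clusters only weakly.
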