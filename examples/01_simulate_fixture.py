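"""Generate a synthetic ischemia-style time course and write it to disk.

The design mirrors the kind of study this package targets: six ordered
condition groups (a sham reference, then increasing ischemia durations)
with three replicates each, negative-binomial counts, a handful of planted
differentially expressed genes, planted temporal trends, planted enriched
gene sets, and a 20-gene dynamic-network-biomarker module at IR22.
"""

from tipdnb import (
    DnbSpec, GeneSetSpec, ProfileSpec, SimulationConfig,
    export_fixture, simulate_timecourse,
)

config = SimulationConfig(
    n_genes=1000,
    replicates=3,
    profile_clusters=(
        ProfileSpec("mono_up", 40, amplitude=2.5),
        ProfileSpec("mono_down", 40, amplitude=2.5),
        ProfileSpec("up_down", 40, amplitude=2.5),
    ),
    dnb=DnbSpec(tipping_group="IR22", module_size=20,
                variance_inflation=4.0, intra_corr=0.9, inter_corr=0.1),
    gene_sets=GeneSetSpec(n_sets=6, set_size=30, n_enriched=3),
    seed=42,
)
matrix, truth = simulate_timecourse(config)
paths = export_fixture(matrix, truth, "scratch/fixture")

print(f"matrix: {matrix.n_genes} genes x {matrix.n_samples} samples "
      f"({' '.join(matrix.design.group_order)})")
print(f"planted DE genes in IR30: {len(truth.de_genes['IR30'])}")
print(f"planted module ({len(truth.dnb_module)} genes) at {truth.tipping_group}: "
      f"{', '.join(truth.dnb_module[:5])}, ...")
print("files written:")
for name, path in paths.items():
    print(f"  {name}: {path}")
# The truth JSON is the ground truth downstream stages should recover:
# the DEG screen should find the planted effects, the DNB stage should
# peak at IR22 with a cluster overlapping the module gene list.
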