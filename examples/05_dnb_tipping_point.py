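"""Dynamic network biomarker analysis: find the tipping-point group.

A 20-gene module planted at IR22 fluctuates strongly (inflated variance),
moves in lockstep (intra-|PCC| 0.9) and decouples from the background
(inter-|PCC| 0.1) — the signature of a system about to transition.  The
DNB stage should produce a composite-index profile peaking at IR22.
"""

from tipdnb import DnbSpec, SimulationConfig, simulate_timecourse
from tipdnb.deg import normalize_log_cpm
from tipdnb.dnb import run_dnb

config = SimulationConfig(
    n_genes=500, replicates=10,
    dnb=DnbSpec(tipping_group="IR22", module_size=20,
                variance_inflation=4.0, intra_corr=0.9, inter_corr=0.1),
    seed=1,
)
matrix, truth = simulate_timecourse(config)

winner, table, results = run_dnb(normalize_log_cpm(matrix),
                                 sd_fold=2.0, pcc_threshold=0.9, min_cluster_size=5)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\npredicted tipping point: {winner} (planted: {truth.tipping_group})")
# Groups without a coherent high-variance cluster have no defined CI; at
# the tipping group the module passes the SD-fold selection, survives the
# |PCC| >= 0.9 clustering, and its CI = mean_SD * pcc1 / pcc0 peaks.

best = next(r.best_cluster for r in results if r.group == winner)
overlap = len(set(best.genes) & set(truth.dnb_module))
print(f"best cluster: {len(best.genes)} genes, {overlap} of the 20 planted module genes")
print(f"  mean_SD={best.mean_sd:.3f}  pcc1={best.pcc1:.3f}  pcc0={best.pcc0:.3f}  "
      f"CI={best.ci:.3f}")
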