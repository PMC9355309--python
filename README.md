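# tipdnb

Tipping-point detection in ordered-condition transcriptome time courses.

Many injury and disease processes pass through a *pre-disease* state: the
system still looks mildly affected, but it is about to shift irreversibly.
In a graded renal ischemia/reperfusion experiment, for example, kidneys
clamped a few minutes longer cross from recoverable to irreversible injury.
`tipdnb` analyses a gene × sample expression matrix over ordered condition
groups (a reference such as sham surgery, then increasing exposure) and
locates that critical transition with the **dynamic network biomarker
(DNB)** method, alongside the standard stages such an analysis chains
together:

1. **DEG screen** — log2-CPM normalisation, per-gene Welch t-test of each
   group against the reference, Benjamini–Hochberg adjustment, and the
   threshold rule `FDR < 0.01 AND |log2FC| > 1.2` (strict), plus top-N
   overlap proportions between contrasts and the qPCR `2^−ΔΔCt` fold change.
2. **Temporal clustering** — per-gene standardized group-mean profiles,
   partitioned by fuzzy c-means (the Mfuzz-style soft clustering) and
   labelled by trend shape (monotone up / monotone down / up-then-down).
3. **GSEA** — weighted running-sum enrichment scores with a permutation
   null, normalised enrichment scores, leading-edge extraction, and a
   two-contrast key-gene screen over the leading edge.
4. **DNB** — per group, select genes whose within-group standard deviation
   is at least `sd_fold` times the reference SD, group them by
   average-linkage clustering on `1 − |PCC|` cut at the 0.9 correlation
   threshold, and score each cluster with the composite index

   ```
   CI = mean_SD · PCC₁ / PCC₀
   ```

   where `mean_SD` is the mean within-group SD of cluster genes, `PCC₁` the
   mean absolute intra-cluster Pearson correlation, and `PCC₀` the mean
   absolute correlation between the cluster and the other selected genes.
   The group whose best cluster maximises CI is the predicted tipping
   point: a gene module that fluctuates strongly, moves in lockstep, and
   decouples from the rest of the transcriptome marks the state just
   before the transition — and the signature disappears once the
   transition has happened.

A synthetic-data generator (`tipdnb.synthetic`) produces negative-binomial
count matrices with planted DE genes, planted temporal trends, planted
enriched gene sets, and a planted DNB module at a known tipping group, so
every stage is verifiable against ground truth without any external data.

## Worked example

`examples/05_dnb_tipping_point.py` simulates six ordered groups
(`sham, IR16, IR18, IR22, IR26, IR30`, 10 replicates, 500 genes) with a
20-gene module planted at IR22 (variance inflation 4, intra-module |PCC|
0.9, module-to-background |PCC| 0.1) and runs the DNB stage:

```
group  selected_gene_number  mean_SD  pcc1  pcc0    CI
 IR16                     9      NaN   NaN   NaN   NaN
 IR18                    12      NaN   NaN   NaN   NaN
 IR22                    32    1.090 0.918 0.467 2.142
 IR26                    12      NaN   NaN   NaN   NaN
 IR30                    12      NaN   NaN   NaN   NaN

predicted tipping point: IR22 (planted: IR22)
best cluster: 17 genes, 17 of the 20 planted module genes
  mean_SD=1.090  pcc1=0.918  pcc0=0.467  CI=2.142
```

Only the planted group develops a coherent high-variance cluster at the
0.9 correlation threshold — the other groups select a few noisy genes that
never cluster, so their CI is undefined — and the recovered cluster is
almost exactly the planted module.  The other examples
(`examples/01…04`) walk through fixture generation, the DEG screen, the
temporal clustering and GSEA in the same style.

The same stages are available from the shell:

```bash
tipdnb simulate --config sim.yaml --out fixture/ --seed 42
tipdnb dnb --matrix fixture/expression.tsv --design fixture/design.tsv --out dnb/
tipdnb run-all --config run.yaml
```

Every stage reads and writes plain TSV/JSON, and `run-all` records all
parameters, seeds and input checksums in a `manifest.json`.

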