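"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain, position-by-position Python, sharing no
code with the package: the running-sum oracle walks the ranked list one gene
at a time, the composite-index oracle recomputes SDs and all pairwise
Pearson correlations directly from raw replicate values, and the BH oracle
evaluates the step-up formula by definition.
"""

import math


def brute_force_running_sum(gene_ids, metrics, gene_set, weight=1.0):
    """Running sum, ES and 1-based peak index, computed one position at a time."""
    members = set(gene_set)
    hits = [g in members for g in gene_ids]
    n = len(gene_ids)
    n_hit = sum(hits)
    assert 0 < n_hit < n
    total = sum(abs(m) ** weight for m, h in zip(metrics, hits) if h)
    running = []
    s = 0.0
    for g, m, h in zip(gene_ids, metrics, hits):
        if h:
            s += (abs(m) ** weight) / total if total > 0 else 1.0 / n_hit
        else:
            s -= 1.0 / (n - n_hit)
        running.append(s)
    es, peak = 0.0, 1
    for i, v in enumerate(running):
        if abs(v) > abs(es):
            es, peak = v, i + 1
    return es, running, peak


def brute_force_leading_edge(gene_ids, gene_set, es, peak):
    members = set(gene_set)
    if es == 0:
        return []
    if es > 0:
        return [g for g in gene_ids[:peak] if g in members]
    return [g for g in gene_ids[peak - 1:] if g in members]


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def sample_sd(x):
    n = len(x)
    m = sum(x) / n
    return math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))


def brute_force_ci(values_by_gene, cluster_genes, all_selected_genes):
    """Composite index from raw per-replicate values.

    values_by_gene: gene id -> list of replicate values in the group.
    """
    cluster = list(cluster_genes)
    outside = [g for g in all_selected_genes if g not in set(cluster)]
    mean_sd = sum(sample_sd(values_by_gene[g]) for g in cluster) / len(cluster)
    pairs = [
        abs(pearson(values_by_gene[a], values_by_gene[b]))
        for i, a in enumerate(cluster)
        for b in cluster[i + 1:]
    ]
    pcc1 = sum(pairs) / len(pairs)
    cross = [
        abs(pearson(values_by_gene[a], values_by_gene[b]))
        for a in cluster
        for b in outside
    ]
    pcc0 = sum(cross) / len(cross)
    return mean_sd * pcc1 / pcc0, mean_sd, pcc1, pcc0


def brute_force_bh(p_values):
    """Step-up BH by definition: adj_(i) = min_{j ≥ i} p_(j)·n/j, clipped at 1."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * n / rank)
        adj[i] = min(running_min, 1.0)
    return adj
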