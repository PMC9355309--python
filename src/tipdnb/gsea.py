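"""Gene-set enrichment between two condition groups.

Classic weighted Kolmogorov–Smirnov running-sum enrichment: genes are ranked
by a contrast metric, and walking down the list each set member ("hit") adds
its weighted metric share while each non-member subtracts 1/(N − N_hit); the
enrichment score (ES) is the signed maximal deviation of this running sum.
Significance comes from a permutation null (sample-label permutations when
the groups are large enough, random same-size gene sets otherwise — the
standard fallback for small-n designs), normalised enrichment scores are
ES over the mean same-sign null, and p-values are Benjamini–Hochberg
adjusted across sets.  The leading edge is the set members at or before the
running-sum peak (after, for negative ES) — the genes driving the signal —
and the key-gene screen applies a two-contrast absolute fold-change rule to
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .deg import bh_adjust
from .io_core import DesignError, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by decreasing ranking metric (ties broken by gene id)."""

    gene_ids: list[str]
    metrics: np.ndarray
    group_a: str
    group_b: str

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GseaResult:
    set_name: str
    es: float
    peak_index: int                 # 1-based rank of the running-sum extremum
    running_sum: np.ndarray
    leading_edge: list[str]
    nominal_p: float | None = None
    nes: float | None = None
    adjusted_p: float | None = None
    significant: bool | None = None
    null_es: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class KeyGeneScreenResult:
    gene_id: str
    lfc_mild: float
    lfc_severe: float
    passes: bool


def rank_genes(
    matrix: ExpressionMatrix, group_a: str, group_b: str, metric: str = "signal2noise"
) -> RankedList:
    """Rank all genes by the contrast ``group_a`` vs ``group_b``.

    signal2noise = (meanA − meanB)/(sdA + sdB), each sd floored at
    max(0.2·|mean|, 0.2) per the classic convention; log2fc is the plain
    mean difference on the log2 scale.
    """
    a = matrix.group_values(group_a)
    b = matrix.group_values(group_b)
    if metric == "signal2noise":
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise DesignError("signal2noise needs ≥ 2 replicates per group; use metric='log2fc'")
        sd_a = _floored_sd(a)
        sd_b = _floored_sd(b)
        r = (a.mean(axis=1) - b.mean(axis=1)) / (sd_a + sd_b)
    elif metric == "log2fc":
        r = a.mean(axis=1) - b.mean(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    order = sorted(range(len(r)), key=lambda i: (-r[i], matrix.gene_ids[i]))
    return RankedList(
        gene_ids=[matrix.gene_ids[i] for i in order],
        metrics=np.asarray([r[i] for i in order], dtype=float),
        group_a=group_a,
        group_b=group_b,
    )


def _floored_sd(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1)
    mean = x.mean(axis=1)
    return np.maximum(sd, np.maximum(0.2 * np.abs(mean), 0.2))


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """ES, full running sum, and 1-based peak index for one gene set.

    Hits add |r|^weight / Σ_hits |r|^weight (uniform shares when every hit
    metric is zero); misses subtract 1/(N − N_hit).  ES is the running-sum
    value of largest magnitude, first occurrence on ties.
    """
    members = set(gene_set)
    n = len(ranked)
    is_hit = np.array([g in members for g in ranked.gene_ids], dtype=bool)
    n_hit = int(is_hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list (miss step undefined)")
    w = np.abs(ranked.metrics) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    total = hit_w.sum()
    if total > 0:
        incr = hit_w / total
    else:
        incr = is_hit / n_hit
    miss = 1.0 / (n - n_hit)
    steps = np.where(is_hit, incr, -miss)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak + 1


def leading_edge(ranked: RankedList, gene_set, es: float, peak_index: int) -> list[str]:
    """Set members at or before the peak (positive ES) / at or after it
    (negative ES), in ranked order.  An ES of exactly 0 has no leading edge.
    """
    if es == 0:
        logger.warning("ES = 0: empty leading edge")
        return []
    members = set(gene_set)
    if es > 0:
        span = ranked.gene_ids[:peak_index]
    else:
        span = ranked.gene_ids[peak_index - 1:]
    return [g for g in span if g in members]


def permutation_null(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    gene_set,
    n_permutations: int = 1000,
    mode: str = "geneset",
    seed: int | None = 0,
    metric: str = "signal2noise",
    weight: float = 1.0,
) -> np.ndarray:
    """Null ES sample for one gene set.

    phenotype mode re-assigns the pooled samples of the two groups to
    relabelled groups (all distinct relabelings when there are at most
    ``n_permutations`` of them, otherwise random ones) and recomputes the
    ranking; geneset mode keeps the observed ranking and scores random
    same-size gene sets.
    """
    if n_permutations < 100:
        raise ValueError("need ≥ 100 permutations for a usable null")
    rng = np.random.default_rng(seed)
    if mode == "geneset":
        ranked = rank_genes(matrix, group_a, group_b, metric)
        size = len(set(gene_set) & set(ranked.gene_ids))
        if size == 0:
            raise ValueError("gene set does not intersect the ranked list")
        return _geneset_null(ranked, size, n_permutations, rng, weight)
    if mode == "phenotype":
        return _phenotype_null(
            matrix, group_a, group_b, gene_set, n_permutations, rng, metric, weight
        )
    raise ValueError(f"unknown permutation mode {mode!r}")


def _es_only(metrics_abs_w: np.ndarray, is_hit: np.ndarray) -> float:
    """ES for precomputed |r|^p weights and a hit mask (no running sum kept)."""
    n = is_hit.size
    n_hit = int(is_hit.sum())
    hit_w = np.where(is_hit, metrics_abs_w, 0.0)
    total = hit_w.sum()
    incr = hit_w / total if total > 0 else is_hit / n_hit
    steps = np.where(is_hit, incr, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _geneset_null(
    ranked: RankedList, size: int, B: int, rng: np.random.Generator, weight: float
) -> np.ndarray:
    n = len(ranked)
    w = np.abs(ranked.metrics) ** weight
    out = np.empty(B)
    for b in range(B):
        hit = np.zeros(n, dtype=bool)
        hit[rng.choice(n, size=size, replace=False)] = True
        out[b] = _es_only(w, hit)
    return out


def _phenotype_null(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    gene_set,
    B: int,
    rng: np.random.Generator,
    metric: str,
    weight: float,
) -> np.ndarray:
    cols_a = matrix.columns_of(group_a)
    cols_b = matrix.columns_of(group_b)
    if cols_a.size < 2 or cols_b.size < 2:
        raise DesignError("phenotype permutation needs ≥ 2 replicates per group")
    pooled = np.concatenate([cols_a, cols_b])
    members = set(gene_set)
    from math import comb

    n_distinct = comb(pooled.size, cols_a.size)
    if n_distinct <= B:
        from itertools import combinations

        splits = [np.array(c) for c in combinations(pooled, cols_a.size)]
    else:
        splits = [rng.permutation(pooled)[: cols_a.size] for _ in range(B)]
    out = []
    for split_a in splits:
        set_a = set(split_a.tolist())
        split_b = np.array([c for c in pooled if c not in set_a])
        ranked = _rank_from_columns(matrix, split_a, split_b, metric)
        hit = np.array([g in members for g in ranked.gene_ids], dtype=bool)
        if not hit.any() or hit.all():
            continue
        out.append(_es_only(np.abs(ranked.metrics) ** weight, hit))
    return np.asarray(out)


def _rank_from_columns(
    matrix: ExpressionMatrix, cols_a: np.ndarray, cols_b: np.ndarray, metric: str
) -> RankedList:
    a = matrix.values[:, cols_a]
    b = matrix.values[:, cols_b]
    if metric == "signal2noise":
        r = (a.mean(axis=1) - b.mean(axis=1)) / (_floored_sd(a) + _floored_sd(b))
    else:
        r = a.mean(axis=1) - b.mean(axis=1)
    order = sorted(range(len(r)), key=lambda i: (-r[i], matrix.gene_ids[i]))
    return RankedList(
        gene_ids=[matrix.gene_ids[i] for i in order],
        metrics=np.asarray([r[i] for i in order], dtype=float),
        group_a="perm_a",
        group_b="perm_b",
    )


def nominal_p_value(es: float, null_es: np.ndarray) -> float:
    """One-sided permutation p on the matching sign side of the null."""
    if es == 0:
        return 1.0
    same_side = null_es > 0 if es > 0 else null_es < 0
    null = null_es[same_side]
    return float((1 + int((np.abs(null) >= abs(es)).sum())) / (1 + null.size))


def nes_and_fdr(results: list[GseaResult]) -> list[GseaResult]:
    """Fill NES (ES over mean same-sign null), BH-adjusted p, significance."""
    for r in results:
        if r.null_es is None:
            raise ValueError(f"set {r.set_name!r} has no null sample")
        if r.nominal_p is None:
            r.nominal_p = nominal_p_value(r.es, r.null_es)
        if r.es > 0:
            pos = r.null_es[r.null_es > 0]
            r.nes = float(r.es / pos.mean()) if pos.size else None
        elif r.es < 0:
            neg = r.null_es[r.null_es < 0]
            r.nes = float(r.es / abs(neg.mean())) if neg.size else None
        else:
            r.nes = 0.0
        if r.nes is None:
            logger.warning("set %s: one-sided null empty, NES undefined", r.set_name)
    adj = bh_adjust([r.nominal_p for r in results])
    for r, q in zip(results, adj):
        r.adjusted_p = float(q)
        r.significant = q < 0.05
    return results


def run_gsea(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    group_a: str,
    group_b: str,
    n_permutations: int = 1000,
    mode: str = "auto",
    seed: int | None = 0,
    metric: str = "signal2noise",
    weight: float = 1.0,
) -> list[GseaResult]:
    """Score every set in ``collection`` for the given contrast.

    ``mode='auto'`` picks phenotype permutation when both groups have ≥ 7
    replicates and geneset permutation otherwise.
    """
    if mode == "auto":
        big = min(matrix.design.replicates(group_a), matrix.design.replicates(group_b)) >= 7
        mode = "phenotype" if big else "geneset"
    ranked = rank_genes(matrix, group_a, group_b, metric)
    universe = set(ranked.gene_ids)
    results: list[GseaResult] = []
    for i, name in enumerate(collection.names()):
        genes = [g for g in collection.genes(name) if g in universe]
        if not genes:
            logger.warning("set %s does not intersect the matrix; skipped", name)
            continue
        es, running, peak = enrichment_score(ranked, genes, weight)
        le = leading_edge(ranked, genes, es, peak)
        null = permutation_null(
            matrix, group_a, group_b, genes, n_permutations, mode,
            seed=None if seed is None else seed + i,
            metric=metric, weight=weight,
        )
        results.append(
            GseaResult(
                set_name=name, es=es, peak_index=peak, running_sum=running,
                leading_edge=le, null_es=null,
            )
        )
    return nes_and_fdr(results)


def key_gene_screen(
    genes, lfc_mild: dict[str, float], lfc_severe: dict[str, float],
    loose: float = 0.7, tight: float = 1.0,
) -> list[KeyGeneScreenResult]:
    """Two-contrast absolute fold-change screen over leading-edge genes.

    A gene passes when (|LFC_mild| > 0.7 and |LFC_severe| > 1) or
    (|LFC_mild| > 1 and |LFC_severe| > 0.7); results are sorted by the
    larger of the two absolute LFCs, descending.  Genes missing an LFC in
    either contrast are skipped with a warning.
    """
    out: list[KeyGeneScreenResult] = []
    for g in genes:
        if g not in lfc_mild or g not in lfc_severe:
            logger.warning("gene %s lacks an LFC in one contrast; skipped", g)
            continue
        a, b = abs(lfc_mild[g]), abs(lfc_severe[g])
        passes = (a > loose and b > tight) or (a > tight and b > loose)
        out.append(KeyGeneScreenResult(g, float(lfc_mild[g]), float(lfc_severe[g]), passes))
    out.sort(key=lambda r: -max(abs(r.lfc_mild), abs(r.lfc_severe)))
    return out
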