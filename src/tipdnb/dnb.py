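"""Dynamic network biomarker (DNB) analysis and tipping-point detection.

A system approaching a critical transition betrays itself before the shift:
a group of genes starts fluctuating strongly (high within-condition standard
deviation), moves in lockstep (high mutual |PCC|), and decouples from the
rest of the transcriptome (low |PCC| to other genes).  Once the transition
has happened the signature disappears again.  For each non-reference
condition this module

1. selects high-deviation genes (within-group SD at least ``sd_fold`` times
   the reference-group SD),
2. builds their Pearson correlation matrix and groups them by average-
   linkage clustering on the distance 1 − |PCC|, cut at 1 − threshold
   (default threshold 0.9),
3. scores each candidate cluster with the composite index

       CI = mean_SD · PCC1 / PCC0

   where mean_SD is the mean within-group SD of cluster genes, PCC1 the mean
   absolute intra-cluster correlation, and PCC0 the mean absolute
   correlation between cluster genes and the other selected genes.

The condition whose best cluster attains the maximal CI is the predicted
tipping point ("pre-disease" state).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_core import DesignError, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_SD_FOLD = 2.0
DEFAULT_PCC_THRESHOLD = 0.9
DEFAULT_MIN_CLUSTER = 5


@dataclass
class DnbClusterStats:
    """Composite-index ingredients for one candidate cluster in one group."""

    group: str
    genes: list[str]
    mean_sd: float
    pcc1: float
    pcc0: float | None
    ci: float | None


@dataclass
class DnbGroupResult:
    group: str
    selected: pd.DataFrame                      # gene_id, sd_group, sd_reference, flagged
    clusters: list[DnbClusterStats] = field(default_factory=list)
    best_cluster: DnbClusterStats | None = None
    edges: pd.DataFrame | None = None           # gene_a, gene_b, pcc (|PCC| ≥ threshold)

    @property
    def selected_gene_number(self) -> int:
        return int(len(self.selected))

    @property
    def ci(self) -> float | None:
        return None if self.best_cluster is None else self.best_cluster.ci


def select_high_sd_genes(
    matrix: ExpressionMatrix,
    group: str,
    reference: str | None = None,
    sd_fold: float = DEFAULT_SD_FOLD,
    min_expressed_fraction: float = 0.5,
    method: str = "fold",
    use_reference: bool = True,
    ftest_alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes with "significantly high deviation" in ``group``.

    The default rule selects genes whose within-``group`` SD is ≥
    ``sd_fold`` × reference SD.  ``method='ftest'`` instead tests the
    variance ratio per gene (one-sided F, BH-adjusted, select at
    ``ftest_alpha`` with ratio > 1).  ``use_reference=False`` drops the
    reference comparison and selects genes whose group SD is at least
    ``sd_fold`` times the median group SD across genes.

    Counts-scale matrices first drop genes that are zero in at least
    ``min_expressed_fraction`` of all samples (no information for a
    correlation analysis); log-scale matrices skip that filter.  Genes with
    zero reference SD are selected whenever their group SD is positive and
    marked ``flagged`` (the fold rule is undefined for them).
    """
    reference = matrix.design.reference if reference is None else reference
    a = matrix.group_values(group)
    b = matrix.group_values(reference)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DesignError("both groups need ≥ 2 replicates to estimate SDs")
    keep = np.ones(matrix.n_genes, dtype=bool)
    if matrix.scale == "counts":
        zero_frac = (matrix.values == 0).mean(axis=1)
        keep = zero_frac < min_expressed_fraction
    sd_g = a.std(axis=1, ddof=1)
    sd_r = b.std(axis=1, ddof=1)
    flagged = np.zeros(matrix.n_genes, dtype=bool)
    if not use_reference:
        baseline = np.median(sd_g[keep]) if keep.any() else 0.0
        sel = keep & (sd_g >= sd_fold * baseline) & (sd_g > 0)
    elif method == "fold":
        regular = keep & (sd_r > 0) & (sd_g >= sd_fold * sd_r)
        flagged = keep & (sd_r == 0) & (sd_g > 0)
        sel = regular | flagged
    elif method == "ftest":
        from scipy import stats as _stats

        from .deg import bh_adjust

        dfg, dfr = a.shape[1] - 1, b.shape[1] - 1
        ok = keep & (sd_r > 0)
        ratio = np.full(matrix.n_genes, np.nan)
        ratio[ok] = (sd_g[ok] / sd_r[ok]) ** 2
        p = np.ones(matrix.n_genes)
        p[ok] = _stats.f.sf(ratio[ok], dfg, dfr)
        fdr = np.ones(matrix.n_genes)
        fdr[keep] = bh_adjust(p[keep])
        flagged = keep & (sd_r == 0) & (sd_g > 0)
        sel = (ok & (fdr < ftest_alpha) & (ratio > 1)) | flagged
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return pd.DataFrame(
        {
            "gene_id": [g for g, s in zip(matrix.gene_ids, sel) if s],
            "sd_group": sd_g[sel],
            "sd_reference": sd_r[sel],
            "flagged": flagged[sel],
        }
    )


def pcc_matrix(matrix: ExpressionMatrix, group: str, genes: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations of ``genes`` across the group replicates.

    Symmetric, unit diagonal; pairs involving a zero-variance gene get 0.
    """
    if len(genes) < 2:
        raise ValueError("need ≥ 2 genes for a correlation matrix")
    cols = matrix.columns_of(group)
    if cols.size < 2:
        raise DesignError("need ≥ 2 replicates for correlations")
    if cols.size == 2:
        logger.warning("only 2 replicates in %s: correlations are degenerate (±1)", group)
    idx = matrix.gene_index()
    rows = np.array([idx[g] for g in genes])
    x = matrix.values[np.ix_(rows, cols)]
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance genes in %s get correlation 0", int(flat.sum()), group)
        c[flat, :] = 0.0
        c[:, flat] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return pd.DataFrame(c, index=genes, columns=genes)


def cluster_by_correlation(
    pcc: pd.DataFrame,
    threshold: float = DEFAULT_PCC_THRESHOLD,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER,
    method: str = "average",
) -> tuple[list[list[str]], list[list[str]]]:
    """Group genes whose mutual |PCC| clears ``threshold``.

    The default is average-linkage clustering on the distance d = 1 − |PCC|
    with the tree cut at 1 − threshold; ``method='components'`` instead
    takes the connected components of the |PCC| ≥ threshold graph.  The two
    agree on well-separated correlation blocks.  Returns (candidate
    clusters with size ≥ min_cluster_size, smaller groups), candidates
    ordered largest first (ties by first gene id).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    genes = list(pcc.index)
    if method == "average":
        d = 1.0 - np.abs(pcc.to_numpy())
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry
        z = linkage(squareform(d, checks=False), method="average")
        labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    elif method == "components":
        from scipy.sparse.csgraph import connected_components

        adj = np.abs(pcc.to_numpy()) >= threshold
        np.fill_diagonal(adj, False)
        _, labels = connected_components(adj, directed=False)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    groups: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        groups.setdefault(int(lab), []).append(g)
    clusters = sorted(groups.values(), key=lambda c: (-len(c), sorted(c)[0]))
    big = [sorted(c) for c in clusters if len(c) >= min_cluster_size]
    small = [sorted(c) for c in clusters if len(c) < min_cluster_size]
    return big, small


def composite_index(mean_sd: float, pcc1: float, pcc0: float, eps: float = 1e-6) -> float:
    """CI = mean_SD · pcc1 / pcc0.

    A near-zero pcc0 denotes a cluster with no measurable coupling to the
    rest of the selected genes; its CI is treated as undefined rather than
    infinite.
    """
    if mean_sd < 0:
        raise ValueError("mean_sd must be ≥ 0")
    if not (0 <= pcc1 <= 1 and 0 <= pcc0 <= 1):
        raise ValueError("pcc1 and pcc0 must lie in [0, 1]")
    if pcc0 < eps:
        raise ValueError("pcc0 below eps: composite index undefined for an isolated cluster")
    return mean_sd * pcc1 / pcc0


def _cluster_stats(
    group: str,
    cluster: list[str],
    all_selected: list[str],
    pcc: pd.DataFrame,
    sd_by_gene: dict[str, float],
    eps: float = 1e-6,
    outside_corr: np.ndarray | None = None,
) -> DnbClusterStats:
    """Stats for one cluster; ``outside_corr`` (cluster × outside |PCC|)
    overrides the default outside universe of the other selected genes."""
    c = np.abs(pcc.loc[cluster, cluster].to_numpy())
    iu = np.triu_indices(len(cluster), k=1)
    pcc1 = float(c[iu].mean())
    mean_sd = float(np.mean([sd_by_gene[g] for g in cluster]))
    if outside_corr is not None:
        if outside_corr.size == 0:
            logger.warning("no outside genes in %s: pcc0 undefined", group)
            return DnbClusterStats(group, cluster, mean_sd, pcc1, None, None)
        pcc0 = float(np.abs(outside_corr).mean())
    else:
        outside = [g for g in all_selected if g not in set(cluster)]
        if not outside:
            logger.warning("cluster covers all selected genes in %s: pcc0 undefined", group)
            return DnbClusterStats(group, cluster, mean_sd, pcc1, None, None)
        pcc0 = float(np.abs(pcc.loc[cluster, outside].to_numpy()).mean())
    try:
        ci = composite_index(mean_sd, pcc1, pcc0, eps)
    except ValueError:
        ci = None
    return DnbClusterStats(group, cluster, mean_sd, pcc1, pcc0, ci)


def _corr_cluster_vs_rest(
    matrix: ExpressionMatrix, group: str, cluster: list[str], exclude: set[str]
) -> np.ndarray:
    """|PCC| of cluster genes against every other (expressed) gene in the
    group — the genome-wide outside universe."""
    cols = matrix.columns_of(group)
    idx = matrix.gene_index()
    rows_c = np.array([idx[g] for g in cluster])
    others = [g for g in matrix.gene_ids if g not in exclude]
    rows_o = np.array([idx[g] for g in others])
    xc = matrix.values[np.ix_(rows_c, cols)]
    xo = matrix.values[np.ix_(rows_o, cols)]
    xc = xc - xc.mean(axis=1, keepdims=True)
    xo = xo - xo.mean(axis=1, keepdims=True)
    sc = np.sqrt((xc**2).sum(axis=1))
    so = np.sqrt((xo**2).sum(axis=1))
    keep = so > 0  # zero-variance outside genes carry no correlation
    if sc.min() == 0:
        sc[sc == 0] = np.inf  # degenerate cluster gene: correlation 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (xc @ xo[keep].T) / np.outer(sc, so[keep])
    return np.clip(np.nan_to_num(c), -1.0, 1.0)


def evaluate_group(
    matrix: ExpressionMatrix,
    group: str,
    reference: str | None = None,
    sd_fold: float = DEFAULT_SD_FOLD,
    pcc_threshold: float = DEFAULT_PCC_THRESHOLD,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER,
    min_expressed_fraction: float = 0.5,
    selection_method: str = "fold",
    use_reference: bool = True,
    cluster_method: str = "average",
    pcc0_universe: str = "selected",
) -> DnbGroupResult:
    """Full DNB evaluation of one group: select → correlate → cluster → CI.

    ``best_cluster`` is the candidate with maximal CI (ties broken toward
    the larger cluster, then the lexicographically first gene).  A group
    with no candidate cluster, or only clusters with undefined CI, returns
    ``best_cluster=None`` rather than raising.  ``pcc0_universe`` chooses
    the outside genes for PCC₀: the other selected genes (default — the
    per-group analysis universe is the selected set) or ``'all'`` genes in
    the matrix.
    """
    if pcc0_universe not in ("selected", "all"):
        raise ValueError("pcc0_universe must be 'selected' or 'all'")
    selected = select_high_sd_genes(
        matrix, group, reference, sd_fold, min_expressed_fraction,
        method=selection_method, use_reference=use_reference,
    )
    result = DnbGroupResult(group=group, selected=selected)
    if len(selected) < 2:
        return result
    genes = selected["gene_id"].tolist()
    pcc = pcc_matrix(matrix, group, genes)
    big, _small = cluster_by_correlation(pcc, pcc_threshold, min_cluster_size, cluster_method)
    sd_by_gene = dict(zip(selected["gene_id"], selected["sd_group"]))
    result.clusters = [
        _cluster_stats(
            group, c, genes, pcc, sd_by_gene,
            outside_corr=(
                _corr_cluster_vs_rest(matrix, group, c, set(c))
                if pcc0_universe == "all" else None
            ),
        )
        for c in big
    ]
    scored = [c for c in result.clusters if c.ci is not None]
    if scored:
        result.best_cluster = max(
            scored, key=lambda c: (c.ci, len(c.genes), _neg_lex(c.genes))
        )
    # edge list for network export
    arr = pcc.to_numpy()
    ii, jj = np.where(np.triu(np.abs(arr) >= pcc_threshold, k=1))
    result.edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in ii],
            "gene_b": [genes[j] for j in jj],
            "pcc": arr[ii, jj],
        }
    )
    return result


class _neg_lex(str):
    """Sort helper: reverses lexicographic order of the first gene id so that
    max() prefers the lexicographically first gene on full ties."""

    def __new__(cls, genes):
        return super().__new__(cls, sorted(genes)[0])

    def __lt__(self, other):  # inverted
        return str(self) > str(other)

    def __gt__(self, other):
        return str(self) < str(other)


def tipping_point(results: list[DnbGroupResult]) -> tuple[str | None, pd.DataFrame]:
    """Arg-max CI over groups, plus the full CI-vs-group table.

    Returns (group label or None, table).  A single defined CI still wins
    but with a low-confidence warning; all-undefined means no transition was
    detected.
    """
    rows = []
    for r in results:
        best = r.best_cluster
        rows.append(
            {
                "group": r.group,
                "selected_gene_number": r.selected_gene_number,
                "mean_SD": None if best is None else best.mean_sd,
                "pcc1": None if best is None else best.pcc1,
                "pcc0": None if best is None else best.pcc0,
                "CI": r.ci,
            }
        )
    table = pd.DataFrame(rows)
    defined = table.dropna(subset=["CI"])
    if defined.empty:
        logger.warning("no group has a defined CI: no transition detected")
        return None, table
    if len(defined) == 1:
        logger.warning("only one group has a defined CI: low-confidence tipping point")
    winner = defined.loc[defined["CI"].idxmax(), "group"]
    return str(winner), table


def run_dnb(
    matrix: ExpressionMatrix,
    sd_fold: float = DEFAULT_SD_FOLD,
    pcc_threshold: float = DEFAULT_PCC_THRESHOLD,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER,
    min_expressed_fraction: float = 0.5,
    selection_method: str = "fold",
    use_reference: bool = True,
    cluster_method: str = "average",
    pcc0_universe: str = "selected",
) -> tuple[str | None, pd.DataFrame, list[DnbGroupResult]]:
    """Evaluate every non-reference group and locate the tipping point."""
    results = [
        evaluate_group(
            matrix, g, None, sd_fold, pcc_threshold, min_cluster_size,
            min_expressed_fraction, selection_method, use_reference,
            cluster_method, pcc0_universe,
        )
        for g in matrix.design.group_order[1:]
    ]
    winner, table = tipping_point(results)
    return winner, table, results
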