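"""Per-group differential-expression screen against the reference condition.

The screen is deliberately simple and transparent: log2-CPM normalisation, a
two-sided Welch (unequal-variance) t-test per gene between each treatment
group and the reference, Benjamini–Hochberg adjustment across genes within
each contrast, and the conjunctive threshold rule

    DEG  ⇔  FDR < 0.01  AND  |log2FC| > 1.2        (strict inequalities)

with both thresholds configurable.  The negative-binomial machinery of
count-based DE packages is intentionally not reproduced here; the threshold
rule is the contract, the test behind the p-values is documented and
swappable.  Also hosts the qPCR 2^−ΔΔCt fold change and the top-N DEG
overlap proportions used to compare contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import DesignError, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.01
DEFAULT_LFC = 1.2


class DataError(ValueError):
    pass


def normalize_log_cpm(matrix: ExpressionMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million: ``log2((c + p) / (libsize + 2p) * 1e6)``.

    Refuses a matrix that is already on the log scale.
    """
    if matrix.scale != "counts":
        raise DataError("matrix is already log-scale; refusing to normalize twice")
    if pseudocount <= 0:
        raise DataError("pseudocount must be > 0")
    lib = matrix.values.sum(axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise DataError(f"zero library size in sample {matrix.sample_ids[zero[0]]!r}")
    cpm = (matrix.values + pseudocount) / (lib + 2 * pseudocount)[None, :] * 1e6
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=np.log2(cpm),
        design=matrix.design,
        scale="log2",
    )


def de_test(matrix: ExpressionMatrix, group: str, reference: str | None = None) -> pd.DataFrame:
    """Per-gene Welch t-test of ``group`` vs ``reference`` on a log2 matrix.

    Returns a DataFrame with columns gene_id, log2FC, p_value in matrix gene
    order.  log2FC is mean(group) − mean(reference).  Genes with zero
    variance in both groups get p = 1 when the means are equal and p = 0
    otherwise (the test is degenerate there; the fold change still orders
    them correctly).
    """
    if matrix.scale != "log2":
        raise DataError("de_test expects a log2-scale matrix (run normalize_log_cpm first)")
    reference = matrix.design.reference if reference is None else reference
    a = matrix.group_values(group)
    b = matrix.group_values(reference)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DesignError("both groups need ≥ 2 replicates for the Welch test")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    both_flat = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[both_flat & (log2fc == 0)] = 1.0
    p[both_flat & (log2fc != 0)] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    return pd.DataFrame({"gene_id": matrix.gene_ids, "log2FC": log2fc, "p_value": p})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
) -> pd.DataFrame:
    """Apply the DEG rule to a (gene_id, log2FC, p_value[, fdr]) table.

    Adds ``fdr`` (BH across the table, unless already present) and
    ``is_deg``; both inequalities are strict, so boundary genes
    (fdr == threshold or |log2FC| == threshold) are not called.
    """
    out = table.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["is_deg"] = (out["fdr"] < fdr_threshold) & (out["log2FC"].abs() > lfc_threshold)
    return out


def deg_summary(table: pd.DataFrame) -> dict[str, int]:
    deg = table[table["is_deg"]]
    return {
        "n_deg": int(len(deg)),
        "n_up": int((deg["log2FC"] > 0).sum()),
        "n_down": int((deg["log2FC"] < 0).sum()),
    }


def run_deg_screen(
    matrix: ExpressionMatrix,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
    pseudocount: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Full screen: every non-reference group vs the reference.

    Counts-scale input is log2-CPM normalised first; log2 input is used as is.
    Returns {group: DEG table}.
    """
    if matrix.scale == "counts":
        matrix = normalize_log_cpm(matrix, pseudocount)
    reference = matrix.design.reference
    return {
        group: call_degs(de_test(matrix, group, reference), fdr_threshold, lfc_threshold)
        for group in matrix.design.group_order[1:]
    }


def _top_n_genes(table: pd.DataFrame, n: int) -> list[str]:
    """Top ``n`` DEGs by |log2FC|; ties by smaller fdr, then gene id."""
    deg = table[table["is_deg"]].copy()
    deg["_abs"] = deg["log2FC"].abs()
    deg = deg.sort_values(["_abs", "fdr", "gene_id"], ascending=[False, True, True])
    return deg["gene_id"].head(n).tolist()


def top_n_overlap(
    deg_tables: dict[str, pd.DataFrame], groups: list[str] | None = None, n: int = 50
) -> dict[str, float]:
    """Overlap of the per-group top-N DEG lists (by |log2FC|).

    Returns both readings of the proportion: ``over_n`` divides the
    intersection by the list length (the smallest actual list when a group
    has fewer than ``n`` DEGs, with a warning) and ``over_union`` divides by
    the union of the lists.
    """
    groups = list(deg_tables) if groups is None else groups
    if len(groups) < 2:
        raise ValueError("need ≥ 2 groups to overlap")
    lists: dict[str, list[str]] = {}
    for g in groups:
        top = _top_n_genes(deg_tables[g], n)
        if len(top) < n:
            logger.warning("group %s has only %d DEGs (< top %d requested)", g, len(top), n)
        lists[g] = top
    inter = set(lists[groups[0]])
    union = set(lists[groups[0]])
    for g in groups[1:]:
        inter &= set(lists[g])
        union |= set(lists[g])
    denom_n = min(len(v) for v in lists.values())
    return {
        "n_intersection": float(len(inter)),
        "over_n": len(inter) / denom_n if denom_n else 0.0,
        "over_union": len(inter) / len(union) if union else 0.0,
    }


def pairwise_top_n_overlap(
    deg_tables: dict[str, pd.DataFrame], n: int = 50
) -> pd.DataFrame:
    """``top_n_overlap`` for every pair of groups, as a tidy table."""
    rows = []
    for a, b in combinations(deg_tables, 2):
        res = top_n_overlap(deg_tables, [a, b], n)
        rows.append({"group_a": a, "group_b": b, **res})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR relative quantification


@dataclass
class DdctInput:
    """Ct tables for one target gene and the reference (housekeeping) gene.

    ``target_ct`` and ``reference_ct`` map group → per-replicate Ct values;
    the reference condition defaults to the first group of ``group_order``.
    """

    target_ct: dict[str, list[float]]
    reference_ct: dict[str, list[float]]
    reference_gene: str = "Ppia"
    reference_group: str | None = None
    group_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.group_order:
            self.group_order = tuple(self.target_ct)
        if self.reference_group is None:
            self.reference_group = self.group_order[0]
        if self.reference_group not in self.target_ct:
            raise ValueError(f"reference group {self.reference_group!r} missing from target Ct")
        if set(self.target_ct) != set(self.reference_ct):
            raise ValueError("target and reference-gene Ct tables must cover the same groups")
        for table in (self.target_ct, self.reference_ct):
            for g, vals in table.items():
                arr = np.asarray(vals, dtype=float)
                if arr.size == 0 or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                    raise ValueError(f"Ct values for group {g!r} must be finite and > 0")


def ddct_fold_change(data: DdctInput) -> dict[str, float]:
    """Relative expression by the 2^−ΔΔCt method.

    ΔCt = mean Ct(target) − mean Ct(reference gene) per group;
    ΔΔCt = ΔCt(group) − ΔCt(reference group); fold = 2^−ΔΔCt.
    The reference group's fold change is exactly 1.
    """
    dct = {
        g: float(np.mean(data.target_ct[g]) - np.mean(data.reference_ct[g]))
        for g in data.group_order
    }
    ref = dct[data.reference_group]
    folds = {g: float(2.0 ** -(d - ref)) for g, d in dct.items()}
    folds[data.reference_group] = 1.0
    return folds
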