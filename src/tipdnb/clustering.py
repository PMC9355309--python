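"""Soft clustering of standardized temporal expression profiles.

Each gene is reduced to its vector of group means across the ordered
conditions and z-scored, so clustering sees trend shape rather than
expression level — the "discrete time points" view of a time course.  The
partition is fuzzy c-means on Euclidean distance, the algorithm behind
Mfuzz-style time-course clustering, implemented here directly so that the
objective, initialisation and tie rules are fully specified:

    J(U, V) = Σ_i Σ_j u_ij^m ||x_i − v_j||²,   Σ_j u_ij = 1

alternating the closed-form membership update
``u_ij ∝ (Σ_k (d_ij/d_ik)^{2/(m−1)})^{−1}`` with the u^m-weighted centroid
update until centroids move less than ``tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .io_core import DesignError, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Standardized gene × group profile matrix (per-row mean 0, SD 1)."""

    gene_ids: list[str]
    group_order: tuple[str, ...]
    values: np.ndarray
    dropped: list[str]  # zero-variance genes excluded from clustering


@dataclass
class FuzzyClustering:
    c: int
    m: float
    gene_ids: list[str]
    group_order: tuple[str, ...]
    centroids: np.ndarray        # c × n_groups
    membership: np.ndarray       # n_genes × c, rows sum to 1
    objective: float
    objective_history: list[float]
    n_iter: int
    converged: bool


def standardize_profiles(matrix: ExpressionMatrix) -> ProfileMatrix:
    """Group means per gene, z-scored across groups (population SD).

    Genes constant across group means carry no trend information and are
    dropped (listed in ``dropped``).
    """
    if matrix.scale != "log2":
        raise DesignError("profiles are computed on a log2-scale matrix")
    if len(matrix.design.group_order) < 2:
        raise DesignError("need ≥ 2 groups for temporal profiles")
    groups = matrix.design.group_order
    means = np.column_stack([matrix.group_values(g).mean(axis=1) for g in groups])
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)  # population SD
    keep = sd[:, 0] > 0
    dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if dropped:
        logger.info("dropped %d zero-variance genes from profiles", len(dropped))
    z = (means[keep] - mu[keep]) / sd[keep]
    return ProfileMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        group_order=tuple(groups),
        values=z,
        dropped=dropped,
    )


def _memberships(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Optimal memberships for fixed centroids (exact-hit rows get indicators)."""
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 0
    u = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = d2 ** -power
    inv[~np.isfinite(inv)] = 0.0
    any_zero = zero.any(axis=1)
    u[~any_zero] = inv[~any_zero] / inv[~any_zero].sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = 0.0
        rows, cols = np.nonzero(zero)
        first = {}
        for r, cidx in zip(rows, cols):
            first.setdefault(r, cidx)
        for r, cidx in first.items():
            u[r, cidx] = 1.0
    return u


def _objective(x: np.ndarray, centroids: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float(((u ** m) * d2).sum())


def fuzzy_cmeans(
    profiles: ProfileMatrix,
    c: int = 8,
    m: float = 1.25,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = 0,
) -> FuzzyClustering:
    """Fuzzy c-means over profile rows, k-means++-seeded from ``seed``.

    The alternating updates make the objective non-increasing; it is tracked
    per iteration in ``objective_history``.  Non-convergence within
    ``max_iter`` returns a result with ``converged=False`` and a warning.
    """
    x = profiles.values
    n = x.shape[0]
    if c < 2:
        raise ValueError("c must be ≥ 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if c > n:
        raise ValueError(f"c = {c} exceeds the number of profiles ({n})")
    if np.unique(x, axis=0).shape[0] < c:
        raise ValueError("need ≥ c distinct profiles")
    rng_state = np.random.RandomState(seed if seed is not None else None)
    centroids, _ = kmeans_plusplus(x, n_clusters=c, random_state=rng_state)
    history: list[float] = []
    converged = False
    u = _memberships(x, centroids, m)
    it = 0
    for it in range(1, max_iter + 1):
        um = u ** m
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        u = _memberships(x, new_centroids, m)
        history.append(_objective(x, new_centroids, u, m))
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    if not converged:
        logger.warning("fuzzy c-means did not converge in %d iterations", max_iter)
    return FuzzyClustering(
        c=c,
        m=m,
        gene_ids=list(profiles.gene_ids),
        group_order=profiles.group_order,
        centroids=centroids,
        membership=u,
        objective=history[-1],
        objective_history=history,
        n_iter=it,
        converged=converged,
    )


def estimate_fuzzifier(profiles: ProfileMatrix) -> float:
    """Data-size-based fuzzifier heuristic (Schwämmle–Jensen rule).

    For N profiles over D conditions:
        m = 1 + (1418/N + 22.05)·D^(−2)
              + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134)

    Offered as an option; the default fuzzifier stays fixed so results are
    a pure function of the configuration.
    """
    n, d = profiles.values.shape
    if n < 2 or d < 2:
        raise ValueError("need ≥ 2 profiles over ≥ 2 conditions")
    return float(
        1.0
        + (1418.0 / n + 22.05) * d**-2.0
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


def assign_clusters(fc: FuzzyClustering, min_membership: float = 0.0) -> dict[str, int | None]:
    """Hard assignment by arg-max membership (ties → lowest cluster index).

    Genes whose maximal membership falls below ``min_membership`` map to
    ``None`` ("unassigned").
    """
    out: dict[str, int | None] = {}
    for gid, row in zip(fc.gene_ids, fc.membership):
        j = int(np.argmax(row))  # argmax returns the first (lowest) index on ties
        out[gid] = j if row[j] >= min_membership else None
    return out


def label_cluster_shape(centroid, group_order=None) -> str:
    """Classify a centroid's trend over the ordered groups.

    mono_up / mono_down tolerate counter-movements up to ε = 5% of the
    centroid range; up_down requires a single +→− sign change (interior
    peak); anything else is "other".
    """
    v = np.asarray(centroid, dtype=float)
    if v.size < 3:
        raise ValueError("need a centroid over ≥ 3 ordered groups")
    eps = 0.05 * float(v.max() - v.min())
    d = np.diff(v)
    if np.all(d >= -eps):
        return "mono_up"
    if np.all(d <= eps):
        return "mono_down"
    signs = [0 if abs(x) <= eps else (1 if x > 0 else -1) for x in d]
    signs = [s for s in signs if s != 0]
    if signs and signs[0] == 1 and signs[-1] == -1:
        flips = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
        if flips == 1:
            return "up_down"
    return "other"
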