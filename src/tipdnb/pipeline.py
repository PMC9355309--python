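"""End-to-end orchestration: one validated config, four stages, one manifest.

Each stage writes only plain-text intermediates (TSV/JSON), so any stage can
be re-run in isolation from the files of the previous one, and a manifest
records every parameter, seed, input checksum and stage wall-time of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, deg, dnb, gsea
from .io_core import ExpressionMatrix, read_expression_tsv, read_gmt

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class DegParams:
    enabled: bool = True
    fdr_threshold: float = 0.01
    lfc_threshold: float = 1.2
    pseudocount: float = 0.5
    top_n: int = 50


@dataclass
class ClusterParams:
    enabled: bool = True
    c: int = 8
    m: float = 1.25
    estimate_m: bool = False     # data-driven fuzzifier heuristic instead of m
    tol: float = 1e-6
    max_iter: int = 500
    min_membership: float = 0.0
    genes: str | None = None     # optional file restricting clustering to listed genes


@dataclass
class GseaParams:
    enabled: bool = True
    contrast: str | None = None     # "GROUPA:GROUPB"; default last:first-treatment
    permutations: int = 1000
    mode: str = "auto"
    metric: str = "signal2noise"
    weight: float = 1.0


@dataclass
class DnbParams:
    enabled: bool = True
    sd_fold: float = 2.0
    pcc_threshold: float = 0.9
    min_cluster_size: int = 5
    min_expressed_fraction: float = 0.5
    selection_method: str = "fold"       # or "ftest"
    use_reference: bool = True           # False: absolute-SD selection
    cluster_method: str = "average"      # or "components"
    pcc0_universe: str = "selected"      # or "all"


@dataclass
class RunConfig:
    matrix: str
    design: str
    out_dir: str
    gene_sets: str | None = None
    matrix_scale: str = "counts"
    seed: int = 0
    log_level: str = "info"
    deg: DegParams = field(default_factory=DegParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    gsea: GseaParams = field(default_factory=GseaParams)
    dnb: DnbParams = field(default_factory=DnbParams)


_SECTIONS = {"deg": DegParams, "cluster": ClusterParams, "gsea": GseaParams, "dnb": DnbParams}
_RANGES = {
    "deg.fdr_threshold": (0.0, 1.0),
    "deg.lfc_threshold": (0.0, float("inf")),
    "deg.pseudocount": (1e-12, float("inf")),
    "cluster.m": (1.0 + 1e-12, float("inf")),
    "gsea.weight": (0.0, float("inf")),
    "dnb.sd_fold": (0.0, float("inf")),
    "dnb.pcc_threshold": (0.0, 1.0),
    "dnb.min_expressed_fraction": (0.0, 1.0),
}
_OPEN_INTERVALS = {"dnb.pcc_threshold"}  # strictly inside


def config_from_dict(raw: dict) -> RunConfig:
    """Build a typed, range-checked RunConfig; unknown keys are hard errors."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    raw = dict(raw)
    top_fields = {f for f in RunConfig.__dataclass_fields__}
    errors: list[str] = []
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping of parameters")
                continue
            sect_fields = set(cls.__dataclass_fields__)
            sect_kwargs = {}
            for k, v in value.items():
                if k not in sect_fields:
                    errors.append(f"unknown key {key}.{k!r}")
                    continue
                sect_kwargs[k] = v
            kwargs[key] = cls(**sect_kwargs)
        elif key in top_fields:
            kwargs[key] = value
        else:
            errors.append(f"unknown key {key!r}")
    for name in ("matrix", "design", "out_dir"):
        if name not in kwargs:
            errors.append(f"missing required key {name!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    cfg = RunConfig(**kwargs)
    for dotted, (lo, hi) in _RANGES.items():
        sect, attr = dotted.split(".")
        val = getattr(getattr(cfg, sect), attr)
        strict = dotted in _OPEN_INTERVALS
        ok = lo < val < hi if strict else lo <= val <= hi
        if not ok:
            kind = "(%g, %g)" % (lo, hi) if strict else "[%g, %g]" % (lo, hi)
            raise ConfigError(f"{dotted} = {val} must be in {kind}")
    if cfg.matrix_scale not in ("counts", "log2"):
        raise ConfigError("matrix_scale must be 'counts' or 'log2'")
    for dotted, allowed in (
        ("dnb.selection_method", ("fold", "ftest")),
        ("dnb.cluster_method", ("average", "components")),
        ("dnb.pcc0_universe", ("selected", "all")),
        ("gsea.mode", ("auto", "phenotype", "geneset")),
        ("gsea.metric", ("signal2noise", "log2fc")),
    ):
        sect, attr = dotted.split(".")
        val = getattr(getattr(cfg, sect), attr)
        if val not in allowed:
            raise ConfigError(f"{dotted} = {val!r} must be one of {allowed}")
    return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; referenced inputs must exist."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    cfg = config_from_dict(raw or {})
    for name in ("matrix", "design", "gene_sets"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{name} path does not exist: {p}")
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the manifest.

    Returns the manifest dictionary.  Stage outputs land in
    ``out_dir/{deg,clusters,gsea,dnb}``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "tipdnb",
        "version": _pkg_version("tipdnb"),
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "inputs": {
            "matrix": {"path": str(config.matrix), "sha256": _sha256(config.matrix)},
            "design": {"path": str(config.design), "sha256": _sha256(config.design)},
        },
        "parameters": {
            "matrix_scale": config.matrix_scale,
            "deg": asdict(config.deg),
            "cluster": asdict(config.cluster),
            "gsea": asdict(config.gsea),
            "dnb": asdict(config.dnb),
        },
        "stages": {},
    }
    if config.gene_sets:
        manifest["inputs"]["gene_sets"] = {
            "path": str(config.gene_sets),
            "sha256": _sha256(config.gene_sets),
        }

    matrix = read_expression_tsv(config.matrix, config.design, scale=config.matrix_scale)
    log_matrix = (
        deg.normalize_log_cpm(matrix, config.deg.pseudocount)
        if matrix.scale == "counts"
        else matrix
    )

    if config.deg.enabled:
        manifest["stages"]["deg"] = _stage_deg(config, log_matrix, out / "deg")
    else:
        manifest["stages"]["deg"] = {"skipped": True}
    if config.cluster.enabled:
        manifest["stages"]["cluster"] = _stage_cluster(config, log_matrix, out / "clusters")
    else:
        manifest["stages"]["cluster"] = {"skipped": True}
    if config.gsea.enabled and config.gene_sets:
        manifest["stages"]["gsea"] = _stage_gsea(config, log_matrix, out / "gsea")
    else:
        manifest["stages"]["gsea"] = {"skipped": True}
    if config.dnb.enabled:
        manifest["stages"]["dnb"] = _stage_dnb(config, log_matrix, out / "dnb")
    else:
        manifest["stages"]["dnb"] = {"skipped": True}

    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _stage_deg(config: RunConfig, log_matrix: ExpressionMatrix, out: Path) -> dict:
    t0 = time.perf_counter()
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        g: deg.call_degs(
            deg.de_test(log_matrix, g), config.deg.fdr_threshold, config.deg.lfc_threshold
        )
        for g in log_matrix.design.group_order[1:]
    }
    summary = {}
    for g, tbl in tables.items():
        _write_tsv(tbl, out / f"deg_{g}.tsv")
        summary[g] = deg.deg_summary(tbl)
    overlaps = deg.pairwise_top_n_overlap(tables, n=config.deg.top_n)
    _write_tsv(overlaps, out / "top_n_overlap.tsv")
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"seconds": round(time.perf_counter() - t0, 3), "summary": summary}


def _stage_cluster(config: RunConfig, log_matrix: ExpressionMatrix, out: Path) -> dict:
    t0 = time.perf_counter()
    out.mkdir(parents=True, exist_ok=True)
    profiles = clustering.standardize_profiles(log_matrix)
    if config.cluster.genes:
        wanted = {
            line.strip()
            for line in Path(config.cluster.genes).read_text().splitlines()
            if line.strip()
        }
        keep = [i for i, g in enumerate(profiles.gene_ids) if g in wanted]
        profiles = clustering.ProfileMatrix(
            gene_ids=[profiles.gene_ids[i] for i in keep],
            group_order=profiles.group_order,
            values=profiles.values[keep],
            dropped=profiles.dropped,
        )
    m_used = (
        clustering.estimate_fuzzifier(profiles) if config.cluster.estimate_m
        else config.cluster.m
    )
    fc = clustering.fuzzy_cmeans(
        profiles,
        c=config.cluster.c,
        m=m_used,
        tol=config.cluster.tol,
        max_iter=config.cluster.max_iter,
        seed=config.seed,
    )
    mem = pd.DataFrame(
        fc.membership, columns=[f"cluster_{j + 1}" for j in range(fc.c)]
    )
    mem.insert(0, "gene_id", fc.gene_ids)
    _write_tsv(mem, out / "membership.tsv")
    hard = clustering.assign_clusters(fc, config.cluster.min_membership)
    hard_df = pd.DataFrame(
        {
            "gene_id": list(hard),
            "cluster": [
                "unassigned" if v is None else f"cluster_{v + 1}" for v in hard.values()
            ],
        }
    )
    _write_tsv(hard_df, out / "assignments.tsv")
    cent = pd.DataFrame(fc.centroids, columns=list(fc.group_order))
    cent.insert(0, "cluster", [f"cluster_{j + 1}" for j in range(fc.c)])
    _write_tsv(cent, out / "centroids.tsv")
    shapes = {
        f"cluster_{j + 1}": clustering.label_cluster_shape(fc.centroids[j], fc.group_order)
        for j in range(fc.c)
    }
    with (out / "shapes.json").open("w") as fh:
        json.dump(
            {"shapes": shapes, "converged": fc.converged, "iterations": fc.n_iter},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    return {
        "seconds": round(time.perf_counter() - t0, 3),
        "converged": fc.converged,
        "fuzzifier": m_used,
        "n_profiles": len(fc.gene_ids),
        "dropped": len(profiles.dropped),
    }


def _stage_gsea(config: RunConfig, log_matrix: ExpressionMatrix, out: Path) -> dict:
    t0 = time.perf_counter()
    out.mkdir(parents=True, exist_ok=True)
    collection = read_gmt(config.gene_sets)
    order = log_matrix.design.group_order
    if config.gsea.contrast:
        group_a, group_b = config.gsea.contrast.split(":")
    else:
        group_a, group_b = order[-1], order[1]  # most severe vs mildest treatment
    results = gsea.run_gsea(
        log_matrix,
        collection,
        group_a,
        group_b,
        n_permutations=config.gsea.permutations,
        mode=config.gsea.mode,
        seed=config.seed,
        metric=config.gsea.metric,
        weight=config.gsea.weight,
    )
    table = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "significant": [r.significant for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
        }
    )
    _write_tsv(table, out / "gsea_results.tsv")
    for r in results:
        rs = pd.DataFrame({"position": np.arange(1, len(r.running_sum) + 1),
                           "running_sum": r.running_sum})
        _write_tsv(rs, out / f"running_sum_{r.set_name}.tsv")
    return {
        "seconds": round(time.perf_counter() - t0, 3),
        "contrast": f"{group_a}:{group_b}",
        "n_sets": len(results),
    }


def _stage_dnb(config: RunConfig, log_matrix: ExpressionMatrix, out: Path) -> dict:
    t0 = time.perf_counter()
    out.mkdir(parents=True, exist_ok=True)
    winner, table, results = dnb.run_dnb(
        log_matrix,
        sd_fold=config.dnb.sd_fold,
        pcc_threshold=config.dnb.pcc_threshold,
        min_cluster_size=config.dnb.min_cluster_size,
        min_expressed_fraction=config.dnb.min_expressed_fraction,
        selection_method=config.dnb.selection_method,
        use_reference=config.dnb.use_reference,
        cluster_method=config.dnb.cluster_method,
        pcc0_universe=config.dnb.pcc0_universe,
    )
    _write_tsv(table, out / "composite_index.tsv")
    for r in results:
        if r.best_cluster is not None:
            with (out / f"best_cluster_{r.group}.txt").open("w") as fh:
                fh.write("\n".join(r.best_cluster.genes) + "\n")
        if r.edges is not None and len(r.edges):
            _write_tsv(r.edges, out / f"edges_{r.group}.tsv")
    with (out / "tipping_point.json").open("w") as fh:
        json.dump(
            {
                "tipping_group": winner,
                "ci_by_group": {
                    row["group"]: (None if pd.isna(row["CI"]) else float(row["CI"]))
                    for _, row in table.iterrows()
                },
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    return {"seconds": round(time.perf_counter() - t0, 3), "tipping_group": winner}
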