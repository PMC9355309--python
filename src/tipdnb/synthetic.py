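"""Synthetic ordered-condition RNA-seq time courses with known ground truth.

The generator emulates the design this pipeline targets — an ordered series
of condition groups (a reference plus graded treatment durations) with a few
replicates each — and plants every kind of structure the downstream stages
are meant to detect:

* differentially expressed genes (group-indexed log2 offsets),
* temporal profile clusters (monotone up/down, up-then-down, late-only),
* enriched gene sets (sets biased toward planted signal genes),
* a dynamic-network-biomarker module at a chosen tipping group: a block of
  genes whose within-group variance is inflated and which share a latent
  per-replicate factor, so they become strongly mutually correlated while
  staying weakly correlated with the background.

Counts are negative-binomial (gamma–Poisson) around log-normal baseline
means, the mean–variance structure bulk RNA-seq screens assume.

Correlation planting
--------------------
On the log2 scale a gene's replicate noise floor is approximately
``σ0² = (φ + 1/μ) / ln(2)²`` (delta method for log2 of an NB with mean μ and
dispersion φ).  A module gene's total log2 variance is set to

    σm² = max(F, 1/(1 − ρ1)) · σ0²

where F is the requested variance inflation and ρ1 the requested
intra-module correlation; the shared latent factor carries ρ1·σm² of it and
independent log-normal jitter tops up the rest.  When ρ1 ≤ (F − 1)/F both
requests are met exactly; otherwise the count-noise floor makes them jointly
unreachable and the correlation target wins (realized inflation is then
1/(1 − ρ1)).  Background genes receive a small loading on the same latent
factor sized so their correlation with module genes sits at the
module-to-background target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_core import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    write_design_tsv,
    write_expression_tsv,
    write_gmt,
)

DEFAULT_GROUPS = ("sham", "IR16", "IR18", "IR22", "IR26", "IR30")

PROFILE_SHAPES = ("mono_up", "mono_down", "up_down", "late_only")


class ConfigError(ValueError):
    """A simulation configuration violates its own constraints."""


@dataclass(frozen=True)
class ProfileSpec:
    """A planted temporal trend: ``n_genes`` genes following ``shape`` with
    peak log2 amplitude ``amplitude``."""

    shape: str
    n_genes: int
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in PROFILE_SHAPES:
            raise ConfigError(f"unknown profile shape {self.shape!r}")
        if self.n_genes < 0:
            raise ConfigError("profile n_genes must be ≥ 0")


@dataclass(frozen=True)
class DnbSpec:
    """A planted pre-transition module.

    variance_inflation: target ratio of within-group variance (tipping group
    vs reference) for module genes, on the log2 scale.
    intra_corr / inter_corr: target pairwise |PCC| within the module and
    between module and background genes in the tipping group.
    """

    tipping_group: str
    module_size: int = 20
    variance_inflation: float = 4.0
    intra_corr: float = 0.9
    inter_corr: float = 0.1

    def __post_init__(self) -> None:
        if self.module_size < 2:
            raise ConfigError("dnb module needs ≥ 2 genes")
        if self.variance_inflation < 1:
            raise ConfigError("variance_inflation must be ≥ 1")
        if not (0 <= self.inter_corr < self.intra_corr <= 1):
            raise ConfigError(
                "need 0 ≤ inter_corr < intra_corr ≤ 1 "
                f"(got intra={self.intra_corr}, inter={self.inter_corr})"
            )
        if self.intra_corr >= 1:
            raise ConfigError("intra_corr must be < 1")


@dataclass(frozen=True)
class GeneSetSpec:
    """Planted gene-set structure: ``n_enriched`` of ``n_sets`` sets draw
    ``signal_fraction`` of their members from planted signal genes."""

    n_sets: int = 6
    set_size: int = 30
    n_enriched: int = 3
    signal_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.signal_fraction <= 1:
            raise ConfigError("signal_fraction must be in [0,1]")
        if self.n_enriched > self.n_sets:
            raise ConfigError("n_enriched cannot exceed n_sets")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated study.

    Defaults mirror the targeted design: six ordered groups (reference
    "sham" then graded ischemia durations) with three replicates each.
    """

    n_genes: int = 2000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates: int = 3
    baseline_log_mean: float = 5.5   # natural-log location of μ_g
    baseline_log_sd: float = 1.2     # natural-log scale of μ_g
    dispersion: float = 0.05         # NB dispersion φ (var = μ + φ μ²)
    de_fraction: float = 0.05        # per non-reference group
    de_effect_loc: float = 2.0       # |log2 effect| ~ N(loc, scale), random sign
    de_effect_scale: float = 0.5
    profile_clusters: tuple[ProfileSpec, ...] = ()
    dnb: DnbSpec | None = None
    gene_sets: GeneSetSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be ≥ 1")
        if self.replicates < 1:
            raise ConfigError("replicates must be ≥ 1")
        if len(self.groups) < 2:
            raise ConfigError("need ≥ 2 groups")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must be in [0,1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be ≥ 0")
        if self.dnb is not None:
            if self.dnb.tipping_group not in self.groups:
                raise ConfigError(f"tipping group {self.dnb.tipping_group!r} not in groups")
            if self.dnb.tipping_group == self.groups[0]:
                raise ConfigError("tipping group cannot be the reference group")
            if self.dnb.module_size > self.n_genes:
                raise ConfigError("dnb module larger than n_genes")


@dataclass
class SimulationTruth:
    """Ground truth of a simulation, for recovery tests."""

    de_genes: dict[str, dict[str, float]]          # group -> gene -> log2 effect
    profile_members: dict[str, list[str]]          # shape -> gene ids
    dnb_module: list[str]
    tipping_group: str | None
    enriched_sets: dict[str, str]                  # set name -> direction up/down/mixed
    gene_sets: GeneSetCollection | None = None

    def to_json_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "profile_members": self.profile_members,
            "dnb_module": self.dnb_module,
            "tipping_group": self.tipping_group,
            "enriched_sets": self.enriched_sets,
        }


def _profile_offsets(shape: str, n_groups: int, amplitude: float) -> np.ndarray:
    """Group-indexed log2 offsets for one planted temporal shape."""
    if shape == "mono_up":
        return np.linspace(0.0, amplitude, n_groups)
    if shape == "mono_down":
        return np.linspace(0.0, -amplitude, n_groups)
    if shape == "up_down":
        peak = n_groups // 2
        out = np.zeros(n_groups)
        out[: peak + 1] = np.linspace(0.0, amplitude, peak + 1)
        out[peak:] = np.linspace(amplitude, 0.0, n_groups - peak)
        return out
    if shape == "late_only":
        out = np.zeros(n_groups)
        out[-1] = amplitude
        if n_groups >= 3:
            out[-2] = amplitude / 2.0
        return out
    raise ConfigError(f"unknown profile shape {shape!r}")


def simulate_timecourse(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a counts-scale matrix plus the planted ground truth.

    Deterministic given ``config.seed``; gene order does not perturb any
    other gene's stream (each gene has its own child seed).
    """
    G, R = len(config.groups), config.replicates
    n_samples = G * R
    rng_struct = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    rng_latent = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"{g}_{r + 1}" for g in config.groups for r in range(R)]
    group_of_col = np.repeat(np.arange(G), R)

    # baseline means
    mu = np.exp(rng_struct.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes))
    mu = np.maximum(mu, 1.0)

    # ---- planted structure ------------------------------------------------
    delta = np.zeros((config.n_genes, G))  # log2 offsets per gene × group
    truth_de: dict[str, dict[str, float]] = {g: {} for g in config.groups[1:]}
    free = rng_struct.permutation(config.n_genes)  # assignment pool
    cursor = 0

    profile_members: dict[str, list[str]] = {}
    for spec in config.profile_clusters:
        idx = free[cursor: cursor + spec.n_genes]
        cursor += spec.n_genes
        if len(idx) < spec.n_genes:
            raise ConfigError("not enough genes for the requested profile clusters")
        offs = _profile_offsets(spec.shape, G, spec.amplitude)
        delta[idx, :] += offs[None, :]
        profile_members.setdefault(spec.shape, []).extend(gene_ids[i] for i in idx)

    module_idx = np.array([], dtype=int)
    if config.dnb is not None:
        module_idx = free[cursor: cursor + config.dnb.module_size]
        cursor += config.dnb.module_size
        if len(module_idx) < config.dnb.module_size:
            raise ConfigError("not enough genes for the dnb module")

    # DE genes per non-reference group (may overlap profile/module genes)
    n_de = int(round(config.de_fraction * config.n_genes))
    for gi, group in enumerate(config.groups[1:], start=1):
        if n_de == 0:
            continue
        idx = rng_struct.choice(config.n_genes, size=n_de, replace=False)
        signs = rng_struct.choice([-1.0, 1.0], size=n_de)
        mags = np.abs(rng_struct.normal(config.de_effect_loc, config.de_effect_scale, n_de))
        delta[idx, gi] += signs * mags
        for i, eff in zip(idx, signs * mags):
            truth_de[group][gene_ids[i]] = truth_de[group].get(gene_ids[i], 0.0) + float(eff)

    # ---- gene sets (membership fixed before sampling; recruited signal
    # genes receive a consistent offset so the planted enrichment is real) --
    enriched: dict[str, str] = {}
    collection: GeneSetCollection | None = None
    if config.gene_sets is not None:
        collection, enriched = _plant_gene_sets(
            config, gene_ids, delta, module_idx, truth_de, rng_struct
        )

    # ---- latent structure for the DNB module ------------------------------
    # per-gene log2 noise floor from the NB model
    sigma0 = np.sqrt(config.dispersion + 1.0 / mu) / math.log(2)
    shared = np.zeros((config.n_genes, R))      # log2 additions in tipping group
    indep_sd = np.zeros(config.n_genes)
    tip_col = -1
    if config.dnb is not None:
        tip_col = config.groups.index(config.dnb.tipping_group)
        rho1, rho0, F = config.dnb.intra_corr, config.dnb.inter_corr, config.dnb.variance_inflation
        # shared per-replicate factor, standardized to zero mean and unit
        # sample variance so the planted correlation is realized in each
        # dataset rather than only in expectation over seeds
        z = rng_latent.normal(size=R)
        z = (z - z.mean()) / z.std()
        inflation = max(F, 1.0 / (1.0 - rho1)) if rho1 > 0 else F
        sig_m2 = inflation * sigma0**2
        a = np.sqrt(rho1 * sig_m2)                       # shared loading, per gene
        b2 = sig_m2 - sigma0**2 - rho1 * sig_m2
        b = np.sqrt(np.maximum(b2, 0.0))                 # independent top-up
        is_module = np.zeros(config.n_genes, dtype=bool)
        is_module[module_idx] = True
        shared[module_idx, :] = a[module_idx, None] * z[None, :]
        indep_sd[module_idx] = b[module_idx]
        if rho0 > 0:
            k = rho0 / math.sqrt(rho1) if rho1 > 0 else 0.0
            if k >= 1:
                raise ConfigError("inter_corr too large relative to intra_corr")
            c = sigma0 * k / math.sqrt(1.0 - k * k)      # background loading
            bg = ~is_module
            shared[bg, :] = c[bg, None] * z[None, :]

    # ---- count sampling (per-gene child streams) ---------------------------
    values = np.empty((config.n_genes, n_samples))
    phi = config.dispersion
    for i in range(config.n_genes):
        rng_g = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2, i)))
        log2_shift = delta[i, group_of_col].astype(float)
        if tip_col >= 0:
            tip_cols = np.where(group_of_col == tip_col)[0]
            log2_shift[tip_cols] += shared[i, :]
            if indep_sd[i] > 0:
                log2_shift[tip_cols] += rng_g.normal(0.0, indep_sd[i], size=R)
        means = mu[i] * np.exp2(log2_shift)
        if phi > 0:
            lam = rng_g.gamma(shape=1.0 / phi, scale=means * phi)
        else:
            lam = means
        values[i, :] = rng_g.poisson(lam)

    design = SampleDesign(
        sample_to_group={s: s.rsplit("_", 1)[0] for s in sample_ids},
        group_order=config.groups,
    )
    matrix = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values, design=design, scale="counts"
    )

    truth = SimulationTruth(
        de_genes=truth_de,
        profile_members=profile_members,
        dnb_module=[gene_ids[i] for i in module_idx],
        tipping_group=config.dnb.tipping_group if config.dnb else None,
        enriched_sets=enriched,
        gene_sets=collection,
    )
    return matrix, truth


def _plant_gene_sets(
    config: SimulationConfig,
    gene_ids: list[str],
    delta: np.ndarray,
    module_idx: np.ndarray,
    truth_de: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Build set membership and make the enriched sets genuinely enriched.

    An enriched set draws its signal members from genes that already carry a
    consistent direction across the treatment groups; when too few exist,
    background genes are recruited and given a uniform log2 offset of
    ``±de_effect_loc`` in every non-reference group (recorded in the DE
    truth), so the planted fraction of signal genes is met by construction.
    Mutates ``delta`` and ``truth_de`` in place.
    """
    spec = config.gene_sets
    # signal pools: genes responding in the same direction in EVERY
    # treatment group (a single-group spike is not "consistently up" and
    # carries no enrichment for most contrasts)
    treat = delta[:, 1:]
    mean_off = treat.mean(axis=1)
    up_pool = list(np.where((treat.min(axis=1) >= 0.25) & (mean_off >= 1.0))[0])
    down_pool = list(np.where((treat.max(axis=1) <= -0.25) & (mean_off <= -1.0))[0])
    in_module = set(module_idx.tolist())
    bg_pool = [
        int(i) for i in np.where(np.abs(mean_off) <= 0.5)[0] if int(i) not in in_module
    ]
    rng.shuffle(bg_pool)
    sets: dict[str, tuple[str, list[str]]] = {}
    enriched: dict[str, str] = {}
    for s in range(spec.n_sets):
        name = f"SET{s + 1:02d}"
        if s < spec.n_enriched:
            direction = "up" if s % 2 == 0 else "down"
            pool = up_pool if direction == "up" else down_pool
            n_sig = int(round(spec.signal_fraction * spec.set_size))
            take = min(n_sig, len(pool))
            sig = list(rng.choice(pool, size=take, replace=False)) if take else []
            shortfall = n_sig - take
            if shortfall > len(bg_pool):
                raise ConfigError("not enough background genes to plant the gene sets")
            recruited, bg_pool = bg_pool[:shortfall], bg_pool[shortfall:]
            sign = 1.0 if direction == "up" else -1.0
            for i in recruited:
                delta[i, 1:] += sign * config.de_effect_loc
                for gi, group in enumerate(config.groups[1:], start=1):
                    truth_de[group][gene_ids[i]] = (
                        truth_de[group].get(gene_ids[i], 0.0) + sign * config.de_effect_loc
                    )
            sig = [int(i) for i in sig] + recruited
            n_bg = spec.set_size - len(sig)
            if n_bg > len(bg_pool):
                raise ConfigError("not enough background genes to plant the gene sets")
            filler, bg_pool = bg_pool[:n_bg], bg_pool[n_bg:]
            members = sorted(set(sig + filler))
            enriched[name] = direction
            desc = f"planted_{direction}"
        else:
            if spec.set_size > len(bg_pool):
                raise ConfigError("not enough background genes to plant the gene sets")
            members, bg_pool = sorted(set(bg_pool[: spec.set_size])), bg_pool[spec.set_size:]
            desc = "background"
        sets[name] = (desc, [gene_ids[int(i)] for i in members])
    return GeneSetCollection(sets=sets), enriched


def export_fixture(
    matrix: ExpressionMatrix, truth: SimulationTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write expression TSV, design TSV, GMT and truth JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    write_expression_tsv(matrix, paths["expression"])
    write_design_tsv(matrix.design, paths["design"])
    if truth.gene_sets is not None and len(truth.gene_sets):
        write_gmt(truth.gene_sets, paths["gene_sets"])
    else:
        del paths["gene_sets"]
    with paths["truth"].open("w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
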