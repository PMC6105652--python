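"""Synthetic three-stage datasets with planted ground truth.

Emulates the structure the analysis assumes: a genes × samples log2
expression matrix over three groups (C, M, E) with replicate samples and
genes planted on temporal profiles; an interaction network with planted
cliques over profile-planted genes plus Erdos-Renyi background edges;
promoter regions with Poisson read coverage and planted methylation fold
shifts; and Ct tables consistent with the planted expression.  All
randomness flows through one seeded generator so a config + seed pair
reproduces every output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .expression import GROUPS, ExpressionMatrix

#: default planted temporal patterns and the fraction of genes on each; the
#: up-then-flat pattern dominates, mirroring an early-activation time course
DEFAULT_PLANTED = {(0, 1, 1): 0.4}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the package's study conditions.

    Expression: 1000 genes in 3 groups x 3 replicates, planted genes shifted
    by ``effect_size`` log2 units per profile level with i.i.d. Gaussian
    noise of sd ``noise_sd``.  Network: planted cliques over planted genes
    plus background edges at ``background_edge_prob``.  Methylation: Poisson
    read counts per promoter region, planted DMRs scaled ``dmr_fold``-fold
    in group M.
    """

    n_genes: int = 1000
    n_replicates_per_group: int = 3
    groups: tuple[str, ...] = GROUPS
    planted_profiles: dict[tuple[int, ...], float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED)
    )
    effect_size: float = 3.0
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    network_n_nodes: int | None = None  # default: all genes
    planted_clique_sizes: tuple[int, ...] = (6, 5)
    background_edge_prob: float = 0.01
    n_regions: int = 200
    region_length: int = 1000
    read_length: int = 50
    reads_per_region_mean: float = 60.0
    dmr_fraction: float = 0.2
    dmr_fold: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates_per_group < 2:
            raise ValueError("need >= 1 gene and >= 2 replicates per group")
        fractions = list(self.planted_profiles.values())
        if any(f < 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
            raise ValueError("planted fractions must be >= 0 and sum to <= 1")
        for levels in self.planted_profiles:
            if len(levels) != len(self.groups) or levels[0] != 0:
                raise ValueError(f"invalid planted pattern {levels}")
        n_nodes = self.network_n_nodes or self.n_genes
        if any(k < 3 for k in self.planted_clique_sizes):
            raise ValueError("planted cliques need size >= 3")
        if sum(self.planted_clique_sizes) > n_nodes:
            raise ValueError("planted clique sizes exceed the node budget")
        if not 0 <= self.background_edge_prob <= 1:
            raise ValueError("background_edge_prob must be a probability")
        if self.n_regions < 1:
            raise ValueError("need n_regions >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "planted_profiles" in raw:
            raw["planted_profiles"] = {
                tuple(int(x) for x in key.split(",")): float(frac)
                for key, frac in raw["planted_profiles"].items()
            }
        for key in ("groups", "planted_clique_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Exactly one truth record per generated gene, node and region."""

    gene_profiles: dict[str, tuple[int, ...]]  # planted levels; flat if unplanted
    hub_nodes: dict[str, bool]
    clique_members: list[set[str]]
    region_dmr: dict[str, str]  # region name -> "none" | "up" | "down"

    def planted_genes(self, levels: tuple[int, ...] | None = None) -> set[str]:
        flat = tuple([0] * len(next(iter(self.gene_profiles.values()))))
        return {
            g
            for g, lv in self.gene_profiles.items()
            if (lv == levels if levels is not None else lv != flat)
        }


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _plan_genes(config: SyntheticConfig) -> dict[str, tuple[int, ...]]:
    """Assign planted patterns to leading gene blocks; remainder is flat."""
    flat = tuple([0] * len(config.groups))
    genes = _gene_ids(config.n_genes)
    plan = {g: flat for g in genes}
    cursor = 0
    for levels, fraction in config.planted_profiles.items():
        count = int(round(fraction * config.n_genes))
        for g in genes[cursor : cursor + count]:
            plan[g] = levels
        cursor += count
    return plan


def generate_expression(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Planted-profile expression matrix with Gaussian log2 noise.

    A gene planted on levels (0, l1, l2) has group mean baseline +
    effect_size * level; every value adds N(0, noise_sd) noise.  Detection
    flags are all true (the detection filter is exercised with explicit
    flags in tests).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    plan = _plan_genes(config)
    genes = list(plan)
    samples = [
        f"{g}{r + 1}" for g in config.groups for r in range(config.n_replicates_per_group)
    ]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    levels = np.array([plan[g] for g in genes], dtype=float)
    group_means = baseline[:, None] + config.effect_size * levels  # genes x groups
    per_sample = np.repeat(group_means, config.n_replicates_per_group, axis=1)
    noise = rng.normal(0.0, config.noise_sd, size=per_sample.shape) if config.noise_sd > 0 else 0.0
    values = pd.DataFrame(per_sample + noise, index=genes, columns=samples)
    groups = pd.Series(
        [s[0] for s in samples], index=samples, name="group"
    )
    truth = GroundTruth(plan, {}, [], {})
    detected = pd.DataFrame(True, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, groups, detected), truth


def generate_network(
    config: SyntheticConfig,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[nx.Graph, GroundTruth]:
    """Planted cliques on disjoint planted-gene blocks + E-R background.

    Clique members are drawn from profile-planted genes (when a truth from
    ``generate_expression`` is supplied) so that planted hubs carry all
    three evidence layers; remaining nodes get only background edges.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_nodes = config.network_n_nodes or config.n_genes
    nodes = _gene_ids(config.n_genes)[:n_nodes]
    if truth is None:
        truth = GroundTruth({g: (0,) * len(config.groups) for g in nodes}, {}, [], {})

    planted_pool = [g for g in nodes if g in truth.planted_genes()]
    pool = planted_pool if len(planted_pool) >= sum(config.planted_clique_sizes) else nodes

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    cursor = 0
    cliques: list[set[str]] = []
    for size in config.planted_clique_sizes:
        members = set(pool[cursor : cursor + size])
        cursor += size
        cliques.append(members)
        for a in members:
            for b in members:
                if a < b:
                    graph.add_edge(a, b)

    if config.background_edge_prob > 0:
        index = {g: i for i, g in enumerate(nodes)}
        mask = rng.random((n_nodes, n_nodes)) < config.background_edge_prob
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if mask[i, j]:
                    graph.add_edge(nodes[i], nodes[j])

    hub_flags = {n: any(n in c for c in cliques) for n in nodes}
    truth.hub_nodes = hub_flags
    truth.clique_members = cliques
    return graph, truth


def generate_methylation(
    config: SyntheticConfig,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[pd.DataFrame]], list, GroundTruth]:
    """Per-group replicate read sets + promoter regions with planted DMRs.

    Regions tile a synthetic chromosome; read counts per replicate are
    Poisson(reads_per_region_mean), scaled by ``dmr_fold`` in group M for
    the planted fraction (alternating hyper/hypo direction).  Read starts
    are uniform within the region, plus strand, fixed read length.  Returns
    ({group: [reads per replicate]}, promoter regions, truth).
    """
    from .methylation import GenomicRegion

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if truth is None:
        truth = GroundTruth({}, {}, [], {})

    gap = 1000
    genes = _gene_ids(config.n_genes)
    regions = []
    for i in range(config.n_regions):
        start = i * (config.region_length + gap)
        name = genes[i] if i < len(genes) else f"region{i:05d}"
        regions.append(GenomicRegion("chrS", start, start + config.region_length, name))

    n_dmr = int(round(config.dmr_fraction * config.n_regions))
    dmr_direction = {}
    for i, region in enumerate(regions):
        if i < n_dmr and config.dmr_fold != 1.0:
            dmr_direction[region.name] = "up" if i % 2 == 0 else "down"
        else:
            dmr_direction[region.name] = "none"

    read_sets: dict[str, list[pd.DataFrame]] = {g: [] for g in config.groups}
    for group in config.groups:
        for _rep in range(config.n_replicates_per_group):
            rows = []
            for region in regions:
                lam = config.reads_per_region_mean
                direction = dmr_direction[region.name]
                if group == "M" and direction == "up":
                    lam *= config.dmr_fold
                elif group == "M" and direction == "down":
                    lam /= config.dmr_fold
                count = rng.poisson(lam)
                span = max(region.end - region.start - config.read_length, 1)
                starts = region.start + rng.integers(0, span, size=count)
                for s in np.sort(starts):
                    rows.append(("chrS", int(s), int(s) + config.read_length, ".", 0, "+"))
            read_sets[group].append(
                pd.DataFrame(
                    rows, columns=["chrom", "start", "end", "name", "score", "strand"]
                )
            )
    truth.region_dmr = dmr_direction
    return read_sets, regions, truth


def generate_qpcr(
    truth: GroundTruth,
    config: SyntheticConfig,
    genes: list[str],
    ct_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Ct tables consistent with the planted expression truth.

    The reference gene is flat at Ct 20; the target's Ct drops by one cycle
    per planted doubling (log2 shift of effect_size * level).  Returns one
    table per requested gene.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    tables = {}
    for gene in genes:
        if gene not in truth.gene_profiles:
            raise KeyError(f"unknown gene {gene!r}")
        levels = truth.gene_profiles[gene]
        rows = []
        for g_idx, group in enumerate(config.groups):
            log2_shift = config.effect_size * levels[g_idx]
            for rep in range(config.n_replicates_per_group):
                noise = rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    (f"{group}{rep + 1}", group, 24.0 - log2_shift + noise, 20.0)
                )
        tables[gene] = pd.DataFrame(
            rows, columns=["sample", "group", "ct_target", "ct_reference"]
        )
    return tables


# ---- whole-dataset orchestration and file output ---------------------------

@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    network: nx.Graph
    read_sets: dict[str, list[pd.DataFrame]]
    promoters: list
    truth: GroundTruth


def generate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every input layer with a coherent shared ground truth."""
    matrix, truth = generate_expression(config)
    graph, truth = generate_network(config, truth)
    read_sets, promoters, truth = generate_methylation(config, truth)
    return SyntheticDataset(matrix, graph, read_sets, promoters, truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write matrix/sample-sheet TSVs, edge-list + SIF, BEDs and truth TSV."""
    from .methylation import write_bed
    from .network import write_sif

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.expression.to_tsv(
        outdir / "expression.tsv", outdir / "samples.tsv", outdir / "detection.tsv"
    )
    with open(outdir / "network.tsv", "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in dataset.network.edges):
            fh.write(f"{a}\t{b}\n")
    write_sif(dataset.network, outdir / "network.sif")
    for group, replicates in dataset.read_sets.items():
        for i, reads in enumerate(replicates):
            write_bed(reads, outdir / f"reads_{group}{i + 1}.bed")
    promoter_frame = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.name) for r in dataset.promoters],
        columns=["chrom", "start", "end", "name"],
    )
    write_bed(promoter_frame, outdir / "promoters.bed")
    truth_rows = [
        (g, ",".join(map(str, lv)), int(dataset.truth.hub_nodes.get(g, False)),
         dataset.truth.region_dmr.get(g, "none"))
        for g, lv in dataset.truth.gene_profiles.items()
    ]
    pd.DataFrame(
        truth_rows, columns=["gene", "planted_levels", "planted_hub", "planted_dmr"]
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
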