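"""Synthetic input generator with planted, parameterized structure.

Every downstream stage gets inputs with a known truth to recover:
negative-binomial counts with planted haplotype/species/interaction
effects, physically clustered sensitive genes, a scale-free network
with boosted low-degree neighborhoods, module labels with a planted
improper-module enrichment, and block-structured developmental
expression profiles.

One master seed spawns fixed per-stage child streams, so any stage can
be regenerated independently and results never depend on stage order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import GeneRecord, GenomeTable, InteractionNetwork, SampleMeta

logger = logging.getLogger(__name__)

_STAGE_KEYS = {
    "genome": 1,
    "clusters": 2,
    "counts": 3,
    "network": 4,
    "modules": 5,
    "dev": 6,
}

MIN_GENE_BP = 500


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named stage, derived from the master seed."""
    if stage not in _STAGE_KEYS:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS[stage],))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 2000
    arms: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("2L", 23_000_000), ("2R", 25_000_000), ("3L", 28_000_000),
            ("3R", 32_000_000), ("X", 23_000_000),
        ]
    )
    haplotypes: list[str] = field(
        default_factory=lambda: ["hapA", "hapB", "hapC", "hapD"]
    )
    species_of: dict[str, str] = field(
        default_factory=lambda: {
            "hapA": "sp1", "hapB": "sp1", "hapC": "sp2", "hapD": "sp2"
        }
    )
    backgrounds: list[str] = field(default_factory=lambda: ["bg1", "bg2"])
    n_replicates: int = 4
    sexes: tuple[str, ...] = ("F", "M")
    effect_gene_fraction: float = 0.05
    fold_change: float = 4.0
    dispersion: float = 0.1
    baseline_mean: float = 100.0
    library_sigma: float = 0.2
    # clustering plan
    n_clusters: int = 5
    cluster_size: int = 4
    max_internal_gap: int = 0
    background_rate: float = 0.0
    # network plan
    n_nodes: int = 1000
    network_model: str = "scale_free"
    network_param: int | float = 3
    n_hotspots: int = 3
    hotspot_boost: float = 5.0
    # modules
    improper_fraction: float = 0.2
    improper_enrichment_factor: float = 3.5
    n_proper_modules: int = 10
    # developmental stages
    n_stages: int = 12
    n_blocks: int = 4

    def __post_init__(self) -> None:
        for name in ("effect_gene_fraction", "background_rate", "library_sigma"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.improper_fraction < 1:
            raise ValueError("improper_fraction must lie in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")


# -- genome ----------------------------------------------------------


def generate_genome(config: SimConfig) -> GenomeTable:
    """Non-overlapping gene intervals distributed over arms by length."""
    rng = stage_rng(config.seed, "genome")
    if config.n_genes == 0:
        return GenomeTable([])
    lengths = np.array([l for _, l in config.arms], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("arm lengths must be positive")
    # proportional allocation with largest-remainder rounding
    quota = config.n_genes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    rem = config.n_genes - counts.sum()
    for i in np.argsort(-(quota - counts))[:rem]:
        counts[i] += 1
    records: list[GeneRecord] = []
    gene_no = 0
    digits = max(4, len(str(config.n_genes)))
    for (arm, length), k in zip(config.arms, counts):
        if k == 0:
            continue
        slot = length // k
        if slot <= MIN_GENE_BP + 1:
            raise ValueError(
                f"arm {arm}: {k} genes do not fit at minimum size {MIN_GENE_BP}"
            )
        for j in range(k):
            gene_len = int(rng.integers(MIN_GENE_BP, min(5000, slot - 1)))
            start = int(j * slot + rng.integers(0, slot - gene_len))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                GeneRecord(f"g{gene_no:0{digits}d}", arm, start, start + gene_len, strand)
            )
            gene_no += 1
    return GenomeTable(records)


# -- planted physical clusters ---------------------------------------


def plant_clustered_gene_set(
    genome: GenomeTable,
    n_clusters: int,
    cluster_size: int,
    max_internal_gap: int = 0,
    background_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Plant runs of consecutive-rank genes plus background singletons.

    Returns (test gene ids, truth frame with a truth_planted column).
    """
    if n_clusters > 0 and cluster_size < 2:
        raise ValueError("cluster_size must be >= 2")
    if max_internal_gap < 0:
        raise ValueError("max_internal_gap must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS["clusters"],)))
    arms = genome.arms
    span = cluster_size + (cluster_size - 1) * max_internal_gap
    eligible = [a for a in arms if len(genome.arm_genes(a)) >= span]
    if n_clusters > 0 and not eligible:
        raise ValueError("no arm long enough for the requested cluster plan")
    planted: set[str] = set()
    used_ranks: dict[str, set[int]] = {a: set() for a in arms}
    for _ in range(n_clusters):
        for _attempt in range(1000):
            arm = eligible[int(rng.integers(len(eligible)))]
            genes = genome.arm_genes(arm)
            anchor = int(rng.integers(0, len(genes) - span + 1))
            ranks = [anchor]
            for _m in range(cluster_size - 1):
                gap = int(rng.integers(0, max_internal_gap + 1))
                ranks.append(ranks[-1] + 1 + gap)
            # keep a buffer of max_internal_gap+1 around the run so planted
            # clusters never merge with each other
            lo, hi = ranks[0] - max_internal_gap - 1, ranks[-1] + max_internal_gap + 1
            if any(r in used_ranks[arm] for r in range(lo, hi + 1)):
                continue
            used_ranks[arm].update(range(lo, hi + 1))
            planted.update(genes[r].gene_id for r in ranks)
            break
        else:
            raise ValueError("could not place all planted clusters without overlap")
    test = set(planted)
    if background_rate > 0:
        for g in genome:
            if g.gene_id not in planted and rng.random() < background_rate:
                test.add(g.gene_id)
    truth = pd.DataFrame(
        {"gene_id": genome.gene_ids,
         "truth_planted": [g in planted for g in genome.gene_ids],
         "truth_in_test_set": [g in test for g in genome.gene_ids]}
    )
    return sorted(test), truth


# -- counts ----------------------------------------------------------


def build_sample_design(config: SimConfig) -> list[SampleMeta]:
    """Sample sheet: all haplotypes in the first background, the first and
    last haplotype in the second (the interaction panel), per sex/replicate."""
    metas = []
    pairs = [(h, config.backgrounds[0]) for h in config.haplotypes]
    if len(config.backgrounds) > 1:
        pairs += [(h, config.backgrounds[1])
                  for h in (config.haplotypes[0], config.haplotypes[-1])]
    for sex in config.sexes:
        for mito, nuc in pairs:
            for rep in range(1, config.n_replicates + 1):
                metas.append(
                    SampleMeta(f"{sex}_{mito}_{nuc}_r{rep}", sex, mito, nuc, rep)
                )
    return metas


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_counts(
    genome: GenomeTable,
    config: SimConfig,
    metas: list[SampleMeta] | None = None,
) -> tuple[pd.DataFrame, list[SampleMeta], pd.DataFrame]:
    """NB counts with planted haplotype / species / interaction effects.

    Effect genes split evenly three ways. A haplotype gene shifts one
    haplotype's mean by fold_change; a species gene shifts both
    haplotypes of the second species; an interaction (GxG) gene applies
    equal-magnitude, opposite-sign haplotype shifts in the two nuclear
    backgrounds. Truth columns record the class and direction.
    """
    if config.dispersion < 0 or config.fold_change <= 0:
        raise ValueError("dispersion must be >= 0 and fold_change > 0")
    rng = stage_rng(config.seed, "counts")
    metas = metas or build_sample_design(config)
    gene_ids = genome.gene_ids
    n = len(gene_ids)
    n_effect = int(round(n * config.effect_gene_fraction))
    effect_idx = rng.choice(n, size=n_effect, replace=False) if n_effect else np.array([], dtype=int)
    classes = np.array(["none"] * n, dtype=object)
    third = n_effect // 3
    classes[effect_idx[:third]] = "haplotype"
    classes[effect_idx[third: 2 * third]] = "species"
    classes[effect_idx[2 * third:]] = "gxg"
    baseline = np.exp(rng.normal(np.log(config.baseline_mean), 0.5, size=n))
    lib = np.exp(rng.normal(0.0, config.library_sigma, size=len(metas)))
    target_hap = config.haplotypes[-1]  # shifted haplotype for "haplotype" genes
    sp2 = {h for h, s in config.species_of.items() if s != config.species_of[config.haplotypes[0]]}
    fc = config.fold_change
    counts = np.empty((n, len(metas)), dtype=int)
    for j, m in enumerate(metas):
        fold = np.ones(n)
        is_hap = classes == "haplotype"
        is_sp = classes == "species"
        is_gxg = classes == "gxg"
        if m.mito == target_hap:
            fold[is_hap] = fc
        if m.mito in sp2:
            fold[is_sp] = fc
        if m.mito == target_hap:
            # opposite-sign interaction across backgrounds
            fold[is_gxg] = fc if m.nuc == config.backgrounds[0] else 1.0 / fc
        mean = baseline * fold * lib[j]
        counts[:, j] = _nb_draw(rng, mean, config.dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=[m.sample_id for m in metas])
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "truth_effect": classes,
         "truth_fold": np.where(classes == "none", 1.0, fc)}
    )
    return counts_df, metas, truth


# -- network ---------------------------------------------------------


def generate_network_with_hotspots(
    config: SimConfig,
    gene_ids: list[str] | None = None,
) -> tuple[InteractionNetwork, dict[str, float], set[str]]:
    """Interaction network plus node attributes with boosted hotspots.

    Attributes are -log10 of Uniform(0,1) draws (the exchangeable null);
    each hotspot is the radius-1 ball around a seed drawn from the
    lowest-degree third of nodes, boosted by ``hotspot_boost``.
    """
    if config.n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = stage_rng(config.seed, "network")
    n = config.n_nodes
    if gene_ids is None:
        digits = max(4, len(str(n)))
        gene_ids = [f"g{i:0{digits}d}" for i in range(n)]
    if len(gene_ids) < n:
        raise ValueError("not enough gene ids for the requested node count")
    gene_ids = list(gene_ids)[:n]
    nx_seed = int(rng.integers(2**31 - 1))
    if n == 1:
        g = nx.empty_graph(1)
    elif config.network_model == "scale_free":
        m = min(int(config.network_param), n - 1)
        g = nx.barabasi_albert_graph(n, m, seed=nx_seed)
    elif config.network_model == "erdos_renyi":
        g = nx.gnp_random_graph(n, float(config.network_param), seed=nx_seed)
    else:
        raise ValueError(f"unknown network model {config.network_model!r}")
    g = nx.relabel_nodes(g, dict(enumerate(gene_ids)))
    for u, v in g.edges:
        g.edges[u, v]["confidence"] = float(np.round(rng.uniform(0.5, 1.0), 3))
    net = InteractionNetwork(g, directed=False)
    attrs = {gid: float(-np.log10(rng.uniform())) for gid in sorted(gene_ids)}
    deg = dict(g.degree())

    def ball_mean_degree(u) -> float:
        ball = [u] + list(g.neighbors(u))
        return float(np.mean([deg[v] for v in ball]))

    # seed candidates whose whole radius-1 ball sits in a low-degree region
    order = sorted(gene_ids, key=lambda x: (ball_mean_degree(x), x))
    low_pool = [x for x in order[: max(1, n // 3)] if deg[x] > 0] or order[: max(1, n // 3)]
    hotspot: set[str] = set()
    if config.n_hotspots > 0:
        if config.n_hotspots > len(low_pool):
            raise ValueError("more hotspots requested than eligible seed nodes")
        seeds = rng.choice(len(low_pool), size=config.n_hotspots, replace=False)
        for si in seeds:
            seed_node = low_pool[int(si)]
            ball = {seed_node} | set(g.neighbors(seed_node))
            hotspot |= ball
        for gid in hotspot:
            attrs[gid] += config.hotspot_boost
    return net, attrs, hotspot


# -- module labels ---------------------------------------------------


def generate_module_labels(
    gene_ids: list[str],
    improper_fraction: float,
    sensitive_set,
    enrichment_factor: float = 1.0,
    n_proper_modules: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Assign genes to proper modules plus one 'improper' module.

    Sensitive genes enter the improper module with probability
    ``enrichment_factor * improper_fraction`` so the expected overlap
    fold equals the requested factor; infeasible requests raise with
    the feasible bound.
    """
    if not 0 < improper_fraction < 1:
        raise ValueError("improper_fraction must lie in (0, 1)")
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    q = enrichment_factor * improper_fraction
    if q > 1:
        raise ValueError(
            f"requested fold {enrichment_factor} infeasible; bound is "
            f"{1.0 / improper_fraction:.3f} at improper_fraction={improper_fraction}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS["modules"],)))
    sensitive = set(sensitive_set)
    rows = []
    for gid in gene_ids:
        p_improper = q if gid in sensitive else improper_fraction
        if rng.random() < p_improper:
            module = "improper"
        else:
            module = f"module{int(rng.integers(n_proper_modules)) + 1:02d}"
        rows.append({"gene_id": gid, "module": module,
                     "truth_sensitive": gid in sensitive})
    table = pd.DataFrame(rows)
    sets = {m: set(sub["gene_id"]) for m, sub in table.groupby("module")}
    return table, sets


# -- developmental expression ----------------------------------------


def generate_dev_expression(
    gene_ids: list[str],
    n_stages: int,
    n_blocks: int = 4,
    seed: int = 0,
    noise_sd: float = 0.3,
    block_amplitude: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-structured expression blocks (genes x stages matrix + truth).

    Each block is active over a contiguous window of stages; genes carry
    their block's mean profile plus iid Gaussian noise, so within-block
    correlation exceeds between-block correlation.
    """
    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS["dev"],)))
    stages = [f"stage{s + 1:02d}" for s in range(n_stages)]
    bounds = np.linspace(0, n_stages, n_blocks + 1).astype(int)
    profiles = np.zeros((n_blocks, n_stages))
    for b in range(n_blocks):
        profiles[b, bounds[b]: bounds[b + 1]] = block_amplitude
    blocks = rng.integers(n_blocks, size=len(gene_ids))
    X = profiles[blocks] + rng.normal(0, noise_sd, size=(len(gene_ids), n_stages))
    expr = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"), columns=stages)
    truth = pd.DataFrame({"gene_id": gene_ids,
                          "truth_block": [f"block{b + 1}" for b in blocks]})
    return expr, truth


# -- one-call bundle -------------------------------------------------


def simulate_all(config: SimConfig, outdir: str | Path | None = None) -> dict:
    """Run every generator under the master seed; optionally write TSVs."""
    from . import io as msio
    from .dendrogram import write_newick  # noqa: F401  (re-exported path)

    genome = generate_genome(config)
    test_set, cluster_truth = plant_clustered_gene_set(
        genome, config.n_clusters, config.cluster_size, config.max_internal_gap,
        config.background_rate, seed=config.seed,
    )
    counts, metas, counts_truth = generate_counts(genome, config)
    net, attrs, hotspot = generate_network_with_hotspots(config, genome.gene_ids)
    sensitive = set(counts_truth.loc[counts_truth["truth_effect"] != "none", "gene_id"])
    modules, module_sets = generate_module_labels(
        genome.gene_ids, config.improper_fraction, sensitive,
        config.improper_enrichment_factor, config.n_proper_modules, seed=config.seed,
    )
    dev, dev_truth = generate_dev_expression(
        genome.gene_ids[: min(len(genome), 500)], config.n_stages, config.n_blocks,
        seed=config.seed,
    )
    bundle = {
        "genome": genome, "test_set": test_set, "cluster_truth": cluster_truth,
        "counts": counts, "samples": metas, "counts_truth": counts_truth,
        "network": net, "attributes": attrs, "hotspot": hotspot,
        "modules": modules, "module_sets": module_sets,
        "dev_expression": dev, "dev_truth": dev_truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        msio.write_bed(genome, outdir / "genome.bed")
        msio.write_gene_list(test_set, outdir / "test_set.txt")
        cluster_truth.to_csv(outdir / "truth_clusters.tsv", sep="\t", index=False)
        msio.write_counts(counts, outdir / "counts.tsv")
        msio.write_sample_meta(metas, outdir / "samples.tsv")
        counts_truth.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
        msio.write_edge_list(net, outdir / "network.tsv")
        pd.DataFrame(
            {"gene_id": sorted(attrs), "attr": [attrs[g] for g in sorted(attrs)]}
        ).to_csv(outdir / "attributes.tsv", sep="\t", index=False)
        msio.write_gene_list(sorted(hotspot), outdir / "truth_hotspot.txt")
        modules.to_csv(outdir / "modules.tsv", sep="\t", index=False)
        msio.write_expression_matrix(dev, outdir / "dev_expression.tsv")
        dev_truth.to_csv(outdir / "truth_dev_blocks.tsv", sep="\t", index=False)
    return bundle
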