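"""End-to-end orchestration over synthetic or user-supplied inputs.

``run_pipeline`` drives simulate -> de -> cluster -> safe -> rank ->
enrich -> concord under one master seed and writes a manifest recording
every parameter, per-stage seed, and output file hash, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, concordance, de, enrich, focal, io, network, simulate
from .dendrogram import write_newick

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "mitosense_out",
    "stages": ["simulate", "de", "cluster", "safe", "rank", "enrich", "concord"],
    "simulate": {"n_genes": 2000, "n_nodes": 600},
    "de": {"top_n": 200, "fdr_threshold": 0.05},
    "cluster": {"max_gap": 5, "min_size": 2, "n_iter": 1000},
    "safe": {"radius": 1, "n_perm": 1000, "alpha": 0.05},
    "rank": {"top_n": 200, "min_interactors": 1},
    "enrich": {"n_perm": 10000},
    "concord": {"window": 50, "L": 1.5, "n_perm": 100},
}

_STAGE_SEED_OFFSET = {
    "de": 11, "cluster": 12, "safe": 13, "rank": 14, "enrich": 15, "concord": 16,
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge with defaults; unknown keys are rejected, not ignored."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if key not in merged:
            raise ConfigError(f"unknown config key: {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            for sub in val:
                if sub not in merged[key] and key != "simulate":
                    raise ConfigError(f"unknown config key: {key}.{sub}")
            merged[key].update(val)
        else:
            merged[key] = val
    unknown_stages = set(merged["stages"]) - set(DEFAULT_CONFIG["stages"])
    if unknown_stages:
        raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")
    return merged


def stage_seed(master: int, stage: str) -> int:
    return int(master) * 100 + _STAGE_SEED_OFFSET.get(stage, 99)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Run the configured stages; returns the manifest dict."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}, "files": {}}

    sim_cfg = simulate.SimConfig(seed=seed, **cfg["simulate"])
    bundle = simulate.simulate_all(sim_cfg, outdir if "simulate" in stages else None)
    genome = bundle["genome"]
    counts = bundle["counts"]
    metas = bundle["samples"]
    manifest["stages"]["simulate"] = {"seed": seed, "n_genes": len(genome)}

    de_tables: dict[str, pd.DataFrame] = {}
    if "de" in stages:
        filtered = de.filter_low_counts(counts)
        for sex in ("F", "M"):
            spec, sample_ids = de.haplotype_anodev_spec(metas, sex)
            table = de.run_contrast(filtered, sample_ids, spec)
            de_tables[sex] = table
            table.to_csv(outdir / f"de_haplotype_{sex}.tsv", sep="\t", index=False)
        manifest["stages"]["de"] = {
            "seed": stage_seed(seed, "de"),
            "n_genes_tested": len(de_tables["F"]),
            "n_significant": {
                s: int((t["fdr"] < cfg["de"]["fdr_threshold"]).sum())
                for s, t in de_tables.items()
            },
        }

    if "cluster" in stages and de_tables:
        p = cfg["cluster"]
        rows = []
        for sex, table in de_tables.items():
            top = de.top_n_by_pvalue(table, min(cfg["de"]["top_n"], len(table)))
            rep = clustering.analyze_gene_list(
                top, genome, p["max_gap"], p["min_size"], p["n_iter"],
                seed=stage_seed(seed, "cluster"),
            )
            rep.to_frame().to_csv(outdir / f"clusters_{sex}.tsv", sep="\t", index=False)
            rows.append(
                {"sex": sex, "n_clusters": rep.n_clusters,
                 "percent_clustered": rep.percent_clustered,
                 "p_randomization": rep.p_randomization}
            )
        pd.DataFrame(rows).to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
        manifest["stages"]["cluster"] = {"seed": stage_seed(seed, "cluster")}

    if "safe" in stages:
        p = cfg["safe"]
        attrs = bundle["attributes"]
        field = network.safe_enrichment(
            bundle["network"], attrs, p["radius"], p["n_perm"],
            seed=stage_seed(seed, "safe"), alpha=p["alpha"],
        )
        metrics = network.network_metrics(bundle["network"])
        field.merge(metrics, on="gene_id").to_csv(outdir / "safe.tsv", sep="\t", index=False)
        manifest["stages"]["safe"] = {
            "seed": stage_seed(seed, "safe"),
            "n_enriched": int(field["enriched"].sum()),
        }

    if "rank" in stages and de_tables:
        p = cfg["rank"]
        edges = [
            (u, v, d.get("confidence", 1.0))
            for u, v, d in bundle["network"].graph.edges(data=True)
        ]
        biotypes = {g.gene_id: g.biotype for g in genome}
        net = focal.preprocess_interactions(edges, biotypes)
        tables = {}
        for sex, table in de_tables.items():
            lr = dict(zip(table["gene_id"], table["lr"]))
            scores = focal.score_focal_genes(net, lr, p["min_interactors"])
            scores.to_csv(outdir / f"focal_{sex}.tsv", sep="\t", index=False)
            tables[sex] = scores
        top_n = min(p["top_n"], min(len(t) for t in tables.values()))
        shared = focal.intersect_top_ranks(tables["F"], tables["M"], top_n)
        io.write_gene_list(shared, outdir / "focal_shared.txt")
        manifest["stages"]["rank"] = {"seed": stage_seed(seed, "rank"),
                                      "n_shared": len(shared)}

    if "enrich" in stages and de_tables:
        universe = set(counts.index) & set(bundle["modules"]["gene_id"])
        lists = {}
        for sex, table in de_tables.items():
            sig = table.loc[table["fdr"] < cfg["de"]["fdr_threshold"], "gene_id"]
            if len(sig) > 0:
                lists[f"significant_{sex}"] = set(sig)
        if lists:
            battery = enrich.enrichment_battery(lists, bundle["module_sets"], universe)
            battery.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {"seed": stage_seed(seed, "enrich"),
                                        "n_lists": len(lists)}

    if "concord" in stages and de_tables:
        p = cfg["concord"]
        dev = bundle["dev_expression"]
        tree_dev, _ = concordance.hclust_expression(dev)
        # second tree: per-group mean log expression ("reaction norm" profiles)
        sub = counts.loc[counts.index.intersection(dev.index)]
        groups = {}
        for m in metas:
            groups.setdefault(f"{m.sex}_{m.mito}_{m.nuc}", []).append(m.sample_id)
        prof = pd.DataFrame(
            {g: np.log1p(sub[ids]).mean(axis=1) for g, ids in groups.items()}
        )
        prof = prof.loc[sorted(set(prof.index) & tree_dev.leaves)]
        tree_expr, excluded = concordance.hclust_expression(prof)
        shared = sorted(tree_dev.leaves & tree_expr.leaves)
        tree_dev_s = _prune_to(tree_dev, shared)
        stats_out, ua, ub = concordance.compare_dendrograms(
            tree_dev_s, tree_expr, L=p["L"], n_perm=p["n_perm"],
            seed=stage_seed(seed, "concord"),
        )
        table = de_tables["F"]
        members = set(de.top_n_by_pvalue(table, min(100, len(table))))
        scan = concordance.rolling_membership_scan(
            tree_dev_s.leaf_order, members, min(p["window"], tree_dev_s.n_leaves)
        )
        pd.DataFrame([stats_out.as_dict()]).to_csv(
            outdir / "concordance_stats.tsv", sep="\t", index=False
        )
        scan.to_frame().to_csv(outdir / "rolling_sums.tsv", sep="\t", index=False)
        write_newick(ua, outdir / "untangled_dev.nwk")
        write_newick(ub, outdir / "untangled_expr.nwk")
        manifest["stages"]["concord"] = {
            "seed": stage_seed(seed, "concord"),
            "entanglement_raw": stats_out.entanglement_raw,
            "entanglement_untangled": stats_out.entanglement_untangled,
        }

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _prune_to(tree, keep: list[str]):
    """Restrict a dendrogram to a leaf subset, preserving heights."""
    from .dendrogram import Dendrogram, Node

    keep_set = set(keep)

    def rec(node: Node):
        if node.is_leaf:
            return node.copy() if node.label in keep_set else None
        left = rec(node.left)
        right = rec(node.right)
        if left is None:
            return right
        if right is None:
            return left
        return Node(height=node.height, left=left, right=right)

    root = rec(tree.root)
    if root is None:
        raise ValueError("no leaves left after pruning")
    return Dendrogram(root)
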