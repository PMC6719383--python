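import numpy as np
import pandas as pd
import pytest

from mitosense import simulate
from mitosense.clustering import find_max_gap_clusters
from mitosense.simulate import SimConfig


def brute_rank_runs(ranks, max_gap, min_size=2):
    """Independent oracle: scan sorted ranks for max-gap runs."""
    ranks = sorted(ranks)
    runs, current = [], []
    for r in ranks:
        if current and r - current[-1] - 1 > max_gap:
            if len(current) >= min_size:
                runs.append(list(current))
            current = []
        current.append(r)
    if len(current) >= min_size:
        runs.append(current)
    return runs


class TestGenerateGenome:
    def test_construction_invariants(self):
        cfg = SimConfig(seed=0, n_genes=100)
        gt = simulate.generate_genome(cfg)
        assert len(gt) == 100
        for arm in gt.arms:
            genes = gt.arm_genes(arm)
            mids = [g.midpoint for g in genes]
            assert mids == sorted(mids)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start  # non-overlapping

    def test_determinism(self):
        a = simulate.generate_genome(SimConfig(seed=7, n_genes=50))
        b = simulate.generate_genome(SimConfig(seed=7, n_genes=50))
        assert [(g.gene_id, g.arm, g.start, g.end) for g in a] == [
            (g.gene_id, g.arm, g.start, g.end) for g in b
        ]

    def test_empty(self):
        assert len(simulate.generate_genome(SimConfig(seed=0, n_genes=0))) == 0

    def test_too_many_genes_errors(self):
        cfg = SimConfig(seed=0, n_genes=1000, arms=[("2L", 100_000)])
        with pytest.raises(ValueError, match="fit"):
            simulate.generate_genome(cfg)


class TestPlantClusteredGeneSet:
    def test_empty_plan(self):
        gt = simulate.generate_genome(SimConfig(seed=1, n_genes=100))
        test, truth = simulate.plant_clustered_gene_set(gt, 0, 4, 0, 0.0, seed=1)
        assert test == []
        assert not truth["truth_planted"].any()

    def test_planted_runs_are_consecutive(self):
        gt = simulate.generate_genome(SimConfig(seed=1, n_genes=300))
        test, truth = simulate.plant_clustered_gene_set(gt, 5, 4, 0, 0.0, seed=1)
        assert len(test) == 20
        by_arm = {}
        for gid in test:
            arm, rank = gt.locate(gid)
            by_arm.setdefault(arm, []).append(rank)
        runs = [run for ranks in by_arm.values() for run in brute_rank_runs(ranks, 0)]
        assert len(runs) == 5
        assert all(len(r) == 4 for r in runs)

    def test_detection_recovers_planted_clusters(self):
        gt = simulate.generate_genome(SimConfig(seed=2, n_genes=300))
        test, _ = simulate.plant_clustered_gene_set(gt, 5, 4, 2, 0.0, seed=2)
        rep = find_max_gap_clusters(test, gt, max_gap=2, min_size=2)
        assert rep.n_clusters == 5
        assert rep.percent_clustered == 100.0

    def test_cluster_size_too_small(self):
        gt = simulate.generate_genome(SimConfig(seed=1, n_genes=50))
        with pytest.raises(ValueError, match="cluster_size"):
            simulate.plant_clustered_gene_set(gt, 1, 1, 0, 0.0, seed=1)


class TestGenerateCounts:
    def test_poisson_limit(self):
        cfg = SimConfig(seed=3, n_genes=200, dispersion=0.0,
                        effect_gene_fraction=0.0, library_sigma=0.0)
        gt = simulate.generate_genome(cfg)
        counts, metas, _ = simulate.generate_counts(gt, cfg)
        x = counts.to_numpy(dtype=float)
        # pooled variance/mean ratio across genes ~ 1 in the Poisson limit
        ratio = (x.var(axis=1, ddof=1) / np.maximum(x.mean(axis=1), 1e-9)).mean()
        assert 0.8 < ratio < 1.2

    def test_truth_classes_partition(self):
        cfg = SimConfig(seed=3, n_genes=300, effect_gene_fraction=0.1)
        gt = simulate.generate_genome(cfg)
        _, _, truth = simulate.generate_counts(gt, cfg)
        n_effect = (truth["truth_effect"] != "none").sum()
        assert n_effect == 30
        assert set(truth["truth_effect"]) <= {"none", "haplotype", "species", "gxg"}

    def test_gxg_sign_flips_between_backgrounds(self):
        cfg = SimConfig(seed=5, n_genes=200, effect_gene_fraction=0.3,
                        fold_change=6.0, dispersion=0.01, library_sigma=0.0)
        gt = simulate.generate_genome(cfg)
        counts, metas, truth = simulate.generate_counts(gt, cfg)
        gxg = truth.loc[truth["truth_effect"] == "gxg", "gene_id"].iloc[0]
        target = cfg.haplotypes[-1]
        other = cfg.haplotypes[0]

        def mean_for(mito, nuc):
            ids = [m.sample_id for m in metas if m.mito == mito and m.nuc == nuc and m.sex == "F"]
            return counts.loc[gxg, ids].mean()

        delta_bg1 = mean_for(target, "bg1") / mean_for(other, "bg1")
        delta_bg2 = mean_for(target, "bg2") / mean_for(other, "bg2")
        assert delta_bg1 > 2.0 and delta_bg2 < 0.5

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, dispersion=-1.0)
        with pytest.raises(ValueError):
            SimConfig(seed=0, fold_change=0.0)

    def test_determinism(self):
        cfg = SimConfig(seed=9, n_genes=50)
        gt = simulate.generate_genome(cfg)
        c1, _, _ = simulate.generate_counts(gt, cfg)
        c2, _, _ = simulate.generate_counts(gt, cfg)
        assert c1.equals(c2)


class TestGenerateNetwork:
    def test_scale_free_degree_spread(self):
        cfg = SimConfig(seed=4, n_nodes=1000, n_hotspots=0)
        net, attrs, hot = simulate.generate_network_with_hotspots(cfg)
        deg = np.array([d for _, d in net.graph.degree()])
        assert deg.max() > 5 * np.median(deg)
        assert hot == set()

    def test_single_node(self):
        cfg = SimConfig(seed=4, n_nodes=1, n_hotspots=0)
        net, attrs, _ = simulate.generate_network_with_hotspots(cfg)
        assert net.n_nodes == 1 and net.n_edges == 0

    def test_hotspots_are_low_degree(self):
        cfg = SimConfig(seed=4, n_nodes=500, n_hotspots=3, hotspot_boost=5.0)
        net, attrs, hot = simulate.generate_network_with_hotspots(cfg)
        assert len(hot) >= 3
        deg = dict(net.graph.degree())
        hot_deg = np.mean([deg[g] for g in hot])
        rest_deg = np.mean([deg[g] for g in net.nodes if g not in hot])
        assert hot_deg < rest_deg

    def test_boost_applied(self):
        cfg = SimConfig(seed=4, n_nodes=200, n_hotspots=2, hotspot_boost=5.0)
        _, attrs, hot = simulate.generate_network_with_hotspots(cfg)
        hot_mean = np.mean([attrs[g] for g in hot])
        rest_mean = np.mean([a for g, a in attrs.items() if g not in hot])
        assert hot_mean > rest_mean + 3.0

    def test_too_many_hotspots(self):
        cfg = SimConfig(seed=4, n_nodes=12, n_hotspots=12)
        with pytest.raises(ValueError, match="hotspots"):
            simulate.generate_network_with_hotspots(cfg)


class TestGenerateModuleLabels:
    def test_neutral_factor_fold_near_one(self):
        ids = [f"g{i}" for i in range(8000)]
        sens = set(ids[:400])
        table, sets = simulate.generate_module_labels(ids, 0.2, sens, 1.0, seed=0)
        k = len(sets["improper"] & sens)
        expected = len(sens) * len(sets["improper"]) / len(ids)
        fold = k / expected
        # binomial CI around fold 1
        assert 0.7 < fold < 1.3

    def test_infeasible_fraction(self):
        with pytest.raises(ValueError):
            simulate.generate_module_labels(["a"], 1.2, set(), 1.0)

    def test_infeasible_fold_reports_bound(self):
        with pytest.raises(ValueError, match="bound"):
            simulate.generate_module_labels(["a"], 0.5, set(), 3.0)


class TestGenerateDevExpression:
    def test_blocks_separate(self):
        ids = [f"g{i}" for i in range(60)]
        expr, truth = simulate.generate_dev_expression(ids, 10, 2, seed=1)
        blocks = dict(zip(truth["gene_id"], truth["truth_block"]))
        X = expr.to_numpy()
        corr = np.corrcoef(X)
        same = []
        diff = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                (same if blocks[ids[i]] == blocks[ids[j]] else diff).append(corr[i, j])
        assert np.mean(same) > np.mean(diff) + 0.5

    def test_stage_count_validated(self):
        with pytest.raises(ValueError):
            simulate.generate_dev_expression(["a"], 1)

    def test_determinism(self):
        ids = [f"g{i}" for i in range(20)]
        a, _ = simulate.generate_dev_expression(ids, 8, 3, seed=5)
        b, _ = simulate.generate_dev_expression(ids, 8, 3, seed=5)
        assert a.equals(b)


def test_simulate_all_writes_bundle(tmp_path):
    cfg = SimConfig(seed=2, n_genes=120, n_nodes=100, n_hotspots=2)
    bundle = simulate.simulate_all(cfg, tmp_path)
    for name in ["genome.bed", "counts.tsv", "samples.tsv", "network.tsv",
                 "modules.tsv", "dev_expression.tsv", "truth_effects.tsv"]:
        assert (tmp_path / name).exists(), name
    assert len(bundle["genome"]) == 120
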