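"""Max-gap physical clustering of a gene set along chromosome arms.

A cluster is a maximal run of >= min_size test genes on one arm in which
consecutive test genes are separated by at most ``max_gap`` intervening
non-test genes. Gaps are counted in gene ranks, not base pairs, so the
report is invariant to coordinate rescaling; the KS uniformity test, by
contrast, uses physical midpoints scaled by arm extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kstest

from .types import GenomeTable

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    arm: str
    gene_ids: list[str]
    rank_start: int
    rank_end: int  # inclusive rank of the last member

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    n_test_genes: int  # test genes with genome coordinates
    n_excluded: int  # test genes absent from the genome table
    max_gap: int
    min_size: int
    ks_per_arm: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_randomization: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_clustered(self) -> int:
        return sum(c.size for c in self.clusters)

    @property
    def percent_clustered(self) -> float:
        if self.n_test_genes == 0:
            return 0.0
        return 100.0 * self.n_clustered / self.n_test_genes

    @property
    def size_distribution(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.clusters:
            out[c.size] = out.get(c.size, 0) + 1
        return dict(sorted(out.items()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"arm": c.arm, "size": c.size, "rank_start": c.rank_start,
             "rank_end": c.rank_end, "genes": ",".join(c.gene_ids)}
            for c in self.clusters
        ]
        return pd.DataFrame(rows, columns=["arm", "size", "rank_start", "rank_end", "genes"])


def _runs_from_ranks(ranks: np.ndarray, max_gap: int, min_size: int) -> list[tuple[int, int]]:
    """Split sorted ranks where the intervening-gene gap exceeds max_gap."""
    if len(ranks) == 0:
        return []
    breaks = np.where(np.diff(ranks) - 1 > max_gap)[0]
    runs = []
    start = 0
    for b in list(breaks) + [len(ranks) - 1]:
        seg = ranks[start: b + 1]
        if len(seg) >= min_size:
            runs.append((int(seg[0]), int(seg[-1])))
        start = b + 1
    return runs


def find_max_gap_clusters(
    test_set,
    genome: GenomeTable,
    max_gap: int = 5,
    min_size: int = 2,
) -> ClusterReport:
    """Locate max-gap clusters of ``test_set`` genes along each arm."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    present: dict[str, list[tuple[int, str]]] = {}
    n_excluded = 0
    for gid in set(test_set):
        if gid in genome:
            arm, rank = genome.locate(gid)
            present.setdefault(arm, []).append((rank, gid))
        else:
            n_excluded += 1
    if n_excluded:
        logger.info("excluded %d test gene(s) absent from the genome table", n_excluded)
    clusters: list[Cluster] = []
    n_present = sum(len(v) for v in present.values())
    for arm in sorted(present):
        pairs = sorted(present[arm])
        ranks = np.array([r for r, _ in pairs])
        by_rank = dict(pairs)
        for lo, hi in _runs_from_ranks(ranks, max_gap, min_size):
            members = [by_rank[r] for r in ranks[(ranks >= lo) & (ranks <= hi)]]
            clusters.append(Cluster(arm, members, lo, hi))
    return ClusterReport(clusters, n_present, n_excluded, max_gap, min_size)


def ks_uniformity(positions, extent: float) -> tuple[float, float]:
    """Two-sided KS test of positions against Uniform(0, extent).

    Exact p for small n (scipy switches automatically below n=100 via
    mode='auto'); D is the classic sup |ECDF - x| statistic.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("ks_uniformity needs at least one position")
    if extent <= 0:
        raise ValueError("extent must be positive")
    if np.any((positions < 0) | (positions > extent)):
        raise ValueError("positions must lie within [0, extent]")
    res = kstest(positions / extent, "uniform", mode="auto")
    return float(res.statistic), float(res.pvalue)


def ks_per_arm(test_set, genome: GenomeTable, rank_based: bool = False) -> dict[str, tuple[float, float]]:
    """KS uniformity per arm for the test genes present on that arm."""
    out: dict[str, tuple[float, float]] = {}
    ids = set(test_set)
    for arm in genome.arms:
        genes = genome.arm_genes(arm)
        if rank_based:
            pos = [i for i, g in enumerate(genes) if g.gene_id in ids]
            extent = float(len(genes) - 1) if len(genes) > 1 else 1.0
        else:
            pos = [g.midpoint for g in genes if g.gene_id in ids]
            extent = float(genome.arm_extent(arm))
        if pos:
            out[arm] = ks_uniformity(pos, extent)
    return out


@dataclass
class RandomizationNull:
    percent_clustered: np.ndarray
    n_clusters: np.ndarray
    observed_percent: float
    observed_n_clusters: int
    p_percent: float
    p_n_clusters: float
    n_iter: int

    @property
    def p_value(self) -> float:
        return self.p_percent

    def format_p(self) -> str:
        bound = 1.0 / (self.n_iter + 1)
        if self.p_percent <= bound:
            return f"< {bound:.3g}"
        return f"{self.p_percent:.3g}"


def _percent_and_count(arm_idx: np.ndarray, rank_arr: np.ndarray, pick: np.ndarray,
                       max_gap: int, min_size: int) -> tuple[float, int]:
    """Clustering summary for the genes at integer positions ``pick``."""
    arms = arm_idx[pick]
    ranks = rank_arr[pick]
    order = np.lexsort((ranks, arms))
    arms, ranks = arms[order], ranks[order]
    clustered = 0
    n_clusters = 0
    for a in np.unique(arms):
        r = ranks[arms == a]
        for lo, hi in _runs_from_ranks(r, max_gap, min_size):
            n_clusters += 1
            clustered += int(((r >= lo) & (r <= hi)).sum())
    pct = 100.0 * clustered / len(pick) if len(pick) else 0.0
    return pct, n_clusters


def randomization_null(
    genome: GenomeTable,
    list_size: int,
    max_gap: int = 5,
    min_size: int = 2,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    observed_percent: float | None = None,
    observed_n_clusters: int | None = None,
) -> RandomizationNull:
    """Empirical null of clustering summaries over random gene lists.

    p = (1 + #{draws >= observed}) / (n_iter + 1); with no observed value
    supplied the p fields are NaN and only the null sample is returned.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be >= 1")
    if list_size > len(genome):
        raise ValueError("list_size exceeds genome size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arm_idx = []
    rank_arr = []
    for ai, arm in enumerate(genome.arms):
        n = len(genome.arm_genes(arm))
        arm_idx.extend([ai] * n)
        rank_arr.extend(range(n))
    arm_idx = np.array(arm_idx)
    rank_arr = np.array(rank_arr)
    pcts = np.empty(n_iter)
    counts = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        pick = rng.choice(len(arm_idx), size=list_size, replace=False)
        pcts[i], counts[i] = _percent_and_count(arm_idx, rank_arr, pick, max_gap, min_size)
    if observed_percent is None:
        p_pct = float("nan")
    else:
        p_pct = (1 + int((pcts >= observed_percent - 1e-12).sum())) / (n_iter + 1)
    if observed_n_clusters is None:
        p_cnt = float("nan")
    else:
        p_cnt = (1 + int((counts >= observed_n_clusters).sum())) / (n_iter + 1)
    return RandomizationNull(
        pcts, counts,
        float("nan") if observed_percent is None else observed_percent,
        -1 if observed_n_clusters is None else observed_n_clusters,
        p_pct, p_cnt, n_iter,
    )


def analyze_gene_list(
    test_set,
    genome: GenomeTable,
    max_gap: int = 5,
    min_size: int = 2,
    n_iter: int = 1000,
    seed: int = 0,
) -> ClusterReport:
    """Full clustering report: clusters, per-arm KS, randomization p."""
    report = find_max_gap_clusters(test_set, genome, max_gap, min_size)
    report.ks_per_arm = ks_per_arm(test_set, genome)
    null = randomization_null(
        genome, report.n_test_genes, max_gap, min_size, n_iter, seed,
        observed_percent=report.percent_clustered,
        observed_n_clusters=report.n_clusters,
    )
    report.p_randomization = null.p_percent
    return report


def clustering_erosion_scan(
    de_results: pd.DataFrame,
    genome: GenomeTable,
    window: int = 200,
    max_gap: int = 5,
    min_size: int = 2,
    n_iter: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomization p of clustering for sequential p-ranked gene windows.

    Window k covers genes ranked (k-1)*window+1 .. k*window by p-value.
    """
    usable = de_results.dropna(subset=["p_value"]).sort_values(
        ["p_value", "gene_id"], kind="stable"
    )
    ids = [g for g in usable["gene_id"] if g in genome]
    n_windows = len(ids) // window
    if n_windows < 1:
        raise ValueError("fewer genes than one window")
    if n_windows == 1:
        logger.warning("erosion scan degenerates to a single window")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_windows):
        chunk = ids[k * window: (k + 1) * window]
        rep = find_max_gap_clusters(chunk, genome, max_gap, min_size)
        null = randomization_null(
            genome, rep.n_test_genes, max_gap, min_size, n_iter, rng,
            observed_percent=rep.percent_clustered,
        )
        rows.append(
            {"window": k + 1, "n_genes": rep.n_test_genes,
             "percent_clustered": rep.percent_clustered,
             "n_clusters": rep.n_clusters, "p_randomization": null.p_percent}
        )
    return pd.DataFrame(rows)
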