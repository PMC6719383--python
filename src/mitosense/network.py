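"""Neighborhood attribute enrichment on interaction networks.

Each node's neighborhood is the unweighted shortest-path ball of radius
``d`` (including the node itself). The neighborhood attribute sum is
compared against a permutation null that shuffles attribute values over
nodes; per-node empirical p uses the +1 correction and heat is
``-log10 p``.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats

from .de import bh_adjust
from .types import InteractionNetwork

logger = logging.getLogger(__name__)


def neighborhoods(net: InteractionNetwork, radius: int = 1) -> dict:
    """Per-node sets of nodes within shortest-path distance <= radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    g = net.undirected_view()
    out = {}
    for node in g.nodes:
        reach = nx.single_source_shortest_path_length(g, node, cutoff=radius)
        out[node] = frozenset(reach)
    return out


def _membership_matrix(nodes: list, hoods: dict) -> sparse.csr_matrix:
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for n, hood in hoods.items():
        i = idx[n]
        for m in hood:
            rows.append(i)
            cols.append(idx[m])
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))


def safe_enrichment(
    net: InteractionNetwork,
    attributes: dict[str, float],
    radius: int = 1,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    batch: int = 200,
) -> pd.DataFrame:
    """Permutation enrichment of neighborhood attribute sums.

    ``attributes`` maps gene_id -> -log10 p (>= 0); genes missing from
    the map are imputed as 0 with a logged count. Returns a per-node
    frame with columns (gene_id, n_neighbors, attr_sum, p_empirical,
    heat, fdr, enriched).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be >= 1")
    nodes = sorted(net.nodes)
    missing = sum(1 for n in nodes if n not in attributes)
    if missing:
        logger.info("imputed attribute 0 for %d/%d node(s)", missing, len(nodes))
    a = np.array([float(attributes.get(n, 0.0)) for n in nodes])
    if not np.all(np.isfinite(a)):
        raise ValueError("attributes must be finite")
    hoods = neighborhoods(net, radius)
    M = _membership_matrix(nodes, hoods)
    observed = M @ a
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = np.zeros(len(nodes), dtype=int)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        P = np.empty((len(nodes), b))
        for j in range(b):
            P[:, j] = rng.permutation(a)
        sums = M @ P
        exceed += (sums >= observed[:, None] - 1e-12).sum(axis=1)
        done += b
    p = (1 + exceed) / (n_perm + 1)
    heat = -np.log10(p)
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": nodes,
            "n_neighbors": [len(hoods[n]) for n in nodes],
            "attr_sum": observed,
            "p_empirical": p,
            "heat": heat,
            "fdr": fdr,
            "enriched": p < alpha,
        }
    )


def network_metrics(net: InteractionNetwork) -> pd.DataFrame:
    """Degree and neighborhood connectivity (mean degree of direct neighbors).

    Isolated nodes get NaN neighborhood connectivity (reported missing).
    """
    g = net.undirected_view()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(g.degree())
    rows = []
    for n in sorted(g.nodes):
        nbrs = list(g.neighbors(n))
        nc = float(np.mean([deg[m] for m in nbrs])) if nbrs else float("nan")
        rows.append({"gene_id": n, "degree": deg[n], "neighborhood_connectivity": nc})
    return pd.DataFrame(rows)


def compare_groups_welch(values: dict[str, float], group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t-test of a metric between two gene-id groups.

    Returns (t, satterthwaite df, two-sided p). Degenerate case of zero
    variance in both groups with equal means yields (0, nan, 1).
    """
    a = np.array([values[g] for g in group_a if g in values and np.isfinite(values[g])])
    b = np.array([values[g] for g in group_b if g in values and np.isfinite(values[g])])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float("nan"), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
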