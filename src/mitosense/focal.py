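"""Focal-gene neighborhood scoring on a scored interaction network.

A focal gene is scored by the mean likelihood-ratio statistic of its
direct interactors (the focal gene's own LR never enters its score);
focal genes are ranked by descending mean LR with a lexicographic
tie-break, and top-n lists from the two sexes are intersected.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import InteractionNetwork

logger = logging.getLogger(__name__)


def preprocess_interactions(
    edges,
    biotypes: dict[str, str] | None = None,
) -> InteractionNetwork:
    """Normalize a raw scored edge list for focal scoring.

    Steps, in order: drop edges without a confidence score; drop edges
    incident to miRNA genes; reciprocally invert (every kept edge is
    present in both directions); collapse exact duplicates.
    """
    biotypes = biotypes or {}
    g = nx.DiGraph()
    n_unscored = 0
    n_mirna = 0
    for e in edges:
        u, v = e[0], e[1]
        conf = e[2] if len(e) > 2 else None
        if conf is None:
            n_unscored += 1
            continue
        if biotypes.get(u) == "miRNA" or biotypes.get(v) == "miRNA":
            n_mirna += 1
            continue
        if u == v:
            continue
        conf = float(conf)
        if not g.has_edge(u, v):
            g.add_edge(u, v, confidence=conf)
        if not g.has_edge(v, u):
            g.add_edge(v, u, confidence=conf)
    logger.info(
        "preprocess: dropped %d unscored and %d miRNA-incident edge(s); kept %d directed edges",
        n_unscored, n_mirna, g.number_of_edges(),
    )
    return InteractionNetwork(g, directed=True)


def score_focal_genes(
    net: InteractionNetwork,
    lr_values: dict[str, float],
    min_interactors: int = 1,
) -> pd.DataFrame:
    """Mean-LR-of-interactors score per focal gene.

    Interactors without an LR value are excluded from the mean (and
    logged); focal genes with fewer than ``min_interactors`` scored
    interactors are dropped. Returns a frame sorted by descending
    mean_lr (lexicographic gene_id tie-break) with a 1-based rank.
    """
    if min_interactors < 1:
        raise ValueError("min_interactors must be >= 1")
    rows = []
    n_unscored_neighbors = 0
    for gene in net.nodes:
        nbrs = net.neighbors(gene)
        scored = [lr_values[m] for m in nbrs if m in lr_values]
        n_unscored_neighbors += len(nbrs) - len(scored)
        if len(scored) < min_interactors:
            continue
        rows.append(
            {"gene_id": gene, "mean_lr": float(np.mean(scored)), "n_interactors": len(scored)}
        )
    if n_unscored_neighbors:
        logger.info("excluded %d interactor slot(s) lacking LR values", n_unscored_neighbors)
    if not rows:
        raise ValueError("no focal gene passes the min_interactors filter")
    df = pd.DataFrame(rows).sort_values(
        ["mean_lr", "gene_id"], ascending=[False, True], kind="stable"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def intersect_top_ranks(scores_a: pd.DataFrame, scores_b: pd.DataFrame, top_n: int = 200) -> list[str]:
    """Intersection of the two top-n gene sets, sorted for determinism."""
    for df in (scores_a, scores_b):
        if top_n > len(df):
            raise ValueError(f"top_n={top_n} exceeds a score table of {len(df)}")
    a = set(scores_a.sort_values("rank")["gene_id"].head(top_n))
    b = set(scores_b.sort_values("rank")["gene_id"].head(top_n))
    return sorted(a & b)


def interactor_count_sensitivity(
    scores: pd.DataFrame,
    thresholds=(1, 2, 3, 5),
    top_n: int = 200,
) -> tuple[pd.DataFrame, tuple[float, int, float]]:
    """Stability of top ranks under minimum-interactor thresholds.

    For each threshold, the Jaccard overlap of the top-n set (after
    re-filtering) against the threshold=1 baseline; plus the Pearson
    correlation between n_interactors and mean_lr (df = n - 2).
    Constant mean_lr makes r undefined -> (nan, df, nan).
    """
    if len(scores) < 3:
        raise ValueError("need >= 3 scored focal genes")
    base = set(scores.sort_values("rank")["gene_id"].head(min(top_n, len(scores))))
    rows = []
    for t in thresholds:
        sub = scores[scores["n_interactors"] >= t]
        top = set(
            sub.sort_values(["mean_lr", "gene_id"], ascending=[False, True])["gene_id"]
            .head(min(top_n, len(sub)))
        )
        denom = len(base | top)
        rows.append(
            {"min_interactors": t, "n_genes": len(sub),
             "jaccard_vs_baseline": len(base & top) / denom if denom else float("nan")}
        )
    x = scores["n_interactors"].to_numpy(dtype=float)
    y = scores["mean_lr"].to_numpy(dtype=float)
    df_corr = len(scores) - 2
    if np.std(y) == 0 or np.std(x) == 0:
        logger.warning("correlation undefined: zero variance")
        corr = (float("nan"), df_corr, float("nan"))
    else:
        r, p = stats.pearsonr(x, y)
        corr = (float(r), df_corr, float(p))
    return pd.DataFrame(rows), corr
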