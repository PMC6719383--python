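"""Hypergeometric over/under gene-set enrichment with a permutation null.

All counting is restricted to an explicitly supplied universe; genes
outside the universe never affect any count. Both tails of the exact
hypergeometric are always reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class OverlapTest:
    """Exact hypergeometric overlap between a test list and an annotated set."""

    N: int  # universe size
    K: int  # annotated genes within the universe
    n: int  # test genes within the universe
    k: int  # observed overlap
    list_name: str = ""
    set_name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError("k must satisfy 0 <= k <= min(n, K)")

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N

    @property
    def fold(self) -> float:
        return self.k / self.expected if self.expected > 0 else float("nan")

    @property
    def p_upper(self) -> float:
        """P(X >= k), exact tail sum."""
        return float(hypergeom.sf(self.k - 1, self.N, self.K, self.n))

    @property
    def p_lower(self) -> float:
        """P(X <= k)."""
        return float(hypergeom.cdf(self.k, self.N, self.K, self.n))

    @property
    def p_headline(self) -> float:
        """Tail chosen by fold direction (over -> upper, under -> lower)."""
        return self.p_upper if self.fold >= 1 else self.p_lower

    def as_dict(self) -> dict:
        return {
            "list": self.list_name, "set": self.set_name,
            "N": self.N, "K": self.K, "n": self.n, "k": self.k,
            "expected": self.expected, "fold": self.fold,
            "p_upper": self.p_upper, "p_lower": self.p_lower,
        }


def hypergeom_overlap(test_list, annotated_set, universe,
                      list_name: str = "", set_name: str = "") -> OverlapTest:
    """Exact overlap test after restricting both inputs to the universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    test = set(test_list) & universe
    if not test:
        raise ValueError("test list empty after restriction to universe")
    annotated = set(annotated_set) & universe
    return OverlapTest(
        N=len(universe), K=len(annotated), n=len(test),
        k=len(test & annotated), list_name=list_name, set_name=set_name,
    )


@dataclass
class PermutationOverlapNull:
    overlaps: np.ndarray
    observed: int | None
    mean_overlap: float
    p_upper: float
    p_lower: float
    p_two_sided: float
    n_iter: int


def permutation_overlap_null(
    universe,
    n: int,
    annotated_set,
    n_iter: int = 10000,
    seed: int | np.random.Generator = 0,
    observed: int | None = None,
) -> PermutationOverlapNull:
    """Null overlap distribution from random same-size gene draws.

    Draws are without replacement from the universe; empirical p-values
    use the +1 correction and the two-sided p is 2*min(tails) capped at 1.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be >= 1")
    universe = sorted(set(universe))
    if n > len(universe):
        raise ValueError("n exceeds universe size")
    annotated = np.array([g in set(annotated_set) for g in universe])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    overlaps = np.empty(n_iter, dtype=int)
    m = len(universe)
    for i in range(n_iter):
        pick = rng.choice(m, size=n, replace=False)
        overlaps[i] = int(annotated[pick].sum())
    if observed is None:
        pu = pl = p2 = float("nan")
    else:
        pu = (1 + int((overlaps >= observed).sum())) / (n_iter + 1)
        pl = (1 + int((overlaps <= observed).sum())) / (n_iter + 1)
        p2 = min(1.0, 2 * min(pu, pl))
    return PermutationOverlapNull(
        overlaps, observed, float(overlaps.mean()), pu, pl, p2, n_iter
    )


def enrichment_battery(
    test_lists: dict[str, set],
    annotated_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """All (list, set) hypergeometric tests with BH-FDR on the headline p.

    Annotated sets disjoint from the universe yield a flagged row
    (k = K = 0, p = NaN) rather than being dropped.
    """
    universe = set(universe)
    rows = []
    for lname in sorted(test_lists):
        for sname in sorted(annotated_sets):
            annotated = set(annotated_sets[sname]) & universe
            if not annotated:
                logger.warning("set %s disjoint from universe; row flagged", sname)
                rows.append(
                    {"list": lname, "set": sname, "N": len(universe), "K": 0,
                     "n": len(set(test_lists[lname]) & universe), "k": 0,
                     "expected": 0.0, "fold": float("nan"),
                     "p_upper": float("nan"), "p_lower": float("nan"),
                     "p_headline": float("nan")}
                )
                continue
            ot = hypergeom_overlap(test_lists[lname], annotated, universe, lname, sname)
            row = ot.as_dict()
            row["p_headline"] = ot.p_headline
            rows.append(row)
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p_headline"].to_numpy())
    return df
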