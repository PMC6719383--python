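"""Shared domain types: genes, samples, DE results, interaction networks.

Coordinate convention: all intervals are 0-based half-open internally.
BED files are read as-is; GFF3 1-based inclusive coordinates are shifted
on input. All chromosomal linearization uses the gene midpoint
``(start + end) / 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}
BIOTYPES = {"protein_coding", "ncRNA", "miRNA", "other"}


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval on a chromosome arm (0-based half-open)."""

    gene_id: str
    arm: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.arm:
            raise ValueError(f"{self.gene_id}: arm must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class GenomeTable:
    """An ordered genome: per-arm gene lists sorted by midpoint.

    Ties on midpoint are broken lexicographically by ``gene_id`` so the
    rank order is a deterministic total order within each arm.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        records = list(records)
        seen: set[str] = set()
        for r in records:
            if r.gene_id in seen:
                raise ValueError(f"duplicate gene_id: {r.gene_id}")
            seen.add(r.gene_id)
        by_arm: dict[str, list[GeneRecord]] = {}
        for r in records:
            by_arm.setdefault(r.arm, []).append(r)
        for arm in by_arm:
            by_arm[arm].sort(key=lambda g: (g.midpoint, g.gene_id))
        self._by_arm = dict(sorted(by_arm.items()))
        self._index: dict[str, tuple[str, int]] = {}
        for arm, genes in self._by_arm.items():
            for rank, g in enumerate(genes):
                self._index[g.gene_id] = (arm, rank)

    @property
    def arms(self) -> list[str]:
        return list(self._by_arm)

    def arm_genes(self, arm: str) -> list[GeneRecord]:
        return list(self._by_arm[arm])

    def arm_extent(self, arm: str) -> int:
        """Span covered by genes on an arm (max end), used for KS scaling."""
        return max(g.end for g in self._by_arm[arm])

    def locate(self, gene_id: str) -> tuple[str, int]:
        """Return (arm, within-arm rank) of a gene."""
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    def __iter__(self) -> Iterator[GeneRecord]:
        for arm in self._by_arm:
            yield from self._by_arm[arm]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self]

    def record(self, gene_id: str) -> GeneRecord:
        arm, rank = self._index[gene_id]
        return self._by_arm[arm][rank]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq sample."""

    sample_id: str
    sex: str
    mito: str
    nuc: str
    replicate: int

    def __post_init__(self) -> None:
        if self.sex not in {"F", "M"}:
            raise ValueError(f"{self.sample_id}: sex must be F or M")


def validate_sample_metas(metas: Sequence[SampleMeta]) -> None:
    keys = [(m.sex, m.mito, m.nuc, m.replicate) for m in metas]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (sex, mito, nuc, replicate) in sample metadata")


@dataclass
class DEResult:
    """Per-gene likelihood-ratio contrast result."""

    gene_id: str
    contrast: str
    sex: str
    lr: float
    df: int
    p_value: float
    fdr: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError(f"{self.gene_id}: lr must be >= 0")
        if self.df < 1:
            raise ValueError(f"{self.gene_id}: df must be >= 1")


class InteractionNetwork:
    """Scored interaction edges over gene nodes.

    Wraps a networkx graph; after deduplication each ordered pair appears
    once. Confidence scores, when present, live on the ``confidence``
    edge attribute.
    """

    def __init__(self, graph: nx.Graph | nx.DiGraph, directed: bool | None = None):
        self.graph = graph
        self.directed = graph.is_directed() if directed is None else directed

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        directed: bool = False,
        allow_self_loops: bool = False,
    ) -> "InteractionNetwork":
        """Build from (source, target[, confidence]) tuples.

        Self-loops are rejected (with a logged count) unless allowed;
        duplicate ordered pairs collapse to one edge, keeping the first
        confidence seen.
        """
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
        n_self = 0
        for e in edges:
            u, v = e[0], e[1]
            conf = e[2] if len(e) > 2 else None
            if u == v and not allow_self_loops:
                n_self += 1
                continue
            if g.has_edge(u, v):
                continue
            if conf is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, confidence=float(conf))
        if n_self:
            logger.warning("rejected %d self-loop edge(s)", n_self)
        return cls(g, directed=directed)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node) -> list:
        """Direct interactors (successors in a directed network)."""
        if self.directed:
            return list(self.graph.successors(node))
        return list(self.graph.neighbors(node))

    def undirected_view(self) -> nx.Graph:
        if self.directed:
            return self.graph.to_undirected(as_view=False)
        return self.graph

    def edge_confidence(self, u, v) -> float | None:
        return self.graph.edges[u, v].get("confidence")
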