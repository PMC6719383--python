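import numpy as np
import pytest

from mitosense.dendrogram import Dendrogram, Node
from mitosense.types import GeneRecord, GenomeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genome(n: int, arm: str = "2L", spacing: int = 1000, gene_len: int = 500,
                prefix: str = "g") -> GenomeTable:
    """A single-arm genome with evenly spaced genes, rank i == gene gi."""
    records = [
        GeneRecord(f"{prefix}{i:03d}", arm, i * spacing, i * spacing + gene_len)
        for i in range(n)
    ]
    return GenomeTable(records)


def random_tree(labels, rng, height_step: float = 1.0) -> Dendrogram:
    """Random binary merge tree over the given labels with increasing heights."""
    nodes = [Node(label=str(lab)) for lab in labels]
    height = 0.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        height += float(rng.uniform(0.1, height_step))
        nodes.append(Node(height=height, left=a, right=b))
    return Dendrogram(nodes[0])


@pytest.fixture
def small_genome():
    return make_genome(30)


@pytest.fixture
def tiny_tree():
    # ((A:1,B:1):1,C:2);
    ab = Node(height=1.0, left=Node(label="A"), right=Node(label="B"))
    return Dendrogram(Node(height=2.0, left=ab, right=Node(label="C")))
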