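import random

import pytest

from gralign.graph import BidirectedEdge, BidirectedGraph, BidirectedNode
from gralign.alignment_graph import build_alignment_graph


def random_bidirected_graph(rng: random.Random, max_nodes: int = 5,
                            max_label: int = 12, max_overlap: int = 3):
    """Small random graph with mixed orientations and overlap edges."""
    n = rng.randint(1, max_nodes)
    nodes = [
        BidirectedNode(
            f"n{i}",
            "".join(rng.choice("ACGT") for _ in range(rng.randint(1, max_label))),
        )
        for i in range(n)
    ]
    g = BidirectedGraph(nodes)
    for _ in range(rng.randint(0, n + 2)):
        a, b = rng.choice(nodes), rng.choice(nodes)
        try:
            g.add_edge(
                BidirectedEdge(
                    a.id, rng.choice("+-"), b.id, rng.choice("+-"),
                    rng.randint(0, max_overlap),
                )
            )
        except Exception:
            pass
    return g


def random_dag(rng: random.Random, max_nodes: int = 12):
    """Random DAG as adjacency lists over 0..n-1 (edges low -> high)."""
    n = rng.randint(2, max_nodes)
    out = {v: [] for v in range(n)}
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < 0.3:
                out[u].append(v)
    return out


class DirectedStub:
    """Minimal directed-graph object with the adjacency surface the
    superbubble detector expects (out, inn, labels)."""

    def __init__(self, out: dict[int, list[int]], labels: dict[int, str] | None = None):
        n = max(out) + 1 if out else 0
        self.out = [sorted(out.get(v, [])) for v in range(n)]
        self.inn = [[] for _ in range(n)]
        for u, vs in out.items():
            for v in vs:
                self.inn[v].append(u)
        for adj in self.inn:
            adj.sort()
        self.labels = [
            (labels or {}).get(v, "A") for v in range(n)
        ]
        self.n_nodes = n


@pytest.fixture
def linear_graph():
    """One 4 kb node: sequence-to-sequence alignment as a special case."""
    rng = random.Random(4242)
    label = "".join(rng.choice("ACGT") for _ in range(4000))
    return BidirectedGraph([BidirectedNode("chr", label)])


@pytest.fixture
def snp_bubble_graph():
    """Backbone - (A|C) - backbone: the smallest variation bubble."""
    g = BidirectedGraph(
        [
            BidirectedNode("left", "ACGTACGTAC"),
            BidirectedNode("ref", "A"),
            BidirectedNode("alt", "C"),
            BidirectedNode("right", "TTGCAAGGTC"),
        ]
    )
    for a, b in [("left", "ref"), ("left", "alt"), ("ref", "right"), ("alt", "right")]:
        g.add_edge(BidirectedEdge(a, "+", b, "+", 0))
    return g


@pytest.fixture
def fig_style_overlap_graph():
    """Three nodes with variable overlaps (1 and 2) on the edges."""
    g = BidirectedGraph(
        [
            BidirectedNode("a", "ACGT"),
            BidirectedNode("b", "GTCA"),
            BidirectedNode("c", "TAGC"),
        ]
    )
    g.add_edge(BidirectedEdge("a", "+", "b", "+", 1))
    g.add_edge(BidirectedEdge("b", "+", "c", "+", 2))
    return g
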