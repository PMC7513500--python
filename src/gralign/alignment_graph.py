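"""Conversion of a bidirected graph into the directed *alignment graph*.

The DP engine runs on a plain directed, node-labelled graph.  Each bidirected
node contributes two traversals (forward label and reverse-complemented label),
each chopped into chunks of at most 64 bp.  Chop positions ("breakpoints") come
from two sources: every edge overlap entering a traversal (so that a path
crossing an edge with overlap n can land *after* the n shared bases and never
spell them twice), and a fixed breakpoint every 64 bp so chunk labels fit one
machine word.

Every base pair of the alignment graph maps back to a (node, offset,
orientation) base pair of the bidirected graph through the mapping tables; the
``pos`` function below is that bijection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import BidirectedGraph, opposite
from .seq import reverse_complement

WORD = 64


@dataclass(frozen=True)
class AlignmentNode:
    aid: int
    label: str


@dataclass
class BreakpointSets:
    """Per source node: chop positions for the forward and backward traversal.

    Backward breakpoints index into the reverse-complemented label.  Both sets
    always contain 0 and the label length.
    """

    forward: dict[str, list[int]] = field(default_factory=dict)
    backward: dict[str, list[int]] = field(default_factory=dict)

    def of(self, nid: str, orient: str) -> list[int]:
        return self.forward[nid] if orient == "+" else self.backward[nid]


@dataclass
class MappingTables:
    """Arrays tying every alignment-graph chunk to its source base pairs."""

    N: list[str]          # aid -> source node id
    O: list[int]          # aid -> start offset within the traversal's frame
    D: list[str]          # aid -> traversal orientation
    A: dict[str, tuple[list[int], list[int]]]  # node -> (fwd aids, bwd aids)
    node_len: dict[str, int]

    def pos(self, aid: int, o: int, label_len: int) -> tuple[str, int, str]:
        if not 0 <= o < label_len:
            raise IndexError(f"offset {o} out of range for chunk {aid}")
        nid = self.N[aid]
        if self.D[aid] == "+":
            return (nid, self.O[aid] + o, "+")
        return (nid, self.node_len[nid] - (self.O[aid] + o) - 1, "-")

    def chunk_at(self, nid: str, orient: str, offset: int) -> tuple[int, int]:
        """(aid, offset-within-chunk) of a traversal-frame base position."""
        aids = self.A[nid][0 if orient == "+" else 1]
        for aid in aids:
            if self.O[aid] <= offset:
                last = aid
            else:
                break
        return last, offset - self.O[last]


class AlignmentGraph:
    """Directed graph of <=64 bp chunks with dense integer ids."""

    def __init__(self) -> None:
        self.labels: list[str] = []
        self.out: list[list[int]] = []
        self.inn: list[list[int]] = []
        self._edges: set[tuple[int, int]] = set()

    def add_node(self, label: str) -> int:
        aid = len(self.labels)
        self.labels.append(label)
        self.out.append([])
        self.inn.append([])
        return aid

    def add_edge(self, u: int, v: int) -> None:
        if (u, v) in self._edges:
            return
        self._edges.add((u, v))
        self.out[u].append(v)
        self.inn[v].append(u)

    def finalize(self) -> None:
        for adj in self.out:
            adj.sort()
        for adj in self.inn:
            adj.sort()

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self):
        return sorted(self._edges)

    def total_label_length(self) -> int:
        return sum(len(l) for l in self.labels)

    def debug_gfa(self) -> str:
        out = ["H\tVN:Z:1.0"]
        for aid, lab in enumerate(self.labels):
            out.append(f"S\t{aid}\t{lab}")
        for u, v in self.edges():
            out.append(f"L\t{u}\t+\t{v}\t+\t0M")
        return "\n".join(out) + "\n"


def compute_breakpoints(g: BidirectedGraph) -> BreakpointSets:
    """Chop positions per node: edge overlaps plus every multiple of 64."""
    bps = BreakpointSets()
    fwd: dict[str, set[int]] = {}
    bwd: dict[str, set[int]] = {}
    for nid, node in g.nodes.items():
        l = len(node.label)
        base = set(range(0, l, WORD)) | {0, l}
        fwd[nid] = set(base)
        bwd[nid] = set(base)
    for e in g.all_edge_members():
        # e enters the 'to' node's traversal with to_orient, skipping overlap bases
        (fwd if e.to_orient == "+" else bwd)[e.to_id].add(e.overlap)
    for nid in g.nodes:
        bps.forward[nid] = sorted(fwd[nid])
        bps.backward[nid] = sorted(bwd[nid])
    return bps


def build_alignment_graph(g: BidirectedGraph) -> tuple[AlignmentGraph, MappingTables]:
    """Chop every traversal at its breakpoints and wire chunk and edge links.

    Each bidirected edge (v1,o1,v2,o2,m) yields a directed edge from the last
    chunk of traversal (v1,o1) to the chunk of (v2,o2) starting at offset m,
    and the mirrored edge between the opposite traversals.  Total label length
    of the result is exactly twice that of the input.
    """
    bps = compute_breakpoints(g)
    ag = AlignmentGraph()
    N: list[str] = []
    O: list[int] = []
    D: list[str] = []
    A: dict[str, tuple[list[int], list[int]]] = {}
    start_of: dict[tuple[str, str, int], int] = {}  # (node, orient, breakpoint) -> aid
    last_of: dict[tuple[str, str], int] = {}

    for nid in sorted(g.nodes):
        fwd_aids: list[int] = []
        bwd_aids: list[int] = []
        for orient, aids in (("+", fwd_aids), ("-", bwd_aids)):
            frame = g.node_seq(nid, orient)
            cuts = bps.of(nid, orient)
            prev_aid = None
            for m, m2 in zip(cuts, cuts[1:]):
                aid = ag.add_node(frame[m:m2])
                N.append(nid)
                O.append(m)
                D.append(orient)
                aids.append(aid)
                start_of[(nid, orient, m)] = aid
                if prev_aid is not None:
                    ag.add_edge(prev_aid, aid)
                prev_aid = aid
            last_of[(nid, orient)] = prev_aid
        A[nid] = (fwd_aids, bwd_aids)

    for e in g.edges():
        ag.add_edge(last_of[(e.from_id, e.from_orient)],
                    start_of[(e.to_id, e.to_orient, e.overlap)])
        ag.add_edge(last_of[(e.to_id, opposite(e.to_orient))],
                    start_of[(e.from_id, opposite(e.from_orient), e.overlap)])
    ag.finalize()

    tables = MappingTables(
        N=N, O=O, D=D, A=A,
        node_len={nid: len(n.label) for nid, n in g.nodes.items()},
    )
    assert ag.total_label_length() == 2 * g.total_label_length()
    return ag, tables


def pos(tables: MappingTables, ag: AlignmentGraph, aid: int, o: int) -> tuple[str, int, str]:
    """Map an alignment-graph base pair to (source node, offset, orientation)."""
    return tables.pos(aid, o, len(ag.labels[aid]))
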