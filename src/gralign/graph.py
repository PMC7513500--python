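"""Bidirected genome graphs and GFA 1.0 I/O.

A bidirected graph stores DNA in its nodes.  A node may be traversed forward
('+', reading the label) or backward ('-', reading the reverse complement).
Edges join node *ends* and carry an exact overlap length in nucleotides: when a
path crosses an edge with overlap n, the first n bases of the target traversal
are the same bases as the last n of the source traversal, and are consumed only
once.  This model covers de Bruijn graphs (uniform k-1 overlaps), assembly
graphs (variable overlaps) and variation graphs (overlap 0).

An edge (v1, o1, v2, o2, n) is equivalent to its reverse (v2, ~o2, v1, ~o1, n):
storing either makes both queryable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .seq import reverse_complement, SequenceError, _VALID


class GFAError(ValueError):
    """Malformed or unsupported GFA input."""


def opposite(o: str) -> str:
    return "-" if o == "+" else "+"


@dataclass(frozen=True)
class BidirectedNode:
    id: str
    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"node {self.id!r}: empty label")


@dataclass(frozen=True)
class BidirectedEdge:
    """One representative of a bidirected edge equivalence class."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: int = 0

    def reverse(self) -> "BidirectedEdge":
        return BidirectedEdge(
            self.to_id, opposite(self.to_orient),
            self.from_id, opposite(self.from_orient), self.overlap,
        )

    def key(self) -> tuple:
        return (self.from_id, self.from_orient, self.to_id, self.to_orient, self.overlap)

    def canonical(self) -> "BidirectedEdge":
        rev = self.reverse()
        return self if self.key() <= rev.key() else rev


class BidirectedGraph:
    """Node set plus an edge set closed under the reverse-equivalence."""

    def __init__(
        self,
        nodes: Iterable[BidirectedNode] = (),
        edges: Iterable[BidirectedEdge] = (),
    ) -> None:
        self.nodes: dict[str, BidirectedNode] = {}
        self._edges: set[tuple] = set()  # canonical keys
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- construction ---------------------------------------------------

    def add_node(self, node: BidirectedNode) -> None:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, edge: BidirectedEdge) -> None:
        for nid in (edge.from_id, edge.to_id):
            if nid not in self.nodes:
                raise GFAError(f"edge endpoint {nid!r} is not a node in the graph")
        la = len(self.nodes[edge.from_id].label)
        lb = len(self.nodes[edge.to_id].label)
        if edge.overlap >= min(la, lb):
            raise GFAError(
                f"edge {edge.key()}: overlap {edge.overlap} not smaller than both "
                f"endpoint labels ({la}, {lb})"
            )
        self._edges.add(edge.canonical().key())

    # -- queries --------------------------------------------------------

    def edges(self) -> Iterator[BidirectedEdge]:
        """Yield one canonical representative per edge equivalence class."""
        for k in sorted(self._edges):
            yield BidirectedEdge(*k)

    def all_edge_members(self) -> Iterator[BidirectedEdge]:
        """Yield both members of every equivalence class (self-reverse once)."""
        for e in self.edges():
            yield e
            r = e.reverse()
            if r.key() != e.key():
                yield r

    def has_edge(self, e: BidirectedEdge) -> bool:
        return e.canonical().key() in self._edges

    def label(self, nid: str) -> str:
        return self.nodes[nid].label

    def node_seq(self, nid: str, orient: str) -> str:
        lab = self.nodes[nid].label
        return lab if orient == "+" else reverse_complement(lab)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def total_label_length(self) -> int:
        return sum(len(n.label) for n in self.nodes.values())


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def _parse_overlap(cigar: str, lineno: int) -> int:
    if cigar == "*" or cigar == "0M":
        return 0
    if cigar.endswith("M") and cigar[:-1].isdigit():
        return int(cigar[:-1])
    raise GFAError(
        f"line {lineno}: unsupported overlap CIGAR {cigar!r} "
        "(only exact-match overlaps '*' or '<n>M' are supported)"
    )


def parse_gfa(stream: Iterable[str]) -> BidirectedGraph:
    """Parse GFA 1.0 S- and L-lines into a :class:`BidirectedGraph`.

    Lowercase sequence is uppercased.  GFA 2.0 and walk/path line types are
    rejected; other line types (H, C, comments) are skipped.  Dangling edge
    endpoints and non-exact-match overlaps raise :class:`GFAError`.
    """
    g = BidirectedGraph()
    pending: list[tuple[int, BidirectedEdge]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        tag = line.split("\t", 1)[0]
        if tag == "S":
            fields = line.split("\t")
            if len(fields) < 3:
                raise GFAError(f"line {lineno}: S-line needs id and sequence")
            sid, seqf = fields[1], fields[2]
            if seqf == "*":
                raise GFAError(f"line {lineno}: S-line without an explicit sequence")
            seqf = seqf.upper()
            if set(seqf) - _VALID:
                raise GFAError(f"line {lineno}: non-IUPAC characters in sequence")
            try:
                g.add_node(BidirectedNode(sid, seqf))
            except ValueError as e:
                raise GFAError(f"line {lineno}: {e}") from None
        elif tag == "L":
            fields = line.split("\t")
            if len(fields) < 6:
                raise GFAError(f"line {lineno}: L-line needs 5 fields")
            _, fid, fo, tid, to, cig = fields[:6]
            if fo not in "+-" or to not in "+-":
                raise GFAError(f"line {lineno}: bad orientation in L-line")
            ov = _parse_overlap(cig, lineno)
            pending.append((lineno, BidirectedEdge(fid, fo, tid, to, ov)))
        elif tag in ("E", "F", "G", "O", "U"):
            raise GFAError(f"line {lineno}: GFA 2.0 line type {tag!r} is not supported")
        elif tag in ("W", "P"):
            raise GFAError(f"line {lineno}: {tag}-lines (paths/walks) are not supported")
        # H, C, comments and unknown tags: ignored
    for lineno, e in pending:
        try:
            g.add_edge(e)
        except GFAError as e2:
            raise GFAError(f"line {lineno}: {e2}") from None
    return g


def write_gfa(g: BidirectedGraph) -> str:
    """Serialize to GFA 1.0; round-trips through :func:`parse_gfa`."""
    out = ["H\tVN:Z:1.0"]
    for nid in sorted(g.nodes):
        out.append(f"S\t{nid}\t{g.nodes[nid].label}")
    for e in g.edges():
        out.append(f"L\t{e.from_id}\t{e.from_orient}\t{e.to_id}\t{e.to_orient}\t{e.overlap}M")
    return "\n".join(out) + "\n"
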