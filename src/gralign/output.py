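"""Alignment records, primary/supplementary selection, GAF output, and
corrected-read extraction.

A :class:`GraphAlignment` is a path of oriented bidirected-graph nodes with a
half-open read interval, a half-open interval on the path's spelled sequence
(overlap bases attributed to the earlier node), the unit-cost edit score, and
a CIGAR.  Selection is the greedy longest-first rule: alignments are kept as
long as their read intervals do not overlap an already-kept one; the first
kept is primary, later kept ones supplementary, the rest secondary (dropped
unless asked for).

Error-corrected reads replace each aligned read interval with the sequence
spelled by the alignment's graph path: *full* mode keeps unaligned stretches
of the read verbatim in one output sequence, *clip* mode emits one sub-read
per alignment containing only corrected sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment_graph import AlignmentGraph, MappingTables
from .graph import BidirectedGraph

PRIMARY = "primary"
SUPPLEMENTARY = "supplementary"
SECONDARY = "secondary"


@dataclass
class GraphAlignment:
    read_id: str
    read_length: int
    qstart: int
    qend: int
    path: list[tuple[str, str]]           # oriented source nodes
    path_entry_offsets: list[int]         # traversal-frame entry offset per element
    pstart: int
    pend: int
    path_length: int
    score: int
    matches: int
    block_length: int
    cigar: str
    graph_seq: str                        # path-spelled sequence of the aligned part
    kind: str = SECONDARY
    mapq: int = 0

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart


@dataclass
class CombinedOp:
    """One alignment column in read coordinates.

    op: '=' match, 'X' mismatch, 'I' read-only, 'D' graph-only.  ``aid``/
    ``col`` give the consumed alignment-graph base for '=', 'X', 'D'.
    """

    op: str
    read_pos: int | None
    aid: int | None
    col: int | None


def ops_to_alignment(
    ops: list[CombinedOp],
    ag: AlignmentGraph,
    tables: MappingTables,
    read_id: str,
    read_length: int,
    score: int,
    mapq: int = 0,
) -> GraphAlignment:
    """Collapse alignment-graph cells into an oriented source-node path."""
    if not ops:
        raise ValueError("empty operation list")
    path: list[tuple[str, str]] = []
    entries: list[int] = []
    prev_key: tuple[str, str] | None = None
    prev_frame: int | None = None
    first_frame: int | None = None
    graph_chars: list[str] = []
    matches = 0
    for o in ops:
        if o.op == "I":
            continue
        nid = tables.N[o.aid]
        orient = tables.D[o.aid]
        frame = tables.O[o.aid] + o.col
        if prev_key != (nid, orient) or frame != prev_frame + 1:
            path.append((nid, orient))
            entries.append(frame)
            if first_frame is None:
                first_frame = frame
        prev_key = (nid, orient)
        prev_frame = frame
        graph_chars.append(ag.labels[o.aid][o.col])
        if o.op == "=":
            matches += 1
    n_graph = len(graph_chars)
    plen = 0
    for i, (nid, orient) in enumerate(path):
        full = tables.node_len[nid]
        overlap = entries[i] if i > 0 else 0
        plen += full - overlap
    pstart = first_frame if first_frame is not None else 0
    pend = pstart + n_graph
    q_positions = [o.read_pos for o in ops if o.read_pos is not None]
    qstart, qend = min(q_positions), max(q_positions) + 1
    cigar = _runs_to_cigar([o.op for o in ops])
    return GraphAlignment(
        read_id=read_id,
        read_length=read_length,
        qstart=qstart,
        qend=qend,
        path=path,
        path_entry_offsets=entries,
        pstart=pstart,
        pend=pend,
        path_length=plen,
        score=score,
        matches=matches,
        block_length=len(ops),
        cigar=cigar,
        graph_seq="".join(graph_chars),
        mapq=mapq,
    )


def _runs_to_cigar(ops: list[str]) -> str:
    out = []
    run_op = None
    run = 0
    for op in ops:
        if op == run_op:
            run += 1
        else:
            if run_op is not None:
                out.append(f"{run}{run_op}")
            run_op, run = op, 1
    if run_op is not None:
        out.append(f"{run}{run_op}")
    return "".join(out)


def select_alignments(
    cands: list[GraphAlignment], include_secondary: bool = False
) -> list[GraphAlignment]:
    """Greedy longest-first read-disjoint selection.

    Kept alignments get classes primary (first) and supplementary; read-
    overlapping leftovers are secondary and returned only on request.
    """
    order = sorted(
        cands,
        key=lambda a: (-(a.query_span), a.qstart, a.score, a.path and a.path[0]),
    )
    kept: list[GraphAlignment] = []
    rest: list[GraphAlignment] = []
    for a in order:
        if all(a.qend <= k.qstart or a.qstart >= k.qend for k in kept):
            a.kind = PRIMARY if not kept else SUPPLEMENTARY
            kept.append(a)
        else:
            a.kind = SECONDARY
            rest.append(a)
    return kept + rest if include_secondary else kept


def to_gaf(a: GraphAlignment) -> str:
    """One GAF line: 12 mandatory columns plus the cg:Z CIGAR tag."""
    path_str = "".join(
        (">" if orient == "+" else "<") + nid for nid, orient in a.path
    )
    cols = [
        a.read_id,
        str(a.read_length),
        str(a.qstart),
        str(a.qend),
        "+",
        path_str,
        str(a.path_length),
        str(a.pstart),
        str(a.pend),
        str(a.matches),
        str(a.block_length),
        str(a.mapq),
        f"cg:Z:{a.cigar}",
    ]
    return "\t".join(cols)


def corrected_read(
    read: str, alignments: list[GraphAlignment], mode: str = "full"
) -> list[str]:
    """Corrected sequence(s) from the selected primary+supplementary set.

    full: one sequence, aligned intervals replaced by the path-spelled graph
    sequence, unaligned intervals verbatim.  clip: one sequence per
    alignment, corrected parts only.
    """
    kept = sorted(
        (a for a in alignments if a.kind in (PRIMARY, SUPPLEMENTARY)),
        key=lambda a: a.qstart,
    )
    if mode == "clip":
        return [a.graph_seq for a in kept]
    if mode != "full":
        raise ValueError(f"unknown correction mode {mode!r}")
    if not kept:
        return [read]
    parts = []
    cursor = 0
    for a in kept:
        parts.append(read[cursor:a.qstart])
        parts.append(a.graph_seq)
        cursor = a.qend
    parts.append(read[cursor:])
    return ["".join(parts)]
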