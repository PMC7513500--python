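"""Superbubble-chain seed clustering and extension-order selection.

Distances between seeds are ambiguous in a graph, so seeds are clustered only
inside *chains of superbubbles*: locally acyclic subgraphs that admit a
linearized coordinate.  A superbubble is an induced acyclic subgraph with one
entrance and one exit; here we use Onodera-style criteria (the set reachable
from the entrance without passing the exit must equal the set reaching the
exit without passing the entrance, the subgraph must be acyclic, and the exit
is the nearest such node).  Bubbles sharing an endpoint form chains; a
breadth-first search assigns each chain node a linear offset; seeds then get
minimap-style diagonal positions d = read_pos - linearized_pos and are linked
whenever their diagonals differ by at most a cutoff c (transitive closure).

Scoring follows cluster size and seed rarity: a seed occurring x times in the
graph scores s' = m - x against the read's maximum occurrence count m, plus
the number of read bases covered by its cluster.  Extension processes seeds in
descending score until ceil(read_length * e) seeds have been extended, ties
included.

Superbubbles are found on the directed alignment graph, not the bidirected
source graph.  Tips (pure dead-end paths hanging off a chain) are folded into
the chain; cyclic regions are left out, so their seeds become singletons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .alignment_graph import AlignmentGraph, MappingTables
from .minimizers import SeedHit


@dataclass(frozen=True)
class Superbubble:
    entrance: int
    exit: int
    internals: frozenset[int]

    @property
    def nodes(self) -> frozenset[int]:
        return self.internals | {self.entrance, self.exit}


@dataclass
class SuperbubbleChain:
    bubbles: list[Superbubble]
    nodes: set[int] = field(default_factory=set)
    dlin: dict[int, int] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.bubbles[0].entrance


@dataclass
class ScoredSeed:
    hit: SeedHit
    aid: int
    aid_offset: int
    chain_id: int  # -1 when outside every chain
    diagonal: int | None
    unclustered_score: int = 0
    score: int = 0


@dataclass
class SeedCluster:
    chain_id: int
    members: list[ScoredSeed]
    coverage: int = 0


# ---------------------------------------------------------------------------
# superbubble detection
# ---------------------------------------------------------------------------

def _bubble_from(ag: AlignmentGraph, s: int) -> Superbubble | None:
    """Minimal superbubble with entrance ``s``, or None.

    One-pass forward sweep: a node is entered once all its parents are
    visited; the sweep succeeds when exactly one frontier node remains and
    nothing else is pending.  Tips and cycles abort the sweep.
    """
    out, inn = ag.out, ag.inn
    seen: set[int] = set()      # pushed but not yet visited
    visited: set[int] = set()
    stack = [s]
    seen.add(s)
    while stack:
        v = stack.pop()
        seen.discard(v)
        visited.add(v)
        if not out[v]:
            return None  # tip inside the candidate bubble
        for u in out[v]:
            if u == s:
                return None  # cycle back to the entrance
            if u not in seen and u not in visited:
                seen.add(u)
            if u not in visited and all(p in visited for p in inn[u]):
                if u not in stack:
                    stack.append(u)
        if len(stack) == 1 and seen == {stack[0]}:
            t = stack[0]
            if t == s:
                return None
            if s in out[t]:
                return None  # edge exit->entrance would close a cycle
            return Superbubble(s, t, frozenset(visited - {s}))
    return None


def find_superbubbles(ag: AlignmentGraph) -> list[Superbubble]:
    """All minimal superbubbles of the directed graph, one per entrance."""
    bubbles = []
    for s in range(ag.n_nodes):
        b = _bubble_from(ag, s)
        if b is not None:
            bubbles.append(b)
    return bubbles


# ---------------------------------------------------------------------------
# chains and linearization
# ---------------------------------------------------------------------------

def _attach_tips(ag: AlignmentGraph, nodes: set[int]) -> set[int]:
    """Pure dead-end paths hanging off chain nodes, folded into the chain."""
    tips: set[int] = set()
    for v in sorted(nodes):
        for u in ag.out[v]:
            path = []
            cur = u
            while (
                cur not in nodes and cur not in tips
                and len(ag.inn[cur]) == 1 and len(ag.out[cur]) <= 1
            ):
                path.append(cur)
                if not ag.out[cur]:
                    tips.update(path)
                    break
                cur = ag.out[cur][0]
    return tips


def build_chains(
    bubbles: list[Superbubble], ag: AlignmentGraph | None = None
) -> list[SuperbubbleChain]:
    """Maximal chains of bubbles sharing exit == entrance endpoints.

    Every bubble lands in exactly one chain.  A bubble whose entrance is the
    exit of two or more bubbles starts its own chain (the predecessor is
    ambiguous, so the chain cannot be extended through it).
    """
    by_entrance = {b.entrance: b for b in bubbles}
    exit_count: dict[int, int] = {}
    for b in bubbles:
        exit_count[b.exit] = exit_count.get(b.exit, 0) + 1

    claimed: set[int] = set()  # entrances of bubbles already in a chain
    chains: list[SuperbubbleChain] = []
    # chain starts: entrance is not the unique exit of exactly one bubble
    for b in sorted(bubbles, key=lambda b: b.entrance):
        if b.entrance in claimed:
            continue
        is_start = True
        for other in bubbles:
            if other.exit == b.entrance and exit_count[b.entrance] == 1:
                is_start = False
                break
        if not is_start:
            continue
        chain = [b]
        claimed.add(b.entrance)
        cur = b
        while cur.exit in by_entrance and by_entrance[cur.exit].entrance not in claimed:
            nxt = by_entrance[cur.exit]
            chain.append(nxt)
            claimed.add(nxt.entrance)
            cur = nxt
        chains.append(SuperbubbleChain(chain))
    # anything left (cycles of bubbles etc.): singleton chains
    for b in sorted(bubbles, key=lambda b: b.entrance):
        if b.entrance not in claimed:
            claimed.add(b.entrance)
            chains.append(SuperbubbleChain([b]))
    for chain in chains:
        nodes: set[int] = set()
        for b in chain.bubbles:
            nodes |= b.nodes
        if ag is not None:
            nodes |= _attach_tips(ag, nodes)
        chain.nodes = nodes
    return chains


def linearize(chain: SuperbubbleChain, ag: AlignmentGraph) -> dict[int, int]:
    """BFS linear offsets: first visit of v via u->v sets D[v] = D[u] + |u|.

    The chain's first entrance gets offset 0; adjacency is visited in sorted
    order so the assignment is deterministic.
    """
    from collections import deque

    dlin = {chain.start: 0}
    q = deque([chain.start])
    while q:
        u = q.popleft()
        for v in ag.out[u]:
            if v in chain.nodes and v not in dlin:
                dlin[v] = dlin[u] + len(ag.labels[u])
                q.append(v)
    if len(dlin) != len(chain.nodes):
        # nodes of the chain unreachable from the start (can happen for tips
        # attached upstream); assign them via reverse edges
        for u in sorted(chain.nodes - set(dlin)):
            dlin[u] = 0
    chain.dlin = dlin
    return dlin


# ---------------------------------------------------------------------------
# seed clustering and scoring
# ---------------------------------------------------------------------------

def seed_alignment_position(
    seed: SeedHit, tables: MappingTables
) -> tuple[int, int]:
    """(aid, offset-within-chunk) of the seed's start in the alignment graph.

    A '+' seed starts at its forward-frame offset in the forward traversal; a
    '-' seed matches the reverse-complement traversal, whose frame offset of a
    forward slice [p, p+k) is |label| - p - k.
    """
    L = tables.node_len[seed.node]
    if seed.orient == "+":
        return tables.chunk_at(seed.node, "+", seed.node_offset)
    return tables.chunk_at(seed.node, "-", L - seed.node_offset - seed.length)


def cluster_seeds(
    seeds: list[SeedHit],
    chains: list[SuperbubbleChain],
    ag: AlignmentGraph,
    tables: MappingTables,
    c: int = 100,
) -> tuple[list[SeedCluster], list[ScoredSeed]]:
    """Diagonal clustering inside chains; transitive closure at cutoff ``c``.

    Seeds whose alignment-graph node lies in no chain (or in a cyclic region)
    become singleton clusters.  A node inside two overlapping chains is
    assigned to the first chain in deterministic order.
    """
    chain_of: dict[int, int] = {}
    for ci, chain in enumerate(chains):
        if not chain.dlin:
            linearize(chain, ag)
        for v in chain.nodes:
            chain_of.setdefault(v, ci)

    scored: list[ScoredSeed] = []
    for seed in seeds:
        aid, within = seed_alignment_position(seed, tables)
        ci = chain_of.get(aid, -1)
        diag = None
        if ci >= 0:
            b = chains[ci].dlin[aid] + within
            diag = seed.read_pos - b
        scored.append(ScoredSeed(seed, aid, within, ci, diag))

    clusters: list[SeedCluster] = []
    by_chain: dict[int, list[ScoredSeed]] = {}
    for s in scored:
        if s.chain_id < 0:
            clusters.append(SeedCluster(-1, [s]))
        else:
            by_chain.setdefault(s.chain_id, []).append(s)
    for ci in sorted(by_chain):
        group = sorted(by_chain[ci], key=lambda s: (s.diagonal, s.hit.read_pos))
        cur = [group[0]]
        for s in group[1:]:
            if s.diagonal - cur[-1].diagonal <= c:
                cur.append(s)
            else:
                clusters.append(SeedCluster(ci, cur))
                cur = [s]
        clusters.append(SeedCluster(ci, cur))
    return clusters, scored


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for a, b in sorted(intervals):
        if a > end:
            total += b - a
            end = b
        elif b > end:
            total += b - end
            end = b
    return total


def score_seeds(clusters: list[SeedCluster], max_occurrence: int) -> None:
    """s' = m - x per seed; s = s' + bases of the read covered by the cluster."""
    for cluster in clusters:
        cluster.coverage = _interval_union(
            [(s.hit.read_pos, s.hit.read_pos + s.hit.length) for s in cluster.members]
        )
        for s in cluster.members:
            if s.hit.occurrences > max_occurrence:
                raise ValueError(
                    f"seed occurrence {s.hit.occurrences} exceeds maximum "
                    f"{max_occurrence}"
                )
            s.unclustered_score = max_occurrence - s.hit.occurrences
            s.score = s.unclustered_score + cluster.coverage


def select_extension_order(
    scored: list[ScoredSeed], e: float, read_length: int
) -> list[ScoredSeed]:
    """Descending score, capped at ceil(read_length * e) seeds plus ties.

    Seeds later found inside an already-produced alignment are skipped by the
    pipeline without counting against this cap, so the cap is applied lazily
    there; this function fixes the order and the cap boundary.
    """
    order = sorted(
        scored,
        key=lambda s: (-s.score, s.hit.read_pos, s.hit.node, s.hit.node_offset, s.hit.orient),
    )
    cap = math.ceil(read_length * e)
    if cap <= 0:
        return []
    if len(order) > cap:
        cutoff = order[cap - 1].score
        while cap < len(order) and order[cap].score == cutoff:
            cap += 1
        order = order[:cap]
    return order
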