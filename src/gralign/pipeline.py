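"""End-to-end read alignment: seed, cluster, extend both ways, clip, select.

Each read is processed independently.  A seed anchors two one-way banded
extensions: forward over the read suffix from the seed's start base, and
backward over the reverse complement of the read prefix anchored at the
opposite-strand copy of the same base (the alignment graph contains both
strands, so backward extension is just forward extension on the other
strand).  The two traces are stitched at the seed into one alignment in read
coordinates.  Seeds are taken in descending cluster score until
ceil(read_length * e) have been extended (ties included); seeds already
covered by a produced alignment are skipped without counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .alignment_graph import AlignmentGraph, MappingTables, build_alignment_graph
from .bitdp import WORD
from .clipping import EmissionModel
from .clustering import (
    ScoredSeed,
    SuperbubbleChain,
    build_chains,
    cluster_seeds,
    find_superbubbles,
    score_seeds,
    seed_alignment_position,
    select_extension_order,
)
from .extend import (
    BandParams,
    ExtensionResult,
    Trace,
    backtrace,
    extend_query,
    seed_init_tops,
)
from .graph import BidirectedGraph
from .minimizers import IndexParams, MinimizerIndex, SeedHit, build_index, collect_seeds
from .output import (
    CombinedOp,
    GraphAlignment,
    ops_to_alignment,
    select_alignments,
)
from .seq import reverse_complement

PRESETS: dict[str, dict] = {
    # tuned for variation graphs: shorter k-mers improve seed clustering in
    # bubble chains; every seed extended
    "vg": dict(k=15, w=20, d=10.0, e=1.0, c=100, b=5, B=10, C_tangle=None),
    # tuned for de Bruijn graphs: long k-mers, few extensions, tangle capped
    "dbg": dict(k=19, w=30, d=5.0, e=0.002, c=100, b=5, B=10, C_tangle=100_000),
}


@dataclass
class AlignerConfig:
    k: int = 15
    w: int = 20
    d: float = 10.0
    x: float = 0.0002
    e: float = 1.0
    c: int = 100
    b: int = 5
    B: int = 10
    C_tangle: int | None = None
    rate_correct: float = 0.20
    rate_wrong: float = 0.50
    p_switch: float = 1e-5
    all_alignments: bool = False

    @classmethod
    def preset(cls, name: str, **overrides) -> "AlignerConfig":
        base = dict(PRESETS[name])
        base.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**base)

    @property
    def band(self) -> BandParams:
        return BandParams(self.b, self.B, self.C_tangle)

    @property
    def emission(self) -> EmissionModel:
        return EmissionModel(self.rate_correct, self.rate_wrong, self.p_switch)


class GraphAligner:
    """A graph plus its derived indices; aligns reads one at a time."""

    def __init__(self, graph: BidirectedGraph, config: AlignerConfig | None = None):
        self.graph = graph
        self.config = config or AlignerConfig()
        self.ag, self.tables = build_alignment_graph(graph)
        self.index: MinimizerIndex = build_index(
            graph, IndexParams(self.config.k, self.config.w, self.config.x)
        )
        bubbles = find_superbubbles(self.ag)
        self.chains: list[SuperbubbleChain] = build_chains(bubbles, self.ag)

    # -- seeding --------------------------------------------------------

    def seeds_for(self, read: str) -> list[SeedHit]:
        return collect_seeds(self.index, read, self.config.d)

    def _opposite_cell(self, aid: int, col: int) -> tuple[int, int]:
        t = self.tables
        nid = t.N[aid]
        L = t.node_len[nid]
        frame = t.O[aid] + col
        o2 = "-" if t.D[aid] == "+" else "+"
        return t.chunk_at(nid, o2, L - 1 - frame)

    # -- extension ------------------------------------------------------

    def _one_way(self, query: str, aid: int, col: int) -> Trace | None:
        """Banded extension of ``query`` anchored so that its first character
        is consumed by the base after (aid, col)."""
        if not query:
            return None
        res = extend_query(
            self.ag, query, seed_init_tops(self.ag, aid, col),
            self.config.band, model=self.config.emission,
        )
        if res.clip_slice is None:
            return None
        return backtrace(self.ag, res)

    def extend_seed_bidirectional(
        self, read: str, seed: SeedHit
    ) -> list[CombinedOp] | None:
        """Forward + backward extension stitched at the seed, or None."""
        aid, within = seed_alignment_position(seed, self.tables)
        rp = seed.read_pos
        combined: list[CombinedOp] = []
        score = 0

        if rp > 0:
            qb = reverse_complement(read[:rp])
            o_aid, o_col = self._opposite_cell(aid, within)
            trb = self._one_way(qb, o_aid, o_col)
            if trb is not None:
                score += trb.score
                for o in reversed(trb.ops):
                    if o.op == "I":
                        combined.append(CombinedOp("I", rp - 1 - o.row, None, None))
                    else:
                        c_aid, c_col = self._opposite_cell(o.aid, o.col)
                        combined.append(
                            CombinedOp(
                                o.op,
                                rp - 1 - o.row if o.row is not None else None,
                                c_aid,
                                c_col,
                            )
                        )

        if within > 0:
            fwd_query = read[rp:]
            fwd_anchor = within - 1
            fwd_offset = rp
        else:
            # the anchor column must precede the first consumed base; when the
            # seed starts a chunk, consume its first base via the seed match
            # itself and extend from it
            combined.append(CombinedOp("=", rp, aid, 0))
            fwd_query = read[rp + 1 :]
            fwd_anchor = 0
            fwd_offset = rp + 1
        if fwd_query:
            trf = self._one_way(fwd_query, aid, fwd_anchor)
            if trf is None and not combined:
                return None
            if trf is not None:
                score += trf.score
                for o in trf.ops:
                    combined.append(
                        CombinedOp(
                            o.op,
                            fwd_offset + o.row if o.row is not None else None,
                            o.aid,
                            o.col,
                        )
                    )
        if not combined:
            return None
        # reversed backward ops, the seed base, then forward ops are already
        # in read order; graph-only deletions stay interleaved where traced
        self._last_score = score
        return combined

    # -- per-read alignment --------------------------------------------

    def align_read(self, read_id: str, read: str) -> list[GraphAlignment]:
        read = read.upper()
        return self.align_read_with_seeds(read_id, read, self.seeds_for(read))

    def align_read_seedless(self, read_id: str, read: str) -> list[GraphAlignment]:
        """Whole-first-row initialization; practical for small graphs only."""
        from .extend import align_seedless

        read = read.upper()
        res = align_seedless(
            self.ag, read, self.config.band,
            model=self.config.emission, use_viterbi=True,
        )
        tr = backtrace(self.ag, res)
        if tr is None:
            return []
        ops = [
            CombinedOp(o.op, o.row, o.aid, o.col) for o in tr.ops
        ]
        aln = ops_to_alignment(
            ops, self.ag, self.tables, read_id, len(read), tr.score
        )
        return select_alignments([aln], self.config.all_alignments)

    def align_read_with_seeds(
        self, read_id: str, read: str, seeds: list[SeedHit]
    ) -> list[GraphAlignment]:
        read = read.upper()
        cfg = self.config
        if not seeds:
            return []
        clusters, scored = cluster_seeds(
            seeds, self.chains, self.ag, self.tables, cfg.c
        )
        max_occ = max(s.occurrences for s in seeds)
        score_seeds(clusters, max_occ)
        order = sorted(
            scored,
            key=lambda s: (
                -s.score, s.hit.read_pos, s.hit.node, s.hit.node_offset, s.hit.orient,
            ),
        )
        unique_best = (
            len(order) == 1 or (len(order) > 1 and order[0].score > order[1].score)
        )
        cap = math.ceil(len(read) * cfg.e)
        cands: list[GraphAlignment] = []
        extended = 0
        cap_score: int | None = None
        for s in order:
            if extended >= cap and (cap_score is None or s.score != cap_score):
                break
            if self._seed_covered(s.hit, cands):
                continue
            ops = self.extend_seed_bidirectional(read, s.hit)
            extended += 1
            if extended == cap:
                cap_score = s.score
            if ops is None:
                continue
            aln = ops_to_alignment(
                ops, self.ag, self.tables, read_id, len(read), self._last_score
            )
            cands.append(aln)
        selected = select_alignments(cands, cfg.all_alignments)
        for a in selected:
            if a.kind == "primary" and unique_best:
                a.mapq = 60
        return selected

    @staticmethod
    def _seed_covered(seed: SeedHit, alignments: list[GraphAlignment]) -> bool:
        for a in alignments:
            if (
                a.qstart <= seed.read_pos
                and seed.read_pos + seed.length <= a.qend
                and (seed.node, seed.orient) in set(a.path)
            ):
                return True
        return False
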