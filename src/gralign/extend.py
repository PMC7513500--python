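"""Slice-by-slice banded DP extension over the alignment graph.

The DP matrix has one column per graph base and one row per query base, and is
computed in horizontal slices of 64 rows.  The unit of band bookkeeping is the
*block*: the intersection of one alignment-graph node's columns with one
slice.  Per slice the minimum last-row score m is discovered as blocks
complete, and a block is inside the band iff any of its cells scores at most
m + b; out-of-band blocks are not propagated.  At forks the band spreads to
all out-neighbors, and the score comparison implicitly prunes wrong paths.
Cyclic regions are handled by recomputing blocks until a fixpoint: scores only
decrease, so the iteration terminates.  An optional *tangle effort* C caps the
cells computed per slice; when exceeded, the slice is frozen as-is and the
extension moves on.

Completed slices are kept sparsely: per block the first and last column
states, the bottom-row score deltas and the corner scores -- enough to
reconstruct every border cell exactly and to recompute interior cells on
demand (needed only by the backtrace).

A two-state Viterbi tracker watches the per-slice score increments; when the
wrongly-aligned state takes over, the extension re-aligns from the last
guaranteed-correct slice with the wider ramp band B, and a guaranteed-wrong
slice terminates it.  The returned alignment is clipped to the last
guaranteed-correct slice.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .alignment_graph import AlignmentGraph, MappingTables
from .bitdp import (
    MASK,
    WORD,
    ColumnState,
    EqTables,
    advance,
    decode,
    merge,
    score_at_row,
)
from .clipping import CorrectnessTracker, EmissionModel, control_extension
from .seq import bases_match

INF = float("inf")


@dataclass(frozen=True)
class BandParams:
    """Initial band width b, ramp band width B > b, optional tangle effort."""

    b: int = 5
    B: int = 10
    C_tangle: int | None = None

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("band width b must be >= 1")
        if self.B <= self.b:
            raise ValueError("ramp band B must exceed b")
        if self.C_tangle is not None and self.C_tangle <= 0:
            raise ValueError("tangle effort must be positive when set")


@dataclass
class SliceSummary:
    index: int
    min_score: int
    cells: int
    e_obs: float


class FullBlock:
    """All column states of one node x one slice, while the slice is live."""

    __slots__ = ("aid", "cols", "tops", "min_cell", "min_last")

    def __init__(self, aid: int, cols: list[ColumnState], tops: list[int]):
        self.aid = aid
        self.cols = cols
        self.tops = tops
        self.min_cell = 0
        self.min_last = 0


class SparseBlock:
    """Corner scores plus 2-bit border deltas of a stored block.

    ``first_col``/``last_col`` are the left/right border columns (their vp/vn
    masks are the 2-bit vertical deltas, their bottom scores the corners);
    ``bottom_deltas`` are the horizontal deltas along the bottom border and
    ``tops`` the absolute top-boundary scores (the bottom border of the block
    above, or the synthetic boundary for the first slice).
    """

    __slots__ = ("aid", "slice_index", "first_col", "last_col", "bottom_deltas", "tops")

    def __init__(self, aid, slice_index, first_col, last_col, bottom_deltas, tops):
        self.aid = aid
        self.slice_index = slice_index
        self.first_col = first_col
        self.last_col = last_col
        self.bottom_deltas = bottom_deltas
        self.tops = tops

    @property
    def corner_bl(self) -> int:
        return self.first_col[2]

    @property
    def corner_br(self) -> int:
        return self.last_col[2]

    def bottom_scores(self) -> list[int]:
        out = [self.corner_bl]
        for d in self.bottom_deltas:
            out.append(out[-1] + d)
        return out


def dense_block_bound_bytes() -> float:
    """Information-theoretic bound, in bytes, for storing every cell of one
    64x64 block: each cell is one of 3 score deltas, so log2(3^(64*64))/8."""
    import math

    return (WORD * WORD) * math.log2(3) / 8


def border_bound_bytes() -> float:
    """Information-theoretic bound for storing only a block's border cells
    (left 64, right 64, bottom 62 interior): log2(3^(64+64+62))/8."""
    import math

    return (WORD + WORD + 62) * math.log2(3) / 8


def sparsify(block: FullBlock, slice_index: int) -> SparseBlock:
    bottoms = [c[2] for c in block.cols]
    deltas = [bottoms[j] - bottoms[j - 1] for j in range(1, len(bottoms))]
    return SparseBlock(
        block.aid, slice_index, block.cols[0], block.cols[-1], deltas, list(block.tops)
    )


def load_border(
    storage: dict[tuple[int, int], SparseBlock], aid: int, slice_index: int
) -> tuple[list[int], list[int], list[int]] | None:
    """(left, right, bottom) border scores of a stored block, or None."""
    sb = storage.get((aid, slice_index))
    if sb is None:
        return None
    left = decode(sb.first_col)[1:]
    right = decode(sb.last_col)[1:]
    return left, right, sb.bottom_scores()


def _block_stats(cols: list[ColumnState], last_row: int) -> tuple[int, int]:
    """(min over cells in rows 0..last_row, min over row last_row)."""
    n = len(cols)
    vp = np.array([c[0] for c in cols], dtype="<u8")
    vn = np.array([c[1] for c in cols], dtype="<u8")
    bottom = np.array([c[2] for c in cols], dtype=np.int64)
    vp_bits = np.unpackbits(vp.view(np.uint8).reshape(n, 8), axis=1, bitorder="little")
    vn_bits = np.unpackbits(vn.view(np.uint8).reshape(n, 8), axis=1, bitorder="little")
    delta = vp_bits.astype(np.int16) - vn_bits
    # score at row i = bottom - sum_{j>i} delta_j
    suffix = np.zeros((n, WORD + 1), dtype=np.int64)
    suffix[:, :WORD] = np.cumsum(delta[:, ::-1], axis=1)[:, ::-1]
    scores = bottom[:, None] - suffix[:, 1:]  # (n, 64), rows 0..63
    sub = scores[:, : last_row + 1]
    return int(sub.min()), int(scores[:, last_row].min())


def block_score_matrix(cols: list[ColumnState], tops: list[int]) -> np.ndarray:
    """(n_cols, 65) absolute scores, rows -1..63; row -1 from ``tops``."""
    n = len(cols)
    vp = np.array([c[0] for c in cols], dtype="<u8")
    vn = np.array([c[1] for c in cols], dtype="<u8")
    bottom = np.array([c[2] for c in cols], dtype=np.int64)
    vp_bits = np.unpackbits(vp.view(np.uint8).reshape(n, 8), axis=1, bitorder="little")
    vn_bits = np.unpackbits(vn.view(np.uint8).reshape(n, 8), axis=1, bitorder="little")
    delta = vp_bits.astype(np.int16) - vn_bits
    suffix = np.zeros((n, WORD + 1), dtype=np.int64)
    suffix[:, :WORD] = np.cumsum(delta[:, ::-1], axis=1)[:, ::-1]
    out = np.empty((n, WORD + 1), dtype=np.int64)
    out[:, 1:] = bottom[:, None] - suffix[:, 1:]
    out[:, 0] = np.asarray(tops, dtype=np.int64)
    return out


def priority_value(k: int, row: int, e_obs: float) -> float:
    """Greedy exploration priority of a cell with score k at global row
    ``row``: k/e - row, or 64k - row when the observed error rate e is at or
    below 1/64.  Zero means as good as the best alignment so far; negative is
    better."""
    if e_obs <= 1.0 / 64:
        return 64 * k - row
    return k / e_obs - row


def column_priority(
    state: ColumnState, slice_index: int, e_obs: float, last_row: int = 63
) -> float:
    """Minimum :func:`priority_value` over the column's rows."""
    scores = decode(state)[1:]
    base_row = slice_index * WORD
    best = INF
    for i in range(last_row + 1):
        p = priority_value(scores[i], base_row + i, e_obs)
        if p < best:
            best = p
    return best


def recalculation_order(
    pending: list[tuple[int, ColumnState]],
    e_obs: float,
    slice_index: int,
    use_priority: bool,
) -> int:
    """Aid of the pending column to recalculate next.

    With the tangle effort set, ordering is by minimum changed priority value;
    otherwise by minimum changed score.  Ties break toward the lower aid.
    """
    best_aid = None
    best_val = INF
    for aid, state in pending:
        if use_priority:
            val = column_priority(state, slice_index, e_obs)
        else:
            val = min(decode(state)[1:])
        if val < best_val or (val == best_val and (best_aid is None or aid < best_aid)):
            best_val = val
            best_aid = aid
    return best_aid


@dataclass
class ExtensionResult:
    query: str
    sparse: dict[tuple[int, int], SparseBlock]
    in_band: list[set[int]]  # per slice: aids in band
    summaries: list[SliceSummary]
    tracker: CorrectnessTracker | None
    clip_slice: int | None  # last slice included in the alignment, None = rejected
    init_tops: dict[int, list[int]]
    completed: bool  # ran to the end of the query without a guaranteed-wrong stop


def _top_of(state: ColumnState) -> int:
    return score_at_row(state, -1)


def _compute_block(
    ag: AlignmentGraph,
    aid: int,
    entry: ColumnState | None,
    above_bottoms: list[int] | None,
    seed_tops: list[int] | None,
    eqt: EqTables,
) -> FullBlock | None:
    label = ag.labels[aid]
    n = len(label)
    if entry is None and above_bottoms is None and seed_tops is None:
        return None
    synth = None
    if seed_tops is not None:
        # virtual start column: the alignment may begin at this node's first
        # base, entering diagonally from the initialization boundary
        synth_top = seed_tops[0]
        synth = (MASK, 0, synth_top + WORD)
    if entry is not None and synth is not None:
        prev = merge(entry, synth)
        prev_top = _top_of(prev)
    elif entry is not None:
        prev = entry
        prev_top = _top_of(entry)
    elif synth is not None:
        prev = synth
        prev_top = synth_top
    else:
        # no in-band left context: synthesize the worst valid column that is
        # consistent with the known top boundary (top + 1, all deltas +1)
        prev_top = above_bottoms[0] + 1
        prev = (MASK, 0, prev_top + WORD)
    cols: list[ColumnState] = []
    tops: list[int] = []
    for j in range(n):
        if above_bottoms is not None:
            t_j = above_bottoms[j]
        elif seed_tops is not None:
            t_j = seed_tops[j]
        else:
            t_j = prev_top + 1
        hin = t_j - prev_top
        if hin > 1:
            hin = 1
        elif hin < -1:
            hin = -1
        vp, vn, sc, _ = advance(prev[0], prev[1], prev[2], eqt.eq(label[j]), hin)
        prev = (vp, vn, sc)
        prev_top = prev_top + hin
        cols.append(prev)
        tops.append(prev_top)
    return FullBlock(aid, cols, tops)


def _compute_slice(
    ag: AlignmentGraph,
    s: int,
    query: str,
    prev_sparse: dict[int, SparseBlock],
    seed_tops: dict[int, list[int]],
    b: int,
    C_tangle: int | None,
    e_obs: float,
    last_row: int,
) -> tuple[dict[int, FullBlock], int, int]:
    """One slice of the band: (blocks in band, slice minimum, cells computed)."""
    window = query[s * WORD : (s + 1) * WORD]
    if len(window) < WORD:
        window = window + "\0" * (WORD - len(window))
    eqt = EqTables(window)

    prev_bottoms: dict[int, list[int]] = {
        aid: sb.bottom_scores() for aid, sb in prev_sparse.items()
    }
    current: dict[int, FullBlock] = {}
    m_known = INF
    cells = 0
    counter = 0
    heap: list[tuple[float, int, int]] = []

    def push(aid: int, priority: float) -> None:
        nonlocal counter
        counter += 1
        heapq.heappush(heap, (priority, aid, counter))

    for aid in prev_bottoms:
        push(aid, min(prev_bottoms[aid]))
    for aid in seed_tops:
        push(aid, min(seed_tops[aid]))

    frozen = False
    while heap:
        _, v, _ = heapq.heappop(heap)
        entry: ColumnState | None = None
        for p in ag.inn[v]:
            blk = current.get(p)
            if blk is not None:
                last = blk.cols[-1]
                entry = last if entry is None else merge(entry, last)
        block = _compute_block(
            ag, v, entry, prev_bottoms.get(v), seed_tops.get(v), eqt
        )
        if block is None:
            continue
        old = current.get(v)
        if old is not None and old.cols == block.cols:
            continue
        cells += WORD * len(block.cols)
        block.min_cell, block.min_last = _block_stats(block.cols, last_row)
        current[v] = block
        if block.min_last < m_known:
            m_known = block.min_last
        if block.min_cell <= m_known + b:
            out_state = block.cols[-1]
            if C_tangle is not None:
                pr = column_priority(out_state, s, e_obs)
            else:
                pr = float(block.min_cell)
            for u in ag.out[v]:
                push(u, pr)
        if C_tangle is not None and cells > C_tangle:
            frozen = True
            break
    if m_known is INF:
        return {}, set(), 0, cells
    in_band = {
        v for v, blk in current.items() if blk.min_cell <= m_known + b
    }
    if frozen and not in_band:
        in_band = set(current)
    return current, in_band, int(m_known), cells


def extend_query(
    ag: AlignmentGraph,
    query: str,
    init_tops: dict[int, list[int]],
    params: BandParams,
    model: EmissionModel | None = None,
    use_viterbi: bool = True,
) -> ExtensionResult:
    """Banded extension of ``query`` from the given top-boundary initialization.

    ``init_tops`` maps alignment-node ids to absolute scores along the top
    boundary row of slice 0 (0 at a seed's start base, increasing with
    distance; all zeros in seedless mode).  Returns the sparse stored matrix,
    per-slice summaries, and the clip decision.
    """
    if not query:
        raise ValueError("empty query")
    n_slices = (len(query) + WORD - 1) // WORD
    tracker = CorrectnessTracker(model) if use_viterbi else None
    sparse: dict[tuple[int, int], SparseBlock] = {}
    in_band_per_slice: list[set[int]] = []
    summaries: list[SliceSummary] = []
    mins: list[int] = []
    min_init = min(min(v) for v in init_tops.values())

    s = 0
    b_cur = params.b
    ramped = False
    ramp_trigger = -1  # slice that triggered the last ramp
    completed = True
    while s < n_slices:
        last_row = WORD - 1 if s < n_slices - 1 else (len(query) - 1) % WORD
        prev_sparse = (
            {aid: sparse[(aid, s - 1)] for aid in in_band_per_slice[s - 1]}
            if s > 0
            else {}
        )
        e_obs = (mins[-1] / (s * WORD)) if s > 0 and mins[-1] > 0 else 0.0
        blocks, in_band, m, cells = _compute_slice(
            ag, s, query, prev_sparse,
            init_tops if s == 0 else {},
            b_cur, params.C_tangle, e_obs, last_row,
        )
        if not in_band:
            completed = False
            break
        # all computed blocks are stored (the backtrace may need an
        # out-of-band predecessor); only in-band blocks propagate
        for aid, blk in blocks.items():
            sparse[(aid, s)] = sparsify(blk, s)
        in_band_per_slice.append(in_band)
        mins.append(m)
        summaries.append(
            SliceSummary(s, m, cells, m / ((s + 1) * WORD))
        )
        if tracker is not None:
            prev_m = mins[s - 1] if s > 0 else min_init
            tracker.observe(m - prev_m)
            action = control_extension(tracker, ramped)
            if action == "terminate":
                completed = False
                s += 1
                break
            if action == "ramp":
                lgc = tracker.last_guaranteed_correct()
                resume = (lgc + 1) if lgc is not None else 0
                for key in [k for k in sparse if k[1] >= resume]:
                    del sparse[key]
                del in_band_per_slice[resume:]
                del summaries[resume:]
                del mins[resume:]
                tracker.truncate(resume)
                b_cur = params.B
                ramped = True
                ramp_trigger = s
                s = resume
                continue
            # re-arm the one-ramp-per-dip rule only once the correct state
            # dominates beyond the slice that triggered the last ramp;
            # re-computed prefix slices must not re-arm it
            if tracker.correct_dominant and s > ramp_trigger:
                ramped = False
        s += 1

    clip = _clip_slice(tracker, len(in_band_per_slice), completed)
    return ExtensionResult(
        query=query,
        sparse=sparse,
        in_band=in_band_per_slice,
        summaries=summaries,
        tracker=tracker,
        clip_slice=clip,
        init_tops=init_tops,
        completed=completed,
    )


def _clip_slice(
    tracker: CorrectnessTracker | None, n_done: int, completed: bool
) -> int | None:
    if n_done == 0:
        return None
    if tracker is None:
        return n_done - 1
    if completed and tracker.correct_dominant:
        return n_done - 1
    return tracker.last_guaranteed_correct()


# ---------------------------------------------------------------------------
# backtrace
# ---------------------------------------------------------------------------

@dataclass
class TraceOp:
    op: str  # '=', 'X', 'I' (read only), 'D' (graph only)
    aid: int | None
    col: int | None
    row: int | None  # query row consumed, None for 'D'


@dataclass
class Trace:
    ops: list[TraceOp]
    score: int
    q_start: int
    q_end: int


class _ScoreCache:
    """Reconstructs interior block scores from the sparse storage on demand."""

    def __init__(self, ag: AlignmentGraph, res: ExtensionResult):
        self.ag = ag
        self.res = res
        self._eqts: dict[int, EqTables] = {}
        self._mats: dict[tuple[int, int], np.ndarray] = {}

    def _eqt(self, s: int) -> EqTables:
        eqt = self._eqts.get(s)
        if eqt is None:
            window = self.res.query[s * WORD : (s + 1) * WORD]
            if len(window) < WORD:
                window = window + "\0" * (WORD - len(window))
            eqt = EqTables(window)
            self._eqts[s] = eqt
        return eqt

    def matrix(self, aid: int, s: int) -> np.ndarray | None:
        key = (aid, s)
        mat = self._mats.get(key)
        if mat is not None:
            return mat
        sb = self.res.sparse.get(key)
        if sb is None:
            return None
        label = self.ag.labels[aid]
        eqt = self._eqt(s)
        cols = [sb.first_col]
        prev = sb.first_col
        prev_top = sb.tops[0]
        for j in range(1, len(label)):
            t_j = sb.tops[j]
            hin = max(-1, min(1, t_j - prev_top))
            vp, vn, sc, _ = advance(prev[0], prev[1], prev[2], eqt.eq(label[j]), hin)
            prev = (vp, vn, sc)
            prev_top = prev_top + hin
            cols.append(prev)
        mat = block_score_matrix(cols, sb.tops)
        self._mats[key] = mat
        return mat

    def score(self, aid: int, col: int, s: int, row: int) -> float:
        """Score at slice ``s`` row ``row`` (-1..63); INF if out of band."""
        if row == -1:
            if s == 0:
                sb = self.res.sparse.get((aid, 0))
                if sb is None:
                    return INF
                return sb.tops[col]
            return self.score(aid, col, s - 1, WORD - 1)
        mat = self.matrix(aid, s)
        if mat is None:
            return INF
        return float(mat[col, row + 1])


def backtrace(ag: AlignmentGraph, res: ExtensionResult) -> Trace | None:
    """Trace the optimal in-band alignment back from the clip slice.

    Starts at the minimum-score cell of the clip slice's last valid row and
    walks DP predecessors (diagonal preferred, then vertical, then horizontal)
    to the top boundary of slice 0.  Leading and trailing graph-only deletions
    are trimmed.
    """
    clip = res.clip_slice
    if clip is None or clip >= len(res.in_band):
        return None
    cache = _ScoreCache(ag, res)
    q_end = min(len(res.query), (clip + 1) * WORD)
    last_row = (q_end - 1) % WORD

    best = None
    for aid in sorted(res.in_band[clip]):
        mat = cache.matrix(aid, clip)
        if mat is None:
            continue
        col = int(np.argmin(mat[:, last_row + 1]))
        sc = int(mat[col, last_row + 1])
        if best is None or sc < best[0]:
            best = (sc, aid, col)
    if best is None:
        return None
    score0, aid, col = best

    ops: list[TraceOp] = []
    s, row = clip, last_row
    cur = float(score0)
    guard = 0
    max_steps = (q_end + 5) * 8 + 64 * (clip + 2) * 4 + 10000
    while True:
        guard += 1
        if guard > max_steps:
            raise RuntimeError("backtrace did not terminate")
        if row == -1 and s == 0:
            break
        ps, prow = (s, row - 1) if row > 0 else (s - 1, WORD - 1)
        if row == 0 and s == 0:
            ps, prow = 0, -1
        qchar = res.query[s * WORD + row]
        gchar = ag.labels[aid][col]
        # graph predecessors of (aid, col)
        if col > 0:
            gpreds = [(aid, col - 1)]
        else:
            gpreds = [
                (p, len(ag.labels[p]) - 1)
                for p in ag.inn[aid]
            ]
        moved = False
        # diagonal
        delta = 0 if bases_match(qchar, gchar) else 1
        for paid, pcol in gpreds:
            pv = cache.score(paid, pcol, ps, prow)
            if pv + delta == cur:
                ops.append(TraceOp("=" if delta == 0 else "X", aid, col, s * WORD + row))
                aid, col, s, row, cur = paid, pcol, ps, prow, pv
                moved = True
                break
        if moved:
            continue
        # vertical: consumes a query row
        pv = cache.score(aid, col, ps, prow)
        if pv + 1 == cur:
            ops.append(TraceOp("I", None, None, s * WORD + row))
            s, row, cur = ps, prow, pv
            continue
        # horizontal: consumes a graph column
        for paid, pcol in gpreds:
            pv = cache.score(paid, pcol, s, row)
            if pv + 1 == cur:
                ops.append(TraceOp("D", aid, col, None))
                aid, col, cur = paid, pcol, pv
                moved = True
                break
        if moved:
            continue
        # virtual free start: a block whose first column was initialized
        # (slice 0) may begin the alignment at its first base
        if s == 0 and col == 0:
            sb = res.sparse.get((aid, 0))
            if sb is not None and sb.tops[0] + row + delta == cur:
                ops.append(
                    TraceOp("=" if delta == 0 else "X", aid, col, s * WORD + row)
                )
                break
        raise RuntimeError(
            f"broken predecessor chain at aid={aid} col={col} slice={s} row={row}"
        )
    ops.reverse()
    while ops and ops[0].op == "D":
        ops.pop(0)
    while ops and ops[-1].op == "D":
        ops.pop()
    if not ops:
        return None
    q_rows = [o.row for o in ops if o.row is not None]
    return Trace(ops=ops, score=score0, q_start=min(q_rows), q_end=max(q_rows) + 1)


# ---------------------------------------------------------------------------
# seeding helpers and seedless mode
# ---------------------------------------------------------------------------

def seed_init_tops(
    ag: AlignmentGraph, aid: int, offset: int
) -> dict[int, list[int]]:
    """Top-boundary scores anchoring an extension at base (aid, offset)."""
    n = len(ag.labels[aid])
    return {aid: [abs(j - offset) for j in range(n)]}


def zeros_init_tops(ag: AlignmentGraph) -> dict[int, list[int]]:
    return {aid: [0] * len(ag.labels[aid]) for aid in range(ag.n_nodes)}


def align_seedless(
    ag: AlignmentGraph, read: str, params: BandParams,
    model: EmissionModel | None = None, use_viterbi: bool = False,
) -> ExtensionResult:
    """Extension initialized with the entire first row at zero cost.

    Equivalent to seeding at every position; practical only for small graphs
    since the whole graph enters the band's first slice.
    """
    if not read:
        raise ValueError("empty read")
    return extend_query(
        ag, read, zeros_init_tops(ag), params, model=model, use_viterbi=use_viterbi
    )


def final_row_scores(ag: AlignmentGraph, res: ExtensionResult) -> dict[tuple[int, int], int]:
    """Scores at the query's last row for every in-band column of the clip slice."""
    clip = res.clip_slice
    if clip is None:
        return {}
    cache = _ScoreCache(ag, res)
    q_end = min(len(res.query), (clip + 1) * WORD)
    last_row = (q_end - 1) % WORD
    out: dict[tuple[int, int], int] = {}
    for aid in res.in_band[clip]:
        mat = cache.matrix(aid, clip)
        if mat is None:
            continue
        for col in range(mat.shape[0]):
            out[(aid, col)] = int(mat[col, last_row + 1])
    return out


# ---------------------------------------------------------------------------
# scalar reference DP (test oracle; also documents the semantics)
# ---------------------------------------------------------------------------

def oracle_full_dp(ag: AlignmentGraph, query: str) -> list[dict[tuple[int, int], int]]:
    """Unit-cost sequence-to-graph edit DP, iterated to a fixpoint.

    Row -1 is 0 everywhere (free start).  Returns one dict per query row
    mapping (aid, col) cells to scores.  Cyclic horizontal dependencies are
    relaxed with a worklist until no score decreases.  Intended for small
    instances only.
    """
    cells = [(v, j) for v in range(ag.n_nodes) for j in range(len(ag.labels[v]))]
    preds: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for v, j in cells:
        if j > 0:
            preds[(v, j)] = [(v, j - 1)]
        else:
            preds[(v, j)] = [(p, len(ag.labels[p]) - 1) for p in ag.inn[v]]
    succs: dict[tuple[int, int], list[tuple[int, int]]] = {c: [] for c in cells}
    for c, ps in preds.items():
        for p in ps:
            succs[p].append(c)
    prev = {c: 0 for c in cells}
    rows: list[dict[tuple[int, int], int]] = []
    for i, ch in enumerate(query):
        cur: dict[tuple[int, int], int] = {}
        for c in cells:
            v, j = c
            delta = 0 if bases_match(ch, ag.labels[v][j]) else 1
            best = prev[c] + 1
            for p in preds[c]:
                d = prev[p] + delta
                if d < best:
                    best = d
            if not preds[c]:
                # source column: diagonal entry from the virtual start column
                # (i skipped query rows, then this base)
                d = i + delta
                if d < best:
                    best = d
            cur[c] = best
        work = set(cells)
        while work:
            c = work.pop()
            for u in succs[c]:
                d = cur[c] + 1
                if d < cur[u]:
                    cur[u] = d
                    work.add(u)
        rows.append(cur)
        prev = cur
    return rows
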