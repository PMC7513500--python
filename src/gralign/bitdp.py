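"""Bit-parallel unit-cost edit-distance column primitives.

The DP matrix (query rows x graph-base columns) is processed in horizontal
slices of 64 query rows.  A column of one slice is held as a *column state*
``(vp, vn, score)``: two 64-bit masks of the vertical score deltas between
adjacent rows (+1 bits in ``vp``, -1 bits in ``vn``) plus the absolute score
at the slice's bottom row.  The implied 65-entry score column runs from the
row above the slice (row -1) down to row 63 and changes by at most 1 per row,
which is what makes the 2-bit delta encoding exact.

``advance`` is Myers' bit-parallel step extended with a horizontal input delta
``hin`` at the top boundary, so slices stack: the bottom-row horizontal deltas
(``hout``) of one slice are the ``hin`` sequence of the next.  ``merge`` takes
the elementwise minimum of two columns, which is how scores meet at graph
nodes with in-degree two or more; the minimum of two unit-step columns is
again a unit-step column, so the result stays representable.
"""

from __future__ import annotations

from .seq import IUPAC_SETS, bases_match

MASK = (1 << 64) - 1
HIGH = 1 << 63
WORD = 64

# a column state is the tuple (vp, vn, score_at_bottom_row)
ColumnState = tuple[int, int, int]


def advance(
    vp: int, vn: int, score: int, eq: int, hin: int
) -> tuple[int, int, int, int]:
    """One Myers column step: returns (vp', vn', score', hout).

    ``eq`` has bit i set when query row i matches the new column's graph
    character; ``hin`` in {-1, 0, +1} is the horizontal score delta along the
    top boundary row.  The implied scores of the result equal one column of
    the unit-cost edit DP (match 0, mismatch/indel 1).
    """
    xv = eq | vn
    if hin < 0:
        eq |= 1
    xh = ((((eq & vp) + vp) & MASK) ^ vp) | eq
    ph = vn | (~(xh | vp) & MASK)
    mh = vp & xh
    if ph & HIGH:
        hout = 1
    elif mh & HIGH:
        hout = -1
    else:
        hout = 0
    ph = (ph << 1) & MASK
    mh = (mh << 1) & MASK
    if hin > 0:
        ph |= 1
    elif hin < 0:
        mh |= 1
    vp_new = mh | (~(xv | ph) & MASK)
    vn_new = ph & xv
    return vp_new, vn_new, score + hout, hout


def decode(state: ColumnState) -> list[int]:
    """Implied 65-entry score column, rows -1..63 top to bottom."""
    vp, vn, score = state
    out = [0] * 65
    out[64] = score
    s = score
    for i in range(63, -1, -1):
        bit = 1 << i
        if vp & bit:
            s -= 1
        elif vn & bit:
            s += 1
        out[i] = s
    return out


def encode(column: list[int]) -> ColumnState:
    """Inverse of :func:`decode`; adjacent entries must differ by at most 1."""
    if len(column) != 65:
        raise ValueError("need 65 score entries (rows -1..63)")
    vp = 0
    vn = 0
    for i in range(64):
        d = column[i + 1] - column[i]
        if d == 1:
            vp |= 1 << i
        elif d == -1:
            vn |= 1 << i
        elif d != 0:
            raise ValueError(f"score step {d} at row {i} not in {{-1,0,1}}")
    return (vp, vn, column[64])


def merge(a: ColumnState, b: ColumnState) -> ColumnState:
    """Elementwise minimum of the two implied score columns."""
    if a[2] - 64 > b[2] + 64:
        return b
    if b[2] - 64 > a[2] + 64:
        return a
    da = decode(a)
    db = decode(b)
    return encode([x if x < y else y for x, y in zip(da, db)])


def score_at_row(state: ColumnState, row: int) -> int:
    """Implied score at slice row ``row`` (-1..63)."""
    vp, vn, score = state
    for i in range(63, row, -1):
        bit = 1 << i
        if vp & bit:
            score -= 1
        elif vn & bit:
            score += 1
    return score


def min_score(state: ColumnState, last_row: int = 63) -> int:
    """Minimum implied score over rows 0..last_row."""
    vp, vn, score = state
    best = score
    s = score
    for i in range(63, 0, -1):
        bit = 1 << i
        if vp & bit:
            s -= 1
        elif vn & bit:
            s += 1
        if i - 1 <= last_row and s < best:
            best = s
    return best


def column_from_scores(scores: list[int]) -> ColumnState:
    return encode(scores)


def uniform_column(top: int, slope: int = 1) -> ColumnState:
    """Column with score top at row -1 increasing by ``slope`` in {0,1} per row."""
    if slope == 0:
        return (0, 0, top)
    return (MASK, 0, top + 64)


# ---------------------------------------------------------------------------
# match masks
# ---------------------------------------------------------------------------

class EqTables:
    """Per-slice 64-bit match masks for each graph character.

    Built from one 64-character window of the query (padded with a sentinel
    that matches nothing); masks for ambiguity codes are unions of the A/C/G/T
    masks per the intersecting-sets match rule.
    """

    def __init__(self, window: str) -> None:
        base_masks = {b: 0 for b in "ACGT"}
        for i, ch in enumerate(window[:WORD]):
            if ch == "\0":
                continue
            for b in "ACGT":
                if b in IUPAC_SETS.get(ch, frozenset()):
                    base_masks[b] |= 1 << i
        self._base = base_masks
        self._cache: dict[str, int] = dict(base_masks)

    def eq(self, graph_char: str) -> int:
        m = self._cache.get(graph_char)
        if m is None:
            sets = IUPAC_SETS.get(graph_char)
            if sets is None:
                m = 0
            else:
                m = 0
                for b in sets:
                    m |= self._base[b]
            self._cache[graph_char] = m
        return m
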