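"""Minimizer extraction, a frequency-aware k-mer index over node labels, and
seed-hit collection for reads.

Only node labels are indexed -- edges are ignored -- so every seed hit is an
exact match fully contained in one node.  Long reads nearly always touch
linear stretches of the graph, so per-node matching loses little sensitivity
while keeping the index a plain string index.  Reverse-complement matches are
found by additionally looking up the reverse complement of each read k-mer and
converting the hit back into the node's forward coordinate frame.

Minimizers: the k-mers of minimal hash within each window of w consecutive
valid k-mers, ties all kept.  Only A/C/G/T k-mers participate; ambiguity codes
break the window.  The hash is a fixed 64-bit invertible mixer over the 2-bit
encoding, so indices are reproducible across platforms and thread counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .graph import BidirectedGraph
from .seq import reverse_complement

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK64 = (1 << 64) - 1


def hash_kmer(code: int) -> int:
    """splitmix64 finalizer: a fixed invertible 64-bit mixer."""
    z = (code + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def encode_kmer(kmer: str) -> int | None:
    """2-bit encoding; None if the k-mer contains a non-ACGT character."""
    code = 0
    for c in kmer:
        v = _ENC.get(c)
        if v is None:
            return None
        code = (code << 2) | v
    return code


def rc_code(code: int, k: int) -> int:
    """2-bit encoding of the reverse complement (A<->T, C<->G, reversed)."""
    out = 0
    for _ in range(k):
        out = (out << 2) | ((code & 3) ^ 3)
        code >>= 2
    return out


def canonical_code(code: int, k: int) -> tuple[int, bool]:
    """(canonical encoding, True if the forward encoding is canonical).

    Hashing canonical k-mers makes minimizer selection strand-symmetric, so a
    read and the reverse complement of a node pick the same positions.
    """
    rc = rc_code(code, k)
    return (code, True) if code <= rc else (rc, False)


@dataclass(frozen=True)
class IndexParams:
    """k-mer length, window length, and the discard fraction for the most
    frequent minimizers (x, default 0.02%)."""

    k: int = 19
    w: int = 30
    x: float = 0.0002

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError("k must be in [1, 31]")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("x must be a fraction in [0, 1]")


@dataclass(frozen=True)
class SeedHit:
    """Exact k-mer match between a read and one node's label.

    ``node_offset`` is always in the node's forward frame; for orient '-' the
    read k-mer equals the reverse complement of the node's forward-frame slice.
    """

    read_pos: int
    node: str
    node_offset: int
    orient: str
    length: int
    occurrences: int


def minimizers(s: str, k: int, w: int) -> list[tuple[int, int]]:
    """(kmer code, start) of every window minimizer of ``s``, sorted by start.

    Every window of w consecutive valid k-mers contains at least one selected
    position; ties within a window are all kept; output is deduplicated.
    """
    n = len(s)
    if n < k:
        return []
    cands: list[tuple[int, int]] = []  # (start, code) for valid k-mers
    code = 0
    run = 0  # number of consecutive valid chars ending here
    mask = (1 << (2 * k)) - 1
    for i, c in enumerate(s):
        v = _ENC.get(c)
        if v is None:
            run = 0
            code = 0
            continue
        code = ((code << 2) | v) & mask
        run += 1
        if run >= k:
            cands.append((i - k + 1, code))
    if not cands:
        return []
    hashes = [hash_kmer(canonical_code(c, k)[0]) for _, c in cands]
    selected: set[int] = set()  # indices into cands
    m = len(cands)
    if m <= w:
        windows = [(0, m)]
    else:
        windows = [(i, i + w) for i in range(m - w + 1)]
    # O(m*w) scan; fine for <=64 bp node labels and test-scale reads.
    for lo, hi in windows:
        best = min(hashes[lo:hi])
        for j in range(lo, hi):
            if hashes[j] == best:
                selected.add(j)
    return sorted((cands[j][0], cands[j][1]) for j in selected)


class MinimizerIndex:
    """Map from canonical minimizer codes to (node, offset, is_forward) lists.

    Offsets are forward-frame starts within the node label; ``is_forward``
    records whether the label's k-mer equals the canonical orientation.  The
    top ``x`` fraction of distinct k-mers by occurrence count is flagged
    unusable for seeding (repeat masking); ties at the cutoff are all
    discarded.
    """

    def __init__(self, params: IndexParams) -> None:
        self.params = params
        self.positions: dict[int, list[tuple[str, int, bool]]] = {}
        self._unusable: set[int] = set()

    @property
    def n_distinct(self) -> int:
        return len(self.positions)

    def _apply_frequency_filter(self) -> None:
        self._unusable.clear()
        n = self.n_distinct
        if n == 0 or self.params.x <= 0.0:
            return
        top = math.ceil(self.params.x * n)
        if top <= 0:
            return
        if top >= n:
            self._unusable = set(self.positions)
            return
        counts = sorted((len(v) for v in self.positions.values()), reverse=True)
        cutoff = counts[top - 1]
        # k-mers strictly more frequent than the cutoff count are discarded;
        # ties at the cutoff are kept, so flat count distributions (typical
        # for de Bruijn graphs, where adjacent nodes share k-mers) are not
        # gutted by the filter
        self._unusable = {
            kmer for kmer, v in self.positions.items() if len(v) > cutoff
        }

    def query(self, kmer: str) -> tuple[list[tuple[str, int, bool]], int, bool]:
        """Positions, occurrence count, and usability of a k-mer string.

        The k-mer is canonicalized before lookup, so forward and reverse-
        complement queries return the same entry.
        """
        if len(kmer) != self.params.k:
            raise ValueError(
                f"query k-mer length {len(kmer)} != index k {self.params.k}"
            )
        code = encode_kmer(kmer)
        if code is None:
            return [], 0, True
        canon, _ = canonical_code(code, self.params.k)
        return self.query_code(canon)

    def query_code(self, canon: int) -> tuple[list[tuple[str, int, bool]], int, bool]:
        pos = self.positions.get(canon)
        if pos is None:
            return [], 0, True
        return pos, len(pos), canon not in self._unusable


def build_index(g: BidirectedGraph, params: IndexParams) -> MinimizerIndex:
    """Index the minimizers of every node's forward label.

    Deterministic: nodes are processed in sorted id order and positions stored
    sorted, so the result is independent of any construction parallelism.
    """
    ix = MinimizerIndex(params)
    for nid in sorted(g.nodes):
        for start, code in minimizers(g.nodes[nid].label, params.k, params.w):
            canon, is_fwd = canonical_code(code, params.k)
            ix.positions.setdefault(canon, []).append((nid, start, is_fwd))
    for v in ix.positions.values():
        v.sort()
    ix._apply_frequency_filter()
    return ix


def collect_seeds(
    ix: MinimizerIndex, read: str, density: float = 5.0
) -> list[SeedHit]:
    """Seed hits for a read: minimizer lookups both ways, frequency-capped.

    Each read minimizer is looked up as-is (orient '+') and as its reverse
    complement (orient '-', coordinates converted to the node's forward
    frame).  Hits are sorted by ascending occurrence count and at most
    ceil(len(read) * density) are kept, extended to include all ties with the
    last kept hit's count.  Unusable (over-frequent) k-mers contribute nothing.
    """
    k = ix.params.k
    if len(read) < k:
        return []
    hits: list[SeedHit] = []
    seen: set[tuple] = set()
    for start, code in minimizers(read.upper(), k, ix.params.w):
        canon, read_fwd = canonical_code(code, k)
        posns, count, usable = ix.query_code(canon)
        if not posns or not usable:
            continue
        for node, off, node_fwd in posns:
            # same canonical orientation on both sides -> forward match;
            # opposite -> the read k-mer is the reverse complement of the
            # node's forward-frame slice
            orient = "+" if node_fwd == read_fwd else "-"
            key = (start, node, off, orient)
            if key in seen:
                continue
            seen.add(key)
            hits.append(SeedHit(start, node, off, orient, k, count))
    hits.sort(key=lambda h: (h.occurrences, h.read_pos, h.node, h.node_offset, h.orient))
    cap = math.ceil(len(read) * density)
    if len(hits) > cap and cap > 0:
        cutoff = hits[cap - 1].occurrences
        while cap < len(hits) and hits[cap].occurrences == cutoff:
            cap += 1
        hits = hits[:cap]
    elif cap <= 0:
        hits = []
    return hits
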