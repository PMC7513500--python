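"""Synthetic references, graphs, error-injected reads, and evaluation.

Everything an end-to-end run needs can be generated here deterministically
from a seed: a uniform-random reference, a variation graph built from the
reference plus non-overlapping variants (SNP bubbles, insertion branches,
deletion bypass edges), a toy node-per-k-mer de Bruijn graph, and long reads
sampled from either strand with i.i.d. per-base substitution/insertion/
deletion errors.  Each read carries a :class:`SimTruth` whose error script
replays to the read exactly, so simulators are themselves testable.

Evaluation follows the standard mapping-accuracy criterion for simulated
reads: a read is correctly mapped when its longest alignment's reference
interval (path projected to backbone coordinates, non-reference branch nodes
ignored) overlaps the simulated source interval by at least 10%.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .graph import BidirectedEdge, BidirectedGraph, BidirectedNode
from .output import GraphAlignment
from .seq import reverse_complement


def simulate_reference(length: int, seed: int) -> str:
    """Uniform random ACGT string, reproducible by seed."""
    if length <= 0:
        raise ValueError("reference length must be positive")
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(length))


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

Variant = tuple[int, str, list[str]]  # (pos, ref allele, alt alleles)


def random_variants(
    ref: str,
    density: float = 1 / 15,
    seed: int = 0,
    p_snp: float = 0.9,
    max_indel: int = 3,
) -> list[Variant]:
    """Non-overlapping variants at the given per-base density (mostly SNPs).

    Positions follow a Poisson process (geometric gaps with mean 1/density),
    mimicking the irregular spacing of real variant sets: dense stretches
    alternate with longer conserved segments.
    """
    rng = random.Random(seed)
    variants: list[Variant] = []
    pos = 1 + round(rng.expovariate(density))
    while pos < len(ref) - max_indel - 1:
        r = rng.random()
        if r < p_snp:
            ref_allele = ref[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref_allele])
            variants.append((pos, ref_allele, [alt]))
            consumed = 1
        elif r < p_snp + (1 - p_snp) / 2:
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, max_indel)))
            variants.append((pos, "", [ins]))
            consumed = 0
        else:
            dlen = rng.randint(1, max_indel)
            variants.append((pos, ref[pos : pos + dlen], [""]))
            consumed = dlen
        pos += consumed + max(1, round(rng.expovariate(density)))
    return variants


def build_variation_graph(
    ref: str, variants: list[Variant]
) -> tuple[BidirectedGraph, dict[str, tuple[int, int]]]:
    """Reference backbone split at variant boundaries, one branch per allele.

    Returns the graph and a map from node id to its half-open reference
    interval (absent for non-reference allele nodes).  Deletions become
    bypass edges rather than empty nodes.
    """
    for (p1, r1, _), (p2, _, _) in zip(variants, variants[1:]):
        if p1 + len(r1) > p2:
            raise ValueError(f"overlapping variants at {p1} and {p2}")
    g = BidirectedGraph()
    ref_pos: dict[str, tuple[int, int]] = {}
    frontier: list[str] = []
    counter = 0

    def add_node(label: str, interval: tuple[int, int] | None) -> str:
        nonlocal counter
        nid = f"n{counter}"
        counter += 1
        g.add_node(BidirectedNode(nid, label))
        if interval is not None:
            ref_pos[nid] = interval
        return nid

    def connect(sources: list[str], target: str) -> None:
        for s in sources:
            g.add_edge(BidirectedEdge(s, "+", target, "+", 0))

    cursor = 0
    for pos, ref_allele, alts in sorted(variants):
        if pos > cursor:
            seg = add_node(ref[cursor:pos], (cursor, pos))
            connect(frontier, seg)
            frontier = [seg]
        entry = list(frontier)
        new_frontier: list[str] = []
        for allele, is_ref in [(ref_allele, True)] + [(a, False) for a in alts]:
            if not allele:
                for e in entry:
                    if e not in new_frontier:
                        new_frontier.append(e)
            else:
                interval = (pos, pos + len(ref_allele)) if is_ref else None
                nid = add_node(allele, interval)
                connect(entry, nid)
                new_frontier.append(nid)
        frontier = new_frontier
        cursor = pos + len(ref_allele)
    if cursor < len(ref):
        seg = add_node(ref[cursor:], (cursor, len(ref)))
        connect(frontier, seg)
    return g, ref_pos


def build_toy_dbg(seqs: list[str], k: int) -> BidirectedGraph:
    """Node-per-distinct-canonical-k-mer de Bruijn graph with k-1 overlaps.

    Every input sequence is spelled by a walk through the graph.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be odd and >= 3")
    g = BidirectedGraph()
    node_of: dict[str, str] = {}

    def canonical(kmer: str) -> tuple[str, str]:
        rc = reverse_complement(kmer)
        return (kmer, "+") if kmer <= rc else (rc, "-")

    def ensure(kmer: str) -> tuple[str, str]:
        canon, orient = canonical(kmer)
        nid = node_of.get(canon)
        if nid is None:
            nid = f"k{len(node_of)}"
            node_of[canon] = nid
            g.add_node(BidirectedNode(nid, canon))
        return nid, orient

    for s in seqs:
        s = s.upper()
        prev: tuple[str, str] | None = None
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if any(c not in "ACGT" for c in kmer):
                prev = None
                continue
            cur = ensure(kmer)
            if prev is not None:
                g.add_edge(BidirectedEdge(prev[0], prev[1], cur[0], cur[1], k - 1))
            prev = cur
    return g


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Provenance of one simulated read, with a replayable error script.

    The script is a list of per-source-base actions over the oriented source
    sequence: 'M' copy, 'S<base>' substitute, 'D' delete; insertions appear
    as 'I<base>' entries between base actions.
    """

    read_id: str
    start: int
    end: int
    strand: str
    n_sub: int
    n_ins: int
    n_del: int
    script: list[str] = field(default_factory=list)

    def replay(self, reference: str) -> str:
        src = reference[self.start : self.end]
        if self.strand == "-":
            src = reverse_complement(src)
        out: list[str] = []
        i = 0
        for action in self.script:
            if action.startswith("I"):
                out.append(action[1])
            elif action == "M":
                out.append(src[i])
                i += 1
            elif action.startswith("S"):
                out.append(action[1])
                i += 1
            elif action == "D":
                i += 1
            else:
                raise ValueError(f"bad script action {action!r}")
        return "".join(out)


def simulate_reads(
    reference: str,
    n: int,
    length: int,
    err_rates: tuple[float, float, float] = (0.04, 0.03, 0.03),
    seed: int = 0,
    id_prefix: str = "read",
) -> tuple[list[tuple[str, str]], list[SimTruth]]:
    """Error-injected reads from both strands of a linear reference.

    ``err_rates`` are i.i.d. per-base (substitution, insertion, deletion)
    probabilities; the insertion draw happens after each emitted base.
    """
    p_sub, p_ins, p_del = err_rates
    if min(err_rates) < 0 or p_sub + p_ins + p_del >= 1:
        raise ValueError("error rates must be in [0,1) and sum below 1")
    if length > len(reference):
        raise ValueError("read length exceeds reference length")
    rng = random.Random(seed)
    reads: list[tuple[str, str]] = []
    truths: list[SimTruth] = []
    for i in range(n):
        start = rng.randint(0, len(reference) - length)
        end = start + length
        strand = rng.choice("+-")
        src = reference[start:end]
        if strand == "-":
            src = reverse_complement(src)
        out: list[str] = []
        script: list[str] = []
        n_sub = n_ins = n_del = 0
        for base in src:
            r = rng.random()
            if r < p_del:
                script.append("D")
                n_del += 1
                continue
            if r < p_del + p_sub:
                sub = rng.choice([b for b in "ACGT" if b != base])
                out.append(sub)
                script.append("S" + sub)
                n_sub += 1
            else:
                out.append(base)
                script.append("M")
            if rng.random() < p_ins:
                ins = rng.choice("ACGT")
                out.append(ins)
                script.append("I" + ins)
                n_ins += 1
        rid = f"{id_prefix}{i}"
        reads.append((rid, "".join(out)))
        truths.append(SimTruth(rid, start, end, strand, n_sub, n_ins, n_del, script))
    return reads, truths


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def reference_interval(
    alignment: GraphAlignment, ref_pos: dict[str, tuple[int, int]]
) -> tuple[int, int] | None:
    """Backbone interval covered by an alignment's path.

    Non-reference branch nodes are ignored; the interval is the minimum and
    maximum of the reference positions covered.
    """
    starts: list[int] = []
    ends: list[int] = []
    for nid, _ in alignment.path:
        iv = ref_pos.get(nid)
        if iv is not None:
            starts.append(iv[0])
            ends.append(iv[1])
    if not starts:
        return None
    return min(starts), max(ends)


def evaluate(
    alignments_by_read: dict[str, list[GraphAlignment]],
    truths: list[SimTruth],
    ref_pos: dict[str, tuple[int, int]],
    overlap_frac: float = 0.10,
) -> float:
    """Fraction of reads whose longest alignment overlaps its source interval
    by at least ``overlap_frac`` of the source interval's length."""
    correct = 0
    for truth in truths:
        alns = alignments_by_read.get(truth.read_id, [])
        if not alns:
            continue
        best = max(alns, key=lambda a: a.query_span)
        iv = reference_interval(best, ref_pos)
        if iv is None:
            continue
        lo = max(iv[0], truth.start)
        hi = min(iv[1], truth.end)
        need = overlap_frac * (truth.end - truth.start)
        if hi - lo >= need:
            correct += 1
    return correct / len(truths) if truths else 0.0


# ---------------------------------------------------------------------------
# plain-text writers
# ---------------------------------------------------------------------------

def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_truth_tsv(path, truths: list[SimTruth]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tstrand\tn_sub\tn_ins\tn_del\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.start}\t{t.end}\t{t.strand}\t"
                f"{t.n_sub}\t{t.n_ins}\t{t.n_del}\n"
            )
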