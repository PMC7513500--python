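# Methods

This note documents the models, the numerical choices, and what the synthetic
data do and do not exercise.  It is the design record for maintainers; the
README gives the user-facing summary.

## Graph model and alignment-graph conversion

Bidirected graphs store sequence in nodes traversable in two orientations;
edges join node ends with an exact overlap of *n* nucleotides (`nM` or `*` in
GFA; any other overlap CIGAR is rejected rather than truncated, since the
model defines overlaps purely as a skip count).  The DP engine needs a plain
directed graph, so each node is materialized twice (forward label,
reverse-complemented label) and chopped at (i) the overlap boundary of every
incoming edge and (ii) every 64 bp.  Offsets are 0-based and intervals
half-open throughout.  Backward-traversal breakpoints index into the
reverse-complemented label; the breakpoint sets of the two orientations are
computed independently (each receives the 64-bp multiples plus its own
incident-edge overlaps).  A bidirected edge `(v1,o1,v2,o2,n)` becomes two
directed edges — last chunk of `(v1,o1)` to the chunk of `(v2,o2)` starting
at offset *n*, and the mirrored pair — de-duplicated for self-loops.  The
mapping tables `N/O/D/A` make `pos` a bijection between alignment-graph base
pairs and (source base pair, orientation); this is property-tested
exhaustively on random graphs, together with total-length doubling and
path-spelling equivalence across every edge.

## Seeding

Seeds are exact matches between read minimizers and node labels; matches
crossing node boundaries are not found, which costs little for long reads
because they almost always touch nodes long enough to host a k-mer.
Minimizers hash **canonical** k-mers (the smaller of the 2-bit encoding and
its reverse complement) through a fixed splitmix64 finalizer, so selection is
strand-symmetric and platform-stable: a read and the reverse complement of a
node pick the same positions, which is what makes reverse-strand seeding work
when only per-node minimizers are indexed.  Hits are reported in the node's
forward frame with an orientation flag.

The frequency filter masks k-mers *strictly more frequent* than the count of
the `⌈x·n⌉`-th most frequent distinct k-mer (x = 0.02% of distinct k-mers).
Ties at the cutoff are kept: in de Bruijn graphs adjacent nodes share k-mers
and the count distribution is flat (almost everything occurs 2–3 times), so
discarding ties would mask a large fraction of the index; with the strict
rule the filter still removes genuinely repetitive k-mers while a uniform
count distribution masks nothing.  `x = 100%` masks everything, preserving
the degenerate-filter contract.

Window semantics: windows are runs of *w* consecutive valid (ACGT-only)
k-mers; ambiguity codes interrupt the run.  Labels with fewer than *w* k-mers
form a single window.  All ties within a window are kept.

## Seed clustering

Superbubbles are detected on the directed alignment graph with a one-pass
forward sweep per candidate entrance (a node is entered once all its parents
are visited; tips and cycles abort), which reports exactly the minimal
single-entrance single-exit acyclic subgraphs of the Onodera-style
definition; a brute-force checker over all node pairs (reachability,
matching, acyclicity, minimality) is the test oracle.  Bubbles sharing
exit = entrance form chains; a BFS from the chain's first entrance assigns
`D[v]`, with `D[v] = D[u] + |label(u)|` on the first visit via `u → v` and
sorted adjacency for determinism.  Pure dead-end paths hanging off a chain
("tips") are folded into the chain and linearized by the same rule; cyclic
regions stay outside chains, so their seeds become singleton clusters —
conservative, since it can only prevent merges, never create false ones.

Seeds map through the tables to alignment-graph coordinates; within a chain
the diagonal is `d = read_pos − (D[v] + offset)` and seeds with
`|d₁ − d₂| ≤ c = 100` are connected; clusters are connected components
(equivalently the transitive closure, computed by sorting within each chain).
Scores: `s′ = m − x` against the read's maximum occurrence count *m*, plus
the cluster's read coverage `c_C` (interval union).  Extension order is by
descending score with deterministic tie-breaks; up to `⌈l·e⌉` seeds are
extended, ties included, and seeds inside an already-produced alignment
(read interval contained, oriented node on the path) are skipped without
counting.

## Banded bit-parallel extension

A column state is `(VP, VN, score)`: 64 vertical ±1 deltas plus the absolute
bottom-row score; the implied 65-entry column changes by at most one per row.
`advance` is Myers' update extended with a horizontal carry `hin ∈ {−1,0,+1}`
at the top boundary, verified cell-for-cell against a scalar DP on 10⁴ random
columns.  Merging at in-degree ≥ 2 takes the elementwise minimum of the
implied columns (decode/min/encode — the minimum of two unit-step columns is
again unit-step); because the DP recurrence is min-plus linear, merging
before advancing is exact.

Slices are 64 read rows; blocks are node × slice.  Within a slice, blocks
are processed best-first from a worklist and re-computed until a fixpoint
(scores only decrease, so this terminates and handles cycles exactly); the
worklist priority is the block's minimum cell, or the minimum *priority
value* `k/e − row` (`64k − row` when the observed error rate `e ≤ 1/64`)
when the tangle effort is set.  The per-slice minimum *m* is discovered as
blocks complete, and a block is in-band iff some cell ≤ `m + b`; blocks out
of band when the slice ends are stored (the backtrace may need them) but not
propagated.  This one-pass discovery can include blocks a stricter two-pass
band would drop; it never loses the optimum relative to the declared band.
When the tangle effort *C* is exceeded, the slice freezes as computed and
extension moves on.

Boundary semantics.  Blocks continuing from the previous slice take their
top row from the stored bottom borders.  A block with no in-band left
context gets a synthetic worst-case entry column consistent with the known
top corner (top + 1, all deltas +1) — a provable upper bound of the unbanded
DP, so banded scores never fall below the true optimum.  Initialization
boundaries (a seed anchor, or the whole first row in seedless mode)
additionally admit a *virtual start column*, so an alignment may begin
diagonally at a node's first base; the scalar oracle implements the same
rule for pred-less columns, and with an effectively unbanded setting the
engine equals the oracle exactly on hundreds of random cyclic instances.

Storage: per block the first/last column states (corner scores + 2-bit
vertical border deltas), the bottom-row horizontal deltas, and the absolute
top boundary.  Interiors are recomputed on demand by re-advancing from the
left border — exact because columns within a node are cycle-free.  The
information-theoretic motivation: storing all 64×64 ternary deltas costs
log₂(3⁴⁰⁹⁶)/8 ≈ 812 bytes versus log₂(3¹⁹⁰)/8 ≈ 38 bytes for borders only.

Seeded extension is bidirectional: forward over the read suffix anchored at
the seed's start base, backward as a forward extension of the
reverse-complemented prefix anchored at the opposite-strand copy of the same
base (the alignment graph contains both strands, so no special machinery is
needed).  The two traces are stitched at the seed in read order; graph-only
deletions keep their traced positions.

## Correctness model and clipping

Observations are per-slice increments of the minimum score, clamped to
[0, 64].  Two hidden states emit Binomial(64, rate) error counts with rates
0.20 (correct) and 0.50 (wrong) — rates chosen to bracket long-read error
levels.  The transition matrix is not part of the emission contract and was
left open; the default is symmetric with stay probability 1 − 10⁻⁵ per
slice, so a single noisy slice cannot flip the state, and the initial
distribution is uniform.  All arithmetic is in log space.  Slice *n* is
guaranteed correct when the Viterbi predecessor of the wrong state at
*n* + 1 is the correct state (every continuation passes through it), and
symmetrically guaranteed wrong; the flags are verified against exhaustive
path enumeration.

Ramping: when the wrong state first dominates, the extension re-aligns from
the slice after the last guaranteed-correct one with the ramp band `B > b`
and keeps `B` for the rest of the extension.  The one-ramp-per-dip rule is
re-armed only when the correct state dominates at a slice *beyond* the one
that triggered the ramp — re-computed prefix slices must not re-arm it, or a
junk tail would ramp indefinitely.  A guaranteed-wrong slice terminates the
extension; the alignment is clipped to the last guaranteed-correct slice
(backtrace from its minimum bottom-row cell, read interval capped at
`(n+1)·64`).  An extension that reaches the query end with the correct state
dominant is reported full-length, since the final slice can have no
successor to certify it.  A seed with no guaranteed-correct slice yields no
alignment.

## Output conventions

GAF coordinates are 0-based half-open; the strand column is `+` with
orientation in the `>`/`<` path string; `cg:Z` uses `=`/`X`/`I`/`D`.
Overlap bases are attributed to the earlier node of the path: the path
interval start is the entry offset within the first node, and the interval
length equals the number of alignment-graph bases consumed (each shared base
counted once).  Leading and trailing deletions are trimmed from traces.
mapq is a stated heuristic, 60 for a primary alignment whose best seed score
was unique, else 0.  Selection is greedy longest-first with read-disjoint
keeps; classification is order-invariant because the sort key is total.

## Presets

| preset | k | w | d | e | c | b | B | C |
|--------|---|---|---|---|---|---|---|----|
| `vg` (variation graphs) | 15 | 20 | 10 | 1 | 100 | 5 | 10 | – |
| `dbg` (de Bruijn graphs) | 19 | 30 | 5 | 0.002 | 100 | 5 | 10 | 100 000 |

k/w/d/e/c follow the recommended values for the two graph families; b, B and
C are exposed flags whose defaults were chosen once as reasonable for ~10%
error reads (b = 5 tolerates the per-slice error fluctuation of such reads;
B = 2b; C = 10⁵ cells keeps a slice under a second in tangled de Bruijn
regions while far exceeding what a clean region needs).

## Synthetic data: what it emulates and what it does not

`simulate_reference` draws uniform ACGT — no repeat structure, GC skew or
compositional bias, so seeding is easier than on real genomes (fewer
frequent k-mers) while tangles are rarer.  `random_variants` places variants
as a Poisson process (geometric gaps, mean 1/density, default 1/15; 90% SNPs,
the rest short indels ≤ 3 bp): real variant spacing is irregular, and that
irregularity is load-bearing — with fixed 15-bp spacing every backbone node
would be shorter than k and within-node seeding would be impossible by
construction, which is not how real variation graphs behave.
`simulate_reads` uses i.i.d. per-base substitution/insertion/deletion errors
(defaults 4%/3%/3%, ~10% total) on both strands; real instruments produce
bursty, homopolymer-biased errors, so passing tests show robustness to error
*rate*, not to error *structure*.  Every read carries a replayable error
script, making the simulator itself testable.  The toy de Bruijn graph
builder (node per distinct canonical k-mer, k−1 overlaps) emulates
unitig-DBG inputs at small scale; it performs no graph cleaning.

Evaluation uses the 10%-overlap criterion on the longest alignment per read,
with alignment paths projected to backbone coordinates (non-reference branch
nodes ignored; interval = min/max reference positions covered) — the
standard criterion for simulated-read mapping accuracy, applied with ≥, so a
boundary-exact 10% overlap counts.

## Problem sizes in the acceptance run

The acceptance script recomputes everything from its seed: 200 random
graph/read instances for the oracle-equivalence rate; 100 linear-graph reads
with ≤ 5 injected errors for the band guarantee; 100 prefix+junk reads on a
4-kb backbone for clip recovery (junction recovered within 2 slices);
recall of 500 1500-bp reads at 10% error against a 50-kb variation graph
with one variant per 15 bp; and 40 1500-bp reads corrected against a k = 21
de Bruijn graph of a 20-kb genome (short reads error-free, 150 bp, 50 bp
stride ≈ 3× tiling), with residual error measured against the known source
interval by an independent alignment library (edlib).  These sizes are the
package's scaled-down study conditions; the synthetic genome sizes keep the
whole run in the minutes range on one CPU while leaving each estimate's
sampling error well below the margins being tested.

## Known limitations

* Seeds never cross node boundaries; graphs whose nodes are all shorter than
  k cannot be seeded (seedless mode or external seeds remain available).
* Seedless mode scans the whole graph and is practical only up to a few
  hundred kb of graph sequence.
* The band's one-pass minimum discovery may compute blocks a two-pass
  implementation would skip; this affects runtime, not results.
* mapq is a coarse heuristic, not a calibrated probability.
* The error-correction mode assumes a clean (error-free or pre-corrected)
  de Bruijn graph; it does not clean the graph itself.
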