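import itertools
import random

import pytest

from gralign.clustering import (
    SeedCluster,
    Superbubble,
    build_chains,
    cluster_seeds,
    find_superbubbles,
    linearize,
    score_seeds,
    select_extension_order,
    ScoredSeed,
)
from gralign.minimizers import SeedHit

from conftest import DirectedStub, random_dag


# ---------------------------------------------------------------------------
# brute-force superbubble oracle (reachability / matching / acyclicity /
# minimality, checked over all node pairs)
# ---------------------------------------------------------------------------

def _reach_avoiding(out, src, avoid):
    seen = {src}
    stack = [src]
    while stack:
        v = stack.pop()
        if v == avoid:
            continue  # do not extend through the avoided node
        for u in out[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _acyclic(out, nodes):
    indeg = {v: 0 for v in nodes}
    for v in nodes:
        for u in out[v]:
            if u in indeg:
                indeg[u] += 1
    queue = [v for v in nodes if indeg[v] == 0]
    done = 0
    while queue:
        v = queue.pop()
        done += 1
        for u in out[v]:
            if u in indeg:
                indeg[u] -= 1
                if indeg[u] == 0:
                    queue.append(u)
    return done == len(nodes)


def brute_force_superbubbles(g: DirectedStub):
    out = {v: g.out[v] for v in range(g.n_nodes)}
    inn = {v: g.inn[v] for v in range(g.n_nodes)}
    rout = {v: inn[v] for v in out}

    def candidate(s, t):
        if s == t:
            return None
        U = _reach_avoiding(out, s, t)
        if t not in U:
            return None
        W = _reach_avoiding(rout, t, s)
        if U != W:
            return None
        if not _acyclic(out, U - {t}):
            return None
        if s in out[t]:
            return None
        return U

    found = []
    for s in range(g.n_nodes):
        # minimal exit: smallest U among valid candidates
        best = None
        for t in range(g.n_nodes):
            U = candidate(s, t)
            if U is not None and (best is None or len(U) < len(best[1])):
                best = (t, U)
        if best is not None:
            t, U = best
            found.append(Superbubble(s, t, frozenset(U - {s, t})))
    return found


class TestFindSuperbubbles:
    def test_snp_bubble(self):
        g = DirectedStub({0: [1, 2], 1: [3], 2: [3], 3: []})
        bubbles = find_superbubbles(g)
        assert Superbubble(0, 3, frozenset({1, 2})) in bubbles

    def test_no_superbubble_contains_a_cycle(self):
        g = DirectedStub({0: [1], 1: [2], 2: [0]})
        for b in find_superbubbles(g):
            assert not {0, 1, 2} <= b.nodes  # acyclicity forbids the full cycle
            assert b.internals == frozenset()

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_brute_force_on_random_dags(self, seed):
        g = DirectedStub(random_dag(random.Random(seed)))
        got = {(b.entrance, b.exit, b.internals) for b in find_superbubbles(g)}
        want = {
            (b.entrance, b.exit, b.internals) for b in brute_force_superbubbles(g)
        }
        assert got == want

    @pytest.mark.parametrize("seed", range(20))
    def test_reported_bubbles_satisfy_definition(self, seed):
        """Entrance reaches all internals, internals reach the exit, no edges
        cross the boundary except through entrance/exit, induced acyclic."""
        g = DirectedStub(random_dag(random.Random(100 + seed)))
        for b in find_superbubbles(g):
            nodes = b.internals | {b.entrance, b.exit}
            reach = _reach_avoiding({v: g.out[v] for v in range(g.n_nodes)},
                                    b.entrance, b.exit)
            assert b.internals <= reach
            for v in b.internals:
                assert all(u in nodes for u in g.out[v])
                assert all(u in nodes for u in g.inn[v])
            assert _acyclic({v: [u for u in g.out[v] if u in nodes] for v in nodes},
                            nodes - {b.exit} | {b.exit})


class TestChains:
    def test_three_bubble_chain(self):
        # A - B - C - D with a two-way branch inside each gap
        out = {0: [1, 2], 1: [3], 2: [3], 3: [4, 5], 4: [6], 5: [6],
               6: [7, 8], 7: [9], 8: [9], 9: []}
        g = DirectedStub(out)
        chains = build_chains(find_superbubbles(g), g)
        assert len(chains) == 1
        assert len(chains[0].bubbles) == 3

    def test_disjoint_bubbles_two_chains(self):
        out = {0: [1, 2], 1: [3], 2: [3], 3: [],
               4: [5, 6], 5: [7], 6: [7], 7: []}
        g = DirectedStub(out)
        chains = build_chains(find_superbubbles(g), g)
        assert len(chains) == 2

    def test_every_bubble_in_exactly_one_chain(self):
        for seed in range(25):
            g = DirectedStub(random_dag(random.Random(200 + seed)))
            bubbles = find_superbubbles(g)
            chains = build_chains(bubbles, g)
            assigned = [b for c in chains for b in c.bubbles]
            assert len(assigned) == len(bubbles)
            assert {(b.entrance, b.exit) for b in assigned} == {
                (b.entrance, b.exit) for b in bubbles
            }


class TestLinearize:
    def test_path_graph_offsets(self):
        g = DirectedStub({0: [1], 1: [2], 2: []},
                         labels={0: "AAAA", 1: "CCCCC", 2: "GGGGGG"})
        chains = build_chains(find_superbubbles(g), g)
        assert len(chains) == 1
        dlin = linearize(chains[0], g)
        assert [dlin[v] for v in (0, 1, 2)] == [0, 4, 9]

    def test_equal_branches_share_offset(self):
        g = DirectedStub({0: [1, 2], 1: [3], 2: [3], 3: []},
                         labels={0: "AAAA", 1: "C", 2: "G", 3: "TT"})
        chains = build_chains(find_superbubbles(g), g)
        dlin = linearize(chains[0], g)
        assert dlin[1] == dlin[2] == 4
        assert dlin[3] == 5

    def test_monotone_along_paths(self):
        g = DirectedStub({0: [1, 2], 1: [3], 2: [3], 3: [4], 4: []},
                         labels={v: "ACGT" for v in range(5)})
        chains = build_chains(find_superbubbles(g), g)
        dlin = linearize(chains[0], g)
        for u in range(5):
            for v in g.out[u]:
                assert dlin[v] > dlin[u]


# ---------------------------------------------------------------------------
# clustering and scoring
# ---------------------------------------------------------------------------

def _union_find_clusters(seeds_with_diag, c):
    """O(n^2) pairwise transitive closure oracle."""
    parent = list(range(len(seeds_with_diag)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(seeds_with_diag)), 2):
        if abs(seeds_with_diag[i] - seeds_with_diag[j]) <= c:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(seeds_with_diag)):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(v) for v in groups.values())


class TestClusterSeeds:
    def _setup(self, length=400):
        """Linear graph of one long node: one chain, simple diagonals."""
        import random as _r
        from gralign.graph import BidirectedGraph, BidirectedNode
        from gralign.alignment_graph import build_alignment_graph
        from gralign.clustering import build_chains as bc, find_superbubbles as fs

        rng = _r.Random(3)
        label = "".join(rng.choice("ACGT") for _ in range(length))
        g = BidirectedGraph([BidirectedNode("v", label)])
        ag, tables = build_alignment_graph(g)
        chains = bc(fs(ag), ag)
        return g, ag, tables, chains

    def test_nearby_diagonals_share_cluster(self):
        g, ag, tables, chains = self._setup()
        seeds = [
            SeedHit(100, "v", 40, "+", 19, 1),   # d = 60
            SeedHit(150, "v", 91, "+", 19, 1),   # d = 59
        ]
        clusters, scored = cluster_seeds(seeds, chains, ag, tables, c=100)
        real = [c for c in clusters if len(c.members) == 2]
        assert len(real) == 1

    def test_boundary_diagonals_split(self):
        g, ag, tables, chains = self._setup()
        seeds = [
            SeedHit(50, "v", 50, "+", 19, 1),    # d = 0
            SeedHit(181, "v", 80, "+", 19, 1),   # d = 101
        ]
        clusters, _ = cluster_seeds(seeds, chains, ag, tables, c=100)
        assert all(len(c.members) == 1 for c in clusters)
        # d difference exactly c stays together
        seeds2 = [
            SeedHit(50, "v", 50, "+", 19, 1),    # d = 0
            SeedHit(180, "v", 80, "+", 19, 1),   # d = 100
        ]
        clusters2, _ = cluster_seeds(seeds2, chains, ag, tables, c=100)
        assert any(len(c.members) == 2 for c in clusters2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        g, ag, tables, chains = self._setup()
        rng = random.Random(seed)
        seeds = [
            SeedHit(rng.randint(0, 300), "v", rng.randint(0, 300), "+", 19, 1)
            for _ in range(20)
        ]
        clusters, scored = cluster_seeds(seeds, chains, ag, tables, c=30)
        diags = [s.diagonal for s in scored]
        want = _union_find_clusters(diags, 30)
        index_of = {id(s): i for i, s in enumerate(scored)}
        got = sorted(
            sorted(index_of[id(m)] for m in c.members) for c in clusters
        )
        assert got == want


class TestScoreSeeds:
    def _cluster(self, hits, chain_id=0):
        scored = [ScoredSeed(h, 0, 0, chain_id, 0) for h in hits]
        return SeedCluster(chain_id, scored), scored

    def test_singleton_scoring(self):
        c, scored = self._cluster([SeedHit(0, "v", 0, "+", 19, 3)])
        score_seeds([c], max_occurrence=10)
        assert scored[0].unclustered_score == 7    # s' = m - x = 10 - 3
        assert c.coverage == 19                     # c_C = k
        assert scored[0].score == 26                # s = s' + c_C

    def test_max_occurrence_scores_zero(self):
        c, scored = self._cluster([SeedHit(0, "v", 0, "+", 19, 10)])
        score_seeds([c], max_occurrence=10)
        assert scored[0].unclustered_score == 0

    def test_occurrence_above_max_rejected(self):
        c, _ = self._cluster([SeedHit(0, "v", 0, "+", 19, 11)])
        with pytest.raises(ValueError):
            score_seeds([c], max_occurrence=10)

    def test_overlapping_coverage_union(self):
        c, scored = self._cluster(
            [SeedHit(0, "v", 0, "+", 19, 1), SeedHit(10, "v", 10, "+", 19, 1)]
        )
        score_seeds([c], max_occurrence=1)
        assert c.coverage == 29  # union of [0,19) and [10,29), not 38


class TestSelectExtensionOrder:
    def _scored(self, scores):
        out = []
        for i, s in enumerate(scores):
            ss = ScoredSeed(SeedHit(i, "v", i, "+", 19, 1), 0, 0, 0, 0)
            ss.score = s
            out.append(ss)
        return out

    def test_all_kept_when_density_large(self):
        scored = self._scored([5, 9, 1])
        order = select_extension_order(scored, e=1.0, read_length=100)
        assert [s.score for s in order] == [9, 5, 1]

    def test_cap_plus_ties(self):
        scored = self._scored([9, 8, 8, 8, 1])
        order = select_extension_order(scored, e=0.002, read_length=1000)
        # cap = 2, but ties with the 2nd kept score (8) extend the prefix
        assert [s.score for s in order] == [9, 8, 8, 8]

    def test_all_same_score_all_kept(self):
        scored = self._scored([4] * 10)
        order = select_extension_order(scored, e=0.002, read_length=1000)
        assert len(order) == 10
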