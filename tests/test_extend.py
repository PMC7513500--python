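import random

import pytest

from gralign.graph import BidirectedGraph, BidirectedNode, BidirectedEdge
from gralign.alignment_graph import build_alignment_graph
from gralign.bitdp import decode
from gralign.extend import (
    BandParams,
    align_seedless,
    backtrace,
    border_bound_bytes,
    dense_block_bound_bytes,
    extend_query,
    final_row_scores,
    load_border,
    oracle_full_dp,
    priority_value,
    seed_init_tops,
    sparsify,
)

from conftest import random_bidirected_graph


def make_linear(label):
    return build_alignment_graph(BidirectedGraph([BidirectedNode("v", label)]))


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestBandParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            BandParams(b=0, B=1)
        with pytest.raises(ValueError):
            BandParams(b=5, B=5)
        with pytest.raises(ValueError):
            BandParams(b=5, B=10, C_tangle=0)


class TestOracleFullDp:
    def test_linear_graph_equals_two_sequence_dp(self):
        rng = random.Random(1)
        ref = rand_seq(rng, 40)
        read = rand_seq(rng, 25)
        ag, _ = make_linear(ref)
        rows = oracle_full_dp(ag, read)
        # independent semi-global DP over the forward strand only
        fwd_cols = [c for c in rows[0] if c[0] == 0]
        import numpy as np
        D = np.zeros((len(read) + 1, len(ref) + 1), dtype=int)
        D[1:, 0] = np.arange(1, len(read) + 1)
        for i, rc in enumerate(read, 1):
            for j, gc in enumerate(ref, 1):
                D[i, j] = min(
                    D[i - 1, j] + 1,
                    D[i, j - 1] + 1,
                    D[i - 1, j - 1] + (rc != gc),
                )
        for (aid, col) in fwd_cols:
            assert rows[-1][(aid, col)] == D[len(read), col + 1]

    def test_cyclic_repeat_scores_zero(self):
        g = BidirectedGraph([BidirectedNode("v", "ACG")])
        g.add_edge(BidirectedEdge("v", "+", "v", "+", 0))
        ag, _ = build_alignment_graph(g)
        rows = oracle_full_dp(ag, "ACGACG")
        assert min(rows[-1].values()) == 0


class TestSeedlessExtension:
    def test_perfect_read_scores_zero(self, linear_graph):
        ag, _ = build_alignment_graph(linear_graph)
        read = linear_graph.label("chr")[100:300]
        res = align_seedless(ag, read, BandParams(b=5, B=10))
        scores = final_row_scores(ag, res)
        assert min(scores.values()) == 0

    def test_verbatim_read_found_in_small_graph(self, snp_bubble_graph):
        ag, _ = build_alignment_graph(snp_bubble_graph)
        read = "ACGTACGTAC" + "A" + "TTGCAAGGTC"
        res = align_seedless(ag, read, BandParams(b=5, B=10))
        assert min(final_row_scores(ag, res).values()) == 0

    def test_empty_read_rejected(self):
        ag, _ = make_linear("ACGT")
        with pytest.raises(ValueError):
            align_seedless(ag, "", BandParams(b=2, B=3))

    @pytest.mark.parametrize("seed", range(60))
    def test_oracle_equivalence_unbanded(self, seed):
        """With b >= |read| every in-band final score equals the full DP,
        including cyclic graphs, and the minima coincide."""
        rng = random.Random(seed)
        g = random_bidirected_graph(rng)
        ag, _ = build_alignment_graph(g)
        read = rand_seq(rng, rng.randint(3, 70))
        res = align_seedless(ag, read, BandParams(b=len(read) + 1, B=len(read) + 2))
        got = final_row_scores(ag, res)
        want = oracle_full_dp(ag, read)[-1]
        assert got
        for cell, sc in got.items():
            assert sc == want[cell]
        assert min(got.values()) == min(want.values())

    @pytest.mark.parametrize("seed", range(25))
    def test_band_guarantee_on_linear_graphs(self, seed):
        """Reads with at most b errors: banded score equals the unbanded
        optimum."""
        rng = random.Random(1000 + seed)
        ref = rand_seq(rng, 300)
        ag, _ = make_linear(ref)
        b = 5
        start = rng.randint(0, 150)
        read = list(ref[start : start + 120])
        n_err = rng.randint(0, b)
        for _ in range(n_err):
            i = rng.randrange(len(read))
            read[i] = rng.choice([c for c in "ACGT" if c != read[i]])
        read = "".join(read)
        banded = align_seedless(ag, read, BandParams(b=b, B=b + 1))
        full = oracle_full_dp(ag, read)[-1]
        assert min(final_row_scores(ag, banded).values()) == min(full.values())

    def test_per_slice_minima_monotone(self, linear_graph):
        ag, _ = build_alignment_graph(linear_graph)
        rng = random.Random(7)
        read = list(linear_graph.label("chr")[500:800])
        for _ in range(20):
            i = rng.randrange(len(read))
            read[i] = rng.choice("ACGT")
        res = align_seedless(ag, "".join(read), BandParams(b=8, B=9))
        mins = [s.min_score for s in res.summaries]
        assert mins == sorted(mins)


class TestSeededExtension:
    def test_anchored_extension_scores_zero_for_exact_suffix(self):
        rng = random.Random(11)
        ref = rand_seq(rng, 500)
        ag, tables = make_linear(ref)
        query = ref[200:380]
        aid, within = tables.chunk_at("v", "+", 199)
        res = extend_query(
            ag, query, seed_init_tops(ag, aid, within), BandParams(b=5, B=10)
        )
        assert min(final_row_scores(ag, res).values()) == 0


class TestSparseStorage:
    def _stored(self, seed=0):
        rng = random.Random(seed)
        ref = rand_seq(rng, 400)
        ag, _ = make_linear(ref)
        read = list(ref[50:250])
        for _ in range(8):
            i = rng.randrange(len(read))
            read[i] = rng.choice("ACGT")
        res = align_seedless(ag, "".join(read), BandParams(b=6, B=7))
        return ag, res

    def test_border_round_trip(self):
        ag, res = self._stored()
        for (aid, s), sb in res.sparse.items():
            borders = load_border(res.sparse, aid, s)
            assert borders is not None
            left, right, bottom = borders
            assert left[-1] == sb.corner_bl
            assert right[-1] == sb.corner_br
            assert bottom[0] == sb.corner_bl and bottom[-1] == sb.corner_br
            assert len(bottom) == len(ag.labels[aid])

    def test_absent_block_signalled(self):
        ag, res = self._stored()
        assert load_border(res.sparse, 10 ** 6, 0) is None

    def test_border_deltas_are_unit_steps(self):
        ag, res = self._stored(seed=3)
        for sb in res.sparse.values():
            assert all(d in (-1, 0, 1) for d in sb.bottom_deltas)
            for state in (sb.first_col, sb.last_col):
                col = decode(state)
                assert all(abs(a - b) <= 1 for a, b in zip(col, col[1:]))

    def test_interior_recomputation_matches_original(self):
        """Interiors rebuilt from the sparse borders equal the originally
        computed full blocks."""
        from gralign.extend import _ScoreCache, _compute_slice
        ag, res = self._stored(seed=4)
        cache = _ScoreCache(ag, res)
        for (aid, s), sb in res.sparse.items():
            mat = cache.matrix(aid, s)
            bottoms = sb.bottom_scores()
            for j in range(len(ag.labels[aid])):
                assert mat[j, 64] == bottoms[j]
            left = decode(sb.first_col)[1:]
            assert list(mat[0, 1:]) == left


class TestBacktrace:
    def test_perfect_match_all_diagonal(self):
        rng = random.Random(5)
        ref = rand_seq(rng, 300)
        ag, _ = make_linear(ref)
        read = ref[40:200]
        res = align_seedless(ag, read, BandParams(b=4, B=5))
        tr = backtrace(ag, res)
        assert tr is not None and tr.score == 0
        assert all(o.op == "=" for o in tr.ops)
        assert tr.q_end - tr.q_start == len(read)

    def test_single_read_deletion_is_one_graph_only_op(self):
        rng = random.Random(6)
        ref = rand_seq(rng, 200)
        ag, _ = make_linear(ref)
        read = ref[20:60] + ref[61:120]  # one reference base missing
        res = align_seedless(ag, read, BandParams(b=4, B=5))
        tr = backtrace(ag, res)
        assert tr.score == 1
        assert sum(1 for o in tr.ops if o.op == "D") == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_traced_cost_equals_score(self, seed):
        rng = random.Random(40 + seed)
        g = random_bidirected_graph(rng)
        ag, _ = build_alignment_graph(g)
        read = rand_seq(rng, rng.randint(5, 60))
        res = align_seedless(ag, read, BandParams(b=len(read) + 1, B=len(read) + 2))
        tr = backtrace(ag, res)
        if tr is None:
            return
        cost = sum(1 for o in tr.ops if o.op in "XID")
        # leading/trailing deletions are trimmed, so cost <= end score
        assert cost <= tr.score
        non_trim = sum(1 for o in tr.ops if o.op in "XI")
        assert non_trim <= tr.score

    def test_paths_respect_topology(self):
        """Consecutive graph cells in the trace are either adjacent within a
        node or joined by an alignment-graph edge."""
        rng = random.Random(77)
        g = random_bidirected_graph(rng, max_nodes=4)
        ag, _ = build_alignment_graph(g)
        read = rand_seq(rng, 50)
        res = align_seedless(ag, read, BandParams(b=len(read), B=len(read) + 1))
        tr = backtrace(ag, res)
        if tr is None:
            return
        cells = [(o.aid, o.col) for o in tr.ops if o.aid is not None]
        for (a1, c1), (a2, c2) in zip(cells, cells[1:]):
            if a1 == a2 and c2 == c1 + 1:
                continue
            assert c2 == 0 and a2 in ag.out[a1]


class TestPriorityValue:
    def test_low_error_rate_uses_64k(self):
        assert priority_value(2, 50, 0.01) == 64 * 2 - 50 == 78

    def test_high_error_rate_uses_ratio(self):
        assert priority_value(2, 50, 0.25) == 2 / 0.25 - 50 == -42


class TestTangleEffort:
    def test_cap_freezes_slice(self):
        """With a tiny tangle cap the slice stops early but still returns a
        usable (frozen) band."""
        rng = random.Random(123)
        ref = rand_seq(rng, 2000)
        ag, _ = make_linear(ref)
        read = rand_seq(rng, 100)  # junk: band wants to spread everywhere
        res = align_seedless(
            ag, read, BandParams(b=50, B=51, C_tangle=2000), use_viterbi=False
        )
        assert all(s.cells <= 2000 + 64 * 64 for s in res.summaries)


class TestStorageBounds:
    def test_dense_block_bound_is_812_bytes(self):
        assert abs(dense_block_bound_bytes() - 812) < 1

    def test_border_bound_is_38_bytes(self):
        assert abs(border_bound_bytes() - 38) < 1
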