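import math

import numpy as np
import pytest

from netpolarity import (
    ChannelMatrixSet,
    DirectedNetwork,
    NetworkValidationError,
    channel_matrices,
    cumulative_horizontal,
    horizontal_profile,
    new_node_counts,
    propagation_profile,
    vertical_degree,
    walk_count_matrix,
)
from netpolarity.propagation import UNDEFINED

from conftest import count_walks_dfs, random_digraph, walk_nodes_dfs


def _roles_first_last(n):
    roles = np.array(["inter"] * n, dtype=object)
    roles[0] = "input"
    roles[-1] = "output"
    return roles


class TestWalkCounts:
    def test_single_edge_counts(self):
        A = np.zeros((2, 2), dtype=int)
        A[0, 1] = 1
        net = DirectedNetwork(A, roles=np.array(["input", "output"], dtype=object))
        cms = channel_matrices(net, max_level=3)
        assert [int(cms.raw_counts[l][0, 0]) for l in range(4)] == [1, 0, 0, 0]

    def test_recurrent_toy_levels(self, recurrent_toy):
        cms = channel_matrices(recurrent_toy, max_level=3)
        # i->v->j at level 1, i->v->w->v->j at level 3, nothing at 0/2
        counts = [int(cms.raw_counts[l][0, 0]) for l in range(4)]
        assert counts == [0, 1, 0, 1]

    def test_log_of_disconnected_channel_is_minus_one(self, recurrent_toy):
        cms = channel_matrices(recurrent_toy, max_level=0)
        assert cms.log_matrix[0][0, 0] == pytest.approx(math.log10(0.1))
        assert cms.log_matrix[0][0, 0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        A = random_digraph(6, 0.35, seed)
        net = DirectedNetwork(A, roles=np.array(
            ["input", "input", "inter", "inter", "output", "output"],
            dtype=object))
        cms = channel_matrices(net, max_level=5)
        for l in range(6):
            for a, i in enumerate(net.input_nodes):
                for b, j in enumerate(net.output_nodes):
                    assert int(cms.raw_counts[l][a, b]) == count_walks_dfs(
                        A, int(i), int(j), l + 1
                    )

    def test_semigroup_identity(self):
        A = random_digraph(7, 0.4, 42)
        net = DirectedNetwork(A)
        for a, b in [(1, 1), (2, 1), (2, 3)]:
            lhs = walk_count_matrix(net, a) @ walk_count_matrix(net, b)
            rhs = walk_count_matrix(net, a + b)
            assert np.array_equal(lhs, rhs)

    def test_exact_big_integer_counts(self):
        # dense 12-node digraph: counts at walk length 40 exceed 2**53
        A = random_digraph(12, 0.8, 0)
        net = DirectedNetwork(A)
        M = walk_count_matrix(net, 40)
        assert M.dtype == object
        assert int(M.max()) > 2**53
        # exactness via the semigroup identity in pure-Python ints
        half = walk_count_matrix(net, 20)
        assert np.array_equal(half.astype(object) @ half.astype(object), M)

    def test_missing_roles_rejected(self):
        net = DirectedNetwork(random_digraph(4, 0.5, 1))
        with pytest.raises(NetworkValidationError):
            channel_matrices(net, 2)


def _cms_from_logs(mats):
    """Build a ChannelMatrixSet directly from given log matrices."""
    mats = [np.asarray(m, dtype=float) for m in mats]
    return ChannelMatrixSet(
        levels=list(range(len(mats))),
        raw_counts=[np.zeros_like(m, dtype=np.int64) for m in mats],
        log_matrix=mats,
        b=0.1,
        input_nodes=np.arange(mats[0].shape[0]),
        output_nodes=np.arange(mats[0].shape[1]),
    )


class TestVerticalDegree:
    def test_identical_matrices_give_one(self):
        m = [[0.0, 1.0], [2.0, 3.0]]
        assert vertical_degree(_cms_from_logs([m, m]), 0) == pytest.approx(1.0)

    def test_affine_invariance(self):
        m = np.array([[0.0, 1.0], [2.0, 3.0]])
        cms = _cms_from_logs([m, 2 * m + 3])
        assert vertical_degree(cms, 0) == pytest.approx(1.0)

    def test_exact_reversal_gives_minus_one(self):
        cms = _cms_from_logs([[[-1, 0], [1, 2]], [[2, 1], [0, -1]]])
        assert vertical_degree(cms, 0) == pytest.approx(-1.0)

    def test_zero_variance_is_undefined(self):
        cms = _cms_from_logs([[[1.0, 1.0], [1.0, 1.0]], [[0.0, 1.0], [2.0, 3.0]]])
        assert vertical_degree(cms, 0) is UNDEFINED

    def test_missing_level_rejected(self):
        cms = _cms_from_logs([[[0.0, 1.0]], [[1.0, 2.0]]])
        with pytest.raises(NetworkValidationError):
            vertical_degree(cms, 5)


class TestHorizontal:
    def test_complete_bipartite_is_one(self):
        n_in, n_out = 3, 4
        A = np.zeros((7, 7), dtype=int)
        A[np.ix_(range(3), range(3, 7))] = 1
        roles = np.array(["input"] * 3 + ["output"] * 4, dtype=object)
        cms = channel_matrices(DirectedNetwork(A, roles=roles), 0)
        _, H = horizontal_profile(cms, 0)
        assert H == 1.0

    def test_no_direct_links_is_zero(self, recurrent_toy):
        cms = channel_matrices(recurrent_toy, 0)
        _, H = horizontal_profile(cms, 0)
        assert H == 0.0

    def test_fixed_pattern(self):
        raw = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 0]], dtype=np.int64)
        cms = ChannelMatrixSet(
            levels=[0, 1],
            raw_counts=[np.zeros_like(raw), raw],
            log_matrix=[np.log10(np.zeros_like(raw) + 0.1),
                        np.log10(raw + 0.1)],
            b=0.1,
            input_nodes=np.arange(3),
            output_nodes=np.arange(3),
        )
        h, H = horizontal_profile(cms, 1)
        assert np.allclose(h, [1 / 3, 2 / 3, 0.0])
        assert H == pytest.approx(1 / 3)

    def test_cumulative_equals_per_level_at_zero(self, recurrent_toy):
        cms = channel_matrices(recurrent_toy, 3)
        assert cumulative_horizontal(cms, 0) == horizontal_profile(cms, 0)

    def test_cumulative_monotone_and_remembers(self, recurrent_toy):
        cms = channel_matrices(recurrent_toy, 3)
        # per-level: connected at 1, disconnected at 2; cumulative keeps it
        _, H2_strict = horizontal_profile(cms, 2)
        h2_cum, H2_cum = cumulative_horizontal(cms, 2)
        assert H2_strict == 0.0
        assert h2_cum[0] == 1.0
        Hs = [cumulative_horizontal(cms, l)[1] for l in range(4)]
        assert all(a <= b for a, b in zip(Hs, Hs[1:]))


class TestNewNodes:
    def test_single_edge_no_new_nodes(self):
        A = np.zeros((2, 2), dtype=int)
        A[0, 1] = 1
        net = DirectedNetwork(A, roles=np.array(["input", "output"], dtype=object))
        assert np.allclose(new_node_counts(net, 3), 0.0)

    def test_chain_one_new_node(self, chain3):
        means = new_node_counts(chain3, 3)
        assert np.allclose(means, [0.0, 1.0, 0.0, 0.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_walk_enumeration_oracle(self, seed):
        A = random_digraph(7, 0.3, 100 + seed)
        roles = np.array(
            ["input", "input", "inter", "inter", "inter", "output", "output"],
            dtype=object,
        )
        net = DirectedNetwork(A, roles=roles)
        max_level = 5
        got = new_node_counts(net, max_level)
        channels = [(int(i), int(j)) for i in net.input_nodes
                    for j in net.output_nodes]
        seen = {c: set() for c in channels}
        for l in range(1, max_level + 1):
            total = 0
            for (i, j) in channels:
                nodes = walk_nodes_dfs(A, i, j, l + 1)
                total += len(nodes - seen[(i, j)])
                seen[(i, j)] |= nodes
            assert got[l] == pytest.approx(total / len(channels))


class TestProfile:
    def test_composition_matches_constituents(self, recurrent_toy):
        prof = propagation_profile(recurrent_toy, 3)
        cms = channel_matrices(recurrent_toy, 3)
        assert prof.V == [vertical_degree(cms, l) for l in range(3)]
        assert prof.H == [cumulative_horizontal(cms, l)[1] for l in range(4)]
        assert prof.levels[-1] == 3 and len(prof.V) == 3  # V needs l+1

    def test_mean_pathways_grow_on_recurrent_network(self):
        # complete bidirectional triangle plus input/output taps: the
        # spectral radius exceeds 1, so walk counts must grow with level
        A = np.zeros((5, 5), dtype=int)
        for i in (1, 2, 3):
            for j in (1, 2, 3):
                if i != j:
                    A[i, j] = 1
        A[0, 1] = A[3, 4] = 1
        roles = np.array(
            ["input", "inter", "inter", "inter", "output"], dtype=object
        )
        prof = propagation_profile(DirectedNetwork(A, roles=roles), 6)
        mp = prof.mean_pathways
        assert mp[6] > mp[4] > mp[2] > 0
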