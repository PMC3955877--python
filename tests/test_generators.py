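import numpy as np
import pytest

from netpolarity import (
    ERConfig,
    HubPlantConfig,
    NetworkValidationError,
    RoleCounts,
    SWConfig,
    assign_io_opposite_clusters,
    assign_io_random,
    clustering_coefficient,
    find_modules,
    make_er,
    make_ring_lattice,
    make_small_world,
    participation_coefficient,
    plant_hubs,
    reassign_io,
)

CE_COUNTS = RoleCounts(88, 82, 109)


class TestRingLattice:
    def test_exact_edge_count_and_even_degree(self):
        net = make_ring_lattice(279, 2194, seed=0)
        assert net.n_edges == 2194
        out_deg = net.adjacency.sum(axis=1)
        assert set(out_deg) <= {2194 // 279, 2194 // 279 + 1}

    def test_small_symmetric_case(self):
        net = make_ring_lattice(5, 10, seed=0)
        for i in range(5):
            assert net.adjacency[i, (i + 1) % 5] == 1
            assert net.adjacency[i, (i - 1) % 5] == 1
        assert net.n_edges == 10

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            make_ring_lattice(4, 13)

    def test_more_clustered_than_er(self):
        rl = make_ring_lattice(279, 2194, seed=1)
        er = make_er(ERConfig(279, 2194 / (279 * 278), seed=1))
        assert clustering_coefficient(rl) > 2 * clustering_coefficient(er)


class TestSmallWorld:
    def test_p0_equals_ring_lattice(self):
        sw = make_small_world(SWConfig(50, 300, 0.0, seed=3))
        rl = make_ring_lattice(50, 300, seed=3)
        assert np.array_equal(sw.adjacency, rl.adjacency)

    @pytest.mark.parametrize("p", [0.1, 0.3, 1.0])
    def test_edge_conservation(self, p):
        net = make_small_world(SWConfig(100, 700, p, seed=4))
        assert net.n_edges == 700

    def test_seed_reproducible(self):
        a = make_small_world(SWConfig(seed=9))
        b = make_small_world(SWConfig(seed=9))
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_p1_clustering_matches_er(self):
        # full rewiring should be statistically indistinguishable from a
        # density-matched random network
        cs_sw = [
            clustering_coefficient(make_small_world(SWConfig(seed=s, rewiring_p=1.0)))
            for s in range(25)
        ]
        cs_er = [
            clustering_coefficient(
                make_er(ERConfig(279, 2194 / (279 * 278), seed=s))
            )
            for s in range(25)
        ]
        sd = np.std(cs_er, ddof=1)
        assert abs(np.mean(cs_sw) - np.mean(cs_er)) < 3 * sd


class TestER:
    def test_extremes(self):
        assert make_er(ERConfig(10, 0.0, seed=0)).n_edges == 0
        assert make_er(ERConfig(10, 1.0, seed=0)).n_edges == 90

    def test_mean_edge_count_binomial(self):
        n, p = 279, 0.0283
        counts = [make_er(ERConfig(n, p, seed=s)).n_edges for s in range(100)]
        npairs = n * (n - 1)
        se = np.sqrt(npairs * p * (1 - p) / len(counts))
        assert abs(np.mean(counts) - npairs * p) < 3 * se


class TestRoleAssignment:
    def test_random_partition_sizes(self):
        net = make_er(ERConfig(279, 0.03, seed=0))
        net = assign_io_random(net, CE_COUNTS, seed=1)
        assert net.role_counts() == CE_COUNTS

    def test_bad_counts_rejected(self):
        net = make_er(ERConfig(10, 0.3, seed=0))
        with pytest.raises(NetworkValidationError):
            assign_io_random(net, RoleCounts(5, 5, 5), seed=0)

    def test_two_seeds_differ(self):
        net = make_er(ERConfig(279, 0.03, seed=0))
        a = assign_io_random(net, CE_COUNTS, seed=1)
        b = assign_io_random(net, CE_COUNTS, seed=2)
        assert not np.array_equal(a.roles, b.roles)

    def test_opposite_clusters_geometry(self):
        net = make_ring_lattice(279, 2194, seed=0)
        net = assign_io_opposite_clusters(net, CE_COUNTS, seed=5)
        roles = net.roles
        assert net.role_counts() == CE_COUNTS
        # arcs: rotate so the input arc starts at position 0, then the
        # layout reads input*88, inter*41, output*109, inter*41
        starts = [
            i
            for i in range(279)
            if roles[i] == "input" and roles[(i - 1) % 279] != "input"
        ]
        assert len(starts) == 1  # contiguous input arc
        s = starts[0]
        seq = [roles[(s + k) % 279] for k in range(279)]
        assert seq == (
            ["input"] * 88 + ["inter"] * 41 + ["output"] * 109 + ["inter"] * 41
        )

    def test_reversed_swaps_and_is_involution(self):
        net = make_er(ERConfig(279, 0.03, seed=0))
        net = assign_io_random(net, CE_COUNTS, seed=1)
        rev = reassign_io(net, "reversed")
        assert rev.role_counts() == RoleCounts(109, 82, 88)
        back = reassign_io(rev, "reversed")
        assert np.array_equal(back.roles, net.roles)

    def test_separated_no_module_mixes_io(self):
        net = make_small_world(SWConfig(seed=2))
        net = assign_io_random(net, CE_COUNTS, seed=2)
        part = find_modules(net, seed=0, n_restarts=5)
        sep = reassign_io(net, "separated", part, seed=3)
        assert sep.role_counts() == CE_COUNTS
        for m in range(part.n_modules):
            r = set(sep.roles[part.module_nodes(m)])
            assert not ({"input", "output"} <= r)

    def test_rand_preserves_sizes(self):
        net = make_er(ERConfig(50, 0.2, seed=1))
        net = assign_io_random(net, RoleCounts(10, 20, 20), seed=1)
        out = reassign_io(net, "rand", seed=9)
        assert out.role_counts() == RoleCounts(10, 20, 20)


@pytest.fixture(scope="module")
def sw_with_modules():
    net = make_small_world(SWConfig(seed=11))
    part = find_modules(net, seed=11, n_restarts=5)
    return net, part


class TestHubPlanting:
    @pytest.mark.parametrize("hub_class", ["provincial", "connector", "kinless"])
    def test_degree_target_and_conservation(self, sw_with_modules, hub_class):
        net, part = sw_with_modules
        cfg = HubPlantConfig(15, hub_class, 40, seed=3)
        planted, hubs = plant_hubs(net, cfg, part)
        assert planted.n_nodes == net.n_nodes
        assert planted.n_edges == net.n_edges
        A = planted.adjacency
        for h in hubs:
            assert int(A[h, :].sum() + A[:, h].sum()) == 40

    def test_participation_matches_class(self, sw_with_modules):
        net, part = sw_with_modules
        prov, hubs_p = plant_hubs(
            net, HubPlantConfig(15, "provincial", 40, seed=4), part
        )
        kin, hubs_k = plant_hubs(
            net, HubPlantConfig(15, "kinless", 40, seed=4), part
        )
        for h in hubs_p:
            assert participation_coefficient(prov, part, int(h)) <= 0.30
        for h in hubs_k:
            assert participation_coefficient(kin, part, int(h)) > 0.75

    def test_seeded_reproducibility(self, sw_with_modules):
        net, part = sw_with_modules
        cfg = HubPlantConfig(15, "connector", 40, seed=8)
        a, ha = plant_hubs(net, cfg, part)
        b, hb = plant_hubs(net, cfg, part)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(ha, hb)

    def test_infeasible_degree_rejected(self, sw_with_modules):
        net, part = sw_with_modules
        with pytest.raises(NetworkValidationError):
            plant_hubs(net, HubPlantConfig(15, "provincial", 200, seed=0), part)
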