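import math

import numpy as np
import pytest

import mscortex as mc
from mscortex.netgen import (
    read_connectome,
    read_macro_csv,
    region_probability_matrix,
    ring_degree,
    write_connectome,
    write_macro_csv,
)


class TestRegionLattice:
    def test_three_by_three_reference_layout(self):
        layout = mc.build_region_lattice(9, 100)
        assert layout.grid_side == 3
        assert layout.n == 900
        # left-to-right, top-down indexing
        assert tuple(layout.coords[0]) == (0.0, 0.0)
        assert tuple(layout.coords[2]) == (2.0, 0.0)
        assert tuple(layout.coords[3]) == (0.0, 1.0)
        # contiguous membership blocks
        assert np.all(layout.membership[:100] == 0)
        assert np.all(layout.membership[300:400] == 3)

    def test_single_region_degenerate_lattice(self):
        layout = mc.build_region_lattice(1, 5)
        assert tuple(layout.coords[0]) == (0.0, 0.0)
        assert np.all(layout.membership == 0)

    def test_four_by_four_max_pairwise_distance(self):
        layout = mc.build_region_lattice(16, 10)
        d = np.linalg.norm(layout.coords[:, None] - layout.coords[None, :], axis=-1)
        assert d.max() == pytest.approx(math.sqrt(18))

    def test_non_square_region_count_rejected(self):
        with pytest.raises(ValueError, match="perfect square"):
            mc.build_region_lattice(8, 10)


class TestSmallWorld:
    def test_reference_density_is_exact(self, rng):
        adj = mc.build_small_world(100, mc.SmallWorldParams(c=0.1, p=0.0), rng)
        # ring lattice of k=10 neighbors -> 1000 directed edges, density 0.1
        assert adj.sum() == 1000
        assert adj.sum() / 100**2 == pytest.approx(0.1)
        assert np.all(adj == adj.T)
        assert np.all(np.diag(adj) == 0)
        # p=0: each node linked to its 10 nearest ring neighbors
        offsets = np.nonzero(adj[0])[0]
        ring_dist = np.minimum(offsets, 100 - offsets)
        assert np.all(ring_dist <= 5)

    @pytest.mark.parametrize(
        "m,c,p", [(100, 0.1, 0.0), (100, 0.1, 0.5), (50, 0.2, 1.0), (30, 0.15, 0.1)]
    )
    def test_rewiring_conserves_edge_count(self, m, c, p, rng):
        adj = mc.build_small_world(m, mc.SmallWorldParams(c=c, p=p), rng)
        k = ring_degree(m, c)
        assert adj.sum() == m * k
        assert np.all(np.diag(adj) == 0)

    def test_full_rewiring_matches_random_graph_clustering(self):
        import networkx as nx

        rng = np.random.default_rng(99)
        ws, er = [], []
        for _ in range(15):
            adj = mc.build_small_world(100, mc.SmallWorldParams(c=0.1, p=1.0), rng)
            ws.append(nx.average_clustering(nx.from_numpy_array(adj)))
            er.append(
                nx.average_clustering(nx.gnm_random_graph(100, 500, seed=int(rng.integers(2**31))))
            )
        ws, er = np.asarray(ws), np.asarray(er)
        se = math.sqrt(ws.var(ddof=1) / 15 + er.var(ddof=1) / 15)
        assert abs(ws.mean() - er.mean()) < 3 * se + 1e-12

    def test_too_sparse_ring_rejected(self, rng):
        with pytest.raises(ValueError, match="ring lattice"):
            mc.build_small_world(10, mc.SmallWorldParams(c=0.05, p=0.1), rng)


class TestConnectionProbability:
    def test_zero_distance_gives_rho(self):
        p = mc.connection_probability((1, 1), (1, 1), mc.InterRegionParams(0.7, 0.4))
        assert p == pytest.approx(0.7)

    def test_unit_distance_hand_value(self):
        p = mc.connection_probability((0, 0), (1, 0), mc.InterRegionParams(0.9, 0.5))
        assert p == pytest.approx(0.9 * math.exp(-2.0), abs=1e-9)
        assert p == pytest.approx(0.121802, abs=1e-6)

    def test_large_sigma_limit_approaches_rho_from_below(self):
        params = mc.InterRegionParams(0.6, 1e6)
        p = mc.connection_probability((0, 0), (2, 2), params)
        assert 0.6 * (1 - 1e-9) < p < 0.6

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            mc.InterRegionParams(0.5, 0.0)

    def test_probability_monotone_in_distance_and_sigma(self):
        layout = mc.build_region_lattice(9, 10)
        p_narrow = region_probability_matrix(layout, mc.InterRegionParams(0.9, 0.3))
        p_wide = region_probability_matrix(layout, mc.InterRegionParams(0.9, 0.6))
        d = np.linalg.norm(layout.coords[:, None] - layout.coords[None, :], axis=-1)
        off = ~np.eye(9, dtype=bool)
        order = np.argsort(d[off])
        assert np.all(np.diff(p_narrow[off][order]) <= 1e-12)
        assert np.all(p_wide[off] >= p_narrow[off])


class TestInterRegionalSampling:
    def test_rho_zero_yields_no_edges(self, rng):
        layout = mc.build_region_lattice(4, 10)
        edges = mc.sample_inter_regional_edges(layout, mc.InterRegionParams(0.0, 0.5), rng)
        assert edges.shape[0] == 0

    def test_dense_limit_includes_every_cross_pair(self, rng):
        layout = mc.build_region_lattice(4, 10)
        edges = mc.sample_inter_regional_edges(layout, mc.InterRegionParams(1.0, 1e9), rng)
        n_cross = 40 * 40 - 4 * 10 * 10
        assert edges.shape[0] == n_cross
        tgt, src = edges[:, 0], edges[:, 1]
        assert np.all(layout.membership[tgt] != layout.membership[src])

    def test_empirical_edge_frequency_matches_distance_rule(self):
        rng = np.random.default_rng(2024)
        layout = mc.build_region_lattice(4, 20)
        params = mc.InterRegionParams(0.9, 0.5)
        p_region = region_probability_matrix(layout, params)
        counts = np.zeros((4, 4))
        n_rep = 100
        for _ in range(n_rep):
            edges = mc.sample_inter_regional_edges(layout, params, rng)
            gi = layout.membership[edges[:, 0]]
            gk = layout.membership[edges[:, 1]]
            np.add.at(counts, (gi, gk), 1)
        n_pairs = 20 * 20 * n_rep
        for i in range(4):
            for k in range(4):
                if i == k:
                    continue
                p = p_region[i, k]
                se = math.sqrt(p * (1 - p) / n_pairs)
                assert abs(counts[i, k] / n_pairs - p) < 3 * se + 1e-9


class TestAssembly:
    def test_strength_rules(self):
        layout = mc.build_region_lattice(4, 3)
        # hand-built: region 0 has edge 0<->1; inter edges 3->0 and 4->0
        local0 = np.zeros((3, 3), dtype=int)
        local0[0, 1] = local0[1, 0] = 1
        empty = np.zeros((3, 3), dtype=int)
        inter = np.array([[0, 3], [0, 4]])
        conn = mc.assemble_connectome([local0, empty, empty, empty], inter, layout)
        # local strength 1/m
        assert conn.A[0, 1] == pytest.approx(1 / 3)
        # N_in(0) = 1 local + 2 inter = 3 -> inter strengths 1/3
        assert conn.N_in[0] == 3
        assert conn.A[0, 3] == pytest.approx(1 / 3)
        assert conn.A[0, 4] == pytest.approx(1 / 3)
        # absent pair -> 0
        assert conn.A[2, 5] == 0.0

    def test_reference_strengths_and_total_in_strength(self, small_connectome):
        conn = small_connectome
        m = conn.layout.m
        mem = conn.layout.membership
        same = mem[:, None] == mem[None, :]
        local_strengths = conn.A[same & (conn.A != 0)]
        assert np.allclose(local_strengths, 1 / m)
        inter_mask = (~same) & (conn.A != 0)
        rows, cols = np.nonzero(inter_mask)
        assert np.allclose(conn.A[rows, cols], 1 / conn.N_in[rows])
        # per-neuron in-strength decomposition is exact
        local_deg = (conn.A == 1 / m).sum(axis=1)
        expected_local = local_deg / m
        actual_local = np.where(same, conn.A, 0).sum(axis=1)
        assert np.allclose(actual_local, expected_local)

    def test_determinism_bit_identical(self):
        a = mc.build_connectome(4, 20, mc.SmallWorldParams(), mc.InterRegionParams(0.5, 0.4), 3)
        b = mc.build_connectome(4, 20, mc.SmallWorldParams(), mc.InterRegionParams(0.5, 0.4), 3)
        assert np.array_equal(a.A, b.A)
        assert np.array_equal(a.N_in, b.N_in)


class TestMacroscale:
    def test_isolated_regions_give_diagonal_R(self, rng):
        layout = mc.build_region_lattice(4, 30)
        local = [mc.build_small_world(30, mc.SmallWorldParams(), rng) for _ in range(4)]
        conn = mc.assemble_connectome(local, np.empty((0, 2), dtype=int), layout)
        R = mc.macroscale_matrix(conn, "raw").R
        assert np.all(R[~np.eye(4, dtype=bool)] == 0)

    def test_diagonal_equals_local_edges_over_m(self, default_connectome):
        R = mc.macroscale_matrix(default_connectome, "raw").R
        # each region: 1000 directed local edges of strength 1/100 -> R_ii = 10
        assert np.allclose(np.diag(R), 10.0)

    def test_per_neuron_mode_divides_exactly(self, default_connectome):
        raw = mc.macroscale_matrix(default_connectome, "raw").R
        per = mc.macroscale_matrix(default_connectome, "per_neuron").R
        assert np.array_equal(per, raw / 100)

    def test_block_sum_definition(self, small_connectome):
        conn = small_connectome
        z, m = conn.layout.z, conn.layout.m
        R = mc.macroscale_matrix(conn, "raw").R
        for i in range(z):
            for k in range(z):
                block = conn.A[i * m : (i + 1) * m, k * m : (k + 1) * m]
                assert R[i, k] == pytest.approx(block.sum(), abs=1e-12)

    def test_adjacent_regions_stronger_than_opposite(self):
        # expected R_ik decreases with regional distance at sigma = 0.5
        totals_near, totals_far = [], []
        for seed in range(5):
            conn = mc.build_connectome(
                9, 50, mc.SmallWorldParams(), mc.InterRegionParams(0.9, 0.5), seed
            )
            R = mc.macroscale_matrix(conn, "raw").R
            totals_near.append(R[0, 1])  # distance 1
            totals_far.append(R[0, 8])  # distance 2*sqrt(2)
        assert np.mean(totals_near) > np.mean(totals_far)


class TestIO:
    def test_connectome_roundtrip(self, tmp_path, small_connectome):
        path = tmp_path / "A.mtx"
        write_connectome(small_connectome, path)
        back = read_connectome(path)
        assert np.allclose(back.A, small_connectome.A)
        assert np.array_equal(back.N_in, small_connectome.N_in)
        assert back.ir_params == small_connectome.ir_params

    def test_macro_csv_roundtrip(self, tmp_path, small_connectome):
        macro = mc.macroscale_matrix(small_connectome, "raw")
        path = tmp_path / "R.csv"
        write_macro_csv(macro, path)
        back = read_macro_csv(path)
        assert np.allclose(back.R, macro.R)
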