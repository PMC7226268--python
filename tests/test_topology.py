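"""Split-and-rewire construction and its analytic connectivity predictions."""

import numpy as np
import pytest

import hmnet as hm
from hmnet.topology import TopologyConfig


def _codes(topo):
    return topo.pre * topo.n_neurons + topo.post


class TestBaseRandom:
    def test_zero_probability_gives_no_edges(self):
        topo = hm.build_base_random(TopologyConfig(n_neurons=1000, connectivity=0.0, seed=1))
        assert topo.n_edges == 0

    def test_full_probability_gives_complete_digraph(self):
        topo = hm.build_base_random(TopologyConfig(n_neurons=1000, connectivity=1.0, seed=1))
        assert topo.n_edges == 1000 * 999
        assert not np.any(topo.pre == topo.post)

    def test_edge_count_matches_binomial_moments(self):
        n, eps = 2 ** 13, 0.01
        topo = hm.build_base_random(TopologyConfig(n_neurons=n, connectivity=eps, seed=2))
        pairs = n * (n - 1)
        mean = pairs * eps
        sd = np.sqrt(pairs * eps * (1 - eps))
        assert abs(topo.n_edges - mean) < 4 * sd

    def test_no_self_edges_and_simple(self):
        topo = hm.build_base_random(TopologyConfig(n_neurons=500, connectivity=0.1, seed=3))
        assert not np.any(topo.pre == topo.post)
        assert np.unique(_codes(topo)).size == topo.n_edges

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TopologyConfig(n_neurons=1, connectivity=0.5)
        with pytest.raises(ValueError):
            TopologyConfig(n_neurons=100, connectivity=1.5)
        with pytest.raises(ValueError):
            TopologyConfig(n_neurons=100, connectivity=0.1, hierarchy_level=5)


class TestElevate:
    def test_no_rewiring_keeps_edge_list(self):
        cfg = TopologyConfig(
            n_neurons=512, connectivity=0.05, rewire_exc=0.0, rewire_inh=0.0, seed=4
        )
        base = hm.build_base_random(cfg)
        up = hm.elevate_hierarchy(base)
        assert np.array_equal(np.sort(_codes(base)), np.sort(_codes(up)))
        assert up.n_modules == 2

    def test_edge_count_and_sign_conserved(self, small_hier_topology):
        cfg = small_hier_topology.config
        base = hm.build_base_random(cfg)
        assert small_hier_topology.n_edges == base.n_edges
        # sign is carried by the presynaptic id, which never changes
        assert np.array_equal(
            np.sort(small_hier_topology.pre), np.sort(base.pre)
        )

    def test_full_inhibitory_rewiring_removes_intermodular_inhibition(self):
        cfg = TopologyConfig(
            n_neurons=1024, connectivity=0.05, hierarchy_level=3,
            rewire_exc=0.5, rewire_inh=1.0, seed=5,
        )
        topo = hm.build_hierarchy(cfg)
        assert topo.n_unrewired == 0  # sparse enough: no saturation
        inter = topo.module_of[topo.pre] != topo.module_of[topo.post]
        inh = ~topo.is_excitatory_edge
        assert np.count_nonzero(inter & inh) == 0

    def test_odd_module_size_rejected(self):
        cfg = TopologyConfig(n_neurons=6, connectivity=0.5, seed=0)
        topo = hm.elevate_hierarchy(hm.build_base_random(cfg))  # modules of 3
        with pytest.raises(ValueError):
            hm.elevate_hierarchy(topo)

    def test_multigraph_mode_reaches_analytic_degree_under_saturation(self):
        # dense enough that a simple graph cannot hold the analytic in-degree
        cfg = TopologyConfig(
            n_neurons=1024, connectivity=0.3, hierarchy_level=4,
            rewire_exc=0.9, rewire_inh=0.9, seed=6, allow_multi_edges=True,
        )
        topo = hm.build_hierarchy(cfg)
        pred = hm.expected_n_in(cfg, 4)
        meas = hm.measure_connectivity(topo)
        assert pred.n_in > topo.module_size - 1  # would saturate a simple graph
        assert abs(meas.n_in - pred.n_in) / pred.n_in < 0.05

    def test_simple_mode_saturates_gracefully(self):
        cfg = TopologyConfig(
            n_neurons=1024, connectivity=0.3, hierarchy_level=4,
            rewire_exc=0.9, rewire_inh=0.9, seed=6,
        )
        topo = hm.build_hierarchy(cfg)
        assert topo.n_unrewired > 0
        assert np.unique(_codes(topo)).size == topo.n_edges  # still simple
        # intramodular in-degree is capped by module size
        meas = hm.measure_connectivity(topo)
        assert meas.n_in <= topo.module_size - 1


class TestHierarchy:
    def test_module_count_and_equal_sizes(self):
        cfg = TopologyConfig(n_neurons=2 ** 12, connectivity=0.02, hierarchy_level=2, seed=7)
        topo = hm.build_hierarchy(cfg)
        assert topo.n_modules == 4
        sizes = np.bincount(topo.module_of)
        assert np.all(sizes == 1024)
        topo3 = hm.build_hierarchy(
            TopologyConfig(n_neurons=2 ** 12, connectivity=0.02, hierarchy_level=3, seed=7)
        )
        assert topo3.n_modules == 8

    def test_h0_identical_to_base_random(self):
        cfg = TopologyConfig(n_neurons=512, connectivity=0.05, hierarchy_level=0, seed=8)
        a = hm.build_hierarchy(cfg)
        b = hm.build_base_random(cfg)
        assert np.array_equal(a.pre, b.pre) and np.array_equal(a.post, b.post)

    def test_determinism(self):
        cfg = TopologyConfig(n_neurons=512, connectivity=0.05, hierarchy_level=3, seed=9)
        a, b = hm.build_hierarchy(cfg), hm.build_hierarchy(cfg)
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.post, b.post)
        assert np.array_equal(a.module_of, b.module_of)


class TestPredictions:
    def test_level0_is_n_eps(self):
        cfg = TopologyConfig(n_neurons=1000, connectivity=0.05, seed=0)
        assert hm.expected_n_in(cfg, 0).n_in == pytest.approx(50.0)

    def test_no_rewiring_halves_each_level(self):
        cfg = TopologyConfig(n_neurons=1024, connectivity=0.1, rewire_exc=0.0, seed=0)
        for h in range(5):
            assert hm.expected_n_in(cfg, h, rewire=0.0).n_in == pytest.approx(
                1024 * 0.1 / 2 ** h
            )

    def test_limit_value_full_scale(self):
        cfg = TopologyConfig(n_neurons=2 ** 17, connectivity=0.01, rewire_exc=0.9, seed=0)
        pred = hm.expected_n_in(cfg, 40)
        assert pred.n_in_limit == pytest.approx(2 * 2 ** 17 * 0.9 * 0.01 / 1.9)
        assert pred.n_in == pytest.approx(pred.n_in_limit, rel=1e-9)
        assert pred.n_in_limit == pytest.approx(1241.69, abs=0.05)

    def test_in_out_identity_and_monotone_density(self):
        cfg = TopologyConfig(n_neurons=2 ** 13, connectivity=0.01, rewire_exc=0.9, seed=0)
        n_eps = 2 ** 13 * 0.01
        prev_eps_in = 0.0
        for h in range(10):
            p = hm.expected_n_in(cfg, h)
            assert p.n_in + p.n_out == pytest.approx(n_eps)
            assert p.eps_in >= prev_eps_in
            prev_eps_in = p.eps_in

    def test_negative_level_rejected(self):
        cfg = TopologyConfig(n_neurons=100, connectivity=0.1, seed=0)
        with pytest.raises(ValueError):
            hm.expected_n_in(cfg, -1)


class TestMeasurement:
    def test_single_module_has_no_intermodular(self):
        topo = hm.build_base_random(TopologyConfig(n_neurons=256, connectivity=0.2, seed=1))
        meas = hm.measure_connectivity(topo)
        assert meas.n_out == 0.0

    def test_complete_graph_split_exact(self):
        cfg = TopologyConfig(
            n_neurons=128, connectivity=1.0, hierarchy_level=1,
            rewire_exc=0.0, rewire_inh=0.0, seed=2,
        )
        topo = hm.build_hierarchy(cfg)
        meas = hm.measure_connectivity(topo)
        assert meas.n_in == pytest.approx(128 / 2 - 1)

    def test_monte_carlo_agrees_with_prediction(self, small_hier_topology):
        meas = hm.measure_connectivity(small_hier_topology)
        pred = hm.expected_n_in(small_hier_topology.config, 3)
        # one realisation: allow a few percent sampling error
        assert meas.n_in == pytest.approx(pred.n_in, rel=0.05)
        assert meas.n_in + meas.n_out == pytest.approx(
            small_hier_topology.n_edges / small_hier_topology.n_neurons
        )


class TestRoundTrip:
    def test_save_load_identity(self, tmp_path, small_hier_topology):
        hm.save_topology(small_hier_topology, tmp_path / "topo")
        back = hm.load_topology(tmp_path / "topo")
        assert np.array_equal(back.pre, small_hier_topology.pre)
        assert np.array_equal(back.post, small_hier_topology.post)
        assert np.array_equal(back.module_of, small_hier_topology.module_of)
        assert back.config == small_hier_topology.config
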