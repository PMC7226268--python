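"""Transfer entropy and mutual information estimators against oracles."""

import math

import numpy as np
import pytest

import hmnet as hm
from hmnet import fixtures as fx
from hmnet.info import _sample_ordered_pairs


def brute_force_te(y, x, d):
    """Independent plug-in TE: explicit dict-based joint tables, shared window
    semantics (same t range for every scanned delay handled by caller)."""
    n = len(x)
    t0 = max(1 - d, 0)
    joint = {}
    for t in range(t0, n - d):
        key = (x[t + d], x[t + d - 1], y[t])
        joint[key] = joint.get(key, 0) + 1
    total = sum(joint.values())
    p_abc = {k: v / total for k, v in joint.items()}
    p_bc, p_ab, p_b = {}, {}, {}
    for (a, b, c), p in p_abc.items():
        p_bc[(b, c)] = p_bc.get((b, c), 0.0) + p
        p_ab[(a, b)] = p_ab.get((a, b), 0.0) + p
        p_b[b] = p_b.get(b, 0.0) + p
    te = 0.0
    for (a, b, c), p in p_abc.items():
        te += p * math.log2(p * p_b[b] / (p_bc[(b, c)] * p_ab[(a, b)]))
    return te


class TestDelayedTE:
    def test_matches_brute_force_to_machine_precision(self):
        rng = np.random.default_rng(1)
        y = (rng.random(10_000) < 0.1).astype(np.int8)
        x = np.roll(y, 4)
        x[: 4] = 0
        x ^= (rng.random(10_000) < 0.02).astype(np.int8)  # noise
        for d in (1, 3, 4, 7):
            prof = hm.delayed_te(y, x, delays=[d])
            assert prof.te[0] == pytest.approx(brute_force_te(y, x, d), abs=1e-12)

    def test_two_neuron_loop_argmaxes_and_asymmetry(self):
        y, x = fx.make_two_neuron_loop(3, 2, 5000)
        p_yx = hm.delayed_te(y, x, np.arange(0, 11))
        p_xy = hm.delayed_te(x, y, np.arange(0, 11))
        assert p_yx.d_star == 3
        assert p_xy.d_star == 2
        assert p_yx.te[3] != p_xy.te[3]

    def test_loop_argmax_invariant_to_single_seed_position(self):
        for bin0 in (0, 13, 41):
            y, x = fx.make_two_neuron_loop(3, 2, 3000, seed_pattern=((bin0, "y"),))
            assert hm.delayed_te(y, x, np.arange(0, 11)).d_star == 3

    def test_independent_trains_near_zero(self):
        rng = np.random.default_rng(2)
        y = (rng.random(50_000) < 0.05).astype(np.int8)
        x = (rng.random(50_000) < 0.05).astype(np.int8)
        prof = hm.delayed_te(y, x, np.arange(0, 10))
        floor = hm.shuffled_te_floor(y, x, np.arange(0, 10), seed=3)
        assert np.all(prof.te < 5 * floor + 1e-6)
        assert prof.te_max < 1e-3

    def test_delayed_copy_equals_binary_entropy(self):
        p, d0 = 0.2, 6
        y, x = fx.make_delayed_copy(p, d0, 200_000, seed=4)
        prof = hm.delayed_te(y, x, np.arange(0, 12))
        assert prof.d_star == d0
        assert prof.te_max == pytest.approx(fx.binary_entropy_bits(p), rel=0.01)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(5)
        y = (rng.random(5000) < 0.1).astype(np.int8)
        x = (rng.random(5000) < 0.1).astype(np.int8)
        assert np.all(hm.delayed_te(y, x, np.arange(0, 50)).te >= 0)

    def test_degenerate_train_flagged_not_raised(self):
        y = np.zeros(1000, dtype=np.int8)
        x = (np.random.default_rng(6).random(1000) < 0.1).astype(np.int8)
        prof = hm.delayed_te(y, x, np.arange(0, 5))
        assert prof.degenerate and np.all(prof.te == 0)

    def test_shuffle_floor_shrinks_with_samples(self):
        rng = np.random.default_rng(7)
        floors = []
        for n in (2_000, 20_000):
            y = (rng.random(n) < 0.1).astype(np.int8)
            x = (rng.random(n) < 0.1).astype(np.int8)
            floors.append(hm.shuffled_te_floor(y, x, np.arange(0, 20), seed=8))
        assert floors[1] < floors[0] / 3  # ~1/n scaling

    def test_printed_form_available_but_different(self):
        y, x = fx.make_two_neuron_loop(3, 2, 2000)
        cond = hm.delayed_te(y, x, np.arange(0, 8), formula="conditional")
        printed = hm.delayed_te(y, x, np.arange(0, 8), formula="printed")
        assert not np.allclose(cond.te, printed.te)


class TestNetworkTE:
    def test_single_pair_mean_is_that_pairs_max(self):
        y, x = fx.make_two_neuron_loop(3, 2, 3000)
        ids = np.concatenate([np.zeros(int(y.sum())), np.ones(int(x.sum()))])
        times = np.concatenate([np.flatnonzero(y) * 0.1, np.flatnonzero(x) * 0.1])
        order = np.argsort(times, kind="stable")
        spk = hm.SpikeData(
            neuron_ids=ids[order].astype(np.int64), times=times[order],
            n_neurons=2, t_total=300.0, dt=0.1,
        )
        mean_te, profiles = hm.network_te(
            spk, n_pairs=10, delay_range=(0, 10), seed=0, return_profiles=True
        )
        assert len(profiles) == 2  # only 2 ordered pairs exist
        assert mean_te == pytest.approx(
            np.mean([p.te_max for p in profiles])
        )

    def test_independent_poisson_near_floor(self):
        spk = fx.make_poisson(20, 150.0, t_total=1000.0, seed=9)
        mean_te = hm.network_te(spk, n_pairs=30, delay_range=(155, 170), seed=1)
        assert mean_te < 5e-3

    def test_pair_sampler_unique_ordered(self):
        rng = np.random.default_rng(10)
        pairs = _sample_ordered_pairs(30, 200, rng)
        assert pairs.shape == (200, 2)
        assert np.all(pairs[:, 0] != pairs[:, 1])
        codes = pairs[:, 0] * 30 + pairs[:, 1]
        assert np.unique(codes).size == 200


class TestMacroTE:
    def test_identical_series_adds_nothing(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(1500)
        assert hm.macro_te(x, x).value == pytest.approx(0.0, abs=0.05)

    def test_independent_white_noise_near_zero(self):
        rng = np.random.default_rng(12)
        res = hm.macro_te(rng.standard_normal(1500), rng.standard_normal(1500))
        assert res.value == pytest.approx(0.0, abs=0.05)

    def test_ar_coupled_within_20pct_of_gaussian_oracle(self):
        y, x = fx.make_ar_coupled(a=0.5, c=0.5, n=2000, sigma=0.5, seed=13)
        oracle = fx.ar_te_bits(0.5, 0.5)
        est = hm.macro_te(y, x).value
        assert abs(est - oracle) / oracle < 0.2

    def test_uncoupled_ar_near_zero(self):
        y, x = fx.make_ar_coupled(a=0.6, c=0.0, n=1500, seed=14)
        assert hm.macro_te(y, x).value == pytest.approx(0.0, abs=0.05)

    def test_constant_series_degenerate(self):
        res = hm.macro_te(np.ones(100), np.arange(100.0))
        assert res.degenerate and res.value == 0.0


class TestMutualInformation:
    def test_gaussian_oracle(self):
        g1, g2 = fx.make_gaussian_pair(0.5, 2000, seed=15)
        est = hm.mutual_information_kde(g1, g2).value
        assert est == pytest.approx(fx.gaussian_mi_bits(0.5), abs=0.05)

    def test_independent_near_zero(self):
        g1, g2 = fx.make_gaussian_pair(0.0, 2000, seed=16)
        assert hm.mutual_information_kde(g1, g2).value == pytest.approx(0.0, abs=0.05)

    def test_identical_series_maximal(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(1000)
        mi_self = hm.mutual_information_kde(x, x).value
        g1, g2 = fx.make_gaussian_pair(0.5, 1000, seed=18)
        assert mi_self > hm.mutual_information_kde(g1, g2).value

    def test_symmetry(self):
        g1, g2 = fx.make_gaussian_pair(0.7, 800, seed=19)
        a = hm.mutual_information_kde(g1, g2).value
        b = hm.mutual_information_kde(g2, g1).value
        assert a == pytest.approx(b, abs=1e-9)


class TestModuleActivity:
    def test_h0_equals_network_rate(self, uncoupled_run):
        topo = hm.build_base_random(
            hm.TopologyConfig(n_neurons=uncoupled_run.n_neurons, connectivity=0.0, seed=0)
        )
        rates = hm.module_activity(uncoupled_run, topo)
        net = hm.population_rate(uncoupled_run)
        assert len(rates) == 1
        assert np.allclose(rates[0].values, net.values)

    def test_module_rate_conservation(self, small_hier_topology):
        spk = hm.simulate(
            small_hier_topology,
            synapse=hm.SynapseParams(j_exc=0.1),
            sim=hm.SimConfig(t_total=500.0, seed=1),
        )
        rates = hm.module_activity(spk, small_hier_topology)
        net = hm.population_rate(spk)
        msize = small_hier_topology.module_size
        combined = sum(r.values * msize for r in rates)
        assert np.allclose(combined, net.values * small_hier_topology.n_neurons)

    def test_adjacent_mi_needs_modules(self, uncoupled_run):
        topo = hm.build_base_random(
            hm.TopologyConfig(n_neurons=uncoupled_run.n_neurons, connectivity=0.0, seed=0)
        )
        rates = hm.module_activity(uncoupled_run, topo)
        with pytest.raises(ValueError):
            hm.adjacent_mi(rates)
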