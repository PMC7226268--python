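import numpy as np
import pytest

import hmnet as hm


@pytest.fixture(scope="session")
def small_hier_topology():
    """N=2048, eps=0.05, H=3, single R=0.9 — cheap but structured."""
    cfg = hm.TopologyConfig(
        n_neurons=2048, connectivity=0.05, hierarchy_level=3,
        rewire_exc=0.9, rewire_inh=0.9, seed=11,
    )
    return hm.build_hierarchy(cfg)


@pytest.fixture(scope="session")
def poisson_raster():
    return hm.fixtures.make_poisson(1000, 100.0, t_total=2000.0, dt=0.1, seed=5)


@pytest.fixture(scope="session")
def uncoupled_run():
    """200 uncoupled neurons under the default constant drive."""
    topo = hm.build_base_random(
        hm.TopologyConfig(n_neurons=200, connectivity=0.0, seed=0)
    )
    spk = hm.simulate(
        topo, synapse=hm.SynapseParams(j_exc=0.0), sim=hm.SimConfig(seed=3)
    )
    return spk
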