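"""Run a miniature J x H protocol sweep and aggregate it.

A tiny grid (two synaptic strengths, two hierarchy levels, one seed) at a
small network size: each point records the mean rate, Fano factor and
correlation time; the aggregate step produces per-point mean/SD tables.
"""

import hmnet as hm
from hmnet.pipeline import SweepConfig, aggregate, run_sweep

cfg = SweepConfig(
    j_values=[0.0, 0.3],
    h_values=[0, 2],
    seeds=[1],
    n_neurons=1024,
    scaling="fixed_eps",
    t_total=1000.0,
    k_spectrum=256,
    k_macro_pairs=8,
)
df = run_sweep(cfg)
print(df[["J", "H", "nu", "fano", "tau_c"]].round(3).to_string(index=False))
out = aggregate(df)
print("\nper-(J,H) summary (single seed, SD is NA by design):")
print(out["per_point"].round(3).to_string(index=False))
# At J = 0 every point reproduces the uncoupled closed-form rate (~69.6 Hz);
# coupling with g = 5 lowers the rate, and the H = 2 rows add the
# macroscopic TE/MI columns computed between the four modules.
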