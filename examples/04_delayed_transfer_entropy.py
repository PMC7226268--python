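"""Delay-resolved transfer entropy recovers synaptic delays and direction.

Two neurons excite each other in a loop: x fires 3 bins after every y spike
and y fires 2 bins after every x spike.  Scanning TE over candidate delays
finds each connection's delay as the argmax, and the asymmetry
TE_{y->x}(d) != TE_{x->y}(d) gives the direction.
"""

import numpy as np

import hmnet as hm

y, x = hm.fixtures.make_two_neuron_loop(delay_yx=3, delay_xy=2, n_bins=5000)
delays = np.arange(0, 11)
p_yx = hm.delayed_te(y, x, delays)
p_xy = hm.delayed_te(x, y, delays)

print("d      TE(y->x)  TE(x->y)   [bits]")
for d in delays:
    print(f"{d:2d}     {p_yx.te[d]:.4f}    {p_xy.te[d]:.4f}")
print(f"\nargmax TE(y->x) = {p_yx.d_star}  (y->x connection delay: 3 bins)")
print(f"argmax TE(x->y) = {p_xy.d_star}  (x->y connection delay: 2 bins)")
# Each profile peaks exactly at its connection delay, and the two directions
# differ at any fixed delay — the delay scan doubles as a functional-delay
# and direction estimator.
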