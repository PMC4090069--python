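"""Compute the symmetry measure of a small weighted directed network.

Builds a 3-neuron network by hand, decomposes it into connection pairs and
prints the measure.  Pair (0,1) has weights 0.6 / 0.2 (z = 0.5, leaning
unidirectional), pair (0,2) is perfectly reciprocal (z = 0), and pair (1,2)
is unconnected, so it is excluded: s = 1 - (0.5 + 0)/2 = 0.75.
"""

import numpy as np

from netsym import WeightMatrix, pair_decompose, symmetry_measure

w = np.array(
    [
        [0.0, 0.6, 0.5],
        [0.2, 0.0, 0.0],
        [0.5, 0.0, 0.0],
    ]
)
W = WeightMatrix(weights=w)

dec = pair_decompose(W)
for i, j, z in zip(dec.i, dec.j, dec.z):
    print(f"pair ({i},{j}): z = {z:.3f}")
print(f"excluded (0,0) pairs: {dec.n_zero_pairs}")

rep = symmetry_measure(W)
print(f"s = {rep.s:.4f} over {rep.n_counted} counted pairs")
print("s near 1 = reciprocal network, s near 0 = one-way network.")
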