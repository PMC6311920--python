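"""Weight features by kernel-density mutual information.

The weight I(x, Y) measures how informative a continuous expression
profile x is about the discrete subtype label Y, using Gaussian-kernel
density estimates for the feature and the 0/1 discrete metric for the
labels.  A feature whose values track the labels scores higher than one
whose values ignore them; a constant feature scores exactly 0.
"""

import numpy as np

from isomirpanel import LabelVector, mi_weight

x = np.array([0.0, 1.0, 0.0, 1.0])
aligned = LabelVector(np.array(["A", "B", "A", "B"], dtype=object))
balanced = LabelVector(np.array(["A", "A", "B", "B"], dtype=object))

w_aligned = mi_weight(x, aligned)
w_balanced = mi_weight(x, balanced)
w_constant = mi_weight(np.full(4, 3.0), aligned)

print(f"label-aligned feature   (x matches labels): I = {w_aligned:.4f}")
print(f"label-balanced feature  (x ignores labels): I = {w_balanced:.4f}")
print(f"constant feature                          : I = {w_constant:.1e}")
# The aligned layout scores ~3x the balanced one, and the constant
# feature cancels analytically to zero: the weight orders features by
# how much their expression says about the subtype.
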