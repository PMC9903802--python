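"""Orientation signature of chromothripsis.

Random shatter-and-rejoin predicts junction classes DEL : DUP : INV in a
1 : 1 : 2 ratio, because the two fragment ends of every join are flipped
independently.  This simulates 50 chromothripsis events of 30 breaks,
classifies the junctions inside COMPLEX clusters, and prints the ratios —
both should be near 0.5.
"""

from svweave.benchmarks import shatter_ratio_study

out = shatter_ratio_study(n_events=50, n_breaks=30, seed=2)
print(f"junctions in COMPLEX clusters: {out['n_junctions']}")
print(f"DEL : INV ratio = {out['del_to_inv_ratio']:.3f}  (random shatter predicts 0.5)")
print(f"DUP : INV ratio = {out['dup_to_inv_ratio']:.3f}  (random shatter predicts 0.5)")
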