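"""Three-regime structure along the kinase-rate axis.

Sweeping the mutant's kinase rate traces the monostable-OFF -> bistable ->
monostable-ON sequence, with two saddle-node (fold) points.  Priming is
what happens when a condition shift (slow growth, high Mg2+) carries the
system past the upper fold into the monostable-ON regime.
"""
import numpy as np
import tcswitch as t

p = t.default_params("t281r")
bt = t.bifurcation_sweep("reduced", p, "k_k", np.logspace(-4, 0, 25))
print("regime sequence:", " -> ".join(bt.regime_sequence))
print("fold points at k_k =", ", ".join(f"{x:.4g}" for x in bt.folds))
print()
print(bt.to_dataframe()[["value", "n_roots", "regime"]].to_string(index=False))
print()
print(f"The default mutant kinase rate k_k = {p.k_k} lies inside the bistable")
print("window, so OFF and ON populations coexist and inherit their state.")
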