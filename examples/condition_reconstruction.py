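"""Recover imposed parameter changes from a cell's phenotype alone.

Mimics a remodelled (e.g. failing) myocyte: several conductances are
changed by known fold-factors, the altered cell's outputs are measured
at three extracellular-potassium levels, and reverse regression maps
those outputs back to the parameter changes.  Uses the fast Luo-Rudy
model so the whole experiment runs in well under a minute.
"""

import numpy as np

from cardioreg import regression as rg

condition = ("G_Na", "G_si", "G_K")
true_folds = np.array([0.75, 1.3, 0.8])

pred, true, (X, Y, names), mdl = rg.reconstruct_condition(
    "lr1", condition, true_folds, n=80, seed=17)

print(f"training population: {X.shape[0]} variants of {len(condition)} "
      f"parameters, {Y.shape[1]} outputs (3 [K+]o levels)")
for name, t, p in zip(condition, true, pred):
    print(f"  {name:5s} true x{t:.2f}  predicted x{p:.2f}")
print()
print("Predictions within ~25% of truth mean the output panel carries")
print("enough information to diagnose the underlying conductance changes.")
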