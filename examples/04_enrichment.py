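"""Hypergeometric over-representation of modules against gene sets.

Builds a toy gene-set collection over a 200-gene universe and asks whether a
module overlaps each set more than chance would allow, with per-module
Benjamini-Hochberg adjustment.  The p-value is the hypergeometric upper tail
P(X >= k) for k observed overlaps.
"""
import numpy as np

from comodule import GeneSetCollection, ModuleSet, enrich_modules

rng = np.random.default_rng(0)
universe = [f"g{i:03d}" for i in range(200)]

collection = GeneSetCollection(
    {
        "pathway_alpha": universe[:30],
        "pathway_beta": universe[30:55],
        "random_set": list(rng.choice(universe, size=25, replace=False)),
    },
    universe=universe,
)

# one module drawn mostly from pathway_alpha, one unrelated
modules = ModuleSet(
    gene_ids=universe,
    modules=[universe[:18] + universe[100:104], universe[150:170]],
)

table = enrich_modules(modules, collection, cutoff=0.05)
print(table.to_string(index=False))
print("\nrows kept: per-module BH-adjusted p < 0.05;")
print("overlap/module_in_universe vs set_size/200 drives the hypergeometric tail")
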