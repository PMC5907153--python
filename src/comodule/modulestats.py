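"""Per-module structure statistics and the cross-network edge-probability test.

For each module the induced subgraph in each network gives an average degree
d-bar = 2m/n and a density D = 2m/(n(n-1)).  To ask whether a module is wired
differently in the two conditions, every unordered gene pair inside the
module is treated as a Bernoulli edge indicator and the two indicator
samples are compared with a two-sample t-test on their means (the edge
probabilities).
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .datatypes import CoexpressionNetwork, ModuleSet, ModuleStatsRecord

__all__ = ["module_degree_density", "structure_test", "stats_table", "edge_indicators"]


def _module_index(module, net: CoexpressionNetwork) -> np.ndarray:
    idx = {g: i for i, g in enumerate(net.gene_ids)}
    missing = [g for g in module if g not in idx]
    if missing:
        raise ValueError(f"module genes missing from the network: {missing[:5]}")
    return np.array([idx[g] for g in module], dtype=int)


def module_degree_density(
    module: list[str], net: CoexpressionNetwork
) -> tuple[float, float]:
    """Average degree and density of the module's induced subgraph.

    With n genes and m induced edges: d-bar = 2m/n, D = 2m/(n(n-1)),
    so D = d-bar/(n-1) exactly.
    """
    n = len(module)
    if n < 2:
        raise ValueError("module must contain at least 2 genes")
    rows = _module_index(module, net)
    sub = net.adjacency[np.ix_(rows, rows)]
    m = int(sub.sum()) // 2
    avg_degree = 2.0 * m / n
    density = avg_degree / (n - 1)  # = 2m / (n (n-1)), exact identity with d-bar
    return avg_degree, density


def edge_indicators(module: list[str], net: CoexpressionNetwork) -> np.ndarray:
    """0/1 vector over the module's n(n-1)/2 unordered gene pairs."""
    rows = _module_index(module, net)
    sub = net.adjacency[np.ix_(rows, rows)]
    iu = np.triu_indices(len(rows), k=1)
    return sub[iu].astype(float)


def structure_test(
    module: list[str],
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    equal_var: bool = False,
) -> float:
    """Two-sided t-test that the module's edge probability is equal in A and B.

    The samples are the two networks' edge-indicator vectors over the module's
    unordered pairs; Welch's unequal-variance form is the default, a
    pooled-variance form is available via ``equal_var=True``.  When both
    indicator vectors are constant the statistic is undefined; equal means
    (e.g. two complete or two empty subgraphs) return p = 1, unequal constant
    means return p = 0.
    """
    if len(module) < 3:
        raise ValueError("structure test needs a module of at least 3 genes")
    xa = edge_indicators(module, net_a)
    xb = edge_indicators(module, net_b)
    if xa.std() == 0.0 and xb.std() == 0.0:
        return 1.0 if xa.mean() == xb.mean() else 0.0
    with warnings.catch_warnings():
        # near-constant indicator vectors trigger a precision warning in the
        # moment computation; the degenerate cases are handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xa, xb, equal_var=equal_var)
    return float(res.pvalue)


def stats_table(
    modules: ModuleSet,
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    equal_var: bool = False,
) -> list[ModuleStatsRecord]:
    """One :class:`ModuleStatsRecord` per module, in module order."""
    records = []
    for mid, genes in enumerate(modules.modules, start=1):
        da, dens_a = module_degree_density(genes, net_a)
        db, dens_b = module_degree_density(genes, net_b)
        p = structure_test(genes, net_a, net_b, equal_var=equal_var)
        records.append(
            ModuleStatsRecord(
                module_id=mid,
                size=len(genes),
                avg_degree_a=da,
                avg_degree_b=db,
                density_a=dens_a,
                density_b=dens_b,
                p_value=p,
            )
        )
    return records
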