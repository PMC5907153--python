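"""Hypergeometric over-representation analysis of modules against gene sets.

Given a background universe of N genes, a gene set with K members and a
module drawing n genes from the universe, the over-representation p-value of
an observed overlap k is the hypergeometric upper tail P(X >= k).  Within
each module, p-values are Benjamini-Hochberg adjusted across the tested sets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import ModuleSet

__all__ = ["GeneSetCollection", "hypergeom_ora", "bh_adjust", "enrich_modules"]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Sets are restricted to the universe on construction; sets left empty by
    the restriction are dropped with a warning.
    """

    sets: dict[str, list[str]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            seen: list[str] = []
            known: set[str] = set()
            for members in self.sets.values():
                for g in members:
                    if g not in known:
                        known.add(g)
                        seen.append(g)
            self.universe = seen
        uni = set(self.universe)
        restricted: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            inside = [g for g in dict.fromkeys(members) if g in uni]
            if inside:
                restricted[name] = inside
            else:
                log.warning("dropping gene set %r: empty after universe restriction", name)
        self.sets = restricted

    @property
    def n_universe(self) -> int:
        return len(self.universe)


def hypergeom_ora(
    module: set[str] | list[str],
    geneset: set[str] | list[str],
    universe: set[str] | list[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns (k, p) where k = |module ∩ geneset| and p = P(X >= k) for X
    hypergeometric with N = |universe|, K = |geneset ∩ universe| marked genes
    and n = |module ∩ universe| draws.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    mod = set(module) & uni
    if not mod:
        raise ValueError("module has no genes in the universe")
    gs = set(geneset) & uni
    k = len(mod & gs)
    N, K, n = len(uni), len(gs), len(mod)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(
    modules: ModuleSet,
    collection: GeneSetCollection,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Over-representation table for every (module, gene set) pair.

    BH adjustment is applied per module across that module's tested sets
    (mirroring per-query enrichment tools); rows with adjusted p < *cutoff*
    are retained, sorted by raw p within each module.  Columns:
    module, set, overlap, module_in_universe, set_size, p, p_adj.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    uni = set(collection.universe)
    rows = []
    for mid, genes in enumerate(modules.modules, start=1):
        mod_in_uni = set(genes) & uni
        if not mod_in_uni:
            log.warning("module %d has no genes in the universe; skipped", mid)
            continue
        names, ks, ps = [], [], []
        for name, members in collection.sets.items():
            k, p = hypergeom_ora(mod_in_uni, members, uni)
            names.append(name)
            ks.append(k)
            ps.append(p)
        if not names:
            continue
        adj = bh_adjust(ps)
        for name, k, p, pa in zip(names, ks, ps, adj):
            if pa < cutoff:
                rows.append(
                    {
                        "module": mid,
                        "set": name,
                        "overlap": k,
                        "module_in_universe": len(mod_in_uni),
                        "set_size": len(collection.sets[name]),
                        "p": p,
                        "p_adj": pa,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["module", "set", "overlap", "module_in_universe", "set_size", "p", "p_adj"],
    )
    return df.sort_values(["module", "p"], kind="stable").reset_index(drop=True)
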