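"""Core in-memory containers shared by all pipeline stages.

Gene identifiers are opaque strings throughout; no symbol/accession
translation layer is provided.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ExpressionMatrix",
    "CoexpressionNetwork",
    "CorrelationSet",
    "ModuleSet",
    "ModuleStatsRecord",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples real matrix with identifiers and a condition label.

    Missing entries are stored as NaN until :func:`comodule.preprocess.impute_missing`
    replaces them.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class CoexpressionNetwork:
    """An unweighted, undirected gene network: symmetric 0/1 adjacency, zero diagonal."""

    gene_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("adjacency shape does not match gene index")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def laplacian(self) -> np.ndarray:
        """L = D - A, positive semidefinite."""
        a = self.adjacency.astype(float)
        return np.diag(a.sum(axis=1)) - a

    def to_graph(self) -> nx.Graph:
        g: nx.Graph = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_edges_from((self.gene_ids[i], self.gene_ids[j]) for i, j in zip(ii, jj))
        return g


#: processing stages a correlation matrix passes through
CORRELATION_STAGES = ("raw", "z", "normalized-z", "normalized-r")


@dataclass
class CorrelationSet:
    """One condition's gene-gene association matrix with a stage tag.

    The diagonal is structural (1 for correlation stages) and is excluded from
    every quantile and normalization computation.
    """

    gene_ids: list[str]
    matrix: np.ndarray
    stage: str = "raw"
    condition: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match gene index")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        if self.stage not in CORRELATION_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.matrix = m

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle off-diagonal values in a fixed (row-major) order."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.matrix[iu]


@dataclass
class ModuleSet:
    """Cluster labels per network plus the derived union modules.

    ``labels_a[i]`` / ``labels_b[i]`` is the cluster index (1..M) of gene
    ``gene_ids[i]`` in each network.  ``modules`` lists gene sets (ordered lists)
    which may overlap: a gene whose two network copies landed in different
    clusters belongs to both unions.
    """

    gene_ids: list[str]
    labels_a: np.ndarray | None = None
    labels_b: np.ndarray | None = None
    modules: list[list[str]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("labels_a", "labels_b"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab, dtype=int)
                if lab.shape != (len(self.gene_ids),):
                    raise ValueError(f"{name} length does not match gene index")
                setattr(self, name, lab)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_sizes(self) -> list[int]:
        return [len(m) for m in self.modules]

    def membership_of(self, gene: str) -> list[int]:
        """0-based indices of the modules containing *gene*."""
        return [i for i, m in enumerate(self.modules) if gene in set(m)]


@dataclass
class ModuleStatsRecord:
    """Structural statistics of one module in both networks.

    ``avg_degree`` is 2m/n and ``density`` 2m/(n(n-1)) over the induced
    subgraph with n genes and m edges, so density = avg_degree/(n-1) exactly.
    ``p_value`` comes from the Bernoulli edge-probability test.
    """

    module_id: int
    size: int
    avg_degree_a: float
    avg_degree_b: float
    density_a: float
    density_b: float
    p_value: float

    def __post_init__(self) -> None:
        for d in (self.density_a, self.density_b):
            if not (0.0 <= d <= 1.0):
                raise ValueError(f"density {d} outside [0, 1]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
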