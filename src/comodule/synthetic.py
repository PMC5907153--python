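"""Two-condition synthetic data with planted shared and differential modules.

Two generators emulate the structure the analysis assumes:

* a graph-level generator drawing two planted-partition (stochastic block
  model) layers over a shared gene universe, with per-module, per-layer
  intra-module edge probabilities — a module can be dense in both layers
  (shared) or dense in only one (differential);
* an expression-level generator producing genes x samples matrices from a
  one-factor-per-module Gaussian model, so that within-module Pearson
  correlation is a chosen rho per module and layer, background genes are
  pure noise, and the full network-construction chain can run on top.

Recovery of the planted labels is scored with the adjusted Rand index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .datatypes import CoexpressionNetwork, ExpressionMatrix, ModuleSet

__all__ = [
    "SyntheticScenario",
    "PlantedTruth",
    "default_sbm_scenario",
    "differential_sbm_scenario",
    "default_expression_scenario",
    "differential_expression_scenario",
    "generate_two_layer_sbm",
    "generate_correlated_expression",
    "omega_index",
    "recovery_score",
]


@dataclass
class SyntheticScenario:
    """Parameters of one simulated two-condition data set.

    ``layer_intra_p[m]`` is the (p_A, p_B) intra-module edge-probability pair
    of planted module m (graph generator); ``rho[m]`` the (rho_A, rho_B)
    within-module expression correlation pair (expression generator).  Genes
    beyond ``sum(module_sizes)`` are background: edge probability
    ``background_p`` / correlation 0.
    """

    n_genes: int = 100
    module_sizes: list[int] = field(default_factory=lambda: [25, 25, 25, 25])
    layer_intra_p: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.30, 0.30)] * 4
    )
    background_p: float = 0.02
    rho: list[tuple[float, float]] = field(default_factory=lambda: [(0.8, 0.8)] * 4)
    samples_per_layer: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the gene universe")
        if len(self.layer_intra_p) != len(self.module_sizes):
            raise ValueError("one intra-module probability pair per module required")
        if len(self.rho) != len(self.module_sizes):
            raise ValueError("one correlation pair per module required")
        probs = [p for pair in self.layer_intra_p for p in pair] + [self.background_p]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if any(not (0.0 <= r < 1.0) for pair in self.rho for r in pair):
            raise ValueError("correlations must lie in [0, 1)")

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    def labels(self) -> np.ndarray:
        """Planted module label per gene; 0 marks background genes."""
        lab = np.zeros(self.n_genes, dtype=int)
        start = 0
        for m, size in enumerate(self.module_sizes, start=1):
            lab[start : start + size] = m
            start += size
        return lab

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


@dataclass
class PlantedTruth:
    """Ground truth of a simulated scenario: gene labels and the parameters used."""

    gene_ids: list[str]
    labels: np.ndarray  # module index per gene, 0 = background
    scenario: SyntheticScenario

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.gene_ids),):
            raise ValueError("label length does not match gene index")


def default_sbm_scenario(seed: int = 0) -> SyntheticScenario:
    """The packaged recovery benchmark: a 100-gene universe of 4 shared
    modules of 25 genes each, intra-module edge probability 0.30 in both
    layers, between-module (background) edge probability 0.02."""
    return SyntheticScenario(seed=seed)


def differential_sbm_scenario(seed: int = 0) -> SyntheticScenario:
    """Like :func:`default_sbm_scenario` but module 4 is differential: dense
    in layer A (intra-module edge probability 0.30) and background-sparse in
    layer B (0.02), emulating a module wired in one condition only."""
    return SyntheticScenario(
        layer_intra_p=[(0.30, 0.30)] * 3 + [(0.30, 0.02)], seed=seed
    )


def default_expression_scenario(seed: int = 0) -> SyntheticScenario:
    """Expression-level counterpart: 4 shared modules of 20 genes with
    within-module correlation 0.8 in both layers, 40 background genes,
    200 samples per layer."""
    return SyntheticScenario(
        n_genes=120,
        module_sizes=[20, 20, 20, 20],
        layer_intra_p=[(0.30, 0.30)] * 4,
        rho=[(0.8, 0.8)] * 4,
        samples_per_layer=200,
        seed=seed,
    )


def differential_expression_scenario(seed: int = 0) -> SyntheticScenario:
    """One planted differential module over a noise background: 20 genes that
    are nearly uncorrelated in layer A (rho 0.05) and tightly correlated in
    layer B (rho 0.8), plus 100 background genes of pure noise — the
    situation where a module is wired in one condition only."""
    return SyntheticScenario(
        n_genes=120,
        module_sizes=[20],
        layer_intra_p=[(0.02, 0.30)],
        rho=[(0.05, 0.8)],
        samples_per_layer=200,
        seed=seed,
    )


def _edge_prob_matrix(scenario: SyntheticScenario, layer: int) -> np.ndarray:
    lab = scenario.labels()
    p = np.full((scenario.n_genes, scenario.n_genes), scenario.background_p)
    for m in range(1, len(scenario.module_sizes) + 1):
        members = np.nonzero(lab == m)[0]
        p[np.ix_(members, members)] = scenario.layer_intra_p[m - 1][layer]
    np.fill_diagonal(p, 0.0)
    return p


def generate_two_layer_sbm(
    scenario: SyntheticScenario,
) -> tuple[CoexpressionNetwork, CoexpressionNetwork, PlantedTruth]:
    """Draw the two planted-partition layers with independent Bernoulli edges."""
    rng = np.random.default_rng(scenario.seed)
    genes = scenario.gene_ids()
    nets = []
    n = scenario.n_genes
    iu = np.triu_indices(n, k=1)
    for layer in range(2):
        p = _edge_prob_matrix(scenario, layer)
        adj = np.zeros((n, n), dtype=np.int8)
        draws = rng.random(len(iu[0]))
        adj[iu] = (draws < p[iu]).astype(np.int8)
        adj += adj.T
        nets.append(CoexpressionNetwork(list(genes), adj))
    truth = PlantedTruth(list(genes), scenario.labels(), scenario)
    return nets[0], nets[1], truth


def generate_correlated_expression(
    scenario: SyntheticScenario,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PlantedTruth]:
    """Draw the two expression layers from the one-factor-per-module model.

    Gene g in module m and sample s of layer k has value
    sqrt(rho_k(m)) * f_{m,s} + sqrt(1 - rho_k(m)) * eps_{g,s} with the module
    factor f and the gene noise eps independent standard normal, giving an
    expected within-module Pearson correlation rho_k(m) and zero correlation
    between modules.  Background genes are pure noise.
    """
    if scenario.samples_per_layer < 10:
        raise ValueError("need at least 10 samples per layer")
    rng = np.random.default_rng(scenario.seed)
    genes = scenario.gene_ids()
    lab = scenario.labels()
    n, s = scenario.n_genes, scenario.samples_per_layer
    layers = []
    for layer, cond in enumerate(("A", "B")):
        factors = rng.standard_normal((len(scenario.module_sizes), s))
        eps = rng.standard_normal((n, s))
        values = eps.copy()
        for m in range(1, len(scenario.module_sizes) + 1):
            rho = scenario.rho[m - 1][layer]
            members = lab == m
            values[members] = np.sqrt(rho) * factors[m - 1] + np.sqrt(1.0 - rho) * eps[members]
        samples = [f"{cond}s{i:03d}" for i in range(s)]
        layers.append(ExpressionMatrix(values, list(genes), samples, condition=cond))
    truth = PlantedTruth(list(genes), lab, scenario)
    return layers[0], layers[1], truth


def omega_index(found: ModuleSet, truth: PlantedTruth) -> float:
    """Overlap-aware agreement between found modules and planted labels.

    For every unordered gene pair the number of shared clusters is counted in
    each grouping (found modules may overlap; planted labels are a partition
    with background class 0; genes in no found module form one background
    class).  The omega index is the chance-corrected fraction of pairs on
    which the two counts agree — the overlapping-cover generalization of the
    adjusted Rand index, equal to it when neither side overlaps.
    """
    if set(found.gene_ids) - set(truth.gene_ids):
        raise ValueError("found modules mention genes outside the planted universe")
    n = len(truth.gene_ids)
    pos = {g: i for i, g in enumerate(truth.gene_ids)}
    iu = np.triu_indices(n, k=1)

    def pair_counts(clusters: list[list[int]]) -> np.ndarray:
        counts = np.zeros((n, n), dtype=np.int64)
        for members in clusters:
            idx = np.asarray(members, dtype=int)
            counts[np.ix_(idx, idx)] += 1
        return counts[iu]

    truth_clusters = [
        np.nonzero(truth.labels == m)[0].tolist() for m in np.unique(truth.labels)
    ]
    found_clusters = [[pos[g] for g in mod] for mod in found.modules]
    in_any = set().union(*(set(c) for c in found_clusters)) if found_clusters else set()
    leftover = [i for i in range(n) if i not in in_any]
    if leftover:
        found_clusters.append(leftover)

    t = pair_counts(truth_clusters)
    f = pair_counts(found_clusters)
    n_pairs = len(iu[0])
    observed = float(np.mean(t == f))
    expected = 0.0
    for k in range(int(max(t.max(), f.max())) + 1):
        expected += float(np.sum(t == k)) * float(np.sum(f == k)) / n_pairs**2
    if expected >= 1.0:
        return 1.0 if observed >= 1.0 else 0.0
    return (observed - expected) / (1.0 - expected)


def recovery_score(found: ModuleSet, truth: PlantedTruth) -> float:
    """Adjusted Rand index between recovered union modules and planted labels.

    Union modules may overlap; a gene is assigned to the first module that
    contains it, and genes in no module join the background class 0 (matching
    the generator's background label).
    """
    if set(found.gene_ids) - set(truth.gene_ids):
        raise ValueError("found modules mention genes outside the planted universe")
    pos = {g: i for i, g in enumerate(truth.gene_ids)}
    pred = np.zeros(len(truth.gene_ids), dtype=int)
    for mid, genes in enumerate(found.modules, start=1):
        for g in genes:
            if pred[pos[g]] == 0:
                pred[pos[g]] = mid
    return float(adjusted_rand_score(truth.labels, pred))
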