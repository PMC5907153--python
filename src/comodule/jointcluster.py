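"""Joint module identification in two networks via a coupled Laplacian.

Both networks are clustered *simultaneously*: the two graph Laplacians
L_k = D_k - A_k are placed on the diagonal of a 2n x 2n block matrix whose
off-diagonal blocks -beta * I pull the two copies of each gene towards the
same cluster,

    C = [[L_1, -beta I], [-beta I, L_2]].

The eigenvectors of the M smallest eigenvalues of C embed the 2n vertex
copies in M dimensions (the relaxed solution of the combined ratio-cut /
cluster-alignment objective, with the columns scaled so S~^T S~ = 2 I_M);
agglomerative clustering with complete linkage under the Spearman distance
then cuts the embedding into M clusters.  Corresponding clusters from the two
networks are merged by union, split into connected components of the union
graph, and size-filtered.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .datatypes import CoexpressionNetwork, ModuleSet

__all__ = [
    "JointModel",
    "remove_dual_isolated",
    "assemble_C",
    "spectral_embed",
    "select_M",
    "cluster_embedding",
    "union_modules",
    "split_disconnected",
    "filter_size",
    "find_modules",
    "clustering_objective",
]

log = logging.getLogger(__name__)

#: switch to an iterative sparse eigensolver above this matrix size
_DENSE_LIMIT = 4000


@dataclass
class JointModel:
    """The coupled two-network model and (once computed) its spectral embedding."""

    beta: float
    gene_ids: list[str]
    C: np.ndarray
    eigenvalues: np.ndarray | None = None
    embedding: np.ndarray | None = None
    M: int | None = None

    @property
    def n(self) -> int:
        return len(self.gene_ids)


def remove_dual_isolated(
    net_a: CoexpressionNetwork, net_b: CoexpressionNetwork
) -> tuple[CoexpressionNetwork, CoexpressionNetwork, list[str]]:
    """Drop genes with no edge in *either* network.

    A gene isolated in only one network is kept: the coupling term lets the
    other network's structure place it in a module, which is exactly how
    condition-specific connectivity loss is detected.
    """
    if net_a.gene_ids != net_b.gene_ids:
        raise ValueError("networks must share the same gene index")
    keep = (net_a.degrees > 0) | (net_b.degrees > 0)
    if not keep.any():
        log.warning("every gene is isolated in both networks")
    idx = np.nonzero(keep)[0]
    genes = [net_a.gene_ids[i] for i in idx]
    sub_a = CoexpressionNetwork(genes, net_a.adjacency[np.ix_(idx, idx)])
    sub_b = CoexpressionNetwork(genes, net_b.adjacency[np.ix_(idx, idx)])
    return sub_a, sub_b, genes


def assemble_C(
    net_a: CoexpressionNetwork, net_b: CoexpressionNetwork, beta: float = 1.0
) -> JointModel:
    """Build the coupled matrix C = [[L1, -beta I], [-beta I, L2]].

    The eigen-decomposition is deferred to :func:`spectral_embed`.  Every
    eigenvalue of C is >= -beta: the Laplacian blocks are positive
    semidefinite and the coupling block alone has spectrum {-beta, +beta}.
    """
    if net_a.gene_ids != net_b.gene_ids:
        raise ValueError("networks must share the same gene index and ordering")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    n = net_a.n_genes
    C = np.zeros((2 * n, 2 * n))
    C[:n, :n] = net_a.laplacian()
    C[n:, n:] = net_b.laplacian()
    C[:n, n:] -= beta * np.eye(n)
    C[n:, :n] -= beta * np.eye(n)
    return JointModel(beta=float(beta), gene_ids=list(net_a.gene_ids), C=C)


def _deterministic_eigvecs(evals: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Make the eigenvector matrix reproducible across solver backends.

    Within each (numerically) degenerate eigenvalue group the returned basis
    is arbitrary up to rotation; it is replaced by the Gram-Schmidt
    orthonormalization of the coordinate projections in fixed vertex order.
    Then every eigenvector's largest-magnitude entry is made positive (ties
    broken by lowest index).
    """
    vecs = vecs.copy()
    scale = max(np.abs(evals).max(), 1.0)
    tol = 1e-8 * scale
    start = 0
    while start < len(evals):
        stop = start + 1
        while stop < len(evals) and evals[stop] - evals[stop - 1] <= tol:
            stop += 1
        g = stop - start
        if g > 1:
            V = vecs[:, start:stop]  # orthonormal basis of the eigenspace
            basis: list[np.ndarray] = []
            for i in range(V.shape[0]):
                v = V @ V[i, :]  # projection of e_i onto the eigenspace
                for b in basis:
                    v = v - (b @ v) * b
                nrm = np.linalg.norm(v)
                if nrm > 1e-10:
                    basis.append(v / nrm)
                if len(basis) == g:
                    break
            if len(basis) == g:
                vecs[:, start:stop] = np.column_stack(basis)
        start = stop
    for j in range(vecs.shape[1]):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


def spectral_embed(model: JointModel, M: int) -> JointModel:
    """Compute the M smallest eigenpairs of C and the 2n x M embedding.

    The embedding columns are orthonormal eigenvectors scaled by sqrt(2) so
    that the relaxed-problem constraint S~^T S~ = 2 I_M holds.  Eigenvectors
    follow a deterministic sign and degenerate-subspace convention (the
    Spearman distance used downstream is not invariant to sign flips).
    """
    two_n = model.C.shape[0]
    if not (1 <= M <= two_n):
        raise ValueError(f"M must be in [1, {two_n}]")
    if two_n <= _DENSE_LIMIT:
        evals, vecs = np.linalg.eigh(model.C)
    else:
        k = min(max(M + 10, 2 * M), two_n - 1)
        try:
            evals, vecs = sparse.linalg.eigsh(
                sparse.csr_matrix(model.C), k=k, which="SA"
            )
        except sparse.linalg.ArpackNoConvergence as err:
            raise RuntimeError(f"sparse eigensolver failed to converge: {err}") from err
        order = np.argsort(evals)
        evals, vecs = evals[order], vecs[:, order]
    vecs = _deterministic_eigvecs(evals, vecs)
    resid = np.linalg.norm(model.C @ vecs[:, :M] - vecs[:, :M] * evals[:M], axis=0)
    norm_c = np.linalg.norm(model.C)
    if norm_c > 0 and np.any(resid > 1e-8 * norm_c):
        raise RuntimeError(
            f"eigenpair residual {resid.max():.3e} exceeds 1e-8 * ||C|| = {1e-8 * norm_c:.3e}"
        )
    model.eigenvalues = evals
    model.embedding = np.sqrt(2.0) * vecs[:, :M]
    model.M = M
    return model


def select_M(
    eigenvalues: np.ndarray,
    search_range: tuple[int, int] = (2, 350),
    factor: float = 3.0,
) -> int:
    """Choose the embedding dimension M at the first big eigengap.

    Over the search range, M is the smallest index whose gap
    lambda_{M+1} - lambda_M is positive and at least *factor* times the median
    gap in the range.  If no gap qualifies the argmax gap is returned with a
    warning.  A fully degenerate spectrum (all gaps zero) is an error.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) < -1e-9 * max(1.0, np.abs(ev).max())):
        raise ValueError("eigenvalues must be ascending")
    lo, hi = search_range
    lo = max(lo, 1)
    hi = min(hi, len(ev) - 1)
    if lo > hi:
        raise ValueError(f"empty search range [{lo}, {hi}] for {len(ev)} eigenvalues")
    ms = np.arange(lo, hi + 1)
    gaps = ev[ms] - ev[ms - 1]  # gap after the M-th smallest eigenvalue (1-based M)
    if np.all(gaps <= 0):
        raise ValueError("degenerate spectrum: all eigengaps are zero in the range")
    tol = 1e-12 * max(1.0, float(np.abs(ev).max()))
    threshold = factor * float(np.median(gaps))
    qualifying = (gaps > tol) & (gaps >= threshold)
    if qualifying.any():
        return int(ms[np.argmax(qualifying)])
    log.warning(
        "no eigengap reaches %.3g x median gap; falling back to the largest gap", factor
    )
    return int(ms[np.argmax(gaps)])


def _rank_distances(embedding: np.ndarray, rank_mode: str) -> np.ndarray:
    """Condensed pairwise rank-based distances between embedding rows.

    ``rank_mode="column"`` replaces each eigenvector by the ranks of its
    entries across the 2n vertex copies (scaled to [0, 1]) and measures
    Euclidean distance between the resulting rank profiles.  This uses
    exactly the information the rank argument for the method relies on: the
    *order* of the entries within an eigenvector is stable even when their
    magnitudes are not.

    ``rank_mode="row"`` is the classical Spearman distance, 1 minus the rank
    correlation between the M coordinates of two rows.  A constant row has no
    defined rank correlation and is assigned distance 1 to every other row.
    With small M this distance is coarse (only M! rank patterns exist), so it
    is mainly useful at large embedding dimensions.
    """
    if rank_mode == "column":
        # round first so rows equal up to eigensolver noise tie exactly
        profiles = rankdata(np.round(embedding, 9), axis=0) / embedding.shape[0]
        return pdist(profiles, metric="euclidean")
    if rank_mode == "row":
        ranks = rankdata(embedding, axis=1)
        const = np.ptp(ranks, axis=1) == 0
        if const.any():
            log.warning(
                "%d constant embedding rows get distance 1 to all rows", int(const.sum())
            )
        d = pdist(ranks, metric="correlation")
        if const.any() or np.isnan(d).any():
            dm = squareform(d)
            dm[const, :] = 1.0
            dm[:, const] = 1.0
            np.fill_diagonal(dm, 0.0)
            dm[np.isnan(dm)] = 1.0
            d = squareform(dm, checks=False)
        return d
    raise ValueError(f"unknown rank_mode {rank_mode!r}; use 'column' or 'row'")


def cluster_embedding(model: JointModel, rank_mode: str = "column") -> ModuleSet:
    """Cut the joint embedding into M clusters.

    All 2n rows (both vertex copies of every gene) are clustered together by
    agglomerative clustering with complete linkage under a rank-based
    (Spearman) distance; rows 1..n yield the network-A labels, rows n+1..2n
    the network-B labels.  Ranks are used because eigenvector entry
    magnitudes vary wildly with matrix size while their ordering is stable;
    see :func:`_rank_distances` for the two available rank readings.
    """
    if model.embedding is None or model.M is None:
        raise ValueError("run spectral_embed before clustering")
    if model.M < 2:
        raise ValueError("clustering needs an embedding with at least 2 columns")
    d = _rank_distances(model.embedding, rank_mode)
    Z = linkage(d, method="complete")
    labels = fcluster(Z, t=model.M, criterion="maxclust")
    n = model.n
    return ModuleSet(
        gene_ids=list(model.gene_ids),
        labels_a=labels[:n],
        labels_b=labels[n:],
        provenance=[f"joint spectral clustering (rank_mode={rank_mode})"],
    )


def union_modules(labels: ModuleSet, allow_overlap: bool = True) -> ModuleSet:
    """Merge corresponding per-network clusters by union.

    Union module m contains every gene labelled m in either network; a gene
    whose two copies received different labels is a member of both unions, so
    modules may overlap (flagged in provenance).  With
    ``allow_overlap=False`` such a gene joins only the lower-indexed of its
    two clusters (with two networks there is no majority to break the tie,
    so the rule is a fixed deterministic choice).
    """
    if labels.labels_a is None or labels.labels_b is None:
        raise ValueError("per-network labels are required")
    modules: list[list[str]] = []
    overlapping = False
    for m in sorted(set(labels.labels_a.tolist()) | set(labels.labels_b.tolist())):
        members = [
            g
            for g, la, lb in zip(labels.gene_ids, labels.labels_a, labels.labels_b)
            if (la == m or lb == m)
            and (allow_overlap or m == min(la, lb))
        ]
        if members:
            modules.append(members)
    assigned = sum(len(m) for m in modules)
    overlapping = assigned > len(labels.gene_ids)
    prov = labels.provenance + ["union of per-network clusters"]
    if overlapping:
        prov.append("overlapping unions present")
    return ModuleSet(
        gene_ids=list(labels.gene_ids),
        labels_a=labels.labels_a,
        labels_b=labels.labels_b,
        modules=modules,
        provenance=prov,
    )


def split_disconnected(
    modules: ModuleSet,
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
) -> ModuleSet:
    """Replace each module by the connected components of its induced subgraph.

    Connectivity is judged in the union graph (an edge in either network
    counts): the joint model deliberately borrows connection information
    across networks, so a module may be held together by either layer.
    """
    if net_a.gene_ids != net_b.gene_ids:
        raise ValueError("networks must share the same gene index")
    union_adj = np.maximum(net_a.adjacency, net_b.adjacency)
    union_net = CoexpressionNetwork(list(net_a.gene_ids), union_adj)
    g = union_net.to_graph()
    out: list[list[str]] = []
    for members in modules.modules:
        sub = g.subgraph(members)
        comps = [sorted(c, key=members.index) for c in nx.connected_components(sub)]
        comps.sort(key=lambda c: members.index(c[0]))
        out.extend(comps)
    return ModuleSet(
        gene_ids=list(modules.gene_ids),
        labels_a=modules.labels_a,
        labels_b=modules.labels_b,
        modules=out,
        provenance=modules.provenance + ["split into union-graph components"],
    )


def filter_size(modules: ModuleSet, min_size: int = 5, max_size: int = 800) -> ModuleSet:
    """Keep modules with min_size <= size <= max_size (inclusive), order preserved."""
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    kept = [m for m in modules.modules if min_size <= len(m) <= max_size]
    return ModuleSet(
        gene_ids=list(modules.gene_ids),
        labels_a=modules.labels_a,
        labels_b=modules.labels_b,
        modules=kept,
        provenance=modules.provenance + [f"size filter [{min_size}, {max_size}]"],
    )


def find_modules(
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    beta: float = 1.0,
    M: int | None = None,
    M_search_range: tuple[int, int] = (2, 350),
    eigengap_factor: float = 3.0,
    min_module_size: int = 5,
    max_module_size: int = 800,
    rank_mode: str = "column",
) -> tuple[ModuleSet, JointModel]:
    """End-to-end joint module discovery for two networks on a shared gene index.

    When *M* is None the embedding dimension is chosen by the first-big-
    eigengap rule on the spectrum of C.  Returns the final module set together
    with the fitted joint model (eigenvalues, embedding).
    """
    sub_a, sub_b, _kept = remove_dual_isolated(net_a, net_b)
    model = assemble_C(sub_a, sub_b, beta=beta)
    if M is None:
        probe = spectral_embed(model, M=min(model.C.shape[0], 2))
        assert probe.eigenvalues is not None
        M = select_M(probe.eigenvalues, search_range=M_search_range, factor=eigengap_factor)
    model = spectral_embed(model, M=M)
    labels = cluster_embedding(model, rank_mode=rank_mode)
    mods = union_modules(labels)
    mods = split_disconnected(mods, sub_a, sub_b)
    mods = filter_size(mods, min_module_size, max_module_size)
    return mods, model


def single_network_modules(
    net: CoexpressionNetwork, M: int, rank_mode: str = "column"
) -> np.ndarray:
    """Cluster one network alone with the same embedding-and-linkage machinery.

    Embeds the n vertices with the eigenvectors of the M smallest eigenvalues
    of L = D - A and cuts into M clusters; the beta = 0 joint model decouples
    into exactly this per network.  Returns the label vector (1..M).
    """
    L = net.laplacian()
    evals, vecs = np.linalg.eigh(L)
    vecs = _deterministic_eigvecs(evals, vecs)
    emb = np.sqrt(2.0) * vecs[:, :M]
    d = _rank_distances(emb, rank_mode)
    Z = linkage(d, method="complete")
    return fcluster(Z, t=M, criterion="maxclust")


def clustering_objective(
    labels: ModuleSet,
    net_a: CoexpressionNetwork,
    net_b: CoexpressionNetwork,
    beta: float = 1.0,
) -> float:
    """Tr(S~^T C S~) for a hard clustering encoded as normalized indicators.

    Column m of S~ stacks the two networks' indicator vectors for cluster m,
    each scaled to unit length (an empty cluster in one network contributes a
    zero block).  Equals the sum of per-network ratio-cut terms minus
    2 * beta * (sum over clusters of the cosine similarity between the two
    networks' indicator vectors).
    """
    if labels.labels_a is None or labels.labels_b is None:
        raise ValueError("per-network labels are required")
    model = assemble_C(net_a, net_b, beta=beta)
    n = model.n
    ms = sorted(set(labels.labels_a.tolist()) | set(labels.labels_b.tolist()))
    S = np.zeros((2 * n, len(ms)))
    for col, m in enumerate(ms):
        for k, lab in enumerate((labels.labels_a, labels.labels_b)):
            ind = (lab == m).astype(float)
            nrm = np.linalg.norm(ind)
            if nrm > 0:
                S[k * n : (k + 1) * n, col] = ind / nrm
    return float(np.trace(S.T @ model.C @ S))
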