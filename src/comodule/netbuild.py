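"""Construction of two cross-comparable unweighted coexpression networks.

The chain is: pairwise Pearson correlation per condition, Fisher z
transformation, standardization of the z-scores within each condition (so the
two correlation populations sit on the same scale), back-transformation to
correlations, and a single hard threshold — the empirical quantile of the
pooled absolute correlations — above which a gene pair receives an edge.
"""
from __future__ import annotations

import logging

import numpy as np

from .datatypes import CoexpressionNetwork, CorrelationSet, ExpressionMatrix

__all__ = [
    "pearson_matrix",
    "fisher_z",
    "inverse_fisher_z",
    "normalize_z",
    "threshold_networks",
    "build_networks",
]

log = logging.getLogger(__name__)

#: clip bound applied to |r| = 1 correlations when explicitly allowed
_CLIP = 1.0 - 1e-12


def pearson_matrix(expr: ExpressionMatrix) -> CorrelationSet:
    """Pairwise Pearson correlations between all gene rows.

    Requires >= 3 samples and no missing values.  A zero-variance gene has no
    defined correlation; its row and column are set to 0 with a warning.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    if expr.has_missing():
        raise ValueError("impute missing values before computing correlations")
    const = np.ptp(expr.values, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(expr.values)
    if const.any():
        log.warning(
            "%d zero-variance genes; their correlations are set to 0", int(const.sum())
        )
        r[const, :] = 0.0
        r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return CorrelationSet(list(expr.gene_ids), r, stage="raw", condition=expr.condition)


def fisher_z(corr: CorrelationSet, clip_perfect: bool = False) -> CorrelationSet:
    """Variance-stabilizing transform z = 0.5 * ln((1 + r) / (1 - r)).

    Perfect off-diagonal correlations (|r| = 1) are outside the domain; they
    are an error unless ``clip_perfect`` is set, in which case they are clipped
    to +/-(1 - 1e-12) with a warning (useful for synthetic data with duplicated
    rows).
    """
    if corr.stage != "raw":
        raise ValueError(f"fisher_z expects a raw correlation set, got {corr.stage!r}")
    r = corr.matrix.copy()
    n = len(corr.gene_ids)
    off = ~np.eye(n, dtype=bool)
    perfect = off & (np.abs(r) >= 1.0)
    if perfect.any():
        if not clip_perfect:
            i, j = np.argwhere(perfect)[0]
            raise ValueError(
                f"|r| >= 1 between {corr.gene_ids[i]!r} and {corr.gene_ids[j]!r}; "
                "drop duplicates or pass clip_perfect=True"
            )
        log.warning("clipping %d perfect correlations", int(perfect.sum()) // 2)
        r[perfect] = np.clip(r[perfect], -_CLIP, _CLIP)
    z = np.arctanh(r, where=off, out=np.zeros_like(r))
    return CorrelationSet(list(corr.gene_ids), z, stage="z", condition=corr.condition)


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    """r = tanh(z), the inverse of the Fisher transform."""
    return np.tanh(z)


def normalize_z(
    z_a: CorrelationSet, z_b: CorrelationSet
) -> tuple[CorrelationSet, CorrelationSet]:
    """Standardize each condition's off-diagonal z-scores and transform back.

    Within each condition the upper-triangle z values are centred on their
    empirical mean and scaled by their empirical standard deviation (the
    structural diagonal is excluded so it cannot bias the scale), then mapped
    back to correlations via tanh.  After this the two off-diagonal z
    populations have mean 0 and unit variance, making one pooled threshold
    meaningful.
    """
    out = []
    for z in (z_a, z_b):
        if z.stage != "z":
            raise ValueError(f"normalize_z expects stage 'z', got {z.stage!r}")
        vals = z.offdiag_values()
        sd = float(np.std(vals))
        if sd == 0.0:
            raise ValueError(
                f"all z values identical in condition {z.condition!r}; cannot standardize"
            )
        zn = (z.matrix - float(np.mean(vals))) / sd
        np.fill_diagonal(zn, np.inf)  # tanh(inf) = 1, the structural diagonal
        r = np.tanh(zn)
        out.append(
            CorrelationSet(list(z.gene_ids), r, stage="normalized-r", condition=z.condition)
        )
    return out[0], out[1]


def threshold_networks(
    r_a: CorrelationSet,
    r_b: CorrelationSet,
    q: float = 0.995,
    pooled: bool = True,
) -> tuple[CoexpressionNetwork, CoexpressionNetwork, float]:
    """Hard-threshold the two normalized correlation sets into 0/1 networks.

    The threshold t is the empirical *q*-quantile (inclusive linear
    interpolation) of the absolute off-diagonal correlations, pooled across
    both conditions by default; gene pair (i, j) receives an edge in condition
    k iff |r'_k(i, j)| > t (strictly).  Returns both networks and t.
    """
    for r in (r_a, r_b):
        if r.stage != "normalized-r":
            raise ValueError(f"threshold expects stage 'normalized-r', got {r.stage!r}")
    if not (0.0 < q < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    va = np.abs(r_a.offdiag_values())
    vb = np.abs(r_b.offdiag_values())
    if pooled:
        t = float(np.quantile(np.concatenate([va, vb]), q, method="linear"))
        ta = tb = t
    else:
        ta = float(np.quantile(va, q, method="linear"))
        tb = float(np.quantile(vb, q, method="linear"))
        t = (ta + tb) / 2.0
    nets = []
    for r, thr in ((r_a, ta), (r_b, tb)):
        adj = (np.abs(r.matrix) > thr).astype(np.int8)
        np.fill_diagonal(adj, 0)
        nets.append(CoexpressionNetwork(list(r.gene_ids), adj))
    if nets[0].n_edges == 0 and nets[1].n_edges == 0:
        log.warning("threshold %.6g leaves both networks empty", t)
    return nets[0], nets[1], t


def build_networks(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    q: float = 0.995,
    pooled: bool = True,
    clip_perfect: bool = False,
) -> tuple[CoexpressionNetwork, CoexpressionNetwork, float]:
    """Full chain from two expression matrices to two thresholded networks."""
    if expr_a.gene_ids != expr_b.gene_ids:
        raise ValueError("the two matrices must share the same gene universe")
    za = fisher_z(pearson_matrix(expr_a), clip_perfect=clip_perfect)
    zb = fisher_z(pearson_matrix(expr_b), clip_perfect=clip_perfect)
    na, nb = normalize_z(za, zb)
    return threshold_networks(na, nb, q=q, pooled=pooled)
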