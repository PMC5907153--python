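"""Missing-value imputation and differential-expression gene selection.

The gene universe carried into network construction is the set of genes whose
expression differs between the two conditions under both a Welch t-test and a
two-sample Kolmogorov-Smirnov test, each Benjamini-Hochberg adjusted across
genes separately.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

__all__ = ["impute_missing", "filter_differential_genes", "restrict_to_genes"]

log = logging.getLogger(__name__)


def impute_missing(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each missing entry by the mean of that gene's observed values.

    A gene with no observed value at all is an error (there is nothing to
    average).  Observed entries are left untouched, so the operation is
    idempotent.
    """
    values = expr.values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return ExpressionMatrix(values, list(expr.gene_ids), list(expr.sample_ids), expr.condition)
    all_missing = missing.all(axis=1)
    if all_missing.any():
        bad = [expr.gene_ids[i] for i in np.nonzero(all_missing)[0]]
        raise ValueError(f"genes with all values missing: {bad}")
    gene_means = np.nanmean(values, axis=1)
    rows, cols = np.nonzero(missing)
    values[rows, cols] = gene_means[rows]
    return ExpressionMatrix(values, list(expr.gene_ids), list(expr.sample_ids), expr.condition)


def filter_differential_genes(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    alpha: float = 0.01,
) -> list[str]:
    """Select genes differentially expressed between the two conditions.

    Per gene, a two-sided Welch t-test and a two-sided (asymptotic) KS test
    compare the two sample groups.  Each test family's p-values are BH-adjusted
    across genes separately; a gene is kept when both adjusted p-values fall
    strictly below *alpha*.  Genes constant in both conditions are excluded
    with a warning (neither test is defined for them).

    Returns the selected gene IDs in input order.  Symmetric in the two
    conditions.
    """
    if expr_a.gene_ids != expr_b.gene_ids:
        raise ValueError("the two matrices must share the same gene universe")
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    if alpha == 0.0:
        return []
    a, b = expr_a.values, expr_b.values
    const = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    testable = ~const
    if const.any():
        skipped = [expr_a.gene_ids[i] for i in np.nonzero(const)[0]]
        log.warning("skipping %d zero-variance genes: %s", len(skipped), skipped[:10])
    p_t = stats.ttest_ind(a[testable], b[testable], axis=1, equal_var=False).pvalue
    p_ks = np.array(
        [stats.ks_2samp(x, y, method="asymp").pvalue for x, y in zip(a[testable], b[testable])]
    )
    adj_t = multipletests(p_t, method="fdr_bh")[1]
    adj_ks = multipletests(p_ks, method="fdr_bh")[1]
    keep_testable = (adj_t < alpha) & (adj_ks < alpha)
    keep = np.zeros(len(expr_a.gene_ids), dtype=bool)
    keep[np.nonzero(testable)[0][keep_testable]] = True
    return [g for g, k in zip(expr_a.gene_ids, keep) if k]


def restrict_to_genes(expr: ExpressionMatrix, keep: set[str] | list[str]) -> ExpressionMatrix:
    """Restrict the matrix rows to ``keep ∩ gene_ids``, preserving row order."""
    keep = set(keep)
    if not keep:
        raise ValueError("keep set is empty")
    mask = [g in keep for g in expr.gene_ids]
    if not any(mask):
        raise ValueError("no overlap between keep set and the gene universe")
    idx = np.nonzero(mask)[0]
    return ExpressionMatrix(
        expr.values[idx],
        [expr.gene_ids[i] for i in idx],
        list(expr.sample_ids),
        expr.condition,
    )
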