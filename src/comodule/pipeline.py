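"""One-call driver tying the stages together under a RunConfig.

Mirrors the full analysis: imputation, differential-gene selection, network
construction, joint module identification, and the per-module statistics
table.  Each stage remains available individually for custom workflows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datatypes import CoexpressionNetwork, ExpressionMatrix, ModuleSet, ModuleStatsRecord
from .io import RunConfig
from .jointcluster import JointModel, find_modules
from .modulestats import stats_table
from .netbuild import build_networks
from .preprocess import filter_differential_genes, impute_missing, restrict_to_genes

__all__ = ["JointAnalysisResult", "run_joint_analysis"]

log = logging.getLogger(__name__)


@dataclass
class JointAnalysisResult:
    """Everything the end-to-end run produces."""

    selected_genes: list[str]
    net_a: CoexpressionNetwork
    net_b: CoexpressionNetwork
    threshold: float
    modules: ModuleSet
    stats: list[ModuleStatsRecord] = field(default_factory=list)
    model: JointModel | None = None


def run_joint_analysis(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    config: RunConfig | None = None,
    select_differential: bool = True,
) -> JointAnalysisResult:
    """Run the whole two-condition module comparison on expression matrices.

    With ``select_differential`` the gene universe is first restricted to the
    genes differing between the conditions under both the t and KS filters at
    ``config.de_alpha``; set it to False to keep every gene (e.g. when the
    two matrices already share a curated universe).
    """
    cfg = config or RunConfig()
    expr_a = impute_missing(expr_a)
    expr_b = impute_missing(expr_b)
    if select_differential:
        selected = filter_differential_genes(expr_a, expr_b, alpha=cfg.de_alpha)
        if not selected:
            raise ValueError(
                f"no gene clears the differential filter at alpha={cfg.de_alpha}"
            )
        expr_a = restrict_to_genes(expr_a, selected)
        expr_b = restrict_to_genes(expr_b, selected)
    else:
        selected = list(expr_a.gene_ids)
    log.info("gene universe: %d genes", len(selected))
    net_a, net_b, threshold = build_networks(
        expr_a, expr_b, q=cfg.quantile_threshold, pooled=cfg.pooled_quantile
    )
    modules, model = find_modules(
        net_a,
        net_b,
        beta=cfg.beta,
        M=cfg.M_override,
        M_search_range=cfg.M_search_range,
        eigengap_factor=cfg.eigengap_factor,
        min_module_size=cfg.min_module_size,
        max_module_size=cfg.max_module_size,
        rank_mode=cfg.rank_mode,
    )
    stats = stats_table(modules, net_a, net_b)
    return JointAnalysisResult(
        selected_genes=selected,
        net_a=net_a,
        net_b=net_b,
        threshold=threshold,
        modules=modules,
        stats=stats,
        model=model,
    )
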