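"""Readers and writers for the package's plain-text formats, plus run configuration.

Formats
-------
* expression matrix: TSV, first column gene IDs, header row sample IDs,
  missing values written as ``NA`` or an empty cell
* network: two-column TSV edge list, undirected semantics
* gene sets: GMT (name, description, tab-separated member IDs)
* modules: a membership TSV plus a statistics TSV mirroring the module table
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .datatypes import CoexpressionNetwork, ExpressionMatrix, ModuleSet, ModuleStatsRecord

__all__ = [
    "RunConfig",
    "load_config",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_modules",
    "read_modules",
]

log = logging.getLogger(__name__)

#: cell contents treated as a missing measurement
MISSING_MARKERS = {"NA", ""}


@dataclass(frozen=True)
class RunConfig:
    """All scalar settings of the pipeline; the defaults reproduce the
    published analysis settings (99.5% quantile threshold, beta = 1,
    module size bounds [5, 800], differential-expression alpha 0.01).
    """

    quantile_threshold: float = 0.995
    beta: float = 1.0
    M_override: int | None = None
    M_search_range: tuple[int, int] = (2, 350)
    eigengap_factor: float = 3.0
    min_module_size: int = 5
    max_module_size: int = 800
    de_alpha: float = 0.01
    rng_seed: int = 0
    linkage: str = "complete"
    distance: str = "spearman"
    rank_mode: str = "column"
    pooled_quantile: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.quantile_threshold < 1.0):
            raise ValueError("quantile_threshold must be in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.min_module_size > self.max_module_size:
            raise ValueError("min_module_size must be <= max_module_size")
        if not (0.0 < self.de_alpha < 1.0):
            raise ValueError("de_alpha must be in (0, 1)")
        if self.M_override is not None and self.M_override < 1:
            raise ValueError("M_override must be a positive integer")
        if self.eigengap_factor <= 0:
            raise ValueError("eigengap_factor must be positive")
        if self.linkage != "complete":
            raise ValueError("only complete linkage is supported")
        if self.distance != "spearman":
            raise ValueError("only the spearman distance is supported")
        if self.rank_mode not in ("column", "row"):
            raise ValueError("rank_mode must be 'column' or 'row'")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a flat key-value YAML config; keyword arguments override file values.

    Unknown keys are rejected rather than ignored.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "M_search_range" in raw:
        raw["M_search_range"] = tuple(raw["M_search_range"])
    cfg = RunConfig(**raw)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, condition: str = "") -> ExpressionMatrix:
    """Read a TSV expression matrix (rows = genes, header = sample IDs).

    Missing entries (``NA`` or empty cell) become NaN.  Ragged rows, duplicate
    gene IDs and non-numeric cells raise a parse error naming the offending
    line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        ncol = len(sample_ids)
        gene_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol + 1} columns, got {len(parts)}"
                )
            gene = parts[0]
            if gene in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gene!r}")
            seen.add(gene)
            gene_ids.append(gene)
            row = []
            for cell in parts[1:]:
                if cell in MISSING_MARKERS:
                    row.append(math.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric cell {cell!r}"
                        ) from None
            rows.append(row)
    values = np.array(rows, dtype=float).reshape(len(gene_ids), ncol)
    return ExpressionMatrix(values, gene_ids, sample_ids, condition=condition)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(expr.sample_ids) + "\n")
        for gene, row in zip(expr.gene_ids, expr.values):
            cells = ["NA" if math.isnan(v) else format(float(v), ".17g") for v in row]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, gene_universe: list[str]) -> CoexpressionNetwork:
    """Read a two-column TSV edge list into a network over *gene_universe*.

    Edges are undirected: duplicate and reversed pairs collapse to one edge.
    Self-loops are dropped with a warning; an edge naming a gene outside the
    universe is an error.
    """
    path = Path(path)
    index = {g: i for i, g in enumerate(gene_universe)}
    n = len(gene_universe)
    adj = np.zeros((n, n), dtype=np.int8)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            a, b = parts
            for g in (a, b):
                if g not in index:
                    raise ValueError(
                        f"{path}:{lineno}: gene {g!r} not in the gene universe"
                    )
            if a == b:
                log.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            adj[index[a], index[b]] = 1
            adj[index[b], index[a]] = 1
    return CoexpressionNetwork(list(gene_universe), adj)


def write_edge_list(net: CoexpressionNetwork, path: str | Path) -> None:
    ii, jj = np.nonzero(np.triu(net.adjacency, k=1))
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{net.gene_ids[i]}\t{net.gene_ids[j]}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping of set name -> member gene IDs."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT rows need name, description and >= 1 member"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# modules + statistics
# ---------------------------------------------------------------------------

def write_modules(
    modules: ModuleSet,
    stats: list[ModuleStatsRecord],
    membership_path: str | Path,
    stats_path: str | Path,
) -> None:
    """Serialize a ModuleSet and its statistics to two TSVs.

    Membership rows carry per-network presence flags (derived from the label
    vectors when present, else 1/1).  Densities are written at full precision;
    round-tripping through :func:`read_modules` recovers the gene sets.
    """
    if len(stats) != len(modules.modules):
        raise ValueError(
            f"{len(stats)} stats records for {len(modules.modules)} modules"
        )
    for i, rec in enumerate(stats):
        if rec.module_id != i + 1:
            raise ValueError(
                f"stats record {i} has module_id {rec.module_id}, expected {i + 1}"
            )
    idx = {g: k for k, g in enumerate(modules.gene_ids)}
    with open(membership_path, "w") as fh:
        fh.write("module\tgene\tin_net_a\tin_net_b\n")
        for m, genes in enumerate(modules.modules, start=1):
            for g in genes:
                if modules.labels_a is not None and modules.labels_b is not None:
                    ia = int(modules.labels_a[idx[g]] == m) if g in idx else 0
                    ib = int(modules.labels_b[idx[g]] == m) if g in idx else 0
                    # a gene can sit in a module only through one network's label,
                    # or through neither after connectivity splitting renumbers
                    if ia == 0 and ib == 0:
                        ia = ib = 1
                else:
                    ia = ib = 1
                fh.write(f"{m}\t{g}\t{ia}\t{ib}\n")
    with open(stats_path, "w") as fh:
        fh.write(
            "module\tsize\tavg_degree_a\tavg_degree_b\tdensity_a\tdensity_b\tp_value\n"
        )
        for rec in stats:
            nums = "\t".join(
                format(float(x), ".17g")
                for x in (
                    rec.avg_degree_a,
                    rec.avg_degree_b,
                    rec.density_a,
                    rec.density_b,
                    rec.p_value,
                )
            )
            fh.write(f"{rec.module_id}\t{rec.size}\t{nums}\n")


def read_modules(membership_path: str | Path) -> ModuleSet:
    """Read a membership TSV back into a ModuleSet (gene sets only; the label
    vectors are not recoverable from the serialized form)."""
    by_module: dict[int, list[str]] = {}
    genes_seen: list[str] = []
    seen: set[str] = set()
    with open(membership_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["module", "gene"]:
            raise ValueError(f"{membership_path}: not a module membership file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{membership_path}:{lineno}: ragged row")
            m = int(parts[0])
            g = parts[1]
            by_module.setdefault(m, []).append(g)
            if g not in seen:
                seen.add(g)
                genes_seen.append(g)
    modules = [by_module[m] for m in sorted(by_module)]
    return ModuleSet(gene_ids=genes_seen, modules=modules, provenance=["read"])
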