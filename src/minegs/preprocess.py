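"""Pre-modeling filters: expression floor, variance, edge sign, isolation, miRNA sparsity.

The pipeline order follows the original study design: genes whose mean
expression is below the detection floor are dropped first, then genes with
near-constant profiles, then network edges whose expression correlation is
not positive, then genes left without any interaction, and finally sparsely
characterised microRNAs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import BindingMatrix, ExpressionDataset, GeneNetwork

__all__ = [
    "FilterReport",
    "filter_unexpressed",
    "filter_low_variance",
    "filter_sparse_mirnas",
    "filter_negative_edges",
    "drop_isolated_genes",
    "preprocess_pipeline",
]


@dataclass
class FilterReport:
    """Record of one filtering stage: what was removed and how much survived."""

    stage: str
    removed: list[str] = field(default_factory=list)
    kept: int = 0
    notes: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def summary(self) -> dict:
        return {"stage": self.stage, "removed": self.n_removed, "kept": self.kept, **self.notes}


def write_reports(reports: list[FilterReport], tsv_path: str | Path, json_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        for rep in reports:
            for item in rep.removed:
                fh.write(f"{rep.stage}\t{item}\n")
    with open(json_path, "w") as fh:
        json.dump([rep.summary() for rep in reports], fh, indent=2)


def filter_unexpressed(
    expr: ExpressionDataset, floor: float = 100.0
) -> tuple[ExpressionDataset, FilterReport]:
    """Drop genes whose across-sample mean expression is below ``floor``.

    The default floor of 100 intensity units marks a gene as unexpressed on
    the original array platform; the comparison is strict (mean == floor kept).
    """
    means = expr.values.mean(axis=1)
    removed = [g for g, mu in zip(expr.gene_ids, means) if mu < floor]
    kept = [g for g in expr.gene_ids if g not in set(removed)]
    report = FilterReport("unexpressed", removed, kept=len(kept), notes={"floor": floor})
    return expr.subset_genes(kept), report


def filter_low_variance(
    expr: ExpressionDataset, min_sd: float = 0.2
) -> tuple[ExpressionDataset, FilterReport]:
    """Drop genes whose sample standard deviation (n−1 denominator) is below ``min_sd``."""
    if expr.n_samples < 2:
        raise ValueError("standard deviation requires at least 2 samples")
    sds = expr.values.std(axis=1, ddof=1)
    removed = [g for g, sd in zip(expr.gene_ids, sds) if sd < min_sd]
    kept = [g for g in expr.gene_ids if g not in set(removed)]
    report = FilterReport("low_variance", removed, kept=len(kept), notes={"min_sd": min_sd})
    return expr.subset_genes(kept), report


def filter_sparse_mirnas(
    binding: BindingMatrix, min_targets: int = 100
) -> tuple[BindingMatrix, FilterReport]:
    """Drop microRNA columns with fewer than ``min_targets`` target genes.

    Sparsely characterised microRNAs are taken as under-studied rather than
    selective; the comparison is strict (< min_targets removed).
    """
    sums = binding.Z.sum(axis=0)
    removed = [m for m, s in zip(binding.mirna_ids, sums) if s < min_targets]
    out = binding.drop_mirnas(removed)
    report = FilterReport(
        "sparse_mirnas", removed, kept=len(out.mirna_ids), notes={"min_targets": min_targets}
    )
    return out, report


def filter_negative_edges(
    network: GeneNetwork, expr: ExpressionDataset
) -> tuple[GeneNetwork, FilterReport]:
    """Remove network edges whose expression Pearson correlation is <= 0.

    Zero correlations are removed along with negative ones: a zero-weight
    edge would carry no diffusion mass and only add degenerate structure.
    Edges with a constant-expression endpoint (correlation undefined) are
    removed and reported separately.
    """
    gidx = expr.gene_index()
    missing = [g for e in network.edges for g in e if g not in gidx]
    if missing:
        raise ValueError(f"network gene(s) missing from expression data: {sorted(set(missing))[:5]}")
    X = expr.values
    sd = X.std(axis=1, ddof=1)
    removed: list[str] = []
    undefined = 0
    drop: list[tuple[str, str]] = []
    for a, b in sorted(network.edges):
        i, j = gidx[a], gidx[b]
        if sd[i] == 0 or sd[j] == 0:
            drop.append((a, b))
            removed.append(f"{a}--{b}")
            undefined += 1
            continue
        pcc = float(np.corrcoef(X[i], X[j])[0, 1])
        if pcc <= 0:
            drop.append((a, b))
            removed.append(f"{a}--{b}")
    out = network.drop_edges(drop)
    report = FilterReport(
        "negative_edges", removed, kept=out.n_edges, notes={"undefined_correlation": undefined}
    )
    return out, report


def drop_isolated_genes(
    expr: ExpressionDataset, network: GeneNetwork, binding: BindingMatrix
) -> tuple[ExpressionDataset, GeneNetwork, BindingMatrix, FilterReport]:
    """Remove genes with zero remaining network edges from all three structures."""
    deg = network.degree()
    kept = [g for g in network.gene_ids if deg.get(g, 0) > 0]
    removed = [g for g in network.gene_ids if g not in set(kept)]
    if not kept:
        raise ValueError("all genes are isolated after edge filtering")
    expr2 = expr.subset_genes(kept)
    net2 = network.subset_genes(kept)
    bind2 = binding.restrict_genes(tuple(expr2.gene_ids))
    net2 = GeneNetwork(tuple(expr2.gene_ids), net2.edges, net2.weights)
    report = FilterReport("isolated_genes", removed, kept=len(kept))
    return expr2, net2, bind2, report


def preprocess_pipeline(
    expr: ExpressionDataset,
    binding: BindingMatrix,
    network: GeneNetwork,
    floor: float = 100.0,
    min_sd: float = 0.2,
    min_targets: int = 100,
    log2: bool = False,
) -> tuple[ExpressionDataset, BindingMatrix, GeneNetwork, list[FilterReport]]:
    """Apply all filters in order and realign the three inputs.

    ``log2`` optionally log2(1+x)-transforms intensities after the
    expression-floor filter (the floor itself is always applied on the raw
    scale); the variance filter then acts on the transformed values.
    """
    reports: list[FilterReport] = []
    expr, rep = filter_unexpressed(expr, floor=floor)
    reports.append(rep)
    if log2:
        expr = ExpressionDataset(
            expr.gene_ids, expr.sample_ids, np.log2(1.0 + expr.values), expr.labels
        )
    expr, rep = filter_low_variance(expr, min_sd=min_sd)
    reports.append(rep)
    if expr.n_genes == 0:
        raise ValueError("no genes survive the expression filters")
    network = network.subset_genes(expr.gene_ids)
    network = GeneNetwork(tuple(expr.gene_ids), network.edges, network.weights)
    network, rep = filter_negative_edges(network, expr)
    reports.append(rep)
    expr, network, binding, rep = drop_isolated_genes(expr, network, binding)
    reports.append(rep)
    binding, rep = filter_sparse_mirnas(binding, min_targets=min_targets)
    reports.append(rep)
    return expr, binding, network, reports
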