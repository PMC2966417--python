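"""Readers and writers for the external text formats, plus ID-space alignment.

Formats
-------
Expression: TSV, genes in rows, samples in columns; labels as a sidecar
two-column TSV (sample, class) or a designated label row inside the matrix.
Network: 2- or 3-column (scored) edge TSV.  microRNA targets: 2-column
(miRNA, gene) TSV, union semantics across files.  Gene sets: GMT.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import BindingMatrix, ExpressionDataset, GeneNetwork, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_mirna_targets",
    "write_mirna_targets",
    "read_network_edges",
    "write_network_edges",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_gene_list",
    "write_gene_list",
    "align_inputs",
]


def read_expression(
    path: str | Path,
    label_file: str | Path | None = None,
    label_row: str | None = None,
) -> ExpressionDataset:
    """Read a gene × sample TSV with a header of sample IDs and gene IDs in column 1.

    Labels come either from ``label_file`` (two-column TSV: sample, class) or
    from ``label_row`` (the name of a row inside the matrix holding the class
    of each sample); exactly one must be given.
    """
    if (label_file is None) == (label_row is None):
        raise ValueError("provide exactly one of label_file or label_row")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty data section")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")

    if label_row is not None:
        if label_row not in df.index:
            raise ValueError(f"{path}: label row {label_row!r} not found")
        labels = tuple(df.loc[label_row])
        df = df.drop(index=label_row)
        if df.shape[0] == 0:
            raise ValueError(f"{path}: empty data section after removing label row")
    else:
        lab = pd.read_csv(label_file, sep="\t", header=None, dtype=str)
        if lab.shape[1] < 2:
            raise ValueError(f"{label_file}: expected two columns (sample, class)")
        mapping = dict(zip(lab[0], lab[1]))
        missing = [s for s in df.columns if s not in mapping]
        if missing:
            raise ValueError(f"{label_file}: no label for sample(s) {missing}")
        labels = tuple(mapping[s] for s in df.columns)

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} at gene {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
    return ExpressionDataset(tuple(df.index), tuple(df.columns), values, labels)


def write_expression(
    dataset: ExpressionDataset, path: str | Path, label_file: str | Path
) -> None:
    df = pd.DataFrame(dataset.values, index=list(dataset.gene_ids), columns=list(dataset.sample_ids))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    pd.DataFrame({"sample": list(dataset.sample_ids), "class": list(dataset.labels)}).to_csv(
        label_file, sep="\t", header=False, index=False
    )


def read_mirna_targets(
    paths: str | Path | Sequence[str | Path], all_gene_ids: Sequence[str]
) -> BindingMatrix:
    """Build the binary binding matrix Z from one or more (miRNA, gene) pair files.

    A pair present in any file sets ``z = 1`` (union semantics: a binding is
    accepted when supported by experimental evidence or by either prediction
    source).  Genes in ``all_gene_ids`` never mentioned get all-zero rows.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    pairs: set[tuple[str, str]] = set()
    for path in paths:
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2 or not fields[0] or not fields[1]:
                    raise ValueError(f"{path}:{ln}: malformed target pair {line!r}")
                pairs.add((fields[0], fields[1]))
    mirna_ids = tuple(sorted({m for m, _ in pairs}))
    gene_ids = tuple(all_gene_ids)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    midx = {m: q for q, m in enumerate(mirna_ids)}
    Z = np.zeros((len(gene_ids), len(mirna_ids)), dtype=np.uint8)
    for m, g in pairs:
        if g in gidx:
            Z[gidx[g], midx[m]] = 1
    return BindingMatrix(gene_ids, mirna_ids, Z)


def write_mirna_targets(binding: BindingMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        rows, cols = np.nonzero(binding.Z)
        for i, q in zip(rows, cols):
            fh.write(f"{binding.mirna_ids[q]}\t{binding.gene_ids[i]}\n")


def read_network_edges(
    path: str | Path, all_gene_ids: Sequence[str]
) -> GeneNetwork:
    """Read an undirected edge list (2 columns, optional third score column).

    Edges are deduplicated, self-loops dropped, and edges touching genes
    outside ``all_gene_ids`` are dropped with a logged warning (real
    interaction-database exports always contain out-of-universe IDs).
    """
    gene_ids = tuple(all_gene_ids)
    universe = set(gene_ids)
    edges: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    any_weight = False
    n_outside = n_loops = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{ln}: malformed edge line {line!r}")
            a, b = fields[0], fields[1]
            if a == b:
                n_loops += 1
                continue
            if a not in universe or b not in universe:
                n_outside += 1
                continue
            e = (a, b) if a <= b else (b, a)
            edges.add(e)
            if len(fields) >= 3 and fields[2] != "":
                try:
                    weights[e] = float(fields[2])
                except ValueError:
                    raise ValueError(f"{path}:{ln}: non-numeric edge score {fields[2]!r}") from None
                any_weight = True
    if n_outside:
        logger.warning("%s: dropped %d edge(s) with endpoints outside the gene universe", path, n_outside)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return GeneNetwork(gene_ids, frozenset(edges), weights if any_weight else None)


def write_network_edges(network: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            if network.weights is not None and (a, b) in network.weights:
                fh.write(f"{a}\t{b}\t{network.weights[(a, b)]:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name TAB description TAB member1 TAB member2 ..."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >=3 fields, got {len(fields)}")
            name, source = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            if name in coll:
                raise ValueError(f"{path}:{ln}: duplicate gene set name {name!r}")
            coll.add(name, members, source=source)
    return coll


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (source, members) in collection.sets.items():
            fh.write("\t".join([name, source or "na", *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line (e.g., a hallmark gene list); blank lines skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                out.append(g)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def align_inputs(
    expr: ExpressionDataset,
    binding: BindingMatrix,
    network: GeneNetwork,
) -> tuple[ExpressionDataset, BindingMatrix, GeneNetwork]:
    """Restrict all three inputs to the shared analysis universe, same order.

    The universe is the set of genes present in the expression data AND
    carrying at least one network edge; genes absent from the binding data
    stay in the universe with all-zero binding rows (non-microRNA-bound genes
    are first-class citizens of the model).  Idempotent.
    """
    connected = {g for e in network.edges for g in e}
    universe = [g for g in expr.gene_ids if g in connected]
    if not universe:
        raise ValueError("empty gene universe: no expression gene has a network edge")
    expr2 = expr.subset_genes(universe)
    uset = set(universe)
    edges = frozenset(e for e in network.edges if e[0] in uset and e[1] in uset)
    weights = None
    if network.weights is not None:
        weights = {e: w for e, w in network.weights.items() if e in edges}
    net2 = GeneNetwork(tuple(universe), edges, weights)
    bind2 = binding.restrict_genes(tuple(universe))
    return expr2, bind2, net2
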