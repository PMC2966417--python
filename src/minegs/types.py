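"""Core in-memory containers shared by every stage of the pipeline.

All gene, sample and microRNA identifiers are opaque, case-sensitive
strings.  The containers validate their own invariants on construction so
that downstream numerical code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ExpressionDataset",
    "BindingMatrix",
    "GeneNetwork",
    "GeneSetCollection",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} ID: {x!r}")
        seen.add(x)


@dataclass
class ExpressionDataset:
    """A gene × sample expression matrix with a binary phenotype label per sample.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers (length ``m``).
    sample_ids
        Ordered unique sample identifiers (length ``n``).
    values
        ``m × n`` real matrix, one row per gene, in the units of the source data.
    labels
        Length-``n`` phenotype classes; at most two distinct values.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.sample_ids = tuple(self.sample_ids)
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")
        n_classes = len(set(self.labels))
        if self.labels and n_classes not in (1, 2):
            raise ValueError(f"labels must take 1 or 2 distinct values, got {n_classes}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index()[gene]]

    def subset_genes(self, keep: Iterable[str]) -> "ExpressionDataset":
        keep_set = set(keep)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep_set]
        return ExpressionDataset(
            tuple(self.gene_ids[i] for i in idx),
            self.sample_ids,
            self.values[idx, :],
            self.labels,
        )

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = list(idx)
        return ExpressionDataset(
            self.gene_ids,
            tuple(self.sample_ids[i] for i in idx),
            self.values[:, idx],
            tuple(self.labels[i] for i in idx),
        )


@dataclass
class BindingMatrix:
    """Binary gene × microRNA binding indicator matrix ``Z``.

    ``Z[i, q] = 1`` means gene ``i`` carries a (verified or predicted) binding
    site for microRNA ``q``.  Genes with an all-zero row are treated as not
    microRNA-regulated; they remain part of the analysis universe.
    """

    gene_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.mirna_ids = tuple(self.mirna_ids)
        self.Z = np.asarray(self.Z)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.mirna_ids, "microRNA")
        if self.Z.shape != (len(self.gene_ids), len(self.mirna_ids)):
            raise ValueError("Z shape does not match ID lists")
        if self.Z.size and not np.isin(self.Z, (0, 1)).all():
            raise ValueError("binding matrix entries must be 0 or 1")
        self.Z = self.Z.astype(np.uint8)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene: str) -> np.ndarray:
        return self.Z[self.gene_index()[gene]]

    def restrict_genes(self, gene_ids: Sequence[str]) -> "BindingMatrix":
        """Re-index to ``gene_ids``; genes never seen get all-zero rows."""
        gene_ids = tuple(gene_ids)
        old = self.gene_index()
        Z = np.zeros((len(gene_ids), len(self.mirna_ids)), dtype=np.uint8)
        for i, g in enumerate(gene_ids):
            if g in old:
                Z[i] = self.Z[old[g]]
        return BindingMatrix(gene_ids, self.mirna_ids, Z)

    def drop_mirnas(self, drop: Iterable[str]) -> "BindingMatrix":
        drop_set = set(drop)
        idx = [q for q, mid in enumerate(self.mirna_ids) if mid not in drop_set]
        return BindingMatrix(
            self.gene_ids,
            tuple(self.mirna_ids[q] for q in idx),
            self.Z[:, idx],
        )


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """Undirected gene interaction graph with optional nonnegative edge scores.

    Self-loops are forbidden; edges are stored as sorted ID pairs so the
    structure is symmetric by construction.
    """

    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    weights: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        universe = set(self.gene_ids)
        normed = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in universe or b not in universe:
                raise ValueError(f"edge endpoint outside gene universe: ({a!r}, {b!r})")
            normed.add(_norm_edge(a, b))
        self.edges = frozenset(normed)
        if self.weights is not None:
            self.weights = {_norm_edge(a, b): float(w) for (a, b), w in self.weights.items()}
            for e, w in self.weights.items():
                if e not in self.edges:
                    raise ValueError(f"weight for unknown edge {e}")
                if w < 0:
                    raise ValueError(f"negative edge weight on {e}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {g: set() for g in self.gene_ids}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degree(self) -> dict[str, int]:
        return {g: len(nb) for g, nb in self.adjacency().items()}

    def subset_genes(self, keep: Iterable[str]) -> "GeneNetwork":
        keep_list = tuple(g for g in self.gene_ids if g in set(keep))
        keep_set = set(keep_list)
        edges = frozenset(e for e in self.edges if e[0] in keep_set and e[1] in keep_set)
        weights = None
        if self.weights is not None:
            weights = {e: w for e, w in self.weights.items() if e in edges}
        return GeneNetwork(keep_list, edges, weights)

    def drop_edges(self, drop: Iterable[tuple[str, str]]) -> "GeneNetwork":
        drop_set = {_norm_edge(a, b) for a, b in drop}
        edges = frozenset(e for e in self.edges if e not in drop_set)
        weights = None
        if self.weights is not None:
            weights = {e: w for e, w in self.weights.items() if e in edges}
        return GeneNetwork(self.gene_ids, edges, weights)


@dataclass
class GeneSetCollection:
    """Named gene sets (annotation categories, pathways) with a source tag each."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, members: Iterable[str], source: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name: {name!r}")
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = (source, members)

    def annotated_genes(self) -> frozenset[str]:
        """All genes carrying at least one annotation in the collection."""
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)
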