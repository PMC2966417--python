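"""Nearest-functional-partner (NFP) selection.

Two rules are provided.  The diffusion rule (MiNeGS/NeGS) takes, for each
gene, the k genes at smallest diffusion distance anywhere in its connected
component — direct or indirect neighbors alike.  The first-order rule (MiGS)
takes the k first-order network neighbors with the largest combined
correlation; genes with fewer than k neighbors get all of them and are
flagged under-filled (downstream analyses may exclude them).  Ties are
broken by lexicographic gene ID for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import EdgeCorrelationTable
from .types import GeneNetwork

__all__ = ["NFPTable", "select_nfps_diffusion", "select_nfps_first_order"]

DEFAULT_K = 3


@dataclass
class NFPTable:
    """Per-gene ordered partner lists with their scores.

    ``scores`` are distances (smaller = closer) for the diffusion rule and
    correlations (larger = closer) for the first-order rule; ``rule`` records
    which.  ``underfilled`` marks genes whose list is shorter than k.
    """

    rule: str
    k: int
    partners: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, plist in self.partners.items():
            if any(p == g for p, _ in plist):
                raise ValueError(f"gene {g!r} listed as its own partner")
            if len(plist) > self.k:
                raise ValueError(f"gene {g!r} has more than k={self.k} partners")

    def partner_ids(self, gene: str) -> list[str]:
        return [p for p, _ in self.partners[gene]]

    def is_underfilled(self, gene: str) -> bool:
        return len(self.partners[gene]) < self.k

    def genes(self) -> list[str]:
        return list(self.partners)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cols = [f"partner_{i + 1}\tscore_{i + 1}" for i in range(self.k)]
            fh.write("gene\trule\t" + "\t".join(cols) + "\tflag_underfilled\n")
            for g in sorted(self.partners):
                cells: list[str] = []
                plist = self.partners[g]
                for i in range(self.k):
                    if i < len(plist):
                        cells.append(f"{plist[i][0]}\t{plist[i][1]:.10g}")
                    else:
                        cells.append("NA\tNA")
                fh.write(f"{g}\t{self.rule}\t" + "\t".join(cells) + f"\t{int(self.is_underfilled(g))}\n")


def select_nfps_diffusion(
    distance_table: np.ndarray,
    gene_ids: tuple[str, ...] | list[str],
    k: int = DEFAULT_K,
) -> NFPTable:
    """For each gene, its k nearest genes by (finite) diffusion distance.

    A gene in a connected component with c members gets min(k, c-1) partners;
    infinite (cross-component) entries are never selected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = np.asarray(distance_table, dtype=float)
    gene_ids = tuple(gene_ids)
    m = len(gene_ids)
    if D.shape != (m, m):
        raise ValueError("distance table shape does not match gene list")
    partners: dict[str, list[tuple[str, float]]] = {}
    for i, g in enumerate(gene_ids):
        cand = [
            (float(D[i, j]), gene_ids[j])
            for j in range(m)
            if j != i and np.isfinite(D[i, j])
        ]
        cand.sort()  # distance asc, then gene ID asc
        partners[g] = [(p, d) for d, p in cand[:k]]
    return NFPTable("diffusion", k, partners)


def select_nfps_first_order(
    network: GeneNetwork,
    correlations: EdgeCorrelationTable,
    k: int = DEFAULT_K,
) -> NFPTable:
    """For each gene, its top-k first-order neighbors by combined correlation."""
    if k < 1:
        raise ValueError("k must be >= 1")
    adj = network.adjacency()
    partners: dict[str, list[tuple[str, float]]] = {}
    for g in network.gene_ids:
        cand = []
        for nb in adj[g]:
            key = (g, nb) if g <= nb else (nb, g)
            cand.append((-correlations.combined[key], nb))
        cand.sort()  # correlation desc, then gene ID asc
        partners[g] = [(p, -negc) for negc, p in cand[:k]]
    return NFPTable("first_order", k, partners)
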