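"""Gene–phenotype ranking: histogram mutual information, NFP-averaged
association (GPA), and the four gene-selection model variants.

The relevance of a single gene to the binary phenotype is the plug-in mutual
information between its (10-bin discretised) expression and the class label,
in bits.  The gene-phenotype association (GPA) of gene i is the average MI
over the gene and its nearest functional partners,

    GPA_i = ( MI_i + sum_{j in NFP(i)} MI_j ) / ( 1 + |NFP(i)| ),

so a gene embedded in a phenotype-relevant module is promoted even when its
own marginal signal is modest.  The variants:

====== ============================= ===========================
model   gene-gene correlation         NFP rule
====== ============================= ===========================
classic (none — genes independent)    (none; GPA = MI)
MiGS    PCC x Jaccard (integrated)    first-order neighbors
NeGS    PCC only                      diffusion distance
MiNeGS  PCC x Jaccard (integrated)    diffusion distance
====== ============================= ===========================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .diffusion import build_weighted_graph, diffusion_embedding, pairwise_diffusion_distances
from .partners import DEFAULT_K, NFPTable, select_nfps_diffusion, select_nfps_first_order
from .similarity import edge_correlations
from .types import BindingMatrix, ExpressionDataset, GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "mutual_information",
    "gene_phenotype_association",
    "rank_genes",
    "run_model",
    "GeneRanking",
    "MODELS",
]

MODELS = ("classic", "MiGS", "NeGS", "MiNeGS")


def mutual_information(x: np.ndarray, y, bins: int = 10) -> float:
    """Plug-in mutual information (bits) between a 10-bin histogram of x and labels y.

    The range [min(x), max(x)] is divided into ``bins`` equal-width bins with
    the maximum assigned to the last bin; cell probabilities are maximum-
    likelihood frequencies and empty cells contribute zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant expression vector: MI undefined under equal-width binning")
    edges = np.linspace(x.min(), x.max(), bins + 1)
    classes = np.unique(y)
    joint = np.zeros((bins, classes.size))
    for c_idx, c in enumerate(classes):
        counts, _ = np.histogram(x[y == c], bins=edges)
        joint[:, c_idx] = counts
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for b in range(bins):
        for c_idx in range(classes.size):
            if p[b, c_idx] > 0:
                mi += p[b, c_idx] * np.log2(p[b, c_idx] / (px[b] * py[c_idx]))
    return float(max(mi, 0.0))


def gene_phenotype_association(
    mi_scores: dict[str, float], nfp_table: NFPTable | None
) -> dict[str, float]:
    """Average MI over each gene and its NFPs; empty lists fall back to own MI."""
    gpa: dict[str, float] = {}
    for g, mi in mi_scores.items():
        if nfp_table is None:
            gpa[g] = mi
            continue
        plist = nfp_table.partners.get(g, [])
        vals = [mi]
        for p, _ in plist:
            if p not in mi_scores:
                raise ValueError(f"NFP {p!r} of {g!r} has no MI score")
            vals.append(mi_scores[p])
        gpa[g] = float(np.mean(vals))
    return gpa


@dataclass
class GeneRanking:
    """Final ranking: per gene, its MI, GPA, and 1-based rank (1 = best)."""

    model: str
    mi: dict[str, float]
    gpa: dict[str, float]
    order: tuple[str, ...]  # gene IDs, best first

    def __post_init__(self) -> None:
        if set(self.order) != set(self.gpa):
            raise ValueError("ranking order must cover exactly the scored genes")

    @property
    def ranks(self) -> dict[str, int]:
        return {g: r + 1 for r, g in enumerate(self.order)}

    def top(self, n: int) -> list[str]:
        if n > len(self.order):
            raise ValueError(f"top_n={n} exceeds the {len(self.order)} ranked genes")
        return list(self.order[:n])

    def write_tsv(self, path, nfp_table: NFPTable | None = None) -> None:
        with open(path, "w") as fh:
            k = nfp_table.k if nfp_table is not None else 0
            nfp_cols = "".join(f"\tNFP{i + 1}" for i in range(k))
            fh.write(f"gene\tmi\tgpa\trank{nfp_cols}\n")
            for r, g in enumerate(self.order, start=1):
                extra = ""
                if nfp_table is not None:
                    ids = nfp_table.partner_ids(g) if g in nfp_table.partners else []
                    extra = "".join(
                        "\t" + (ids[i] if i < len(ids) else "NA") for i in range(k)
                    )
                fh.write(f"{g}\t{self.mi[g]:.10g}\t{self.gpa[g]:.10g}\t{r}{extra}\n")


def rank_genes(gpa: dict[str, float], mi: dict[str, float], model: str) -> GeneRanking:
    """Rank genes by descending GPA; ties broken by lexicographic gene ID."""
    for g, v in gpa.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite GPA for {g!r}")
    order = tuple(sorted(gpa, key=lambda g: (-gpa[g], g)))
    return GeneRanking(model, mi, gpa, order)


def run_model(
    dataset: ExpressionDataset,
    binding: BindingMatrix,
    network: GeneNetwork,
    model: str = "MiNeGS",
    k: int = DEFAULT_K,
    t: int = 1,
    bins: int = 10,
    L: int | str = "auto",
) -> tuple[GeneRanking, NFPTable | None]:
    """Run one gene-selection variant end to end on preprocessed, aligned inputs.

    Expects the edge-sign filter to have been applied (all edge PCCs > 0).
    Integrated-mode edges whose combined correlation is exactly zero (a
    bound/unbound gene pair has Jaccard 0) are dropped before the diffusion
    graph is built; genes isolated by that drop keep empty NFP lists and fall
    back to GPA = MI.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    mi = {
        g: mutual_information(dataset.values[i], np.asarray(dataset.labels), bins=bins)
        for i, g in enumerate(dataset.gene_ids)
    }
    if model == "classic":
        return rank_genes(mi, mi, model), None

    mode = "expression_only" if model == "NeGS" else "integrated"
    corr = edge_correlations(dataset, binding, network, mode=mode)

    if model == "MiGS":
        nfp = select_nfps_first_order(network, corr, k=k)
    else:
        zero_edges = [e for e, c in corr.combined.items() if c <= 0]
        net = network
        if zero_edges:
            logger.info("dropping %d zero-combined-correlation edge(s)", len(zero_edges))
            net = network.drop_edges(zero_edges)
        graph = build_weighted_graph(net, corr)
        emb = diffusion_embedding(graph, t=t, L=L)
        D = pairwise_diffusion_distances(emb)
        nfp = select_nfps_diffusion(D, graph.gene_ids, k=k)
    gpa = gene_phenotype_association(mi, nfp)
    return rank_genes(gpa, mi, model), nfp
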