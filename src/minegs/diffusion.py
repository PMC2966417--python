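"""Diffusion distances and diffusion-map embeddings on a correlation-weighted
gene network.

The correlation-weighted graph defines a random walk whose t-step transition
probabilities aggregate *every* path between two genes, not just the
shortest one.  The diffusion distance at time t compares the t-step
transition distributions of two genes,

    D_t(i, j)^2 = sum_k ( p_t(i, k) - p_t(j, k) )^2 / phi(k),

where phi(k) = d_k / sum(d) is the stationary (normalized-degree) weight of
gene k, which up-weights differences at low-density nodes.  The spectral
shortcut: with W symmetric, the walk operator is conjugate to the symmetric
matrix S = D^{-1/2} W D^{-1/2}; if S = sum_l lambda_l u_l u_l^T with
orthonormal u_l, then the coordinates

    Psi_t(i) = ( lambda_2^t psi_2(i), ..., lambda_L^t psi_L(i) ),
    psi_l(i) = sqrt(sum(d)) * u_l(i) / sqrt(d_i),

reproduce D_t exactly as a Euclidean distance when all m-1 nontrivial
components are kept, and approximate it from below when truncated.  The
trivial component (lambda = 1, psi constant) contributes nothing to any
distance and is excluded.

Conventions: the literature's walk operator is row-stochastic P = D^{-1} W;
the column-stochastic matrix Q = W D^{-1} exposed by :func:`transition_matrix`
is its transpose (W symmetric), and both give identical diffusion distances.
Disconnected graphs are embedded per connected component; the distance
between genes in different components is an infinite sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .similarity import EdgeCorrelationTable
from .types import GeneNetwork

__all__ = [
    "WeightedGraph",
    "DiffusionEmbedding",
    "build_weighted_graph",
    "transition_matrix",
    "diffusion_distance_brute",
    "diffusion_embedding",
    "pairwise_diffusion_distances",
]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix over an ordered gene list."""

    gene_ids: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.W = np.asarray(self.W, dtype=float)
        m = len(self.gene_ids)
        if self.W.shape != (m, m):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")

    @property
    def degrees(self) -> np.ndarray:
        """d_j = sum_i w_ij (row sums equal column sums by symmetry)."""
        return self.W.sum(axis=1)

    def normalized_degrees(self) -> np.ndarray:
        """phi(k) = d_k / sum(d), computed within each connected component."""
        d = self.degrees
        labels = self.component_labels()
        phi = np.zeros_like(d)
        for c in np.unique(labels):
            mask = labels == c
            total = d[mask].sum()
            if total > 0:
                phi[mask] = d[mask] / total
        return phi

    def component_labels(self) -> np.ndarray:
        _, labels = connected_components(self.W > 0, directed=False)
        return labels


def build_weighted_graph(
    network: GeneNetwork, correlations: EdgeCorrelationTable
) -> WeightedGraph:
    """Weight the network's edges with their combined correlations.

    Every retained edge must have a strictly positive combined correlation
    (the edge-sign filter contract); a nonpositive weight raises.
    """
    gene_ids = tuple(network.gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    m = len(gene_ids)
    W = np.zeros((m, m))
    for a, b in network.edges:
        key = (a, b) if a <= b else (b, a)
        if key not in correlations.combined:
            raise ValueError(f"no correlation for edge {key}")
        c = correlations.combined[key]
        if not c > 0:
            raise ValueError(
                f"nonpositive combined correlation {c:g} on retained edge {key}; "
                "apply the edge filters first"
            )
        W[idx[a], idx[b]] = c
        W[idx[b], idx[a]] = c
    return WeightedGraph(gene_ids, W)


def transition_matrix(W: np.ndarray | WeightedGraph) -> np.ndarray:
    """Column-stochastic Markov operator Q = W D^{-1}; each column sums to 1."""
    if isinstance(W, WeightedGraph):
        W = W.W
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=0)
    if np.any(d <= 0):
        bad = int(np.argmin(d))
        raise ValueError(f"zero-degree column {bad}: transition probabilities undefined")
    return W / d[np.newaxis, :]


def _row_stochastic(W: np.ndarray) -> np.ndarray:
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("zero-degree node: random walk undefined")
    return W / d[:, np.newaxis]


def diffusion_distance_brute(
    W: np.ndarray | WeightedGraph, t: int, i: int, j: int
) -> float:
    """Diffusion distance between nodes i and j by explicit matrix powering.

    This is the definitional computation (density-weighted Euclidean distance
    between the t-step transition distributions) and serves as the oracle for
    the spectral embedding.  Nodes in different connected components are at
    infinite distance.
    """
    if isinstance(W, WeightedGraph):
        W = W.W
    W = np.asarray(W, dtype=float)
    if not (isinstance(t, (int, np.integer)) and t >= 1):
        raise ValueError("t must be a positive integer")
    if i == j:
        return 0.0
    _, labels = connected_components(W > 0, directed=False)
    if labels[i] != labels[j]:
        return float("inf")
    mask = labels == labels[i]
    sub = np.flatnonzero(mask)
    Wc = W[np.ix_(sub, sub)]
    pos = {g: a for a, g in enumerate(sub)}
    P = np.linalg.matrix_power(_row_stochastic(Wc), t)
    d = Wc.sum(axis=1)
    phi = d / d.sum()
    diff = P[pos[i]] - P[pos[j]]
    return float(np.sqrt(np.sum(diff**2 / phi)))


@dataclass
class DiffusionEmbedding:
    """Spectral coordinates whose Euclidean geometry carries diffusion distance.

    ``coordinates`` is an m × L matrix; components belonging to different
    connected components occupy disjoint column blocks (rows outside a block's
    component are zero there), so within-component Euclidean distances are
    exact while cross-component pairs are flagged via ``component``.
    """

    gene_ids: tuple[str, ...]
    t: int
    eigenvalues: np.ndarray  # concatenated per component, ordered |lambda| desc
    coordinates: np.ndarray  # m x L
    component: np.ndarray  # component label per gene

    def __post_init__(self) -> None:
        if np.any(np.abs(self.eigenvalues) > 1 + 1e-9):
            raise ValueError("eigenvalues of a stochastic operator must satisfy |lambda| <= 1")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")

    @property
    def n_components_retained(self) -> int:
        return self.coordinates.shape[1]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            L = self.coordinates.shape[1]
            fh.write("gene\t" + "\t".join(f"coord_{l + 1}" for l in range(L)) + "\n")
            for i, g in enumerate(self.gene_ids):
                fh.write(g + "\t" + "\t".join(f"{v:.12g}" for v in self.coordinates[i]) + "\n")


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: first entry of largest magnitude positive."""
    out = U.copy()
    for col in range(out.shape[1]):
        v = out[:, col]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            out[:, col] = -v
    return out


def diffusion_embedding(
    W: np.ndarray | WeightedGraph,
    t: int = 1,
    L: int | str = "auto",
    gene_ids: tuple[str, ...] | None = None,
) -> DiffusionEmbedding:
    """Diffusion-map embedding at time ``t`` retaining ``L`` nontrivial components.

    ``L="auto"`` keeps every component with |lambda_l|^t >= 1e-6 * |lambda_2|^t,
    making truncation error negligible; ``L`` is interpreted per connected
    component (each component of size m_c has at most m_c - 1 nontrivial
    components).  Computed via the symmetric conjugate S = D^{-1/2} W D^{-1/2}
    for numerical stability.
    """
    if isinstance(W, WeightedGraph):
        if gene_ids is None:
            gene_ids = W.gene_ids
        W = W.W
    W = np.asarray(W, dtype=float)
    m = W.shape[0]
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(m))
    if not (isinstance(t, (int, np.integer)) and t >= 1):
        raise ValueError("t must be a positive integer")
    if L != "auto" and not (isinstance(L, (int, np.integer)) and 1 <= L <= m - 1):
        raise ValueError("L must be 'auto' or an integer in [1, m-1]")

    _, labels = connected_components(W > 0, directed=False)
    blocks: list[np.ndarray] = []  # per-component coordinate blocks
    eigs: list[np.ndarray] = []
    widths: list[int] = []
    members: list[np.ndarray] = []
    for c in np.unique(labels):
        sub = np.flatnonzero(labels == c)
        members.append(sub)
        if sub.size == 1:
            # singleton component: walk undefined, no coordinates
            blocks.append(np.zeros((1, 0)))
            eigs.append(np.array([]))
            widths.append(0)
            continue
        Wc = W[np.ix_(sub, sub)]
        d = Wc.sum(axis=1)
        if np.any(d <= 0):
            raise ValueError("zero-degree node inside a component")
        inv_sqrt = 1.0 / np.sqrt(d)
        S = Wc * inv_sqrt[:, None] * inv_sqrt[None, :]
        S = (S + S.T) / 2.0
        lam, U = np.linalg.eigh(S)
        if not np.all(np.isfinite(lam)):
            raise RuntimeError("eigendecomposition did not converge")
        lam = np.clip(lam, -1.0, 1.0)
        # drop the trivial lambda = 1 component (eigenvector ~ sqrt(d), psi constant)
        top = int(np.argmax(lam))
        keep_idx = [k for k in range(lam.size) if k != top]
        order = sorted(keep_idx, key=lambda k: (-abs(lam[k]), -lam[k]))
        lam_nt = lam[order]
        U_nt = _fix_signs(U[:, order])
        if L == "auto":
            if lam_nt.size:
                thresh = 1e-6 * abs(lam_nt[0]) ** t
                n_keep = int(np.sum(np.abs(lam_nt) ** t >= thresh)) if thresh > 0 else 0
                n_keep = max(n_keep, 1) if lam_nt.size else 0
            else:
                n_keep = 0
        else:
            n_keep = min(int(L), lam_nt.size)
        lam_k = lam_nt[:n_keep]
        psi = np.sqrt(d.sum()) * U_nt[:, :n_keep] * inv_sqrt[:, None]
        coords = psi * (lam_k**t)[None, :]
        blocks.append(coords)
        eigs.append(lam_k)
        widths.append(n_keep)

    total_L = int(sum(widths))
    coordinates = np.zeros((m, total_L))
    col = 0
    for sub, block, width in zip(members, blocks, widths):
        coordinates[sub, col : col + width] = block
        col += width
    eigenvalues = np.concatenate(eigs) if eigs else np.array([])
    return DiffusionEmbedding(tuple(gene_ids), int(t), eigenvalues, coordinates, labels)


def pairwise_diffusion_distances(embedding: DiffusionEmbedding) -> np.ndarray:
    """Symmetric m × m Euclidean distance matrix over embedding coordinates.

    Cross-component entries are set to ``inf``; the diagonal is exactly zero.
    """
    X = embedding.coordinates
    sq = np.sum(X**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D2, 0.0, out=D2)
    D = np.sqrt(D2)
    np.fill_diagonal(D, 0.0)
    cross = embedding.component[:, None] != embedding.component[None, :]
    D[cross] = np.inf
    return (D + D.T) / 2.0
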