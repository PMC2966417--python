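"""Evaluation procedures: NFP functional-coordination analysis with
randomization nulls, hallmark-gene recovery, and hypergeometric gene-set
enrichment with Benjamini–Hochberg correction.

Coordination: a gene g with k=3 NFPs is *functionally coordinated* when at
least 3 of the 4 genes {g} ∪ NFP(g) fall into one common annotation set of
at most 200 genes (larger categories are too unspecific to witness
coordination).  The observed coordination rate is compared against two
randomization nulls — uniformly random partner triples, and random triples
drawn from each gene's first-order network neighbors — via a one-sample
t-test of the 100 null rates against the observed rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .partners import NFPTable
from .types import GeneNetwork, GeneSetCollection
from .ranking import GeneRanking

__all__ = [
    "CoordinationResult",
    "EnrichmentRow",
    "coordination_rate",
    "null_coordination",
    "one_sample_ttest",
    "hallmark_recovery",
    "hypergeometric_p",
    "bh_adjust",
    "enrichment_scan",
]


@dataclass
class CoordinationResult:
    evaluable: int
    coordinated: int

    def __post_init__(self) -> None:
        if self.coordinated > self.evaluable:
            raise ValueError("coordinated count exceeds evaluable count")

    @property
    def rate(self) -> float:
        return self.coordinated / self.evaluable if self.evaluable else float("nan")

    def summary(self) -> dict:
        return {"evaluable": self.evaluable, "coordinated": self.coordinated, "rate": self.rate}


def _small_sets(gene_sets: GeneSetCollection, max_set_size: int) -> list[frozenset[str]]:
    return [members for _, members in gene_sets.sets.values() if len(members) <= max_set_size]


def coordination_rate(
    nfp_table: NFPTable,
    gene_sets: GeneSetCollection,
    max_set_size: int = 200,
    min_shared: int = 3,
) -> CoordinationResult:
    """Fraction of evaluable genes whose 4-gene group shares a common small set.

    A gene is evaluable iff its NFP list is full (not under-filled) and the
    gene and every partner carry at least one annotation in the collection;
    it is coordinated iff some single set of size <= ``max_set_size`` contains
    at least ``min_shared`` of the group {g} ∪ NFP(g).
    """
    annotated = gene_sets.annotated_genes()
    small = _small_sets(gene_sets, max_set_size)
    evaluable = coordinated = 0
    for g in nfp_table.genes():
        if nfp_table.is_underfilled(g):
            continue
        group = [g, *nfp_table.partner_ids(g)]
        if any(member not in annotated for member in group):
            continue
        evaluable += 1
        for members in small:
            if sum(member in members for member in group) >= min_shared:
                coordinated += 1
                break
    return CoordinationResult(evaluable, coordinated)


def null_coordination(
    mode: str,
    gene_universe: tuple[str, ...] | list[str],
    network: GeneNetwork | None,
    gene_sets: GeneSetCollection,
    reps: int = 100,
    seed: int = 0,
    k: int = 3,
    max_set_size: int = 200,
    min_shared: int = 3,
) -> np.ndarray:
    """Null distribution of the coordination rate under randomized NFPs.

    ``mode="uniform"``: each gene's partners are k genes sampled without
    replacement from the universe (excluding the gene itself).
    ``mode="network"``: partners are sampled from the gene's first-order
    neighbors; genes with fewer than k neighbors get all of them and are
    flagged under-filled (hence excluded from the rate, as in the observed
    analysis).  Returns one rate per repetition; bit-reproducible under seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mode not in ("uniform", "network"):
        raise ValueError(f"unknown null mode {mode!r}")
    if mode == "network" and network is None:
        raise ValueError("network null requires a network")
    rng = np.random.default_rng(seed)
    universe = list(gene_universe)
    adj = network.adjacency() if network is not None else {}
    rates = np.empty(reps)
    for r in range(reps):
        partners: dict[str, list[tuple[str, float]]] = {}
        for g in universe:
            if mode == "uniform":
                pool = [x for x in universe if x != g]
                picks = rng.choice(len(pool), size=k, replace=False)
                partners[g] = [(pool[i], float("nan")) for i in picks]
            else:
                nbrs = sorted(adj.get(g, ()))
                if len(nbrs) <= k:
                    partners[g] = [(p, float("nan")) for p in nbrs]
                else:
                    picks = rng.choice(len(nbrs), size=k, replace=False)
                    partners[g] = [(nbrs[i], float("nan")) for i in picks]
        table = NFPTable(f"null_{mode}", k, partners)
        rates[r] = coordination_rate(
            table, gene_sets, max_set_size=max_set_size, min_shared=min_shared
        ).rate
    return rates


def one_sample_ttest(null_rates: np.ndarray, observed_rate: float) -> float:
    """Two-sided one-sample t-test p-value of the null rates against the observed rate."""
    null_rates = np.asarray(null_rates, dtype=float)
    if null_rates.size < 2:
        raise ValueError("need at least 2 null rates")
    if np.ptp(null_rates) == 0:
        raise ValueError("zero-variance null distribution: t undefined")
    res = stats.ttest_1samp(null_rates, popmean=observed_rate)
    return float(res.pvalue)


def hallmark_recovery(ranking: GeneRanking, hallmark_ids, top_n: int) -> int:
    """Number of hallmark genes among the top ``top_n`` ranked genes.

    Hallmarks outside the ranked universe are ignored (they were filtered out
    upstream and cannot be recovered).
    """
    universe = set(ranking.order)
    hallmarks = {h for h in hallmark_ids if h in universe}
    top = set(ranking.top(top_n))
    return len(hallmarks & top)


def hypergeometric_p(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= x <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, x={x}")
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


@dataclass
class EnrichmentRow:
    name: str
    N: int  # universe size
    K: int  # set size within universe
    n: int  # selection size
    x: int  # overlap
    p: float
    p_adj: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if self.x > min(self.K, self.n):
            raise ValueError("overlap exceeds set or selection size")


def enrichment_scan(
    selected,
    collection: GeneSetCollection,
    universe,
    min_size: int = 10,
    max_size: int = 200,
    alpha: float = 0.1,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``selected`` in each qualifying set.

    Set sizes K are computed within the analysis universe (the hypergeometric
    population must equal the sampling frame); sets with K outside
    [min_size, max_size] are excluded.  Raw p-values are BH-adjusted across
    all tested sets and flagged significant at adjusted p < ``alpha``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must lie within the universe")
    N, n = len(universe), len(selected)
    rows: list[EnrichmentRow] = []
    for name in collection.names():
        members = collection.members(name) & universe
        K = len(members)
        if K < min_size or K > max_size:
            continue
        x = len(members & selected)
        rows.append(EnrichmentRow(name, N, K, n, x, hypergeometric_p(N, K, n, x)))
    if rows:
        adj = bh_adjust([r.p for r in rows])
        for r, a in zip(rows, adj):
            r.p_adj = float(a)
            r.significant = bool(a < alpha)
    return rows


def write_enrichment_tsv(rows: list[EnrichmentRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("set\tN\tK\tn\tx\tp\tp_adj\tsignificant\n")
        for r in sorted(rows, key=lambda r: (r.p_adj, r.p, r.name)):
            fh.write(
                f"{r.name}\t{r.N}\t{r.K}\t{r.n}\t{r.x}\t{r.p:.6g}\t{r.p_adj:.6g}\t{int(r.significant)}\n"
            )
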