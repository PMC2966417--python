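"""Synthetic data with the statistical structure the model assumes.

The generator emulates the study conditions end to end: a scale-free
background gene network (preferential attachment) with densified wiring
inside a few planted functional modules; two-class expression in which
module genes carry a coordinated mean shift of delta·sigma between classes
on top of independent Gaussian noise; binary microRNA binding in which genes
of one module share a common regulator set with high probability while
background binding is sparse; gene-set annotations consisting of the true
modules plus size-matched random decoys; and a hallmark list equal to the
planted differential genes.  Every artifact can be written in the package's
text formats, so the full pipeline is testable without any download.

The defaults are the shipped study configuration: 300 genes, 20 samples per
class, three modules of 20 genes, delta = 1.5 noise-SD units, sigma = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import networkx as nx
import numpy as np

from .io import (
    write_expression,
    write_gene_list,
    write_gene_sets_gmt,
    write_mirna_targets,
    write_network_edges,
)
from .partners import NFPTable
from .ranking import GeneRanking
from .types import BindingMatrix, ExpressionDataset, GeneNetwork, GeneSetCollection

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "recovery_report", "write_bundle"]


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the shipped study conditions."""

    m: int = 300  # genes
    n_per_class: int = 20  # samples per phenotype class
    n_modules: int = 3
    module_size: int = 20
    delta: float = 1.5  # between-class mean shift, in units of sigma
    sigma: float = 1.0  # i.i.d. Gaussian noise SD
    baseline: float = 1000.0  # baseline intensity (clears the expression floor)
    ba_attachment: int = 2  # preferential-attachment edges per new node
    module_density: float = 0.3  # extra intra-module wiring probability
    n_mirnas: int = 60
    regulators_per_module: int = 10
    sharing_prob: float = 0.8  # P(module gene bound by each module regulator)
    background_binding: float = 0.05  # P(any gene bound by each non-regulator miRNA)
    n_decoy_sets: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.m:
            raise ValueError("modules do not fit into the gene universe")
        for p in (self.module_density, self.sharing_prob, self.background_binding):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.n_modules * self.regulators_per_module > self.n_mirnas:
            raise ValueError("not enough microRNAs for disjoint module regulator sets")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    modules: dict[str, list[str]]  # module name -> member genes
    differential: dict[str, bool]  # gene -> truly class-shifted?
    regulators: dict[str, list[str]]  # module name -> regulator miRNAs

    def module_of(self) -> dict[str, str]:
        out = {}
        for name, members in self.modules.items():
            for g in members:
                out[g] = name
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "modules": self.modules,
                "differential": self.differential,
                "regulators": self.regulators,
            },
            indent=2,
        )


def generate(
    config: SyntheticConfig,
) -> tuple[
    ExpressionDataset, GeneNetwork, BindingMatrix, GeneSetCollection, list[str], SyntheticTruth
]:
    """Generate one synthetic study; bit-reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    m = config.m
    gene_ids = tuple(f"g{i:04d}" for i in range(m))

    # --- network: preferential attachment + densified modules -------------
    G = nx.barabasi_albert_graph(m, config.ba_attachment, seed=int(rng.integers(2**31)))
    module_genes = rng.choice(m, size=config.n_modules * config.module_size, replace=False)
    modules: dict[str, list[str]] = {}
    module_idx: dict[str, np.ndarray] = {}
    for mod in range(config.n_modules):
        idx = np.sort(
            module_genes[mod * config.module_size : (mod + 1) * config.module_size]
        )
        name = f"module_{mod + 1}"
        module_idx[name] = idx
        modules[name] = [gene_ids[i] for i in idx]
        for a_pos in range(idx.size):
            for b_pos in range(a_pos + 1, idx.size):
                if rng.random() < config.module_density:
                    G.add_edge(int(idx[a_pos]), int(idx[b_pos]))
    edges = frozenset(
        (gene_ids[min(a, b)], gene_ids[max(a, b)]) for a, b in G.edges() if a != b
    )
    network = GeneNetwork(gene_ids, edges)

    # --- expression: class shift on module genes + Gaussian noise ----------
    n = 2 * config.n_per_class
    labels = tuple(["A"] * config.n_per_class + ["B"] * config.n_per_class)
    sample_ids = tuple(f"s{j:03d}" for j in range(n))
    values = config.baseline + config.sigma * rng.standard_normal((m, n))
    is_b = np.array([lab == "B" for lab in labels])
    differential = {g: False for g in gene_ids}
    if config.delta > 0:
        for idx in module_idx.values():
            values[np.ix_(idx, np.flatnonzero(is_b))] += config.delta * config.sigma
            for i in idx:
                differential[gene_ids[i]] = True
    expr = ExpressionDataset(gene_ids, sample_ids, values, labels)

    # --- binding: disjoint module regulator sets + sparse background -------
    mirna_ids = tuple(f"mir{q:03d}" for q in range(config.n_mirnas))
    perm = rng.permutation(config.n_mirnas)
    regulators: dict[str, list[str]] = {}
    Z = (rng.random((m, config.n_mirnas)) < config.background_binding).astype(np.uint8)
    for mod, name in enumerate(modules):
        regs = np.sort(
            perm[mod * config.regulators_per_module : (mod + 1) * config.regulators_per_module]
        )
        regulators[name] = [mirna_ids[q] for q in regs]
        idx = module_idx[name]
        hit = rng.random((idx.size, regs.size)) < config.sharing_prob
        Z[np.ix_(idx, regs)] = hit.astype(np.uint8)
        # module regulators stay specific: wipe background binding elsewhere
        others = np.setdiff1d(np.arange(m), idx)
        Z[np.ix_(others, regs)] = 0
    binding = BindingMatrix(gene_ids, mirna_ids, Z)

    # --- gene sets: true modules + size-matched random decoys --------------
    collection = GeneSetCollection()
    for name, members in modules.items():
        collection.add(name, members, source="truth")
    for d in range(config.n_decoy_sets):
        picks = rng.choice(m, size=config.module_size, replace=False)
        collection.add(f"decoy_{d + 1}", [gene_ids[i] for i in np.sort(picks)], source="decoy")

    hallmarks = [g for g in gene_ids if differential[g]]
    truth = SyntheticTruth(modules, differential, regulators)
    return expr, network, binding, collection, hallmarks, truth


def recovery_report(
    truth: SyntheticTruth,
    ranking: GeneRanking,
    nfp_table: NFPTable | None,
    top_n: int,
) -> dict:
    """Score a pipeline run against the planted truth.

    Reports the fraction of planted differential genes found among the top
    ``top_n`` ranked genes and, when an NFP table is given, the fraction of
    partner assignments of module genes that stay within the gene's own
    module (the synthetic analogue of the functional-coordination rate).
    """
    planted = [g for g, flag in truth.differential.items() if flag]
    top = set(ranking.top(top_n))
    recovered = sum(g in top for g in planted)
    out = {
        "top_n": top_n,
        "planted": len(planted),
        "recovered": recovered,
        "recovery": recovered / len(planted) if planted else float("nan"),
    }
    if nfp_table is not None:
        mod_of = truth.module_of()
        intra = total = 0
        for g in nfp_table.genes():
            if g not in mod_of:
                continue
            for p in nfp_table.partner_ids(g):
                total += 1
                intra += int(mod_of.get(p) == mod_of[g])
        out["nfp_assignments"] = total
        out["intra_module_nfp_fraction"] = intra / total if total else float("nan")
    return out


def write_bundle(
    outdir: str | Path,
    expr: ExpressionDataset,
    network: GeneNetwork,
    binding: BindingMatrix,
    collection: GeneSetCollection,
    hallmarks: list[str],
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the six artifacts of one synthetic study in the package formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "network": outdir / "network.tsv",
        "targets": outdir / "mirna_targets.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "hallmarks": outdir / "hallmarks.txt",
        "truth": outdir / "truth.json",
    }
    write_expression(expr, paths["expression"], paths["labels"])
    write_network_edges(network, paths["network"])
    write_mirna_targets(binding, paths["targets"])
    write_gene_sets_gmt(collection, paths["gene_sets"])
    write_gene_list(hallmarks, paths["hallmarks"])
    paths["truth"].write_text(truth.to_json())
    return paths
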