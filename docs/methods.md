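# Methods

This note documents the model as implemented, the defaults and why, the
numerical choices, what the synthetic generator does and does not emulate,
and the known limitations.

## Pipeline and assumptions

The pipeline consumes a gene × sample expression matrix with binary
phenotype labels, a binary gene × microRNA binding matrix *Z*, and an
undirected gene interaction network, all reduced to a common analysis
universe: genes present in the expression data that carry at least one
network edge. Genes without any binding evidence stay in the universe with
all-zero rows of *Z* — being free of microRNA regulation is information,
not missingness.

Preprocessing applies, in order: an expression floor (drop genes with mean
intensity < 100, the detection floor of the original array platform; strict
inequality), a variance filter (sample SD < 0.2, n−1 denominator; strict),
removal of network edges whose expression Pearson correlation is ≤ 0,
removal of genes left without edges, and removal of microRNAs with fewer
than 100 targets (under-studied rather than selective). The floor always
acts on the raw intensity scale; an optional log2(1+x) transform, applied
after the floor and before the variance filter, is exposed because the
appropriate scale for the SD threshold depends on how the input was
normalized upstream. Zero correlations are removed along with negative
ones: a zero-weight edge carries no diffusion mass and only contributes
degenerate graph structure.

## Integrated correlation

Edge weight *C*ᵢⱼ = *PCC*ᵢⱼ · *J*ᵢⱼ. The Jaccard factor uses the
conventions *J* = 1 when both binding rows are all-zero and *J* = 0 when
exactly one is; these are modeling choices, not the common
"undefined" convention — two unregulated genes face identical (absent)
post-transcriptional pressure, while a regulated/unregulated pair does not.
Correlations are evaluated on network edges only (they are consumed solely
as edge weights), keeping cost O(|E|·n).

A consequence the upstream filters do not prevent: a sign-filtered edge can
still have *C* = 0 when it joins a bound and an unbound gene. Such edges
are dropped before the diffusion graph is built; a gene isolated by that
drop becomes a singleton component with an empty partner list and falls
back to GPA = MI. This is the one place the implementation departs from the
idealization that the weighted graph is strictly positive on every network
edge.

## Diffusion distance and embedding

With symmetric weights *W* and degrees *d*ⱼ = Σᵢ *w*ᵢⱼ, the column-
stochastic operator is *Q* = *W D*⁻¹; its transpose is the row-stochastic
random-walk operator *P* = *D*⁻¹*W* of the diffusion-maps literature, and
both yield the same distances, so the implementation works with *P*
internally and asserts the column-sum-1 property on *Q*. The distance at
integer time *t* ≥ 1 is

D_t(i,j)² = Σₖ (p_t(i,k) − p_t(j,k))² / φ(k),  φ(k) = d_k / Σ d,

with φ computed within each connected component (so it sums to 1 on the
component containing the compared pair). Dividing by φ emphasizes
low-density nodes and prevents hubs from dominating the metric.

The spectral route: *P* is conjugate to the symmetric
*S* = *D*^(−1/2) *W D*^(−1/2), whose orthonormal eigenpairs (λ_l, u_l)
give stationary-normalized eigenvectors ψ_l = √(Σd) · *D*^(−1/2) u_l
(Σₖ φ(k) ψ_l(k)² = 1). Euclidean distance between the coordinate rows
Ψ_t(i) = (λ₂ᵗψ₂(i), …) reproduces D_t *exactly* when all m−1 nontrivial
components are retained, and from below when truncated. The trivial pair
(λ₁ = 1, ψ₁ constant) contributes nothing to any distance and is excluded.
The definitional matrix-power computation is kept as an independent oracle;
the test suite checks the two routes agree to < 1e−8 on random connected
graphs of up to 25 nodes at t ∈ {1, 2, 3}.

Numerical choices: eigendecomposition of the symmetrized *S* (stable, real
spectrum in [−1, 1], clipped against rounding); deterministic eigenvector
signs (first non-negligible entry positive) for reproducible serialization;
negative eigenvalues retained (integer powers are well defined and enter
distances through squares); disconnected graphs embedded per component with
an infinite-distance sentinel across components. Defaults: t = 1 (the
smallest power already mixes all paths through the spectral sum; the
original description leaves t unspecified, so it is exposed as a
parameter), L = "auto" retaining every component with |λ_l|ᵗ ≥ 1e−6·|λ₂|ᵗ,
making truncation error negligible.

A structural fact worth knowing: a degree-1 gene's transition row is the
point mass on its only neighbor, so two leaves hanging off the same node
are at identical diffusion distance from it at every t, whatever the edge
weights. Ties like this are resolved by the deterministic lexicographic
gene-ID tie-break.

## Partners and ranking

k = 3 partners per gene by default — small enough that partners plausibly
share one pathway, large enough to exploit the network. The first-order
rule (MiGS) cannot serve genes with fewer than k neighbors; it returns the
partial list with an under-filled flag, and the coordination evaluation
excludes such genes while the ranking still uses the partial average. The
diffusion rule serves every gene whose component has more than k members.

Mutual information uses the plug-in joint-histogram estimator with 10
equal-width bins over each gene's observed [min, max] (the top bin closed
on the right), log base 2. The base is a unit choice that cannot affect any
ranking; per-gene binning is the natural reading of discretising "the space
of xᵢ". No bias correction is applied — the plug-in estimator's upward
bias is shared by all genes with the same marginal support and largely
cancels in ranking. GPA is the arithmetic mean of MI over the gene and its
partners; ranking is by descending GPA with lexicographic tie-break.

## Evaluation procedures

Coordination: a gene with a full partner list is evaluable when all four
group members carry at least one annotation; it is coordinated when a
single annotation set of ≤ 200 genes contains ≥ 3 of the four. Sets larger
than 200 genes are too unspecific to witness coordination. Two nulls are
provided (uniform partner triples; triples from first-order neighbors),
100 repetitions each, compared by a two-sided one-sample t-test of the null
rates against the observed rate (the reported p-values are extreme enough
that sidedness is immaterial).

Enrichment: hypergeometric upper tail per set with the population equal to
the analysis universe (set sizes K are computed within the universe — the
sampling frame and the population must coincide), sets with K outside
[10, 200] excluded, BH correction across all tested sets, significance at
adjusted p < 0.1.

Cross-validation: stratified folds (default 6, matching 35 samples split
6/6/6/6/6/5 with per-fold class balance within one), 20 repeats, gene
selection rerun inside each training fold — the selection step receives
only the training partition by construction, which is what the leakage
audit test verifies at the interface level. Held-out scores are pooled
across folds within a repeat before one AUC is computed (rather than
averaging per-fold AUCs of 5–6 samples each), then averaged over repeats.
Classifiers sit behind a fit/score contract; the bundled ones wrap standard
implementations — an RBF-kernel SVM and a single-hidden-layer network with
⌊√J⌋ hidden units — each preceded by feature standardization, with library
defaults for the remaining hyperparameters (recorded as this package's
choice; no tuning is performed).

## Synthetic data

The generator emulates the premises the model relies on: a scale-free
background network (Barabási–Albert preferential attachment, 2 edges per
new node), three planted 20-gene modules with extra intra-module wiring
(density 0.3), expression 1000 + δ·σ·1[class B, module gene] + N(0, σ²)
with δ = 1.5 and σ = 1 over 20 samples per class, disjoint 10-microRNA
regulator sets per module bound with probability 0.8 against a 0.05
background rate over 60 microRNAs, annotation sets equal to the true
modules plus 20 size-matched random decoys, and a hallmark list equal to
the planted differential genes. The baseline of 1000 clears the expression
floor so the platform-specific filters pass through cleanly at this scale;
the microRNA-sparsity threshold, defined for genome-scale binding tables,
is scaled to ≥ 1 target when the pipeline runs on these 300-gene studies.

What it does not emulate: array-specific noise (probe effects, intensity-
dependent variance), realistic interaction-database topology beyond the
heavy-tailed degree distribution, overlapping modules, correlated
background genes, or partial/incorrect annotation. Passing tests therefore
demonstrate that the implementation does what the model says under the
model's own assumptions — not that the model's advantages transfer to any
particular real dataset.

Within-module expression correlation here arises purely from the shared
class shift (pooled-sample correlation ≈ δ²/4 / (1 + δ²/4) ≈ 0.36 at
δ = 1.5), which is what survives the edge-sign filter on module edges while
roughly half of background edges are removed.

## Known limitations

- Gene identifiers are opaque case-sensitive strings; no symbol mapping or
  probe collapsing is attempted.
- The diffusion machinery materialises dense m × m matrices; fine for the
  few-thousand-gene universes the model targets, not for genome-scale
  graphs without sparse eigensolvers.
- The MI estimator requires non-constant expression (guaranteed by the
  variance filter) and at least a handful of samples per class to be
  informative.
- Cross-validated runs recompute the full diffusion pipeline per fold and
  repeat; cost grows as n_folds × n_repeats × (model run), so large grids
  call for modest repeat counts.
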