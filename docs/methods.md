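# Methods

This note documents the statistical model behind `cofunnet`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions used throughout.

## Evidence scores

Each evidence layer maps observations to a raw pairwise score that needs
only to be *monotone* in evidence strength — calibration (below) re-maps
every layer onto a common likelihood scale, so the raw units never mix.

| Code | Observation | Raw score |
|------|-------------|-----------|
| CX | gene × sample expression | Pearson correlation of profiles |
| CC | gene → citing documents | −log₁₀ hypergeometric upper tail of the document overlap, given each gene's document count and the corpus size |
| DC | gene → protein domains | same statistic over shared domains in the domain universe |
| PG | gene × genome presence/absence | mutual information (bits) of the binary profiles across reference genomes |
| GN | ortholog positions per reference genome | fraction of co-present genomes in which the orthologs lie within `window` positions (default 1 = adjacency) |
| XFER | a network in another species | source edge weight copied to every cross-product of the endpoints' orthologs (self-pairs excluded, duplicates keep the max) |
| HT / LC | protein-interaction edge lists | imported as-is; nothing to infer |

Conventions: zero-variance genes are excluded from CX and negative
correlations retained (calibration decides their worth); zero-overlap
pairs are omitted from CC/DC; constant profiles are excluded from PG
(their marginal entropy is zero, so MI is undefined as association
evidence); GN pairs co-present in fewer than two genomes are unscored
(one genome cannot separate conservation from coincidence).  Hypergeometric
tails are clipped into (0, 1] before the log so extreme overlaps stay
finite.

## Gold standard

Positives are pairs co-annotated to at least one term with size in
[`min_term`, `max_term`] (defaults 3 and 500: pairs from two-gene terms are
statistically fragile, and giant terms assert near-vacuous
co-functionality).  Negatives are pairs of annotated genes sharing *no*
term of any size — an oversized term therefore still shields its pairs from
the negative set.  Unannotated genes appear in neither class.

## Log-likelihood calibration

Scored gold pairs are sorted by raw score and cut into at most `n_bins`
equal-frequency bins (default 10); bins holding fewer than `min_bin_count`
gold pairs (default 10) are merged downward from the top of the score
range, so the high-score end — where evidence layers are sparsest — never
yields an unstable estimate.  Each bin receives

    LLS = ln[(n_pos/n_neg) / (prior_pos/prior_neg)]

with the priors counted over the gold pairs this layer scores.  Add-one
smoothing is applied only when a bin class count is zero, keeping pure bins
finite without biasing the others.  Applying a curve assigns every scored
pair (gold or not) the LLS of its bin, clamping below the lowest and above
the highest bin; edges with LLS ≤ 0 are dropped — a co-functional link is,
by definition, positive evidence.  Whether the original lineage of this
scheme regressed LLS continuously within bins is not recoverable; the step
lookup is fixed here as the contract because it makes calibration exactly
invertible from the serialized curve.

## Weighted-sum integration

Per gene pair, component LLS values ≥ `T` are sorted descending and
combined as `WS = L0 + Σ_{i≥1} Li/(D·i)`.  `D = 1, T = 0` approaches a
naive-Bayes log-score sum; `D → ∞` recovers the single best layer.  Both
are exposed and can be fitted by exhaustive grid search maximizing the
PR-AUC of the integrated network on the gold standard (ties break toward
larger `D`, then larger `T`, i.e. toward the more conservative
combination).  PR-AUC is computed as average precision over the
gold-labeled edges with the *full* positive set as recall base, so a layer
that scores few positives cannot win by cherry-picking.  Integration is
permutation-invariant and, for every retained pair, WS ≥ the best
component score, with equality exactly when one component passes `T`.

## Prioritization

*Direct neighborhood*: score(g) = Σ weights of edges from g to the guide
set, excluding g itself — guides are scored against the other guides, not
themselves, so single-guide queries cannot trivially retrieve themselves.

*Network diffusion*: with W the weighted adjacency, Dg its diagonal
weighted-degree matrix and `S = Dg^{-1/2} W Dg^{-1/2}`, the score vector
solves `(I − αS) f = y` for the 0/1 guide indicator y.  α defaults to 0.9
(long-range propagation; the system stays well conditioned because the
spectral radius of S is ≤ 1 and α < 1).  The default solver is a sparse
direct solve; a fixed-point iteration `f ← αSf + y` to residual < 1e−8 is
available and agrees with the direct solve to < 1e−6 on random instances.
Isolated guides keep their indicator value (their S row is zero) with a
warning.

Guide-retrieval AUC uses plain retrieval — guides as positives against all
other networked genes, scores as ranked — rather than leave-one-out
re-fitting; it is a predictability gauge, not a cross-validated accuracy.
All rankings break score ties by lexicographic gene id so outputs are
reproducible byte for byte.

*Function prioritization* scores each annotation term by the summed edge
weight from the query to its annotated neighbors; the query's own
annotations never contribute (self-annotation is what the user is trying
to extend, not evidence).

*STNs*: a gene is "expressed" in a context iff its mean value over that
context's samples exceeds the threshold (default 1, the conventional BPKM
floor); an edge survives iff both endpoints are expressed.  The mean was
chosen as the per-context aggregate as the simplest defensible summary.
Genes absent from the expression matrix count as not expressed.  Raising
the threshold provably never adds edges.  Context-specific links are
reported as edges present in exactly one context of their kind — a
reporting convention of this package, exposed but not used downstream.
Neighbor-count profiles report per-gene STN degrees, the unique-neighbor
union of the query set, a log₁₀(count+1) view, and the arg-max context per
context kind.

*Disease prioritization* maps guide genes from the disease namespace onto
the network through an ortholog table (many-to-many unions, no confidence
weighting), ranks with either algorithm, and maps candidates back for
reporting.  The second tier is all mapped candidates in rank order; the
first tier is exactly second_tier ∩ support genes, preserving rank.
Network-space candidates without a disease-namespace ortholog remain in
the network-level ranking but cannot appear in the tiers.

## Evaluation battery

Precision–recall walks the edges by descending weight and records running
precision/recall among gold-labeled edges every `step` edges (default
1000); unlabeled edges advance the x axis but are not counted as
negatives, since the benchmark is only defined on labeled pairs.  The
coverage mode replaces the x axis with the fraction of the gene universe
seen so far.  ROC AUC uses the rank-sum formula with half-credit ties.
Discovery rate at k is |top-k ∩ validation|/k, with the random expectation
|validation|/universe and fold = observed/expected.  Gene-set enrichment
is the upper-tail hypergeometric test per term with Benjamini–Hochberg
correction across tested terms (BH because the terms are positively
dependent in practice and BH is the field's convention).  The null model
rewires by repeated double-edge swaps (rejecting self-loops and
multi-edges) with a fixed attempt budget of `n_swaps_per_edge × m`, then
shuffles the original weights over the rewired edges — the degree sequence
is preserved exactly, swap-saturated graphs (a triangle) return unchanged,
and everything is reproducible per seed.  The Wilcoxon signed-rank test
drops zero differences and uses the exact null for n ≤ 25, the normal
approximation with continuity correction beyond.

## Synthetic data

The generators plant one latent structure — a partition of genes into
functional modules — and emit every input the pipeline reads.  Defaults:
300 genes, 10 modules of 20, within-module edge probability 0.3 against
background 0.01, 42 expression samples round-robined over 4 developmental
stages and 10 tissues (3 samples per context), expression = per-module
latent Uniform(2, 8) plus Normal(0, 0.2) noise clipped non-negative, edge
weights Uniform(0.5, 3.0).  These sizes keep the full suite fast while
leaving every statistic comfortably estimable (≈1200 gold positives,
≈11500 negatives).  The pure-noise layer covers a random 40% of all pairs:
dense coverage is what makes its calibration *stable* (per-bin positive
counts ≈ 50), so its near-zero LLS is a property of the method rather than
of sampling noise.  Annotations split each module into a gold term
(coverage 0.8, floor rounding) and a disjoint held-out validation term;
gold standards are derived from the gold terms only, so validation genes
are genuinely unannotated during calibration.

What the generator does **not** emulate: heavy-tailed expression
distributions and batch effects, citation-count skew, overlapping or
hierarchical pathway membership, gene-family paralogy confounding the
profile and neighborhood layers, and genome-scale class imbalance
(real networks have ~10⁴ genes and ~10⁵–10⁶ candidate pairs).  Passing
tests therefore demonstrate the correctness and internal consistency of
the algorithms and the recoverability of clean planted structure — not
performance on real heterogeneous data.

## Numerical conventions

Edge weights serialize with 6 significant digits, pairs in lexicographic
order, rows by descending weight then pair; duplicate pairs collapse to
the maximum weight (scores are confidences; re-listing should not decay
them).  All ties, everywhere, break lexicographically.  Every random
choice flows from an explicit integer seed through `numpy.random.
default_rng`; layer-specific generators derive from the spec seed by fixed
offsets so layers are mutually independent but jointly reproducible.

## Known limitations

Raw-score formulas for the evidence layers follow the established lineage
of likelihood-calibrated network integration but are fixed here by
contract, not recovered from any specific historical build; with real data
the calibration step absorbs reasonable variations.  The binning
calibrator is a step function (no within-bin interpolation).  Dependence
between evidence layers is handled only through the rank-discount `D`, not
modeled explicitly.  The diffusion solver is dense-solve-backed sparse
arithmetic; networks beyond ~10⁵ nodes would warrant an iterative-only
path.  Discovery-rate assessment assumes the validation set is independent
of the ranking — as with any benchmark, leakage through shared literature
cannot be excluded by the code.
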