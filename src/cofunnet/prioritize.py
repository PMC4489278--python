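"""Network prioritization of genes, functions, contexts and disease candidates.

Two complementary guilt-by-association algorithms rank genes against a set
of user-supplied *guide genes*:

* **direct neighborhood** — a candidate's score is the sum of its edge
  weights to the guide genes, so information travels one hop;
* **network diffusion** — label propagation over the symmetric-normalized
  weight matrix ``S = Dg^{-1/2} W Dg^{-1/2}``: the score vector solves
  ``(I - alpha*S) f = y`` for the 0/1 guide indicator ``y``, spreading
  guide information through the whole network (Gaussian-field smoothing).

Spatiotemporal-specific networks (STNs) restrict the parent network to the
edges whose endpoints are both expressed (mean BPKM above a threshold) in a
given developmental stage or tissue; counting a gene's neighbors across the
STNs profiles where its functional links are active.  A disease prioritizer
maps guide genes across an ortholog table, ranks on the model-organism
network and reports candidates back in the disease namespace, optionally
split into support-gene-backed first-tier and full second-tier lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator

from .evaluate import roc_auc
from .types import AnnotationSet, ExpressionBundle, GeneNetwork, OrthologMap, Pair

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scoring estimators


class DirectNeighborhoodRanker(BaseEstimator):
    """Sum-of-edge-weights association with the guide genes (one hop)."""

    def fit(self, net: GeneNetwork) -> "DirectNeighborhoodRanker":
        self.network_ = net
        return self

    def score_genes(self, guides: set[str]) -> dict[str, float]:
        net: GeneNetwork = self.network_
        guides_in = guides & net.genes
        scores = {g: 0.0 for g in net.genes}
        for (a, b), w in net.items():
            if b in guides_in:
                scores[a] += w
            if a in guides_in:  # guides themselves score against the *other* guides
                scores[b] += w
        return scores


class NetworkDiffusionRanker(BaseEstimator):
    """Gaussian-field label propagation over the normalized weight matrix.

    Solves ``(I - alpha*S) f = y`` with ``S = Dg^{-1/2} W Dg^{-1/2}``, either
    by a sparse direct solve (default) or by the fixed-point iteration
    ``f <- alpha*S*f + y`` to a residual below ``tol``.  An isolated guide
    keeps its own indicator value (its S row is zero).
    """

    def __init__(self, alpha: float = 0.9, tol: float = 1e-8,
                 solver: str = "exact", max_iter: int = 10_000) -> None:
        self.alpha = alpha
        self.tol = tol
        self.solver = solver
        self.max_iter = max_iter

    def fit(self, net: GeneNetwork) -> "NetworkDiffusionRanker":
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.solver not in ("exact", "iterative"):
            raise ValueError("solver must be 'exact' or 'iterative'")
        self.network_ = net
        self.nodes_ = sorted(net.genes)
        index = {g: i for i, g in enumerate(self.nodes_)}
        n = len(self.nodes_)
        rows, cols, vals = [], [], []
        for (a, b), w in net.items():
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        deg = np.asarray(W.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
        Dhalf = sp.diags(inv_sqrt)
        self.S_ = (Dhalf @ W @ Dhalf).tocsr()
        self._index = index
        return self

    def score_genes(self, guides: set[str]) -> dict[str, float]:
        nodes = self.nodes_
        n = len(nodes)
        y = np.zeros(n)
        guides_in = guides & set(nodes)
        for g in guides_in:
            i = self._index[g]
            y[i] = 1.0
            if self.S_[i].nnz == 0:
                logger.warning("guide %r is isolated; its score equals its indicator", g)
        if not guides_in:
            return {g: 0.0 for g in nodes}
        if self.solver == "exact":
            A = sp.identity(n, format="csr") - self.alpha * self.S_
            f = spla.spsolve(A.tocsc(), y)
        else:
            f = y.copy()
            for _ in range(self.max_iter):
                f_new = self.alpha * (self.S_ @ f) + y
                if np.max(np.abs(f_new - f)) < self.tol:
                    f = f_new
                    break
                f = f_new
            else:  # pragma: no cover
                logger.warning("diffusion iteration hit max_iter without converging")
        return {g: float(f[i]) for g, i in self._index.items()}


def score_direct_neighborhood(net: GeneNetwork, guides: set[str]) -> dict[str, float]:
    """Functional wrapper around :class:`DirectNeighborhoodRanker`."""
    _require_guides(net, guides)
    return DirectNeighborhoodRanker().fit(net).score_genes(guides)


def score_network_diffusion(
    net: GeneNetwork,
    guides: set[str],
    alpha: float = 0.9,
    tol: float = 1e-8,
    solver: str = "exact",
) -> dict[str, float]:
    """Functional wrapper around :class:`NetworkDiffusionRanker`."""
    if guides:
        _require_guides(net, guides)
    return NetworkDiffusionRanker(alpha=alpha, tol=tol, solver=solver).fit(net).score_genes(guides)


def _require_guides(net: GeneNetwork, guides: set[str]) -> set[str]:
    present = guides & net.genes
    absent = guides - net.genes
    if absent:
        logger.warning("guides absent from the network (ignored): %s", sorted(absent))
    if guides and not present:
        raise ValueError(f"no guide gene present in the network: {sorted(guides)}")
    return present


# ---------------------------------------------------------------------------
# Gene prioritization


@dataclass(frozen=True)
class RankedGene:
    gene: str
    score: float
    rank: int
    is_guide: bool


@dataclass
class PrioritizationResult:
    """Ranked genes with guide flags and the guide-retrieval AUC."""

    algorithm: str
    records: list[RankedGene]
    auc: float
    stn_counts: "STNNeighborProfile | None" = None

    @property
    def candidates(self) -> list[str]:
        return [r.gene for r in self.records if not r.is_guide]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.rank, r.gene, r.score, r.is_guide) for r in self.records],
            columns=["rank", "gene", "score", "is_guide"],
        )


def prioritize_genes(
    net: GeneNetwork,
    guides: set[str],
    algorithm: str = "direct",
    stns: "STNSet | None" = None,
    alpha: float = 0.9,
    tol: float = 1e-8,
    top_candidates_for_stn: int = 50,
) -> PrioritizationResult:
    """Rank every networked gene by association with the guide genes.

    The guide-retrieval AUC (guides as positives, all other networked genes
    as negatives) estimates how predictable the trait depicted by the guides
    is from the network.  With ``stns``, the STN neighbor-count profile for
    guides and the top candidates is attached.
    """
    present = _require_guides(net, guides)
    if algorithm == "direct":
        scores = DirectNeighborhoodRanker().fit(net).score_genes(present)
    elif algorithm == "diffusion":
        scores = NetworkDiffusionRanker(alpha=alpha, tol=tol).fit(net).score_genes(present)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    order = sorted(scores, key=lambda g: (-scores[g], g))
    records = [
        RankedGene(g, scores[g], i, g in present) for i, g in enumerate(order, start=1)
    ]
    negatives = net.genes - present
    auc = roc_auc(scores, present, negatives) if negatives else 1.0
    result = PrioritizationResult(algorithm, records, auc)
    if stns is not None:
        focus = set(present) | set(result.candidates[:top_candidates_for_stn])
        result.stn_counts = stn_neighbor_counts(stns, focus)
    return result


def prioritize_functions(
    net: GeneNetwork,
    query: str,
    ann: AnnotationSet,
) -> list[tuple[str, float]]:
    """Rank annotation terms for a query gene.

    A term's score is the summed edge weight from the query to its
    neighbors annotated with that term; the query's own annotations do not
    contribute.  Zero-score terms are omitted; ties break by term id.
    """
    if query not in net.genes:
        raise ValueError(f"query gene {query!r} absent from the network")
    neighbor_w = net.neighbors(query)
    scores: dict[str, float] = {}
    for term in ann:
        s = sum(w for g, w in neighbor_w.items() if g in term.genes)
        if s > 0:
            scores[term.term_id] = s
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# Spatiotemporal-specific networks


@dataclass
class STNSet:
    """One expression-filtered subnetwork per spatiotemporal context."""

    contexts: list[tuple[str, str]]  # ordered (label, kind)
    networks: dict[str, GeneNetwork]  # label -> subnetwork
    threshold: float

    def __len__(self) -> int:
        return len(self.contexts)


def build_stns(
    net: GeneNetwork,
    bundle: ExpressionBundle,
    threshold: float = 1.0,
) -> STNSet:
    """Filter the network into one STN per stage/tissue context.

    A gene counts as expressed in a context iff its mean value over that
    context's samples exceeds ``threshold`` (BPKM > 1 by default); an edge
    survives iff both endpoints are expressed.  Genes missing from the
    expression matrix are treated as not expressed.
    """
    contexts = bundle.contexts()
    if not contexts:
        raise ValueError("expression bundle defines no contexts")
    missing = net.genes - set(bundle.genes)
    if missing:
        logger.info(
            "%d network genes lack expression values; treated as not expressed",
            len(missing),
        )
    networks: dict[str, GeneNetwork] = {}
    for label, _kind in contexts:
        samples = bundle.samples_for(label)
        if not samples:
            raise ValueError(f"context {label!r} has no samples")
        means = bundle.matrix[samples].mean(axis=1)
        expressed = set(means.index[means > threshold])
        stn = GeneNetwork()
        for (a, b), w in net.items():
            if a in expressed and b in expressed:
                stn.add(a, b, w)
        networks[label] = stn
    return STNSet(contexts, networks, threshold)


@dataclass
class STNNeighborProfile:
    """Per-gene neighbor counts across STNs, with a set-level aggregate."""

    counts: pd.DataFrame            # genes x context labels, STN degree
    unique_neighbors: pd.Series     # per context: unique neighbors of the gene set
    log_counts: pd.DataFrame        # log10(count + 1)
    most_enriched: dict[str, str]   # context kind -> label with most unique neighbors


def stn_neighbor_counts(stns: STNSet, genes: set[str]) -> STNNeighborProfile:
    """Count network neighbors of each gene (and of the set) in every STN."""
    labels = [label for label, _ in stns.contexts]
    rows = sorted(genes)
    counts = pd.DataFrame(0, index=rows, columns=labels, dtype=int)
    unique = pd.Series(0, index=labels, dtype=int)
    for label in labels:
        stn = stns.networks[label]
        adj: dict[str, set[str]] = {}
        for (a, b), _ in stn.items():
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        union: set[str] = set()
        for g in rows:
            nbrs = adj.get(g, set())
            counts.loc[g, label] = len(nbrs)
            union |= nbrs
        unique[label] = len(union)
    log_counts = np.log10(counts + 1)
    most: dict[str, str] = {}
    for kind in dict.fromkeys(k for _, k in stns.contexts):
        kind_labels = [l for l, k in stns.contexts if k == kind]
        sub = unique[kind_labels]
        most[kind] = str(sub.idxmax())
    return STNNeighborProfile(counts, unique, log_counts, most)


def context_specific_links(stns: STNSet) -> dict[str, set[Pair]]:
    """Edges present in exactly one context of their kind, per context label."""
    out: dict[str, set[Pair]] = {}
    for kind in dict.fromkeys(k for _, k in stns.contexts):
        labels = [l for l, k in stns.contexts if k == kind]
        membership: dict[Pair, list[str]] = {}
        for label in labels:
            for pair, _ in stns.networks[label].items():
                membership.setdefault(pair, []).append(label)
        for label in labels:
            out[label] = {p for p, ls in membership.items() if ls == [label]}
    return out


# ---------------------------------------------------------------------------
# Disease prioritization across orthology


@dataclass
class TieredCandidates:
    """Disease-namespace candidates: support-backed first tier, full second tier."""

    first_tier: list[str]
    second_tier: list[str]
    support_genes_used: set[str] = field(default_factory=set)


def prioritize_disease(
    net: GeneNetwork,
    omap: OrthologMap,
    guide_genes: set[str],
    guide_namespace: str = "human",
    support_genes: set[str] | None = None,
    algorithm: str = "direct",
    alpha: float = 0.9,
) -> tuple[TieredCandidates, PrioritizationResult]:
    """Prioritize disease candidates on a model-organism network.

    Guide genes in the disease (source) namespace map through the ortholog
    table onto the network's namespace; prioritization runs there, and the
    ranked candidates map back for reporting.  ``second_tier`` holds all
    mapped candidates in rank order; ``first_tier`` is its intersection with
    the support genes, in the same order.
    """
    if guide_namespace not in ("human", "fly"):
        raise ValueError("guide_namespace must be 'human' or 'fly'")
    if guide_namespace == "human":
        mapped: set[str] = set()
        for h in sorted(guide_genes):
            orths = omap.targets(h)
            if not orths:
                logger.warning("guide %r has no ortholog; skipped", h)
            mapped |= orths
        if not mapped:
            raise ValueError("no guide gene maps onto the network namespace")
        fly_guides = mapped
    else:
        fly_guides = set(guide_genes)

    result = prioritize_genes(net, fly_guides, algorithm=algorithm, alpha=alpha)

    second_tier: list[str] = []
    seen: set[str] = set()
    for fly_gene in result.candidates:
        for h in sorted(omap.sources(fly_gene)):
            if h not in seen:
                seen.add(h)
                second_tier.append(h)
    support = set(support_genes) if support_genes else set()
    first_tier = [g for g in second_tier if g in support]
    return TieredCandidates(first_tier, second_tier, support), result
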