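"""Core domain containers for co-functional gene networks.

The central object is :class:`GeneNetwork`, an undirected gene graph whose
edge weights are log-likelihood scores (LLS, in nats) expressing evidence
that two genes act in the same biological process.  Everything upstream
(raw evidence scores, annotation sets, expression bundles, ortholog maps)
and downstream (gold standards, calibration curves, rankings) is built
around it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: An unordered gene pair in canonical (lexicographic) order.
Pair = tuple[str, str]

EVIDENCE_CODES = frozenset({"CC", "CX", "DC", "GN", "PG", "HT", "LC", "XFER"})


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical lexicographic order.

    Raises ``ValueError`` for self-pairs or empty gene ids.
    """
    if not a or not b:
        raise ValueError("gene ids must be non-empty strings")
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


class _PairMap:
    """Shared machinery: a map from canonical gene pairs to finite scores."""

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()) -> None:
        self._w: dict[Pair, float] = {}
        for a, b, w in edges:
            self.add(a, b, w)

    def add(self, a: str, b: str, weight: float) -> None:
        """Insert an edge; a duplicate unordered pair keeps the max weight."""
        weight = float(weight)
        if not math.isfinite(weight):
            raise ValueError(f"non-finite weight for pair ({a}, {b}): {weight}")
        pair = canonical_pair(a, b)
        old = self._w.get(pair)
        if old is None or weight > old:
            self._w[pair] = weight

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        return self._w.get(canonical_pair(a, b), default)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._w

    def __len__(self) -> int:
        return len(self._w)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), w in self._w.items():
            yield a, b, w

    def items(self) -> Iterator[tuple[Pair, float]]:
        return iter(self._w.items())

    @property
    def pair_dict(self) -> Mapping[Pair, float]:
        return self._w

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._w:
            out.add(a)
            out.add(b)
        return out


class GeneNetwork(_PairMap):
    """Undirected weighted gene network; weights are LLS values in nats.

    Invariants: no self-loops, each unordered pair at most once, finite
    weights, non-empty gene ids.  Duplicate insertions collapse keeping the
    maximum weight.
    """

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self._w)

    def neighbors(self, gene: str) -> dict[str, float]:
        """Map neighbor -> edge weight for ``gene`` (empty if absent)."""
        out: dict[str, float] = {}
        for (a, b), w in self._w.items():
            if a == gene:
                out[b] = w
            elif b == gene:
                out[a] = w
        return out

    def degree(self, weighted: bool = False) -> dict[str, float]:
        deg: dict[str, float] = {}
        for (a, b), w in self._w.items():
            inc = w if weighted else 1
            deg[a] = deg.get(a, 0) + inc
            deg[b] = deg.get(b, 0) + inc
        return deg

    def subnetwork(self, genes: set[str]) -> "GeneNetwork":
        """Edge-induced subnetwork on ``genes`` (both endpoints retained)."""
        sub = GeneNetwork()
        for (a, b), w in self._w.items():
            if a in genes and b in genes:
                sub.add(a, b, w)
        return sub

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), w in self._w.items():
            g.add_edge(a, b, weight=w)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._w.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            [(a, b, w) for (a, b), w in rows],
            columns=["gene_a", "gene_b", "weight"],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneNetwork(n_genes={self.n_genes}, n_edges={self.n_edges})"


class ScoredPairSet(_PairMap):
    """Raw (uncalibrated) evidence scores for gene pairs, one evidence type.

    ``evidence_code`` is one of CC (co-citation), CX (co-expression),
    DC (domain co-occurrence), GN (gene neighborhood), PG (phylogenetic
    profile), HT/LC (high-throughput / literature-curated PPI) or XFER
    (orthology transfer).  Scores are evidence-specific; higher = stronger.
    """

    def __init__(
        self,
        evidence_code: str,
        pairs: Iterable[tuple[str, str, float]] = (),
    ) -> None:
        if evidence_code not in EVIDENCE_CODES:
            raise ValueError(
                f"unknown evidence code {evidence_code!r}; "
                f"expected one of {sorted(EVIDENCE_CODES)}"
            )
        self.evidence_code = evidence_code
        super().__init__(pairs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ScoredPairSet({self.evidence_code}, n_pairs={len(self)})"


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    description: str
    source: str  # e.g. GO-BP, KEGG, MetaCyc/BioCyc, GenomeRNAi, other
    genes: frozenset[str]


class AnnotationSet:
    """Functional annotation terms (GO-BP / KEGG / pathway / phenotype).

    Maps term id -> (description, source tag, gene set); every term holds at
    least one gene in the same id namespace as :class:`GeneNetwork`.
    """

    def __init__(self, terms: Iterable[AnnotationTerm] = ()) -> None:
        self._terms: dict[str, AnnotationTerm] = {}
        for t in terms:
            self.add(t)

    def add(self, term: AnnotationTerm) -> None:
        if not term.genes:
            raise ValueError(f"term {term.term_id!r} has no genes")
        self._terms[term.term_id] = term

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __iter__(self) -> Iterator[AnnotationTerm]:
        return iter(self._terms.values())

    def __getitem__(self, term_id: str) -> AnnotationTerm:
        return self._terms[term_id]

    @property
    def term_ids(self) -> list[str]:
        return list(self._terms)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for t in self._terms.values():
            out |= t.genes
        return out

    def terms_for(self, gene: str) -> set[str]:
        return {tid for tid, t in self._terms.items() if gene in t.genes}

    def subset(self, term_ids: Iterable[str]) -> "AnnotationSet":
        keep = set(term_ids)
        return AnnotationSet(t for t in self if t.term_id in keep)


class ExpressionBundle:
    """Gene x sample expression matrix with a sample -> context map.

    Values are non-negative expression measures (BPKM for RNA-seq, intensity
    for arrays).  Each sample carries a context ``(label, kind)`` where kind
    is ``"stage"`` or ``"tissue"``.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        context_map: Mapping[str, tuple[str, str]],
    ) -> None:
        if (matrix.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in matrix.columns if s not in context_map]
        if missing:
            raise ValueError(f"samples lacking a context: {missing}")
        extra = [s for s in context_map if s not in matrix.columns]
        if extra:
            logger.warning("context map lists unknown samples: %s", extra)
        self.matrix = matrix
        self.context_map = dict(context_map)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def contexts(self) -> list[tuple[str, str]]:
        """Distinct (label, kind) contexts: stages first, then tissues,
        each in order of first appearance across samples."""
        seen: list[tuple[str, str]] = []
        for s in self.matrix.columns:
            ctx = self.context_map[s]
            if ctx not in seen:
                seen.append(ctx)
        stages = [c for c in seen if c[1] == "stage"]
        tissues = [c for c in seen if c[1] != "stage"]
        return stages + tissues

    def samples_for(self, label: str) -> list[str]:
        return [s for s in self.matrix.columns if self.context_map[s][0] == label]


class OrthologMap:
    """Many-to-many ortholog pairs between a source and a target species."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self.pairs: set[tuple[str, str]] = set()
        self._fwd: dict[str, set[str]] = {}
        self._rev: dict[str, set[str]] = {}
        for s, t in pairs:
            self.add(s, t)

    def add(self, source: str, target: str) -> None:
        if not source or not target:
            raise ValueError("ortholog ids must be non-empty")
        if (source, target) in self.pairs:
            return
        self.pairs.add((source, target))
        self._fwd.setdefault(source, set()).add(target)
        self._rev.setdefault(target, set()).add(source)

    def __len__(self) -> int:
        return len(self.pairs)

    def targets(self, source: str) -> set[str]:
        return set(self._fwd.get(source, ()))

    def sources(self, target: str) -> set[str]:
        return set(self._rev.get(target, ()))

    def inverted(self) -> "OrthologMap":
        """The same pairs with source and target species swapped."""
        return OrthologMap((t, s) for s, t in self.pairs)


@dataclass(frozen=True)
class GoldStandard:
    """Disjoint positive / negative gene-pair sets for calibration.

    Positives co-occur in at least one eligible pathway/GO term; negatives
    are pairs of annotated genes sharing no term.
    """

    positives: frozenset[Pair]
    negatives: frozenset[Pair]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")

    def label(self, a: str, b: str) -> int | None:
        """+1 positive, -1 negative, None unlabeled."""
        p = canonical_pair(a, b)
        if p in self.positives:
            return 1
        if p in self.negatives:
            return -1
        return None

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)
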