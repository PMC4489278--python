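"""Raw co-functionality scores per evidence type.

Each inference turns one kind of genome-scale observation into a
:class:`~cofunnet.types.ScoredPairSet` of uncalibrated pairwise scores:

* CX — Pearson correlation of expression profiles;
* CC — co-citation: -log10 hypergeometric tail of shared-document counts;
* DC — domain co-occurrence: same statistic over shared protein domains;
* PG — phylogenetic profiles: mutual information (bits) of binary
  presence/absence patterns across reference genomes;
* GN — gene neighborhood: the fraction of reference genomes in which the
  two genes' orthologs are chromosomal neighbors;
* XFER — orthology transfer of an existing network into another species.

Raw scores only need to be monotone in evidence strength: the calibrate
module re-maps them onto a common log-likelihood scale against a gold
standard, so units are not comparable across evidence types.

High-throughput (HT) and literature-curated (LC) protein interaction
evidence arrives as pre-scored edge lists through :mod:`cofunnet.netio`;
there is nothing to infer for those codes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .netio import NetworkParseError, _data_lines
from .types import ExpressionBundle, GeneNetwork, OrthologMap, ScoredPairSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Evidence-specific carriers


@dataclass
class DocIncidence:
    """gene -> set of citing document ids, plus the total corpus size."""

    docs: dict[str, set[str]]
    corpus_size: int

    def __post_init__(self) -> None:
        listed = set().union(*self.docs.values()) if self.docs else set()
        if self.corpus_size < len(listed):
            raise ValueError(
                f"corpus_size {self.corpus_size} smaller than the "
                f"{len(listed)} distinct documents listed"
            )


@dataclass
class ProfileMatrix:
    """gene x reference-genome binary presence/absence profiles."""

    profiles: dict[str, np.ndarray]
    genomes: list[str]

    def __post_init__(self) -> None:
        if len(self.genomes) < 2:
            raise ValueError("phylogenetic profiles need >=2 reference genomes")
        n = len(self.genomes)
        for g, p in self.profiles.items():
            p = np.asarray(p)
            if p.shape != (n,):
                raise ValueError(f"profile for {g!r} has wrong length")
            if not np.isin(p, (0, 1)).all():
                raise ValueError(f"profile for {g!r} has non-binary entries")
            self.profiles[g] = p.astype(np.int8)


@dataclass
class DomainTable:
    """gene -> set of protein-domain ids, plus the domain universe size."""

    domains: dict[str, set[str]]
    universe_size: int

    def __post_init__(self) -> None:
        self.domains = {g: s for g, s in self.domains.items() if s}
        biggest = max((len(s) for s in self.domains.values()), default=0)
        if self.universe_size < biggest:
            raise ValueError(
                f"domain universe {self.universe_size} smaller than the largest "
                f"per-gene domain set ({biggest})"
            )


@dataclass
class NeighborhoodTable:
    """Per reference genome: chromosomal position of each query gene's ortholog."""

    positions: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, genome: str, gene: str, position: int) -> None:
        g = self.positions.setdefault(genome, {})
        if position in g.values():
            raise ValueError(f"duplicate position {position} in genome {genome!r}")
        g[gene] = int(position)


# ---------------------------------------------------------------------------
# Readers for the evidence-specific tables


def read_doc_incidence(path: str | Path, corpus_size: int | None = None) -> DocIncidence:
    """Read a two-column ``gene<TAB>doc-id`` table.

    If ``corpus_size`` is omitted it defaults to the number of distinct
    document ids observed.
    """
    docs: dict[str, set[str]] = {}
    all_docs: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise NetworkParseError(f"{path}:{lineno}: expected 2 columns (gene, doc)")
        docs.setdefault(fields[0], set()).add(fields[1])
        all_docs.add(fields[1])
    return DocIncidence(docs, corpus_size if corpus_size is not None else len(all_docs))


def read_profile_matrix(path: str | Path) -> ProfileMatrix:
    """Read a gene x genome 0/1 matrix (header row = genome names)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    profiles = {str(g): df.loc[g].to_numpy() for g in df.index}
    return ProfileMatrix(profiles, [str(c) for c in df.columns])


def read_domain_table(path: str | Path, universe_size: int | None = None) -> DomainTable:
    """Read a two-column ``gene<TAB>domain-id`` table."""
    domains: dict[str, set[str]] = {}
    all_domains: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise NetworkParseError(f"{path}:{lineno}: expected 2 columns (gene, domain)")
        domains.setdefault(fields[0], set()).add(fields[1])
        all_domains.add(fields[1])
    return DomainTable(domains, universe_size if universe_size is not None else len(all_domains))


def read_neighborhood_table(path: str | Path) -> NeighborhoodTable:
    """Read a three-column ``genome<TAB>gene<TAB>position`` table."""
    nbr = NeighborhoodTable()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise NetworkParseError(f"{path}:{lineno}: expected 3 columns (genome, gene, position)")
        try:
            pos = int(fields[2])
        except ValueError as exc:
            raise NetworkParseError(f"{path}:{lineno}: non-integer position {fields[2]!r}") from exc
        try:
            nbr.add(fields[0], fields[1], pos)
        except ValueError as exc:
            raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
    return nbr


# ---------------------------------------------------------------------------
# Inference


def _neglog10_hypergeom_tail(k: int, n_a: int, n_b: int, universe: int) -> float:
    """-log10 P(X >= k) for X ~ Hypergeom(universe, n_a, n_b).

    The upper-tail probability of observing at least ``k`` shared items
    between a set of ``n_a`` and a set of ``n_b`` items drawn from a
    universe of ``universe`` items.
    """
    p = stats.hypergeom.sf(k - 1, universe, n_a, n_b)
    # clip into (0, 1]; sf can round to 0 for extreme overlaps
    p = min(max(float(p), 5e-324), 1.0)
    return -np.log10(p)


def _overlap_pairset(
    sets: Mapping[str, set[str]],
    universe: int,
    code: str,
) -> ScoredPairSet:
    """Vectorized -log10 hypergeometric-tail scores for all set pairs
    sharing at least one item."""
    genes = sorted(sets)
    out = ScoredPairSet(code)
    if len(genes) < 2:
        return out
    items = sorted(set().union(*(sets[g] for g in genes)))
    idx = {d: j for j, d in enumerate(items)}
    A = np.zeros((len(genes), len(items)), dtype=np.int32)
    for i, g in enumerate(genes):
        for d in sets[g]:
            A[i, idx[d]] = 1
    sizes = A.sum(axis=1)
    overlap = A @ A.T
    iu, ju = np.triu_indices(len(genes), k=1)
    k = overlap[iu, ju]
    mask = k > 0
    iu, ju, k = iu[mask], ju[mask], k[mask]
    if k.size == 0:
        return out
    p = stats.hypergeom.sf(k - 1, universe, sizes[iu], sizes[ju])
    scores = -np.log10(np.clip(p, 5e-324, 1.0))
    for i, j, s in zip(iu, ju, scores):
        out.add(genes[i], genes[j], float(s))
    return out


def infer_coexpression(bundle: ExpressionBundle, min_samples: int = 4) -> ScoredPairSet:
    """Pearson correlation of expression profiles, one score per gene pair.

    Genes with zero variance are excluded; pairs with undefined PCC are
    omitted.  Negative correlations are retained — the calibration stage
    decides how informative they are.
    """
    out = ScoredPairSet("CX")
    mat = bundle.matrix
    if mat.shape[1] < min_samples:
        raise ValueError(
            f"co-expression needs >= {min_samples} samples, got {mat.shape[1]}"
        )
    if mat.shape[0] < 2:
        logger.warning("fewer than 2 genes; empty co-expression set")
        return out
    values = mat.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    if not keep.all():
        logger.info("excluding %d zero-variance genes", int((~keep).sum()))
    genes = [g for g, k in zip(mat.index, keep) if k]
    values = values[keep]
    if len(genes) < 2:
        logger.warning("fewer than 2 variable genes; empty co-expression set")
        return out
    corr = np.corrcoef(values)
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu, ju):
        r = corr[i, j]
        if np.isfinite(r):
            out.add(genes[i], genes[j], float(r))
    return out


def infer_cocitation(docs: DocIncidence, min_docs: int = 2) -> ScoredPairSet:
    """Co-citation strength: -log10 hypergeometric tail of document overlap.

    Genes cited in fewer than ``min_docs`` documents are excluded; pairs
    with zero overlap are omitted.
    """
    eligible = {g: d for g, d in docs.docs.items() if len(d) >= min_docs}
    return _overlap_pairset(eligible, docs.corpus_size, "CC")


def infer_phylo_profile(profiles: ProfileMatrix) -> ScoredPairSet:
    """Mutual information (bits) between binary phylogenetic profiles.

    All-zero and all-one profiles are degenerate (zero-entropy marginals)
    and are excluded.
    """
    out = ScoredPairSet("PG")
    informative = {
        g: p for g, p in profiles.profiles.items() if 0 < int(p.sum()) < p.size
    }
    dropped = len(profiles.profiles) - len(informative)
    if dropped:
        logger.info("excluding %d genes with constant profiles", dropped)
    genes = sorted(informative)
    if len(genes) < 2:
        return out
    n = len(profiles.genomes)
    P = np.stack([informative[g] for g in genes]).astype(np.int64)
    n11 = P @ P.T
    ones = P.sum(axis=1)
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = n - n11 - n10 - n01

    def term(c: np.ndarray, ma: np.ndarray, mb: np.ndarray) -> np.ndarray:
        # c * log2(c*n / (ma*mb)) / n, with zero cells contributing zero
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (c / n) * np.log2(np.where(c > 0, c * n / (ma * mb), 1.0))
        return np.where(c > 0, t, 0.0)

    zeros = n - ones
    mi = (
        term(n11, ones[:, None], ones[None, :])
        + term(n10, ones[:, None], zeros[None, :])
        + term(n01, zeros[:, None], ones[None, :])
        + term(n00, zeros[:, None], zeros[None, :])
    )
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu, ju):
        out.add(genes[i], genes[j], max(float(mi[i, j]), 0.0))
    return out


def infer_domain_cooccurrence(domains: DomainTable) -> ScoredPairSet:
    """Domain co-occurrence: -log10 hypergeometric tail of shared domains."""
    return _overlap_pairset(domains.domains, domains.universe_size, "DC")


def infer_gene_neighborhood(nbr: NeighborhoodTable, window: int = 1) -> ScoredPairSet:
    """Chromosomal-proximity score across reference genomes.

    score = (# genomes where both orthologs lie within ``window`` positions)
    / (# genomes where both genes have orthologs).  Pairs co-present in
    fewer than 2 genomes, or never within the window, are omitted.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not nbr.positions:
        raise ValueError("neighborhood table has no reference genomes")
    copresent: dict[tuple[str, str], int] = {}
    near: dict[tuple[str, str], int] = {}
    for genome, posmap in nbr.positions.items():
        genes = sorted(posmap)
        for ga, gb in itertools.combinations(genes, 2):
            pair = (ga, gb) if ga < gb else (gb, ga)
            copresent[pair] = copresent.get(pair, 0) + 1
            if abs(posmap[ga] - posmap[gb]) <= window:
                near[pair] = near.get(pair, 0) + 1
    out = ScoredPairSet("GN")
    for pair, n_co in copresent.items():
        if n_co < 2:
            continue
        n_near = near.get(pair, 0)
        if n_near == 0:
            continue
        out.add(pair[0], pair[1], n_near / n_co)
    return out


def transfer_orthology(net: GeneNetwork, omap: OrthologMap) -> ScoredPairSet:
    """Transfer a source-species network into the target species.

    Each source edge (a, b, w) emits every target pair (a', b') with
    a' in orth(a), b' in orth(b), a' != b', at raw score w.  Duplicates
    collapse keeping the max; edges with an unmapped endpoint are dropped.
    """
    out = ScoredPairSet("XFER")
    for a, b, w in net:
        for ta in omap.targets(a):
            for tb in omap.targets(b):
                if ta != tb:
                    out.add(ta, tb, w)
    return out
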