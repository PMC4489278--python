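"""Readers and writers for the toolkit's tab-delimited interchange formats.

All formats are UTF-8, tab-delimited, with ``#`` comment lines ignored:

* network edge list — ``gene_a  gene_b  weight`` (>=3 columns);
* GMT — ``term  description  gene1  gene2 ...``;
* expression matrix — genes x samples with a sample-id header row;
* context map — ``sample  label  kind``;
* ortholog map — ``source_gene  target_gene``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .types import AnnotationSet, AnnotationTerm, ExpressionBundle, GeneNetwork, OrthologMap

logger = logging.getLogger(__name__)

_NETWORK_HEADER = "#gene_a\tgene_b\tweight\n"


class NetworkParseError(ValueError):
    """A network/GMT/table file violated its dialect; message names the line."""


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_network(path: str | Path) -> GeneNetwork:
    """Read a weighted edge list into a :class:`GeneNetwork`.

    Duplicate unordered pairs collapse keeping the maximum weight;
    self-loops are dropped with a warning.
    """
    net = GeneNetwork()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise NetworkParseError(
                f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
            )
        a, b, w = fields[0], fields[1], fields[2]
        try:
            weight = float(w)
        except ValueError as exc:
            raise NetworkParseError(f"{path}:{lineno}: non-numeric weight {w!r}") from exc
        if a == b:
            logger.warning("%s:%d: self-loop on %r dropped", path, lineno, a)
            continue
        try:
            net.add(a, b, weight)
        except ValueError as exc:
            raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_network(net: GeneNetwork, path: str | Path) -> None:
    """Write a canonical, byte-deterministic edge list.

    Pairs are in lexicographic order (gene_a < gene_b); rows sorted by
    descending weight, then pair; weights printed with 6 significant digits.
    """
    rows = sorted(net.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_NETWORK_HEADER)
        for (a, b), w in rows:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def read_gmt(path: str | Path, source: str = "other") -> AnnotationSet:
    """Read a GMT file (term, description, gene ids) into an AnnotationSet.

    Terms with no genes are dropped with a warning; duplicate genes within
    one line are deduplicated.
    """
    ann = AnnotationSet()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise NetworkParseError(
                f"{path}:{lineno}: GMT line needs at least term and description"
            )
        term_id, desc = fields[0], fields[1]
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            logger.warning("%s:%d: term %r has no genes; dropped", path, lineno, term_id)
            continue
        ann.add(AnnotationTerm(term_id, desc, source, genes))
    return ann


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(ann.term_ids):
            t = ann[tid]
            fh.write("\t".join([t.term_id, t.description, *sorted(t.genes)]) + "\n")


def read_expression(matrix_path: str | Path, context_path: str | Path) -> ExpressionBundle:
    """Read an expression matrix plus its sample -> (label, kind) context map."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    if not np.issubdtype(matrix.values.dtype, np.number):
        raise NetworkParseError(f"{matrix_path}: non-numeric expression values")
    if (matrix.values < 0).any():
        raise ValueError(f"{matrix_path}: negative expression values")
    context: dict[str, tuple[str, str]] = {}
    for lineno, line in _data_lines(context_path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise NetworkParseError(
                f"{context_path}:{lineno}: expected 3 columns (sample, label, kind)"
            )
        sample, label, kind = fields
        if kind not in ("stage", "tissue"):
            raise NetworkParseError(
                f"{context_path}:{lineno}: context kind must be 'stage' or 'tissue', got {kind!r}"
            )
        context[sample] = (label, kind)
    return ExpressionBundle(matrix, context)


def write_expression(bundle: ExpressionBundle, matrix_path: str | Path, context_path: str | Path) -> None:
    bundle.matrix.to_csv(matrix_path, sep="\t", float_format="%.6g")
    with open(context_path, "w", encoding="utf-8") as fh:
        fh.write("#sample\tlabel\tkind\n")
        for s in bundle.samples:
            label, kind = bundle.context_map[s]
            fh.write(f"{s}\t{label}\t{kind}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column source->target ortholog table (deduplicated)."""
    omap = OrthologMap()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise NetworkParseError(
                f"{path}:{lineno}: expected exactly 2 columns, got {len(fields)}"
            )
        omap.add(fields[0], fields[1])
    return omap


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in sorted(omap.pairs):
            fh.write(f"{s}\t{t}\n")


def read_pairs(path: str | Path, evidence_code: str) -> "ScoredPairSet":
    """Read a 3-column raw-score pair list (same dialect as networks)."""
    from .types import ScoredPairSet

    net = read_network(path)
    out = ScoredPairSet(evidence_code)
    for a, b, w in net:
        out.add(a, b, w)
    return out


def write_pairs(pairs, path: str | Path) -> None:
    """Write a ScoredPairSet in the canonical 3-column format."""
    net = GeneNetwork()
    for a, b, w in pairs:
        net.add(a, b, w)
    write_network(net, path)


def read_gold_standard(path: str | Path) -> "GoldStandard":
    """Read a labeled pair list: gene_a, gene_b, label (P or N)."""
    from .types import GoldStandard, canonical_pair

    pos, neg = set(), set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3 or fields[2] not in ("P", "N"):
            raise NetworkParseError(
                f"{path}:{lineno}: expected gene_a, gene_b, label in {{P,N}}"
            )
        (pos if fields[2] == "P" else neg).add(canonical_pair(fields[0], fields[1]))
    return GoldStandard(frozenset(pos), frozenset(neg))


def write_gold_standard(gold, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_a\tgene_b\tlabel\n")
        for a, b in sorted(gold.positives):
            fh.write(f"{a}\t{b}\tP\n")
        for a, b in sorted(gold.negatives):
            fh.write(f"{a}\t{b}\tN\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line ('#' comments ignored), order preserved."""
    out: list[str] = []
    for _, line in _data_lines(path):
        out.append(line.split("\t")[0])
    return out


class NetworkStats(NamedTuple):
    n_genes: int
    n_links: int
    weight_quantiles: dict[float, float]


def network_stats(net: GeneNetwork, quantiles: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)) -> NetworkStats:
    """Gene count, link count and weight quantiles of a network."""
    weights = np.array([w for _, _, w in net], dtype=float)
    if weights.size:
        qs = {q: float(v) for q, v in zip(quantiles, np.quantile(weights, quantiles))}
    else:
        qs = {}
    return NetworkStats(net.n_genes, net.n_edges, qs)
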