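"""Assessment battery for calibrated gene networks and prioritizations.

Precision–recall curves over gold-standard pairs, rank-sum ROC/AUC,
discovery rates with fold enrichment, hypergeometric gene-set enrichment
with Benjamini–Hochberg correction, degree-preserving random networks and
the paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AnnotationSet, GeneNetwork, GoldStandard

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRPoint:
    x: float  # pairs examined, or genome-coverage fraction
    precision: float
    recall: float


@dataclass(frozen=True)
class PRCurve:
    points: tuple[PRPoint, ...]
    step: int
    x_axis: str  # "pairs" or "coverage"


def _sorted_edges(net: GeneNetwork) -> list[tuple[str, str, float]]:
    """Edges by descending weight; ties broken by the canonical pair id."""
    return sorted(net, key=lambda e: (-e[2], e[0], e[1]))


def precision_recall_curve(
    net: GeneNetwork,
    gold: GoldStandard,
    step: int = 1000,
    x_axis: str = "pairs",
    universe: set[str] | None = None,
) -> PRCurve:
    """Precision/recall measured every ``step`` edges down the weight ranking.

    Only gold-labeled edges enter the precision and recall counts; unlabeled
    edges advance the x axis but are neither positives nor negatives.  In
    ``coverage`` mode the x axis is the fraction of ``universe`` genes seen
    among the nodes walked so far (default universe: the network's genes).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if x_axis not in ("pairs", "coverage"):
        raise ValueError("x_axis must be 'pairs' or 'coverage'")
    uni = universe if universe is not None else net.genes
    edges = _sorted_edges(net)
    cum_pos = cum_neg = 0
    seen: set[str] = set()
    points: list[PRPoint] = []
    any_labeled = False

    def record(i: int) -> None:
        if cum_pos + cum_neg == 0:
            return
        prec = cum_pos / (cum_pos + cum_neg)
        rec = cum_pos / gold.n_pos if gold.n_pos else 0.0
        x = float(i) if x_axis == "pairs" else len(seen & uni) / len(uni)
        if points and points[-1].x == x:
            points.pop()  # keep the latest value at a repeated x
        points.append(PRPoint(x, prec, rec))

    for i, (a, b, _) in enumerate(edges, start=1):
        lab = gold.label(a, b)
        if lab == 1:
            cum_pos += 1
        elif lab == -1:
            cum_neg += 1
        if lab is not None:
            any_labeled = True
        seen.add(a)
        seen.add(b)
        if i % step == 0:
            record(i)
    if not any_labeled:
        raise ValueError("no gold-labeled edge in the network")
    if len(edges) % step != 0 or not points:
        record(len(edges))
    return PRCurve(tuple(points), step, x_axis)


def pr_auc(net: GeneNetwork, gold: GoldStandard) -> float:
    """Area under the precision–recall curve as average precision.

    Walks the gold-labeled edges in descending-weight order and averages the
    precision at each retrieved positive; gold positives absent from the
    network contribute zero, so the recall base is the full positive set.
    """
    if gold.n_pos == 0:
        raise ValueError("gold standard has no positives")
    cum_pos = cum_neg = 0
    total = 0.0
    any_labeled = False
    for a, b, _ in _sorted_edges(net):
        lab = gold.label(a, b)
        if lab is None:
            continue
        any_labeled = True
        if lab == 1:
            cum_pos += 1
            total += cum_pos / (cum_pos + cum_neg)
        else:
            cum_neg += 1
    if not any_labeled:
        raise ValueError("no gold-labeled edge in the network")
    return total / gold.n_pos


def roc_auc(
    scores: Mapping[str, float],
    positives: set[str],
    negatives: set[str],
) -> float:
    """AUC by the rank-sum (Mann–Whitney) formula; ties contribute 1/2."""
    if not positives or not negatives:
        raise ValueError("both positive and negative sets must be non-empty")
    missing = (positives | negatives) - scores.keys()
    if missing:
        raise ValueError(f"unscored genes: {sorted(missing)[:5]}...")
    pos = sorted(positives)
    neg = sorted(negatives)
    vals = np.array([scores[g] for g in pos + neg], dtype=float)
    ranks = stats.rankdata(vals)
    n_pos, n_neg = len(pos), len(neg)
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class DiscoveryRate:
    k: int
    rate: float
    expected: float
    fold: float


def discovery_rate(
    ranked: Sequence[str],
    validation: set[str],
    ks: Iterable[int],
    universe_size: int,
) -> list[DiscoveryRate]:
    """Fraction of the top-k candidates found in a validation gene set.

    ``expected`` is the random-chance rate |validation| / universe_size and
    ``fold`` the observed/expected ratio.
    """
    if universe_size < len(validation):
        raise ValueError("universe smaller than the validation set")
    expected = len(validation) / universe_size
    out = []
    for k in ks:
        if k <= 0:
            raise ValueError("k must be positive")
        if k > len(ranked):
            raise ValueError(f"k={k} exceeds the {len(ranked)} ranked candidates")
        rate = len(set(ranked[:k]) & validation) / k
        fold = rate / expected if expected > 0 else float("nan")
        out.append(DiscoveryRate(k, rate, expected, fold))
    return out


def hypergeom_enrichment(
    query: set[str],
    ann: AnnotationSet,
    universe: set[str],
) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric enrichment of a query gene set.

    Returns a frame (term, k, K, n, N, p, q) sorted by p then term id, with
    Benjamini–Hochberg q values across all tested terms.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(ann.term_ids):
        term_genes = ann[term].genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(max(p, 5e-324), 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = []
    return df


def degree_preserving_null(
    net: GeneNetwork,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> GeneNetwork:
    """Random network with the exact degree sequence of ``net``.

    Repeated double-edge swaps (a-b, c-d -> a-d, c-b) with rejection of
    self-loops and multi-edges; the original weights are then shuffled
    uniformly over the rewired edges.  Swap-saturated graphs (e.g. a
    triangle) come back with their edge set unchanged.
    """
    edges: list[tuple[str, str]] = sorted((a, b) for a, b, _ in net)
    weights = [w for _, _, w in sorted(net, key=lambda e: (e[0], e[1]))]
    m = len(edges)
    if m < 2:
        logger.warning("network has <2 edges; returned unchanged")
        out = GeneNetwork()
        for a, b, w in net:
            out.add(a, b, w)
        return out
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    n_attempts = n_swaps_per_edge * m
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i], edges[j] = new1, new2
    final = sorted(edge_set)
    perm = rng.permutation(m)
    out = GeneNetwork()
    for (a, b), k in zip(final, perm):
        out.add(a, b, weights[k])
    return out


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped.  The exact null distribution is used for
    n <= 25 remaining pairs; beyond that, the normal approximation with
    continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("paired samples must have equal length >= 5")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    exact = d.size <= 25
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return float(res.statistic), float(res.pvalue)
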