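"""Gold standards, log-likelihood calibration and weighted-sum integration.

Raw evidence scores are only ordinal.  To put heterogeneous evidence on a
common scale, each evidence layer is benchmarked against a gold standard of
known co-functional (positive) and non-co-functional (negative) gene pairs:
scored gold pairs are cut into equal-frequency raw-score bins and each bin
receives a log-likelihood score

    LLS = ln[ (P(L|E) / ~P(L|E)) / (P(L) / ~P(L)) ]

i.e. the log ratio of the in-bin positive:negative odds to the prior odds
among all scorable gold pairs, in nats.  Calibrated component networks are
then merged by a rank-discounted weighted sum: for one gene pair with
component scores L0 >= L1 >= ... (each >= cutoff T),

    WS = L0 + sum_{i>=1} L_i / (D * i)

with degradation divisor D >= 1 controlling how much corroborating evidence
beyond the strongest layer counts (D -> inf recovers the max; D = 1 with
T = 0 approaches a naive-Bayes sum).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .evaluate import pr_auc
from .types import AnnotationSet, GeneNetwork, GoldStandard, Pair, ScoredPairSet

logger = logging.getLogger(__name__)


def derive_gold_standard(
    ann: AnnotationSet,
    min_term: int = 3,
    max_term: int = 500,
    universe: set[str] | None = None,
) -> GoldStandard:
    """Positive/negative gene pairs from pathway-style annotations.

    Positives: pairs co-annotated to at least one term whose size falls in
    [min_term, max_term].  Negatives: pairs of annotated genes that share no
    term at all (of any size).  Genes outside ``universe`` (when given) are
    ignored; unannotated genes contribute to neither set.
    """
    if len(ann) == 0:
        raise ValueError("empty annotation set")
    if not (1 <= min_term <= max_term):
        raise ValueError("need 1 <= min_term <= max_term")
    uni = universe if universe is not None else ann.genes
    gene_terms: dict[str, set[str]] = {}
    for t in ann:
        for g in t.genes:
            if g in uni:
                gene_terms.setdefault(g, set()).add(t.term_id)

    positives: set[Pair] = set()
    for t in ann:
        genes = sorted(g for g in t.genes if g in uni)
        if not (min_term <= len(t.genes) <= max_term):
            continue
        positives.update(itertools.combinations(genes, 2))

    negatives: set[Pair] = set()
    annotated = sorted(gene_terms)
    for ga, gb in itertools.combinations(annotated, 2):
        pair = (ga, gb)
        if pair in positives:
            continue
        if gene_terms[ga].isdisjoint(gene_terms[gb]):
            negatives.add(pair)
    return GoldStandard(frozenset(positives), frozenset(negatives))


@dataclass(frozen=True)
class CalibrationBin:
    lower: float  # lowest raw score observed in the bin
    upper: float  # highest raw score observed in the bin
    n_pos: int
    n_neg: int
    lls: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Raw-score bins with per-bin log-likelihood scores (ascending order)."""

    evidence_code: str
    bins: tuple[CalibrationBin, ...]
    prior_pos: int
    prior_neg: int

    def lookup(self, raw_score: float) -> float:
        """LLS of the bin containing ``raw_score`` (clamped at the extremes)."""
        if not self.bins:
            raise ValueError("empty calibration curve")
        for b in reversed(self.bins):
            if raw_score >= b.lower:
                return b.lls
        return self.bins[0].lls


def _bin_lls(n_pos: int, n_neg: int, prior_pos: int, prior_neg: int) -> float:
    # add-one smoothing only when a class count is empty
    if n_pos == 0 or n_neg == 0:
        n_pos, n_neg = n_pos + 1, n_neg + 1
    return math.log((n_pos / n_neg) / (prior_pos / prior_neg))


class LLSCalibrator(BaseEstimator):
    """Maps raw evidence scores to log-likelihood scores by gold-standard binning.

    Parameters
    ----------
    n_bins : int
        Maximum number of equal-frequency bins over the scored gold pairs.
    min_bin_count : int
        Minimum number of gold pairs per bin; thinner bins are merged
        downward from the top of the score range.

    Attributes (after fit)
    ----------------------
    curve_ : CalibrationCurve
    prior_pos_, prior_neg_ : int
        Gold positives/negatives among the pairs the evidence scores.
    """

    def __init__(self, n_bins: int = 10, min_bin_count: int = 10) -> None:
        self.n_bins = n_bins
        self.min_bin_count = min_bin_count

    def fit(self, pairs: ScoredPairSet, gold: GoldStandard) -> "LLSCalibrator":
        if self.n_bins < 1 or self.min_bin_count < 1:
            raise ValueError("n_bins and min_bin_count must be >= 1")
        labeled: list[tuple[float, Pair, int]] = []
        for pair, score in pairs.items():
            if pair in gold.positives:
                labeled.append((score, pair, 1))
            elif pair in gold.negatives:
                labeled.append((score, pair, -1))
        if len(labeled) < self.min_bin_count:
            raise ValueError(
                "insufficient gold-standard coverage: "
                f"{len(labeled)} scorable gold pairs < min_bin_count={self.min_bin_count}"
            )
        prior_pos = sum(1 for _, _, lab in labeled if lab == 1)
        prior_neg = len(labeled) - prior_pos
        if prior_pos == 0 or prior_neg == 0:
            raise ValueError("gold pairs scorable by this evidence are all one class")

        # descending raw score; ties broken by pair id for determinism
        labeled.sort(key=lambda t: (-t[0], t[1]))
        chunks = [list(c) for c in np.array_split(np.arange(len(labeled)), self.n_bins) if len(c)]
        # merge thin bins downward, starting from the top of the score range
        merged: list[list[int]] = []
        for c in chunks:
            if merged and len(merged[-1]) < self.min_bin_count:
                merged[-1].extend(c)
            else:
                merged.append(list(c))
        if len(merged) > 1 and len(merged[-1]) < self.min_bin_count:
            merged[-2].extend(merged.pop())

        bins: list[CalibrationBin] = []
        for idx in merged:  # high scores first
            scores = [labeled[i][0] for i in idx]
            n_pos = sum(1 for i in idx if labeled[i][2] == 1)
            n_neg = len(idx) - n_pos
            bins.append(
                CalibrationBin(
                    lower=min(scores),
                    upper=max(scores),
                    n_pos=n_pos,
                    n_neg=n_neg,
                    lls=_bin_lls(n_pos, n_neg, prior_pos, prior_neg),
                )
            )
        bins.reverse()  # ascending raw score
        self.curve_ = CalibrationCurve(pairs.evidence_code, tuple(bins), prior_pos, prior_neg)
        self.prior_pos_ = prior_pos
        self.prior_neg_ = prior_neg
        return self

    def transform(self, pairs: ScoredPairSet) -> GeneNetwork:
        """Calibrated network: every pair gets its bin's LLS; LLS <= 0 dropped."""
        curve = getattr(self, "curve_", None)
        if curve is None:
            raise ValueError("calibrator is not fitted")
        if pairs.evidence_code != curve.evidence_code:
            raise ValueError(
                f"curve was fitted for {curve.evidence_code}, got {pairs.evidence_code}"
            )
        net = GeneNetwork()
        for (a, b), score in pairs.items():
            lls = curve.lookup(score)
            if lls > 0:
                net.add(a, b, lls)
        return net

    def fit_transform(self, pairs: ScoredPairSet, gold: GoldStandard) -> GeneNetwork:
        return self.fit(pairs, gold).transform(pairs)


def calibrate_lls(
    pairs: ScoredPairSet,
    gold: GoldStandard,
    n_bins: int = 10,
    min_bin_count: int = 10,
) -> CalibrationCurve:
    """Functional wrapper around :class:`LLSCalibrator`.fit."""
    return LLSCalibrator(n_bins=n_bins, min_bin_count=min_bin_count).fit(pairs, gold).curve_


def apply_calibration(pairs: ScoredPairSet, curve: CalibrationCurve) -> GeneNetwork:
    """Functional wrapper around :class:`LLSCalibrator`.transform."""
    cal = LLSCalibrator()
    cal.curve_ = curve
    return cal.transform(pairs)


@dataclass(frozen=True)
class IntegrationParams:
    """Free parameters of the weighted-sum integration."""

    D: float = 1.0  # degradation divisor (>= 1)
    T: float = 0.0  # minimum component LLS admitted to the sum (nats)

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("degradation divisor D must be >= 1")
        if not math.isfinite(self.T):
            raise ValueError("cutoff T must be finite")


class WeightedSumIntegrator(BaseEstimator):
    """Integrates calibrated component networks by rank-discounted weighted sum.

    ``fit`` with a gold standard and parameter grids performs an exhaustive
    grid search maximizing the integrated network's PR-AUC; without grids it
    simply freezes the supplied (D, T).  Ties break toward larger D, then
    larger T.
    """

    def __init__(
        self,
        D: float = 1.0,
        T: float = 0.0,
        D_grid: Sequence[float] | None = None,
        T_grid: Sequence[float] | None = None,
    ) -> None:
        self.D = D
        self.T = T
        self.D_grid = D_grid
        self.T_grid = T_grid

    def fit(
        self,
        nets: Sequence[GeneNetwork],
        gold: GoldStandard | None = None,
    ) -> "WeightedSumIntegrator":
        if not nets:
            raise ValueError("need at least one component network")
        if self.D_grid is not None and self.T_grid is not None:
            if gold is None:
                raise ValueError("grid search requires a gold standard")
            if not self.D_grid or not self.T_grid:
                raise ValueError("parameter grids must be non-empty")
            best: tuple[float, IntegrationParams] | None = None
            for D in sorted(self.D_grid):
                for T in sorted(self.T_grid):
                    integrated = _weighted_sum(nets, IntegrationParams(D, T))
                    try:
                        score = pr_auc(integrated, gold)
                    except ValueError:
                        continue  # no gold-labeled edge survives this T
                    if best is None or score >= best[0]:
                        best = (score, IntegrationParams(D, T))
            if best is None:
                raise ValueError("gold standard not scorable by any component/grid point")
            self.params_ = best[1]
            self.pr_auc_ = best[0]
        else:
            self.params_ = IntegrationParams(self.D, self.T)
        return self

    def transform(self, nets: Sequence[GeneNetwork]) -> GeneNetwork:
        params = getattr(self, "params_", None) or IntegrationParams(self.D, self.T)
        return _weighted_sum(nets, params)

    def fit_transform(
        self, nets: Sequence[GeneNetwork], gold: GoldStandard | None = None
    ) -> GeneNetwork:
        return self.fit(nets, gold).transform(nets)


def _weighted_sum(nets: Sequence[GeneNetwork], params: IntegrationParams) -> GeneNetwork:
    if not nets:
        raise ValueError("need at least one component network")
    per_pair: dict[Pair, list[float]] = {}
    for net in nets:
        for pair, w in net.items():
            if w >= params.T:
                per_pair.setdefault(pair, []).append(w)
    out = GeneNetwork()
    for (a, b), scores in per_pair.items():
        scores.sort(reverse=True)
        ws = scores[0] + sum(s / (params.D * i) for i, s in enumerate(scores[1:], start=1))
        out.add(a, b, ws)
    return out


def integrate_weighted_sum(
    nets: Sequence[GeneNetwork],
    params: IntegrationParams | None = None,
) -> GeneNetwork:
    """Functional wrapper around :class:`WeightedSumIntegrator`.transform."""
    return _weighted_sum(nets, params or IntegrationParams())


def optimize_integration_params(
    nets: Sequence[GeneNetwork],
    gold: GoldStandard,
    D_grid: Sequence[float],
    T_grid: Sequence[float],
) -> IntegrationParams:
    """Grid search for (D, T) maximizing PR-AUC on the gold standard."""
    integ = WeightedSumIntegrator(D_grid=list(D_grid), T_grid=list(T_grid)).fit(nets, gold)
    return integ.params_


# ---------------------------------------------------------------------------
# Curve serialization (TSV: lower, upper, n_pos, n_neg, lls)


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#evidence_code={curve.evidence_code}\t"
                 f"prior_pos={curve.prior_pos}\tprior_neg={curve.prior_neg}\n")
        fh.write("#lower\tupper\tn_pos\tn_neg\tlls\n")
        for b in curve.bins:
            fh.write(f"{b.lower:.6g}\t{b.upper:.6g}\t{b.n_pos}\t{b.n_neg}\t{b.lls:.6g}\n")


def read_curve(path: str | Path) -> CalibrationCurve:
    code = "XFER"
    prior_pos = prior_neg = 0
    bins: list[CalibrationBin] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#evidence_code="):
                parts = dict(p.split("=", 1) for p in line[1:].split("\t"))
                code = parts["evidence_code"]
                prior_pos = int(parts["prior_pos"])
                prior_neg = int(parts["prior_neg"])
            elif line.startswith("#") or not line:
                continue
            else:
                lo, hi, npos, nneg, lls = line.split("\t")
                bins.append(CalibrationBin(float(lo), float(hi), int(npos), int(nneg), float(lls)))
    return CalibrationCurve(code, tuple(bins), prior_pos, prior_neg)
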