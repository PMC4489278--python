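"""Seeded toy-data generators with planted co-functional structure.

Real inputs to the pipeline (expression atlases, literature incidence,
domain assignments, phylogenetic profiles, gene order in reference
genomes) all share one latent property: genes working in the same pathway
leave correlated traces in each of them.  These generators plant that
structure explicitly — a partition of genes into functional modules — and
emit every input format the pipeline consumes, so calibration, integration
and prioritization can be exercised and checked end to end at desk scale
with no downloads.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evidence as ev
from .calibrate import LLSCalibrator, WeightedSumIntegrator, derive_gold_standard
from .types import (
    AnnotationSet,
    AnnotationTerm,
    ExpressionBundle,
    GeneNetwork,
    GoldStandard,
    OrthologMap,
    ScoredPairSet,
)

DEFAULT_STAGES = ["embryo", "larva", "pupa", "adult"]
DEFAULT_TISSUES = [
    "accessory_gland", "carcass", "cns", "digestive_system", "fat_body",
    "head", "imaginal_disc", "ovary", "salivary_gland", "testis",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the planted-module toy world.

    Defaults are sized for fast test runs: 300 genes in 10 modules of 20,
    dense within-module connectivity (p_in = 0.3) over sparse background
    (p_out = 0.01), 42 expression samples covering 4 developmental stages
    and 10 tissues (3 samples per context), and mild Gaussian expression
    noise relative to the latent profile spread.
    """

    n_genes: int = 300
    n_modules: int = 10
    module_size: int = 20
    p_in: float = 0.3
    p_out: float = 0.01
    n_samples: int = 42
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules cannot exceed the gene count")
        for p in (self.p_in, self.p_out):
            if not 0 <= p <= 1:
                raise ValueError("edge probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gene_names(spec: SynthSpec) -> list[str]:
    return [f"g{i:04d}" for i in range(spec.n_genes)]


def module_membership(spec: SynthSpec) -> dict[str, int | None]:
    """gene -> module index (None for background genes)."""
    names = gene_names(spec)
    members: dict[str, int | None] = {}
    for i, g in enumerate(names):
        m = i // spec.module_size
        members[g] = m if m < spec.n_modules else None
    return members


def gen_modular_network(spec: SynthSpec) -> tuple[GeneNetwork, dict[str, int | None]]:
    """Planted-partition network: p_in within modules, p_out elsewhere.

    Edge weights are Uniform(0.5, 3.0).
    """
    rng = np.random.default_rng(spec.seed)
    names = gene_names(spec)
    members = module_membership(spec)
    mvec = np.array([-1 if members[g] is None else members[g] for g in names])
    n = spec.n_genes
    iu, ju = np.triu_indices(n, k=1)
    same = (mvec[iu] == mvec[ju]) & (mvec[iu] >= 0)
    prob = np.where(same, spec.p_in, spec.p_out)
    keep = rng.random(iu.size) < prob
    weights = rng.uniform(0.5, 3.0, size=iu.size)
    net = GeneNetwork()
    for i, j, w in zip(iu[keep], ju[keep], weights[keep]):
        net.add(names[i], names[j], float(w))
    return net, members


def gen_expression(
    membership: Mapping[str, int | None],
    spec: SynthSpec,
    silenced: Mapping[int, Sequence[str]] | None = None,
) -> ExpressionBundle:
    """Module-correlated expression over 4 stages + 10 tissues (round-robin).

    Each module follows a latent per-sample profile Uniform(2, 8); members
    observe it plus Normal(0, noise_sd) noise, clipped non-negative.
    Background genes get independent profiles.  ``silenced`` maps a module
    index to context labels in which its members are set to zero expression
    (below any sensible BPKM threshold), planting STN specificity.
    """
    if spec.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(spec.seed + 1)
    contexts = [(s, "stage") for s in DEFAULT_STAGES] + [(t, "tissue") for t in DEFAULT_TISSUES]
    genes = sorted(membership)
    samples = [f"s{i:03d}" for i in range(spec.n_samples)]
    context_map = {s: contexts[i % len(contexts)] for i, s in enumerate(samples)}

    latent = rng.uniform(2.0, 8.0, size=(spec.n_modules, spec.n_samples))
    values = np.empty((len(genes), spec.n_samples))
    for gi, g in enumerate(genes):
        m = membership[g]
        base = latent[m] if m is not None else rng.uniform(2.0, 8.0, size=spec.n_samples)
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_samples) if spec.noise_sd > 0 else 0.0
        values[gi] = np.clip(base + noise, 0.0, None)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    if silenced:
        for module, labels in silenced.items():
            mgenes = [g for g in genes if membership[g] == module]
            for label in labels:
                cols = [s for s in samples if context_map[s][0] == label]
                matrix.loc[mgenes, cols] = 0.0
    return ExpressionBundle(matrix, context_map)


def gen_annotations(
    membership: Mapping[str, int | None],
    coverage: float = 0.8,
    seed: int = 0,
) -> AnnotationSet:
    """One gold term per module plus a disjoint validation term.

    The gold term ``M<k>_gold`` holds floor(coverage * module_size) randomly
    chosen members; the validation term ``M<k>_val`` holds the remaining
    members (dropped when empty).  Gold standards should be derived from
    the ``*_gold`` terms only, leaving the validation genes unannotated.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    modules: dict[int, list[str]] = {}
    for g in sorted(membership):
        m = membership[g]
        if m is not None:
            modules.setdefault(m, []).append(g)
    ann = AnnotationSet()
    for m, genes in sorted(modules.items()):
        k = math.floor(coverage * len(genes))
        chosen = sorted(rng.choice(genes, size=k, replace=False)) if k else []
        rest = sorted(set(genes) - set(chosen))
        if chosen:
            ann.add(AnnotationTerm(f"M{m:02d}_gold", f"module {m} (gold subset)",
                                   "other", frozenset(chosen)))
        if rest:
            ann.add(AnnotationTerm(f"M{m:02d}_val", f"module {m} (held-out subset)",
                                   "other", frozenset(rest)))
    return ann


def gold_annotation_terms(ann: AnnotationSet) -> AnnotationSet:
    """The ``*_gold`` subset of a generated annotation set."""
    return ann.subset([t for t in ann.term_ids if t.endswith("_gold")])


def gen_evidence_bundle(
    membership: Mapping[str, int | None],
    spec: SynthSpec,
) -> dict[str, ScoredPairSet]:
    """Module-correlated evidence layers plus one pure-noise layer.

    CX comes from :func:`gen_expression`; CC/DC/PG/GN from module-correlated
    incidence tables (shared documents, shared domains, shared phylogenetic
    profiles, clustered gene order); the HT layer is random scores on a
    dense random 40% subset of all pairs, independent of the modules — a
    negative control whose calibrated LLS should hover near zero.
    """
    genes = sorted(membership)
    layers: dict[str, ScoredPairSet] = {}

    # CX: Pearson correlation of the module-correlated expression matrix
    bundle = gen_expression(membership, spec)
    layers["CX"] = ev.infer_coexpression(bundle)

    # CC: module-specific documents + random background citations
    rng = np.random.default_rng(spec.seed + 2)
    n_bg_docs = 100
    docs: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        m = membership[g]
        if m is not None:
            for d in range(6):
                if rng.random() < 0.6:
                    docs[g].add(f"doc_m{m:02d}_{d}")
        for d in rng.choice(n_bg_docs, size=3, replace=False):
            docs[g].add(f"doc_bg_{d:03d}")
    corpus = 6 * spec.n_modules + n_bg_docs
    layers["CC"] = ev.infer_cocitation(ev.DocIncidence(docs, corpus))

    # DC: module-specific domains + random background domains
    rng = np.random.default_rng(spec.seed + 3)
    n_bg_domains = 50
    domains: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        m = membership[g]
        if m is not None:
            for d in range(3):
                if rng.random() < 0.7:
                    domains[g].add(f"dom_m{m:02d}_{d}")
        for d in rng.choice(n_bg_domains, size=2, replace=False):
            domains[g].add(f"dom_bg_{d:02d}")
    universe = 3 * spec.n_modules + n_bg_domains
    layers["DC"] = ev.infer_domain_cooccurrence(ev.DomainTable(domains, universe))

    # PG: members share a module profile with a 10% flip rate
    rng = np.random.default_rng(spec.seed + 4)
    n_genomes = 24
    module_profiles = rng.integers(0, 2, size=(spec.n_modules, n_genomes))
    profiles: dict[str, np.ndarray] = {}
    for g in genes:
        m = membership[g]
        if m is not None:
            flips = rng.random(n_genomes) < 0.1
            profiles[g] = np.where(flips, 1 - module_profiles[m], module_profiles[m])
        else:
            profiles[g] = rng.integers(0, 2, size=n_genomes)
    layers["PG"] = ev.infer_phylo_profile(
        ev.ProfileMatrix(profiles, [f"genome_{i:02d}" for i in range(n_genomes)])
    )

    # GN: per reference genome, present module members sit in contiguous blocks
    rng = np.random.default_rng(spec.seed + 5)
    nbr = ev.NeighborhoodTable()
    for gi in range(8):
        genome = f"ref_{gi}"
        present = [g for g in genes if rng.random() < 0.6]
        blocks: dict[int, list[str]] = {}
        background: list[str] = []
        for g in present:
            m = membership[g]
            if m is None:
                background.append(g)
            else:
                blocks.setdefault(m, []).append(g)
        order: list[str] = []
        for m in rng.permutation(sorted(blocks)):
            block = blocks[int(m)]
            order.extend(np.array(block)[rng.permutation(len(block))])
        order.extend(np.array(background)[rng.permutation(len(background))]
                     if background else [])
        for pos, g in enumerate(order):
            nbr.add(genome, str(g), pos)
    layers["GN"] = ev.infer_gene_neighborhood(nbr, window=1)

    # HT stand-in: pure noise, dense enough to calibrate stably
    rng = np.random.default_rng(spec.seed + 6)
    noise = ScoredPairSet("HT")
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < 0.4
    scores = rng.random(iu.size)
    for i, j, s in zip(iu[keep], ju[keep], scores[keep]):
        noise.add(genes[i], genes[j], float(s))
    layers["HT"] = noise
    return layers


def gen_orthologs(
    genes: Sequence[str],
    dup_fraction: float = 0.0,
    seed: int = 0,
) -> OrthologMap:
    """Identity-like source->target ortholog map with optional duplications.

    Every gene g maps to ``H_<g>``; a seeded ``dup_fraction`` of genes get a
    second target ortholog ``H_<g>_b`` (exercising many-to-many paths).
    """
    if not 0 <= dup_fraction <= 1:
        raise ValueError("dup_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    omap = OrthologMap()
    ordered = sorted(genes)
    n_dup = round(dup_fraction * len(ordered))
    dup = set(rng.choice(ordered, size=n_dup, replace=False)) if n_dup else set()
    for g in ordered:
        omap.add(g, f"H_{g}")
        if g in dup:
            omap.add(g, f"H_{g}_b")
    return omap


@dataclass
class RecoveryFixture:
    """Everything needed to exercise the pipeline end to end on one seed."""

    spec: SynthSpec
    membership: dict[str, int | None]
    layers: dict[str, ScoredPairSet]
    annotations: AnnotationSet
    gold: GoldStandard
    component_nets: dict[str, GeneNetwork]
    integrated: GeneNetwork


def recovery_fixture(
    spec: SynthSpec,
    n_bins: int = 10,
    min_bin_count: int = 10,
    D: float = 1.0,
    T: float = 0.0,
) -> RecoveryFixture:
    """Generate evidence, calibrate each layer and integrate, on one seed."""
    membership = module_membership(spec)
    layers = gen_evidence_bundle(membership, spec)
    ann = gen_annotations(membership, coverage=0.8, seed=spec.seed + 7)
    gold = derive_gold_standard(gold_annotation_terms(ann), min_term=3, max_term=500)
    nets: dict[str, GeneNetwork] = {}
    for code, pairs in layers.items():
        try:
            nets[code] = LLSCalibrator(n_bins=n_bins, min_bin_count=min_bin_count).fit_transform(pairs, gold)
        except ValueError:
            continue  # layer covers too few gold pairs on this seed
    integrated = WeightedSumIntegrator(D=D, T=T).fit([*nets.values()]).transform([*nets.values()])
    return RecoveryFixture(spec, membership, layers, ann, gold, nets, integrated)
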