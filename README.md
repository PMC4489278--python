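# cofunnet

Co-functional gene network construction, calibration and network-based
prioritization of genes, functions and disease candidates.

## The problem

Genome-scale screens are expensive and noisy; network prioritization makes
them cheaper by ranking candidate genes through *guilt by association* on a
functional gene network.  Heterogeneous observations — co-expression across
samples, co-citation in the literature, shared protein domains, conserved
chromosomal neighborhood, phylogenetic co-occurrence, protein interactions,
networks transferred from other species by orthology — each hint that two
genes act in the same biological process, but on incomparable scales.
`cofunnet` turns such evidence into a single weighted network and runs a
full prioritization and assessment battery on it.  It is written for
computational biologists who have (or can simulate) pairwise evidence and
want a calibrated, testable pipeline rather than a web service.

## The model

**Calibration.**  Each evidence layer produces raw pairwise scores
(Pearson *r*, −log₁₀ hypergeometric tails, mutual information, co-adjacency
fractions, …).  Against a gold standard of positive pairs *L* (co-annotated
to a pathway term) and negative pairs (annotated, sharing nothing), scored
gold pairs are cut into equal-frequency raw-score bins and each bin *E*
receives a log-likelihood score in nats:

```
LLS = ln[ (P(L|E) / ¬P(L|E)) / (P(L) / ¬P(L)) ]
```

**Integration.**  For each gene pair, component scores passing a cutoff *T*
are sorted L₀ ≥ L₁ ≥ … and combined by a rank-discounted weighted sum with
degradation divisor *D* ≥ 1 (a modified naive-Bayes combination that damps
correlated evidence):

```
WS = L0 + Σ_{i≥1} Li / (D · i)
```

**Prioritization.**  Guide genes define a trait; candidates are ranked by
the *direct neighborhood* score (summed edge weights to guides) or by
*network diffusion* — Gaussian-field label propagation solving
`(I − αS) f = y` with `S = D⁻¹ᐟ² W D⁻¹ᐟ²`.  Retrieval of the guides
themselves, summarized as an ROC AUC, estimates how predictable the trait
is.  Spatiotemporal-specific networks (STNs) keep only edges whose
endpoints are expressed (mean BPKM > 1) in a developmental stage or
tissue; neighbor counts across STNs localize a trait in space and time.  A
disease prioritizer maps guide genes through an ortholog table, ranks on
the model-organism network, and reports candidates back in the disease
namespace, optionally intersected with *support genes* from human genetics
into a high-confidence first tier.

The evaluation battery covers precision–recall curves over gold pairs,
rank-sum ROC/AUC, top-k discovery rates with fold enrichment,
hypergeometric gene-set enrichment with Benjamini–Hochberg correction,
degree-preserving random networks, and the paired Wilcoxon signed-rank
test.

## Worked example

Everything is runnable offline from the seeded synthetic generator, which
plants 10 functional modules of 20 genes among 300 and emits every
evidence type the pipeline consumes:

```python
from cofunnet import synthdata as sd
from cofunnet import prioritize as pri, evaluate as evl

fix = sd.recovery_fixture(sd.SynthSpec(seed=7))   # generate + calibrate + integrate
for code, net in fix.component_nets.items():
    print(f"PR-AUC {code}: {evl.pr_auc(net, fix.gold):.3f}")
print(f"PR-AUC integrated: {evl.pr_auc(fix.integrated, fix.gold):.3f}")

module = sorted(g for g, m in fix.membership.items() if m == 4)
res = pri.prioritize_genes(fix.integrated, set(module[:10]), algorithm="diffusion")
print(f"guide-retrieval AUC: {res.auc:.3f}")
print("top 5 candidates:", res.candidates[:5])
```

prints

```
PR-AUC CX: 0.928
PR-AUC CC: 0.685
PR-AUC DC: 0.560
PR-AUC PG: 0.687
PR-AUC GN: 0.250
PR-AUC HT: 0.029
PR-AUC integrated: 1.000
guide-retrieval AUC: 1.000
top 5 candidates: ['g0093', 'g0097', 'g0092', 'g0090', 'g0091']
```

Co-expression (CX) is the strongest single layer (PR-AUC 0.928), the
module-blind noise layer (HT) is uninformative (0.029), and the calibrated
weighted sum recovers the planted pathway structure essentially perfectly
(1.000).  Seeding half of module 4 as guides, all five top-ranked
candidates — and in fact the entire top 10 — are the held-out members of
the same module.

The same pipeline is available from the shell:

```
cofunnet simulate all --seed 7 --out toy/
cofunnet calibrate gold --gmt toy/annotations.gmt --out gold.tsv
cofunnet calibrate lls --pairs toy/evidence_cx.tsv --code CX --gold gold.tsv --out cx.curve.tsv
cofunnet calibrate apply --pairs toy/evidence_cx.tsv --curve cx.curve.tsv --out cx.net.tsv
cofunnet calibrate integrate --nets cx.net.tsv --out net.tsv
cofunnet prioritize genes --net net.tsv --guides guides.txt --algorithm diffusion --out ranked.tsv
```

All commands are byte-deterministic for a given seed.

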