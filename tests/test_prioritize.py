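import numpy as np
import pandas as pd
import pytest

from cofunnet import prioritize as pri
from cofunnet.types import (
    AnnotationSet,
    AnnotationTerm,
    ExpressionBundle,
    GeneNetwork,
    OrthologMap,
)


def _random_net(n_nodes: int, p: float, seed: int) -> GeneNetwork:
    rng = np.random.default_rng(seed)
    net = GeneNetwork()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                net.add(f"g{i:03d}", f"g{j:03d}", float(rng.uniform(0.2, 3.0)))
    # make sure nothing is isolated
    for i in range(n_nodes - 1):
        if net.get(f"g{i:03d}", f"g{i+1:03d}") is None:
            net.add(f"g{i:03d}", f"g{i+1:03d}", 0.2)
    return net


class TestDirectNeighborhood:
    def test_sum_of_guide_edge_weights(self):
        net = GeneNetwork([("c", "g1", 1.5), ("c", "g2", 2.5), ("c", "x", 9.0)])
        scores = pri.score_direct_neighborhood(net, {"g1", "g2"})
        assert scores["c"] == pytest.approx(4.0)

    def test_gene_without_guide_neighbors_scores_zero(self):
        net = GeneNetwork([("c", "g1", 1.0), ("x", "y", 5.0)])
        scores = pri.score_direct_neighborhood(net, {"g1"})
        assert scores["x"] == 0.0 and scores["y"] == 0.0

    def test_single_guide_self_exclusion(self):
        net = GeneNetwork([("g1", "n1", 1.3), ("g1", "n2", 0.7)])
        scores = pri.score_direct_neighborhood(net, {"g1"})
        assert scores["g1"] == 0.0
        assert scores["n1"] == pytest.approx(1.3) and scores["n2"] == pytest.approx(0.7)

    def test_guides_scored_against_other_guides(self):
        net = GeneNetwork([("g1", "g2", 2.0), ("g1", "n1", 1.0)])
        scores = pri.score_direct_neighborhood(net, {"g1", "g2"})
        assert scores["g1"] == pytest.approx(2.0) and scores["g2"] == pytest.approx(2.0)

    def test_no_guide_in_network_is_error(self):
        net = GeneNetwork([("a", "b", 1.0)])
        with pytest.raises(ValueError, match="zz"):
            pri.score_direct_neighborhood(net, {"zz"})


class TestNetworkDiffusion:
    def test_two_node_closed_form(self):
        # single edge a-b (w=1), guide {a}, alpha=0.5:
        # S = [[0,1],[1,0]], (I - 0.5 S)^-1 [1,0] = [4/3, 2/3]
        net = GeneNetwork([("a", "b", 1.0)])
        f = pri.score_network_diffusion(net, {"a"}, alpha=0.5)
        assert f["a"] == pytest.approx(4 / 3, abs=1e-10)
        assert f["b"] == pytest.approx(2 / 3, abs=1e-10)

    def test_empty_guide_set_all_zero(self):
        net = GeneNetwork([("a", "b", 1.0)])
        f = pri.score_network_diffusion(net, set())
        assert set(f.values()) == {0.0}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_iterative_matches_exact_solver(self, seed):
        net = _random_net(50, 0.08, seed)
        guides = set(sorted(net.genes)[:5])
        exact = pri.score_network_diffusion(net, guides, alpha=0.8, solver="exact")
        iterative = pri.score_network_diffusion(net, guides, alpha=0.8, tol=1e-10,
                                                solver="iterative")
        for g in net.genes:
            assert iterative[g] == pytest.approx(exact[g], abs=1e-6)

    def test_matches_dense_linear_solve_oracle(self):
        """Independent oracle: assemble the dense system with plain numpy."""
        net = _random_net(100, 0.05, seed=9)
        guides = set(sorted(net.genes)[:8])
        alpha = 0.9
        nodes = sorted(net.genes)
        idx = {g: i for i, g in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for (a, b), w in net.items():
            W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
        d = W.sum(axis=1)
        S = W / np.sqrt(np.outer(d, d))
        y = np.array([1.0 if g in guides else 0.0 for g in nodes])
        expected = np.linalg.solve(np.eye(len(nodes)) - alpha * S, y)
        f = pri.score_network_diffusion(net, guides, alpha=alpha)
        for g in nodes:
            assert f[g] == pytest.approx(expected[idx[g]], abs=1e-6)

    def test_residual_below_tolerance(self):
        net = _random_net(40, 0.1, seed=4)
        guides = set(sorted(net.genes)[:4])
        ranker = pri.NetworkDiffusionRanker(alpha=0.9, tol=1e-9, solver="iterative").fit(net)
        f = ranker.score_genes(guides)
        fv = np.array([f[g] for g in ranker.nodes_])
        y = np.array([1.0 if g in guides else 0.0 for g in ranker.nodes_])
        residual = fv - (0.9 * (ranker.S_ @ fv) + y)
        assert np.max(np.abs(residual)) < 1e-8

    def test_invalid_alpha_rejected(self):
        net = GeneNetwork([("a", "b", 1.0)])
        with pytest.raises(ValueError, match="alpha"):
            pri.score_network_diffusion(net, {"a"}, alpha=1.5)


class TestPrioritizeGenes:
    def test_guide_clique_perfect_auc(self):
        net = GeneNetwork([("g1", "g2", 2.0), ("g1", "g3", 2.0), ("g2", "g3", 2.0),
                           ("x", "y", 1.0)])
        res = pri.prioritize_genes(net, {"g1", "g2", "g3"}, algorithm="direct")
        assert res.auc == 1.0

    def test_all_scores_equal_gives_half_auc(self):
        # symmetric construction: guides a,b and candidates x,y all score 1.0
        net = GeneNetwork([("a", "b", 1.0), ("a", "x", 1.0), ("b", "y", 1.0)])
        res = pri.prioritize_genes(net, {"a", "b"}, algorithm="direct")
        assert res.auc == 0.5

    def test_ranks_follow_descending_score_with_id_ties(self):
        net = GeneNetwork([("g", "b", 1.0), ("g", "a", 1.0), ("g", "c", 2.0)])
        res = pri.prioritize_genes(net, {"g"}, algorithm="direct")
        order = [r.gene for r in res.records]
        assert order.index("c") < order.index("a") < order.index("b")
        assert [r.rank for r in res.records] == list(range(1, len(order) + 1))

    def test_planted_module_enrichment_beats_permutation(self, recovery):
        """Held-out module members concentrate in the top ranks far beyond a
        degree-blind random baseline."""
        fix = recovery
        mod = sorted(g for g, m in fix.membership.items() if m == 3)
        guides, held = set(mod[:10]), set(mod[10:])
        res = pri.prioritize_genes(fix.integrated, guides, algorithm="direct")
        top20 = set(res.candidates[:20])
        observed = len(top20 & held)
        rng = np.random.default_rng(0)
        null_hits = [
            len(set(rng.choice(res.candidates, 20, replace=False)) & held)
            for _ in range(200)
        ]
        assert observed > np.percentile(null_hits, 99)

    def test_absent_guides_ignored_with_valid_result(self):
        net = GeneNetwork([("g1", "c", 1.0)])
        res = pri.prioritize_genes(net, {"g1", "missing"}, algorithm="direct")
        assert {r.gene for r in res.records} == {"g1", "c"}


class TestPrioritizeFunctions:
    def _ann(self):
        return AnnotationSet([
            AnnotationTerm("T1", "", "GO-BP", frozenset({"n1", "n2"})),
            AnnotationTerm("T2", "", "GO-BP", frozenset({"n2"})),
            AnnotationTerm("T3", "", "GO-BP", frozenset({"q"})),
        ])

    def test_summed_neighbor_weights(self):
        net = GeneNetwork([("q", "n1", 2.0), ("q", "n2", 1.0)])
        ranked = pri.prioritize_functions(net, "q", self._ann())
        assert ranked[0] == ("T1", pytest.approx(3.0))
        assert ranked[1] == ("T2", pytest.approx(1.0))

    def test_query_without_neighbors_empty(self):
        net = GeneNetwork([("q", "n1", 1.0), ("x", "y", 1.0)])
        assert pri.prioritize_functions(net, "x", AnnotationSet(
            [AnnotationTerm("T", "", "other", frozenset({"q"}))])) == []

    def test_self_annotation_excluded(self):
        net = GeneNetwork([("q", "n1", 2.0)])
        ranked = pri.prioritize_functions(net, "q", self._ann())
        assert all(t != "T3" for t, _ in ranked)

    def test_query_absent_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            pri.prioritize_functions(GeneNetwork([("a", "b", 1.0)]), "zz", self._ann())

    def test_term_score_bounded_by_direct_neighborhood(self):
        net = GeneNetwork([("q", "n1", 2.0), ("q", "n2", 1.0), ("q", "n3", 4.0)])
        ann = self._ann()
        ranked = dict(pri.prioritize_functions(net, "q", ann))
        for term_id, score in ranked.items():
            guides = set(ann[term_id].genes)
            direct = pri.score_direct_neighborhood(net, guides & net.genes)["q"]
            assert score <= direct + 1e-12


def _stn_bundle(values: dict[str, dict[str, float]], contexts: dict[str, tuple[str, str]]):
    samples = sorted(contexts)
    matrix = pd.DataFrame({s: [values[g][s] for g in sorted(values)] for s in samples},
                          index=sorted(values))
    return ExpressionBundle(matrix, contexts)


class TestSTN:
    def test_edge_kept_when_both_expressed(self):
        bundle = _stn_bundle(
            {"a": {"s1": 2.0}, "b": {"s1": 2.0}},
            {"s1": ("embryo", "stage")},
        )
        stns = pri.build_stns(GeneNetwork([("a", "b", 1.0)]), bundle, threshold=1.0)
        assert stns.networks["embryo"].n_edges == 1

    def test_edge_removed_when_one_endpoint_silent(self):
        bundle = _stn_bundle(
            {"a": {"s1": 2.0}, "b": {"s1": 0.5}},
            {"s1": ("embryo", "stage")},
        )
        stns = pri.build_stns(GeneNetwork([("a", "b", 1.0)]), bundle, threshold=1.0)
        assert stns.networks["embryo"].n_edges == 0

    def test_fourteen_contexts_give_fourteen_stns(self, recovery):
        from cofunnet import synthdata as sd

        bundle = sd.gen_expression(recovery.membership, recovery.spec)
        stns = pri.build_stns(recovery.integrated, bundle)
        assert len(stns) == 14
        assert sum(1 for _, k in stns.contexts if k == "stage") == 4
        assert sum(1 for _, k in stns.contexts if k == "tissue") == 10

    def test_every_stn_subset_of_parent(self, recovery):
        from cofunnet import synthdata as sd

        bundle = sd.gen_expression(recovery.membership, recovery.spec)
        stns = pri.build_stns(recovery.integrated, bundle)
        parent = set(recovery.integrated.pair_dict)
        for label, stn in stns.networks.items():
            assert set(stn.pair_dict) <= parent

    def test_raising_threshold_never_adds_edges(self):
        bundle = _stn_bundle(
            {"a": {"s1": 2.0}, "b": {"s1": 1.5}, "c": {"s1": 3.0}},
            {"s1": ("embryo", "stage")},
        )
        net = GeneNetwork([("a", "b", 1.0), ("a", "c", 1.0)])
        low = pri.build_stns(net, bundle, threshold=1.0).networks["embryo"]
        high = pri.build_stns(net, bundle, threshold=2.0).networks["embryo"]
        assert set(high.pair_dict) <= set(low.pair_dict)


class TestSTNNeighborCounts:
    def _stns(self):
        emb = GeneNetwork([("g", "a", 1.0), ("g", "b", 1.0), ("g", "c", 1.0)])
        hd = GeneNetwork([("g", "a", 1.0), ("h", "a", 1.0)])
        return pri.STNSet(
            [("embryo", "stage"), ("head", "tissue")],
            {"embryo": emb, "head": hd},
            1.0,
        )

    def test_degree_counts(self):
        prof = pri.stn_neighbor_counts(self._stns(), {"g"})
        assert prof.counts.loc["g", "embryo"] == 3
        assert prof.counts.loc["g", "head"] == 1

    def test_zero_count_log_view(self):
        prof = pri.stn_neighbor_counts(self._stns(), {"h"})
        assert prof.counts.loc["h", "embryo"] == 0
        assert prof.log_counts.loc["h", "embryo"] == 0.0

    def test_shared_neighbor_counted_once_in_aggregate(self):
        prof = pri.stn_neighbor_counts(self._stns(), {"g", "h"})
        assert prof.unique_neighbors["head"] == 1  # 'a' shared by g and h

    def test_most_enriched_context_per_kind(self):
        prof = pri.stn_neighbor_counts(self._stns(), {"g"})
        assert prof.most_enriched == {"stage": "embryo", "tissue": "head"}


class TestPrioritizeDisease:
    def _setup(self):
        net = GeneNetwork([
            ("f_guide", "f_a", 3.0),
            ("f_guide", "f_b", 2.0),
            ("f_guide", "f_c", 1.0),
        ])
        omap = OrthologMap([
            ("H_GUIDE", "f_guide"),
            ("H_A", "f_a"), ("H_B", "f_b"), ("H_C", "f_c"),
        ])
        return net, omap

    def test_empty_support_empty_first_tier(self):
        net, omap = self._setup()
        tiers, _ = pri.prioritize_disease(net, omap, {"H_GUIDE"})
        assert tiers.first_tier == []
        assert tiers.second_tier == ["H_A", "H_B", "H_C"]

    def test_first_tier_is_support_intersection_in_rank_order(self):
        net, omap = self._setup()
        tiers, _ = pri.prioritize_disease(net, omap, {"H_GUIDE"},
                                          support_genes={"H_B", "H_ZZZ"})
        assert tiers.first_tier == ["H_B"]
        assert tiers.second_tier == ["H_A", "H_B", "H_C"]
        assert set(tiers.first_tier) == set(tiers.second_tier) & tiers.support_genes_used

    def test_human_guide_with_two_fly_orthologs_union(self):
        net = GeneNetwork([("f1", "x", 1.0), ("f2", "y", 2.0)])
        omap = OrthologMap([("H", "f1"), ("H", "f2"), ("H_X", "x"), ("H_Y", "y")])
        tiers, result = pri.prioritize_disease(net, omap, {"H"})
        guide_flags = {r.gene for r in result.records if r.is_guide}
        assert guide_flags == {"f1", "f2"}
        assert tiers.second_tier == ["H_Y", "H_X"]  # y scores 2.0 > x 1.0

    def test_fly_namespace_guides_skip_forward_mapping(self):
        net, omap = self._setup()
        tiers, _ = pri.prioritize_disease(net, omap, {"f_guide"}, guide_namespace="fly")
        assert tiers.second_tier == ["H_A", "H_B", "H_C"]

    def test_unmappable_guides_are_error(self):
        net, omap = self._setup()
        with pytest.raises(ValueError, match="no guide gene maps"):
            pri.prioritize_disease(net, omap, {"H_NOPE"})
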