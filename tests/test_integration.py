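import math

import numpy as np
import pytest

from _oracles import brute_hypergeom_sf
from capmir.diffexpr import DETestResult
from capmir.integration import (
    build_network,
    enrich_pathways,
    intersect_de_targets,
    select_de_mirnas,
    significant_pathways,
)
from capmir.io import PathwayCollection
from capmir.simulate import simulate_pathways
from capmir.targets import TargetSite


def _result(fid, log2fc, de_class):
    return DETestResult(fid, 10, 10, 100, 100, 1.0, 1.0, log2fc, 0.001, 0.0005,
                        de_class, "fold>2")


def _site(mirna, gene):
    return TargetSite(mirna, gene, 0, 22, 0.0, -20.0, "M" * 22)


class TestSelectDeMirnas:
    def test_threshold_inclusive(self):
        table = [
            _result("a", 3.2, "up"),
            _result("b", 2.9, "up"),
            _result("c", -3.0, "down"),
            _result("d", 5.0, "not_de"),
        ]
        assert select_de_mirnas(table) == {"a", "c"}

    def test_empty_table(self):
        assert select_de_mirnas([]) == set()


class TestIntersectDeTargets:
    def test_set_arithmetic_on_fixture(self):
        sites = [
            _site("m1", "g1"), _site("m1", "g2"), _site("m1", "g3"),
            _site("m2", "g1"), _site("m2", "g2"), _site("m2", "g4"),
        ]
        de_mirnas = {"m1", "m2"}
        dirs = {"m1": "up", "m2": "down"}
        degs = {"g1": "down", "g2": "up"}
        out = intersect_de_targets(sites, de_mirnas, dirs, degs)
        assert out.edges == {("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2")}
        assert out.gene_direction == degs

    def test_disjoint_sets_empty(self):
        out = intersect_de_targets([_site("m1", "g9")], {"m1"}, {"m1": "up"}, {})
        assert out.edges == frozenset()

    def test_order_invariance(self):
        sites = [_site("m1", "g1"), _site("m2", "g1")]
        a = intersect_de_targets(sites, {"m1", "m2"}, {"m1": "up", "m2": "up"},
                                 {"g1": "up"})
        b = intersect_de_targets(sites[::-1], {"m2", "m1"}, {"m2": "up", "m1": "up"},
                                 {"g1": "up"})
        assert a.edges == b.edges

    def test_non_de_mirna_excluded(self):
        out = intersect_de_targets([_site("m1", "g1")], set(), {}, {"g1": "up"})
        assert out.edges == frozenset()


class TestEnrichment:
    def test_pathway_equal_to_background_p_one(self):
        genes = {f"g{i}" for i in range(20)}
        coll = PathwayCollection({"all": frozenset(genes)})
        (res,) = enrich_pathways({"g1", "g2"}, coll, genes)
        assert res.p == pytest.approx(1.0)

    def test_matches_combinatorial_summation(self):
        genes = [f"g{i}" for i in range(100)]
        coll = PathwayCollection({"p": frozenset(genes[:10])})
        de = set(genes[:5]) | set(genes[50:55])  # k=5, K=10, n=10, N=100
        (res,) = enrich_pathways(de, coll, genes)
        assert res.k == 5 and res.K == 10 and res.n == 10 and res.N == 100
        assert res.p == pytest.approx(brute_hypergeom_sf(5, 100, 10, 10), rel=1e-12)

    def test_empty_de_targets_all_p_one(self):
        genes = [f"g{i}" for i in range(30)]
        coll = PathwayCollection(
            {"a": frozenset(genes[:10]), "b": frozenset(genes[5:20])}
        )
        results = enrich_pathways(set(), coll, genes)
        assert all(r.p == pytest.approx(1.0) for r in results)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            enrich_pathways(set(), PathwayCollection({"a": frozenset("x")}), set())

    def test_de_targets_outside_background_rejected(self):
        coll = PathwayCollection({"a": frozenset({"g1"})})
        with pytest.raises(ValueError):
            enrich_pathways({"zz"}, coll, {"g1"})

    def test_planted_enriched_pathway_ranks_first_usually(self):
        genes = [f"g{i}" for i in range(200)]
        favored = genes[:25]
        top_hits = 0
        for seed in range(20):
            coll, truth = simulate_pathways(
                genes, n_pathways=20, size_range=(15, 30), enriched_pathways=1,
                favored_genes=favored, odds=20.0, seed=seed,
            )
            results = enrich_pathways(set(favored), coll, genes)
            top_hits += results[0].pathway_id in truth.enriched
        assert top_hits >= 18

    def test_null_pathways_uniformish_p(self):
        genes = [f"g{i}" for i in range(300)]
        de = set(genes[:30])
        sig = total = 0
        for seed in range(5):
            coll, _ = simulate_pathways(genes, n_pathways=40, size_range=(10, 30),
                                        seed=100 + seed)
            results = enrich_pathways(de, coll, genes)
            sig += sum(r.p < 0.05 for r in results)
            total += len(results)
        assert sig / total <= 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / total)

    def test_significant_filter(self):
        genes = [f"g{i}" for i in range(100)]
        coll = PathwayCollection({"p": frozenset(genes[:10])})
        results = enrich_pathways(set(genes[:8]), coll, genes[:50])
        assert significant_pathways(results) == [
            r for r in results if r.p < 0.05 and r.fdr <= 0.05
        ]


class TestBuildNetwork:
    def _de_targets(self):
        sites = [_site("miR-424-5p", f"g{i}") for i in range(16)]
        sites += [_site("miR-29a", "g0"), _site("miR-29a", "g1")]
        dirs = {"miR-424-5p": "down", "miR-29a": "down"}
        degs = {f"g{i}": ("up" if i % 2 else "down") for i in range(16)}
        return intersect_de_targets(
            sites, set(dirs), dirs, degs
        )

    def test_hub_mirna_degree(self):
        net = build_network(self._de_targets())
        assert net.graph["hub_mirnas"] == ["miR-424-5p"]
        assert net.graph["hub_degree"] == 16

    def test_pathway_restriction(self):
        net = build_network(self._de_targets(), pathway_genes={"g0", "g1"})
        assert net.degree["miR-424-5p"] == 2
        assert net.degree["miR-29a"] == 2
        assert net.degree["g0"] == 2

    def test_empty_intersection_empty_network(self):
        net = build_network(self._de_targets(), pathway_genes=set())
        assert net.number_of_edges() == 0
        assert net.graph["hub_mirnas"] == []

    def test_bipartite_and_attributes(self):
        net = build_network(self._de_targets())
        for u, v in net.edges:
            assert {net.nodes[u]["kind"], net.nodes[v]["kind"]} == {"mirna", "gene"}
        assert net.nodes["miR-29a"]["direction"] == "down"

    def test_edges_traceable_to_sites_and_degs(self):
        de_targets = self._de_targets()
        net = build_network(de_targets)
        for u, v in net.edges:
            m, g = (u, v) if net.nodes[u]["kind"] == "mirna" else (v, u)
            assert (m, g) in de_targets.edges
            assert g in de_targets.gene_direction
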