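"""Mediator evidence: cis-gene enumeration, coding proxies, eQTL scoring,
shortest paths, rewiring and the permutation significance test."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pqtlkit import (
    EqtlDataset,
    GeneModel,
    NodeAbsentError,
    NodeScoreMap,
    cis_eqtl_scan,
    coding_proxy_evidence,
    enumerate_cis_genes,
    path_permutation_p,
    rewire_network,
    shortest_path,
    trans_eqtl_scores,
)
from pqtlkit.simulate import simulate_expression, simulate_genotypes

from conftest import make_gm, make_variant, path_enumeration_oracle


class TestEnumerateCisGenes:
    # distance is SNP-relative: positive when the SNP lies 3' of the gene
    ANN = [
        GeneModel("OVER", "OVER", "3", 990_000, 1_010_000),
        GeneModel("UP43", "UP43", "3", 900_000, 957_000),
        GeneModel("DOWN53", "DOWN53", "3", 1_053_000, 1_100_000),
        GeneModel("FAR", "FAR", "3", 1_700_000, 1_750_000),
        GeneModel("OTHER", "OTHER", "4", 990_000, 1_010_000),
    ]

    def test_overlap_then_distance_ranked(self):
        snp = make_variant("rsX", "3", 1_000_000)
        out = enumerate_cis_genes(snp, self.ANN, 500)
        assert [(g.symbol, round(d), r) for g, d, r in out] == [
            ("OVER", 0, 1), ("UP43", 43, 2), ("DOWN53", -53, 3),
        ]

    def test_beyond_window_empty(self):
        snp = make_variant("rsX", "5", 1_000_000)
        far = [GeneModel("G", "G", "5", 1_600_000, 1_650_000)]
        assert enumerate_cis_genes(snp, far, 500) == []


class TestCodingProxy:
    def _ld_ref(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, 3000).astype(float)
        g2 = np.where(rng.random(3000) < 0.9, g1, rng.integers(0, 3, 3000))
        g3 = rng.integers(0, 3, 3000).astype(float)
        variants = [
            make_variant("rs_idx", "1", 1_000_000),
            make_variant("rs_mis", "1", 1_100_000, missense=True),
            make_variant("rs_far_mis", "1", 1_050_000, missense=True),
        ]
        return make_gm(np.column_stack([g1, g2, g3]), variants=variants)

    def test_index_snp_itself_when_missense(self):
        gm = self._ld_ref()
        idx = make_variant("rs_idx", "1", 1_000_000, missense=True)
        variants = [idx] + gm.variants[1:]
        hit = coding_proxy_evidence(idx, variants, gm)
        assert hit[0].id == "rs_idx" and hit[1] == 1.0

    def test_ld_missense_found_above_threshold(self):
        gm = self._ld_ref()
        hit = coding_proxy_evidence(gm.variants[0], gm.variants, gm, 0.6)
        assert hit is not None and hit[0].id == "rs_mis" and hit[1] > 0.6

    def test_below_threshold_none(self):
        gm = self._ld_ref()
        hit = coding_proxy_evidence(gm.variants[0], gm.variants, gm, 0.99)
        assert hit is None


class TestEqtlScores:
    def _dataset(self, seed=1, n=200, ve=0.0, gene="G1"):
        gm = simulate_genotypes(400, [("1", 1000, 0.3)], 0.0, seed=seed)
        spec = [("rs1", gene, None, ve)] if ve else []
        datasets, _ = simulate_expression(gm, [gene], spec, {"d": n}, seed=seed)
        return gm.variants[0], datasets

    def test_strict_report_threshold(self):
        snp, datasets = self._dataset(ve=0.25)
        hits = cis_eqtl_scan(snp, "G1", datasets, eqtl_cis_p=5e-4)
        assert hits and hits[0][1] < 5e-4
        assert cis_eqtl_scan(snp, "G1", datasets, eqtl_cis_p=1e-30) == []

    def test_score_map_thresholds(self):
        scores = NodeScoreMap(scores={})
        assert scores.score("unmeasured") == 1.0
        snp, datasets = self._dataset(ve=0.2)
        m = trans_eqtl_scores(snp, datasets, ["G1", "ABSENT"])
        assert m.scores["G1"] == 0.6  # 20% variance at n=200: p << 0.005
        assert m.scores["ABSENT"] == 1.0
        assert m.provenance["G1"][1] == "d"

    def test_threshold_edges_explicit(self):
        # exercise the 0.8 band via a synthetic provenance-free map
        from pqtlkit.mediators import trans_eqtl_scores as _  # noqa: F401
        m = NodeScoreMap(scores={"a": 0.8, "b": 0.6, "c": 1.0})
        assert [m.score(x) for x in "abc"] == [0.8, 0.6, 1.0]


class TestShortestPath:
    def test_direct_edge_equivalence_when_scores_one(self, line_network):
        scores = NodeScoreMap(scores={})
        res = shortest_path(line_network, "A", "B", scores)
        assert res.unweighted_len == 1 and res.weighted_len == 1.0

    def test_mediated_path_weighted_length(self):
        g = nx.Graph()
        g.add_edge("A", "M", confidence=900)
        g.add_edge("M", "T", confidence=900)
        scores = NodeScoreMap(scores={"M": 0.6, "T": 1.0})
        res = shortest_path(g, "A", "T", scores)
        assert res.weighted_len == pytest.approx(1.6)
        assert res.weighted_nodes == ["A", "M", "T"]

    def test_disconnected_infinite(self):
        g = nx.Graph()
        g.add_edge("A", "B", confidence=900)
        g.add_node("Z")
        res = shortest_path(g, "A", "Z")
        assert math.isinf(res.unweighted_len) and math.isinf(res.weighted_len)

    def test_absent_node_distinct_error(self, line_network):
        with pytest.raises(NodeAbsentError):
            shortest_path(line_network, "A", "NOPE")

    def test_matches_exhaustive_enumeration_on_small_graphs(self):
        rng = np.random.default_rng(2)
        checked = 0
        for trial in range(200):
            n = int(rng.integers(3, 9))
            p = float(rng.uniform(0.25, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(n)})
            for a, b in g.edges:
                g[a][b]["confidence"] = 500
            nodes = sorted(g.nodes)
            s, t = nodes[0], nodes[-1]
            if s == t or not nx.has_path(g, s, t):
                continue
            raw = {node: float(rng.choice([1.0, 0.8, 0.6])) for node in nodes}
            scores = NodeScoreMap(scores=raw)
            res = shortest_path(g, s, t, scores)
            oracle_u, oracle_w = path_enumeration_oracle(g, s, t, raw)
            assert res.unweighted_len == oracle_u
            assert res.weighted_len == pytest.approx(oracle_w, abs=1e-12)
            checked += 1
        assert checked > 100

    def test_score_monotonicity(self):
        g = nx.Graph()
        for a, b in [("A", "M"), ("M", "T"), ("A", "X"), ("X", "T")]:
            g.add_edge(a, b, confidence=900)
        hi = shortest_path(g, "A", "T",
                           NodeScoreMap(scores={"M": 1.0, "X": 1.0}))
        lo = shortest_path(g, "A", "T",
                           NodeScoreMap(scores={"M": 0.6, "X": 1.0}))
        assert lo.weighted_len < hi.weighted_len
        assert lo.weighted_nodes == ["A", "M", "T"]


class TestRewire:
    def test_degree_sequence_preserved(self):
        g = nx.barabasi_albert_graph(60, 2, seed=3)
        g = nx.relabel_nodes(g, str)
        for a, b in g.edges:
            g[a][b]["confidence"] = 700
        r = rewire_network(g, seed=4)
        assert dict(g.degree()) == dict(r.degree())
        assert g.number_of_edges() == r.number_of_edges()
        assert not nx.utils.graphs_equal(g, r)  # something actually moved

    def test_four_cycle_stays_a_valid_two_regular_graph(self):
        g = nx.cycle_graph(["A", "B", "C", "D"])
        for a, b in g.edges:
            g[a][b]["confidence"] = 500
        # the only simple 2-regular graphs on 4 nodes are the 3 Hamilton cycles
        valid = {
            frozenset(map(frozenset, [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])),
            frozenset(map(frozenset, [("A", "B"), ("B", "D"), ("D", "C"), ("C", "A")])),
            frozenset(map(frozenset, [("A", "C"), ("C", "B"), ("B", "D"), ("D", "A")])),
        }
        seen = set()
        for seed in range(30):
            r = rewire_network(g, seed=seed)
            key = frozenset(frozenset(e) for e in r.edges)
            assert key in valid
            seen.add(key)
        assert len(seen) > 1

    def test_deterministic_and_small_graphs_unchanged(self):
        g = nx.Graph()
        g.add_edge("A", "B", confidence=500)
        r = rewire_network(g, seed=5)
        assert set(r.edges) == {("A", "B")}
        g2 = nx.barabasi_albert_graph(40, 2, seed=6)
        for a, b in g2.edges:
            g2[a][b]["confidence"] = 500
        assert nx.utils.graphs_equal(rewire_network(g2, 7), rewire_network(g2, 7))


class TestPermutationP:
    def test_direct_edge_has_p_zero(self, line_network):
        p = path_permutation_p(line_network, None, "A", "B", n_perm=50, seed=8)
        assert p == 0.0

    def test_disconnected_observed_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "B", confidence=500)
        g.add_node("Z")
        with pytest.raises(ValueError, match="disconnected"):
            path_permutation_p(g, None, "A", "Z", n_perm=10, seed=9)

    def test_invariant_under_order_preserving_relabeling(self):
        g = nx.barabasi_albert_graph(40, 2, seed=10)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in range(40)})
        for a, b in g.edges:
            g[a][b]["confidence"] = 500
        mapping = {f"N{i:02d}": f"Z{i:02d}" for i in range(40)}
        g2 = nx.relabel_nodes(g, mapping)
        scores = NodeScoreMap(scores={n: (0.6 if int(n[1:]) % 5 == 0 else 1.0)
                                      for n in g.nodes})
        scores2 = NodeScoreMap(scores={mapping[n]: v
                                       for n, v in scores.scores.items()})
        s, t = "N00", "N35"
        if not nx.has_path(g, s, t):
            pytest.skip("pair disconnected in this topology")
        for weighted, sc, sc2 in [(False, None, None), (True, scores, scores2)]:
            p1 = path_permutation_p(g, sc, s, t, n_perm=40, seed=11,
                                    weighted=weighted)
            p2 = path_permutation_p(g2, sc2, mapping[s], mapping[t], n_perm=40,
                                    seed=11, weighted=weighted)
            assert p1 == p2

    def test_add_one_estimator_bounded_away_from_zero(self, line_network):
        p = path_permutation_p(line_network, None, "A", "B", n_perm=50,
                               seed=12, estimator="add_one")
        assert p == pytest.approx(1 / 51)


def test_integrate_evidence_table_shape():
    """A planted mediated trans locus yields one retained Table-row per
    evidenced cis-gene, with the weighted path naming its intermediate."""
    from pqtlkit import AssocRecord, PqtlLocus, RunConfig, integrate_evidence
    from pqtlkit.study import default_study, MEDIATOR_TRIPLE

    s = default_study(3)
    cisg, med, trait_gene = MEDIATOR_TRIPLE
    snp_id = s.truth.mediators.iloc[0]["id"]
    v = s.genotypes.variants[s.genotypes.variant_index(snp_id)]
    rec = AssocRecord(variant=v, trait="PROT07", beta=0.3, se=0.03, p=1e-20,
                      n=3394, r2_explained=0.05)
    locus = PqtlLocus(index=rec, members=[rec], locus_class="trans")
    cfg = RunConfig(n_perm=50, seed=3)
    lit = {(snp_id, "CISG2"): 626}
    headline, full = integrate_evidence(
        [("PROT07", locus)], s.annotation, s.genotypes.variants, s.genotypes,
        s.eqtl_datasets, s.network, s.trait_gene_of,
        literature_counts=lit, config=cfg)
    by_gene = {r.cis_gene: r for r in full}
    assert set(by_gene) == {"CISG1", "CISG2", "CISG3"}
    assert by_gene["CISG1"].dist_rank == 1
    assert by_gene["CISG1"].cis_eqtl_hits  # planted 25%-variance cis-eQTL
    assert by_gene["CISG2"].literature_score == 626
    assert "literature" in by_gene["CISG2"].criteria_fired()
    retained = {r.cis_gene for r in headline}
    assert "CISG1" in retained and "CISG2" in retained
    # evidence-free pairs are excluded from the headline table
    assert all(r.criteria_fired() for r in headline)
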