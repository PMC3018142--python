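"""Network mapping: construction, Rc/Nc, fusion, coverage."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from alvinest import network, simulate
from alvinest.network import (
    FusionParams,
    HomologMapping,
    SubNetwork,
    build_network,
    coverage_summary,
    extract_subnetworks,
    fuse_all,
    fusion_score,
    induced_subnetwork,
    map_to_network,
    nc,
    should_fuse,
)


def edges_frame(rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])


class TestBuildNetwork:
    def test_score_cutoff_boundary(self):
        g = build_network(
            edges_frame([("a", "b", 0.89), ("b", "c", 0.90)]), cutoff=0.9
        )
        assert not g.has_edge("a", "b")
        assert g.has_edge("b", "c")
        assert "a" in g  # isolated node retained

    def test_duplicate_edges_keep_max_score(self):
        g = build_network(
            edges_frame([("a", "b", 0.92), ("b", "a", 0.97)]), cutoff=0.9
        )
        assert g["a"]["b"]["combined_score"] == 0.97

    def test_empty_edge_list(self):
        g = build_network(edges_frame([]), cutoff=0.9)
        assert g.number_of_nodes() == 0

    def test_self_loop_rejected_with_row(self):
        with pytest.raises(ValueError, match="row 2"):
            build_network(edges_frame([("a", "b", 0.95), ("c", "c", 0.95)]))

    def test_bad_score_rejected(self):
        with pytest.raises(ValueError):
            build_network(edges_frame([("a", "b", 1.5)]))


class TestExtractAndRc:
    def test_triangle_rc_one(self):
        g = build_network(
            edges_frame([("s", "x", 1.0), ("s", "y", 1.0), ("x", "y", 1.0)])
        )
        (sub,) = extract_subnetworks(g, ["s"])
        assert sub.nodes == {"s", "x", "y"}
        assert sub.rc == 1.0

    def test_path_rc_two_thirds(self):
        g = build_network(edges_frame([("s", "x", 1.0), ("s", "y", 1.0)]))
        (sub,) = extract_subnetworks(g, ["s"])
        assert sub.rc == pytest.approx(2 / 3)

    def test_isolated_seed_singleton(self):
        g = build_network(edges_frame([("a", "b", 0.95)]))
        g.add_node("lone")
        (sub,) = extract_subnetworks(g, ["lone"])
        assert sub.nodes == {"lone"}
        assert sub.rc == 1.0  # vacuous consistency for n <= 1

    def test_unknown_seed_rejected(self):
        g = build_network(edges_frame([("a", "b", 0.95)]))
        with pytest.raises(ValueError):
            extract_subnetworks(g, ["nope"])


class TestNcAndFusion:
    def _sub(self, nodes, n_edges=0):
        return SubNetwork(nodes=frozenset(nodes), n_edges=n_edges)

    def test_nc_hand_counts(self):
        a = self._sub("abcd")
        b = self._sub("cde")
        assert nc(a, b) == pytest.approx(2 / 3)
        assert nc(a, a) == 1.0
        assert nc(self._sub("ab"), self._sub("xy")) == 0.0

    def test_nc_empty_rejected(self):
        with pytest.raises(ValueError):
            nc(self._sub(""), self._sub("ab"))

    def test_should_fuse_nc_one_always(self):
        a = self._sub("abc", 0)   # rc 0
        b = self._sub("abc", 0)
        ok, score = should_fuse(a, b)
        assert ok and score == 1.0

    def test_should_fuse_score_below_threshold(self):
        # Nc=0.5, RcA=RcB=0 -> score 0.5 < 0.7
        a = self._sub("ab", 0)
        b = self._sub("bc", 0)
        ok, score = should_fuse(a, b)
        assert score == pytest.approx(0.5)
        assert not ok

    def test_should_fuse_nc_gate(self):
        # cliques with Nc = 0.4: score 1.0 but the Nc >= 0.5 gate fails
        a = self._sub("abcde", 10)
        b = self._sub("afghi", 10)
        assert a.rc == 1.0
        ok, score = should_fuse(a, b)
        assert score == 1.0
        assert nc(a, b) == pytest.approx(0.2)
        assert not ok

    def test_fusion_score_monotone_on_grid(self):
        values = np.linspace(0, 1, 6)
        for nc_v, rca, rcb in itertools.product(values, repeat=3):
            base = 1 - (1 - nc_v) * (1 - rca) * (1 - rcb)
            for eps_target in ("nc", "rca", "rcb"):
                bumped = {
                    "nc": (min(nc_v + 0.1, 1), rca, rcb),
                    "rca": (nc_v, min(rca + 0.1, 1), rcb),
                    "rcb": (nc_v, rca, min(rcb + 0.1, 1)),
                }[eps_target]
                score = 1 - (1 - bumped[0]) * (1 - bumped[1]) * (1 - bumped[2])
                assert score >= base - 1e-12


def random_instance(rng, n_nodes=12, n_seeds=5):
    g = nx.gnp_random_graph(n_nodes, 0.35, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    for _a, _b, d in g.edges(data=True):
        d["combined_score"] = 1.0
    seeds = sorted(rng.choice(sorted(g.nodes), size=n_seeds, replace=False))
    return g, list(seeds)


def fuse_oracle(subnets, graph, params=FusionParams()):
    """Step-by-step exhaustive search over all pairs, recomputing Rc/Nc
    from the graph with networkx primitives (independent code path)."""
    pool = sorted({s.nodes for s in subnets}, key=sorted)
    while True:
        candidates = []
        for a, b in itertools.combinations(pool, 2):
            inter = len(a & b)
            nc_v = inter / min(len(a), len(b))
            rc = {}
            for s in (a, b):
                n = len(s)
                rc[s] = 1.0 if n <= 1 else nx.density(graph.subgraph(s))
            score = 1 - (1 - nc_v) * (1 - rc[a]) * (1 - rc[b])
            if score >= params.score_threshold and nc_v >= params.nc_threshold:
                candidates.append((-score, -nc_v, sorted(a), sorted(b), a, b))
        if not candidates:
            return sorted(pool, key=sorted)
        candidates.sort(key=lambda t: t[:4])
        _s, _n, _ka, _kb, a, b = candidates[0]
        union = a | b
        pool = [p for p in pool if p not in (a, b) and p != union]
        pool.append(union)


class TestFuseAll:
    def test_identical_subnets_collapse(self):
        g = build_network(edges_frame([("a", "b", 1.0)]))
        sub = induced_subnetwork(g, {"a", "b"})
        out = fuse_all([sub, sub], g)
        assert len(out) == 1
        assert out[0].nodes == {"a", "b"}

    def test_terminates_and_reduces_count(self):
        planted = simulate.generate_ppi(3, 8, 0.9, 0.02, seed=2)
        g = build_network(planted.edge_frame(), cutoff=0.9)
        subs = extract_subnetworks(g, sorted(g.nodes))
        out = fuse_all(subs, g)
        assert len(out) <= len(subs)

    def test_input_order_invariance(self):
        planted = simulate.generate_ppi(3, 6, 0.9, 0.05, seed=3)
        g = build_network(planted.edge_frame(), cutoff=0.9)
        subs = extract_subnetworks(g, sorted(g.nodes))
        a = fuse_all(subs, g)
        b = fuse_all(list(reversed(subs)), g)
        assert [s.nodes for s in a] == [s.nodes for s in b]

    def test_equals_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g, seeds = random_instance(rng)
            subs = extract_subnetworks(g, seeds)
            got = sorted((s.nodes for s in fuse_all(subs, g)), key=sorted)
            expected = fuse_oracle(subs, g)
            assert got == expected

    def test_planted_module_recovery(self):
        best = []
        for seed in range(5):
            planted = simulate.generate_ppi(6, 10, p_in=0.9, p_out=0.01, seed=seed)
            g = build_network(planted.edge_frame(), cutoff=0.9)
            fused = fuse_all(extract_subnetworks(g, sorted(g.nodes)), g)
            modules = {}
            for node, m in planted.module_assignment.items():
                modules.setdefault(m, set()).add(node)
            for nodes in modules.values():
                best.append(
                    max(
                        len(nodes & set(s.nodes)) / len(nodes | set(s.nodes))
                        for s in fused
                    )
                )
        assert float(np.median(best)) >= 0.9


class TestMapping:
    def test_identifier_order_precedence(self):
        tables = {
            "uniprot_id": pd.DataFrame({"query": ["q1"], "node": ["upA"]}),
            "gene_name": pd.DataFrame({"query": ["q1"], "node": ["gnB"]}),
        }
        result = map_to_network(["q1"], tables)
        assert result.mapping["q1"] == "upA"
        assert result.method["q1"] == "uniprot_id"

    def test_ambiguous_level_falls_through(self):
        tables = {
            "uniprot_id": pd.DataFrame(
                {"query": ["q1", "q1"], "node": ["x", "y"]}
            ),
            "gene_name": pd.DataFrame({"query": ["q1"], "node": ["z"]}),
        }
        result = map_to_network(["q1"], tables)
        assert result.mapping["q1"] == "z"
        assert result.warnings

    def test_similarity_threshold(self):
        hits = pd.DataFrame(
            {"query": ["q1", "q2"], "node": ["a", "b"], "evalue": [1e-4, 1e-6]}
        )
        result = map_to_network(["q1", "q2"], {}, hits)
        assert "q1" in result.unmapped
        assert result.mapping["q2"] == "b"
        assert result.method["q2"] == "similarity-best-hit"

    def test_nothing_matches_unmapped(self):
        result = map_to_network(["q1"], {})
        assert result.unmapped == ["q1"]


class TestCoverage:
    def test_pathway_fraction_and_flag(self):
        mapping = HomologMapping(
            mapping={f"q{i}": f"e{i}" for i in range(6)},
            method={}, unmapped=["q9"],
        )
        pathways = pd.DataFrame(
            {"pathway": ["P"] * 10, "enzyme": [f"e{i}" for i in range(10)]}
        )
        summary = coverage_summary(mapping, [], pathways)
        row = summary["pathways"].iloc[0]
        assert row["coverage"] == pytest.approx(0.6)
        assert bool(row["over_half"])

    def test_duplicate_enzyme_counted_once(self):
        mapping = HomologMapping(mapping={"q": "e1"}, method={}, unmapped=[])
        pathways = pd.DataFrame(
            {"pathway": ["P"] * 3, "enzyme": ["e1", "e1", "e2"]}
        )
        summary = coverage_summary(mapping, [], pathways)
        assert summary["pathways"].iloc[0]["n_enzymes"] == 2
        assert summary["pathways"].iloc[0]["coverage"] == pytest.approx(0.5)

    def test_no_mapped_queries(self):
        mapping = HomologMapping(mapping={}, method={}, unmapped=["q"])
        pathways = pd.DataFrame({"pathway": ["P"], "enzyme": ["e"]})
        g = nx.Graph()
        g.add_edge("a", "b")
        subs = [induced_subnetwork(g, {"a", "b"})]
        summary = coverage_summary(mapping, subs, pathways)
        assert summary["pathways"]["coverage"].eq(0).all()
        assert summary["fraction_subnets_populated"] == 0.0
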