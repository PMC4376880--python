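"""Signed-network construction and graph statistics, with brute-force oracles."""

from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall

from ienet import constants as C
from ienet import network as nm
from ienet import reporter_effects as rep
from ienet import synthetic_data as syn

FIX = nm.canonical_network()


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def enumerate_paths(edges, s, t, nodes):
    """All simple directed s->t paths, by exhaustive recursion."""
    paths = []

    def walk(path):
        head = path[-1]
        if head == t:
            paths.append(tuple(path))
            return
        for n in nodes:
            if n not in path and (head, n) in edges:
                walk(path + [n])

    walk([s])
    return paths


def betweenness_oracle(nodes, edges):
    """Exhaustive shortest-path enumeration, normalized by (n-1)(n-2)."""
    n = len(nodes)
    out = dict.fromkeys(nodes, 0.0)
    for s, t in permutations(nodes, 2):
        paths = enumerate_paths(edges, s, t, nodes)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            out[v] += sum(v in p for p in sp) / len(sp)
    return {v: x / ((n - 1) * (n - 2)) for v, x in out.items()}


def random_digraph(seed, n_min=5, n_max=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    nodes = tuple(f"g{i}" for i in range(n))
    edges = []
    for a, b in permutations(nodes, 2):
        if rng.random() < 0.3:
            edges.append(nm.SignedEdge(a, b, +1 if rng.random() < 0.7 else -1))
    return nm.RegulatoryNetwork(nodes, tuple(edges))


# ---------------------------------------------------------------------------
# Canonical fixture
# ---------------------------------------------------------------------------

class TestCanonicalNetwork:
    def test_edge_counts(self):
        assert len(FIX.edges) == 15
        assert sum(1 for e in FIX.edges if e.sign > 0 and not e.is_auto) == 11
        assert sum(1 for e in FIX.edges if e.is_auto) == 3

    def test_ie1_degrees(self):
        deg, _ = nm.degree_summary(FIX)
        row = deg.set_index("gene").loc["ie1"]
        assert row["in_degree"] == 1 and row["out_degree"] == 3

    def test_ie2_out_degree(self):
        deg, _ = nm.degree_summary(FIX)
        assert deg.set_index("gene").loc["ie2", "out_degree"] == 4

    def test_mean_activating_in_degree(self):
        _, mean_act = nm.degree_summary(FIX)
        assert mean_act == pytest.approx(2.2)

    def test_shortest_paths(self):
        _, s = nm.shortest_path_matrix(FIX)
        assert s["mean_shortest_path"] == pytest.approx(1.45)
        assert s["max_shortest_path"] == 3
        assert s["max_pair"] == ("me53", "ie1")
        assert s["unreachable_pairs"] == 0

    def test_betweenness_hubs(self):
        b = nm.normalized_betweenness(FIX)
        assert b["pe38"] == pytest.approx(3 / 12)
        assert b["ie0"] == pytest.approx(2.5 / 12)
        ranked = sorted(b, key=b.get, reverse=True)
        assert ranked[:2] == ["pe38", "ie0"]

    def test_ffls(self):
        loops = nm.enumerate_ffls(FIX)
        assert len(loops) == 9
        assert sum(1 for x, _, _ in loops if x == "ie1") == 4
        assert sum(1 for x, _, _ in loops if x == "ie2") == 4

    def test_perturbation_scan(self):
        results, changed, comparisons = nm.perturbation_scan(FIX)
        assert (changed, comparisons) == (6, 60)
        per = {r.removed: r.n_changed for r in results}
        assert per["ie2"] == 0
        assert per["pe38"] == 3
        pe38 = next(r for r in results if r.removed == "pe38")
        # losing pe38 isolates ie1 from all inputs
        assert set(pe38.changed_pairs) == {(s, "ie1") for s in ("ie0", "ie2", "me53")}
        assert all(pd.isna(pe38.perturbed.loc[s, "ie1"]) for s, _ in pe38.changed_pairs)


# ---------------------------------------------------------------------------
# Generic behaviour
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_pipeline_consistency_zero_noise(self, noiseless_reporter_truth):
        df = syn.simulate_reporter_dataset(noiseless_reporter_truth, seed=0)
        eff = rep.fit_reporter_model(rep.preprocess_measurements(df))
        net = nm.build_network(eff)
        got = {(e.regulator, e.target): e.sign for e in net.edges}
        want = {(e.regulator, e.target): e.sign for e in FIX.edges}
        assert got == want

    def test_all_none_gives_edgeless(self):
        calls = pd.DataFrame(
            {
                "promoter": ["ie0"],
                "driver": ["IE1"],
                "effect_log10": [0.2],
                "call": ["none"],
            }
        )
        net = nm.build_network(calls)
        assert len(net.edges) == 0 and len(net.nodes) == 5

    def test_single_positive_call(self):
        calls = pd.DataFrame(
            {
                "promoter": ["ie0"],
                "driver": ["IE1"],
                "effect_log10": [0.8],
                "call": ["positive"],
            }
        )
        net = nm.build_network(calls)
        assert len(net.edges) == 1
        assert net.edges[0] == nm.SignedEdge("ie1", "ie0", +1, 0.8)

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            nm.RegulatoryNetwork(
                ("a", "b"),
                (nm.SignedEdge("a", "b", 1), nm.SignedEdge("a", "b", -1)),
            )


class TestSmallGraphs:
    def test_complete_digraph_distances_all_one(self):
        nodes = tuple("abcde")
        edges = tuple(
            nm.SignedEdge(a, b, 1) for a, b in permutations(nodes, 2)
        )
        _, s = nm.shortest_path_matrix(nm.RegulatoryNetwork(nodes, edges))
        assert s["mean_shortest_path"] == 1.0 and s["max_shortest_path"] == 1

    def test_chain_betweenness(self):
        net = nm.RegulatoryNetwork(
            ("a", "b", "c"),
            (nm.SignedEdge("a", "b", 1), nm.SignedEdge("b", "c", 1)),
        )
        b = nm.normalized_betweenness(net)
        assert b == {"a": 0.0, "b": pytest.approx(0.5), "c": 0.0}

    def test_triangle_single_ffl(self):
        net = nm.RegulatoryNetwork(
            ("a", "b", "c"),
            (
                nm.SignedEdge("a", "b", 1),
                nm.SignedEdge("b", "c", 1),
                nm.SignedEdge("a", "c", 1),
            ),
        )
        assert nm.enumerate_ffls(net) == [("a", "b", "c")]

    def test_edgeless_ffls_empty(self):
        assert nm.enumerate_ffls(nm.RegulatoryNetwork(("a", "b", "c"), ())) == []

    def test_negative_edge_excluded_in_positive_mode(self):
        net = nm.RegulatoryNetwork(
            ("a", "b", "c"),
            (
                nm.SignedEdge("a", "b", 1),
                nm.SignedEdge("b", "c", -1),
                nm.SignedEdge("a", "c", 1),
            ),
        )
        assert nm.enumerate_ffls(net, "positive_only") == []
        assert nm.enumerate_ffls(net, "any_sign") == [("a", "b", "c")]


# ---------------------------------------------------------------------------
# Oracle equivalence on random digraphs
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_distances_match_floyd_warshall(self, seed):
        net = random_digraph(seed)
        mat, _ = nm.shortest_path_matrix(net)
        idx = {v: i for i, v in enumerate(net.nodes)}
        adj = np.zeros((len(net.nodes),) * 2)
        for e in net.edges:
            if not e.is_auto:
                adj[idx[e.regulator], idx[e.target]] = 1
        fw = floyd_warshall(adj, directed=True, unweighted=True)
        for s in net.nodes:
            for t in net.nodes:
                if s == t:
                    continue
                want = fw[idx[s], idx[t]]
                got = mat.loc[s, t]
                if np.isinf(want):
                    assert pd.isna(got)
                else:
                    assert got == want

    @pytest.mark.parametrize("seed", range(100))
    def test_betweenness_matches_enumeration(self, seed):
        net = random_digraph(seed, n_min=5, n_max=6)
        got = nm.normalized_betweenness(net)
        edges = {(e.regulator, e.target) for e in net.edges if not e.is_auto}
        want = betweenness_oracle(list(net.nodes), edges)
        for v in net.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_perturbation_against_recomputed_baseline(self, seed):
        net = random_digraph(seed)
        results, total, comparisons = nm.perturbation_scan(net)
        n = len(net.nodes)
        assert comparisons == n * (n - 1) * (n - 2)
        assert total == sum(r.n_changed for r in results)
        for r in results:
            rest = [v for v in net.nodes if v != r.removed]
            for s in rest:
                for t in rest:
                    if s == t:
                        continue
                    b, p = r.baseline.loc[s, t], r.perturbed.loc[s, t]
                    changed = (s, t) in r.changed_pairs
                    same = (b == p) or (pd.isna(b) and pd.isna(p))
                    assert changed == (not same)
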