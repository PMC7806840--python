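"""Longest repressor-distinct chains in the compatibility graph."""

import numpy as np
import pytest

from contextgates import (
    CompatibilityGraph,
    DataError,
    GateContext,
    Thresholds,
    build_graph,
    compatibility_matrix,
    longest_chains,
)
from contextgates.chains import depth_by_context_policy
from contextgates.compatibility import CompatibilityEdge, CompatibilityTable


def gc(name, backbone="pAN", host="EcDH5a"):
    return GateContext(gate_name=name, backbone=backbone, host=host)


def graph_from_adjacency(adj, families, backbone="pAN"):
    fams = list(families)
    nodes = [gc(f"{f}-{f}{i}", backbone=backbone) for i, f in enumerate(fams)]
    return CompatibilityGraph(nodes=nodes, adjacency=np.asarray(adj), repressors=fams)


def brute_force_longest(adj, families):
    """All simple paths, no repressor family reused; exhaustive recursion."""
    n = len(families)
    best = {"depth": 1, "paths": [(i,) for i in range(n)]}

    def extend(path, used):
        depth = len(path)
        if depth > best["depth"]:
            best["depth"], best["paths"] = depth, [tuple(path)]
        elif depth == best["depth"] and depth > 1:
            best["paths"].append(tuple(path))
        for j in range(n):
            if adj[path[-1]][j] and families[j] not in used:
                extend(path + [j], used | {families[j]})

    for i in range(n):
        extend([i], {families[i]})
    if best["depth"] == 1:
        best["paths"] = [(i,) for i in range(n)]
    return best["depth"], set(best["paths"])


class TestLongestChains:
    def test_edgeless_graph_is_depth_one(self):
        g = graph_from_adjacency(np.zeros((5, 5), int), ["A", "B", "C", "D", "E"])
        depth, chains = longest_chains(g)
        assert depth == 1
        assert len(chains) == 5

    def test_repressor_reuse_blocks_extension(self):
        # G1(R1) -> G2(R2) -> G3(R1): the 3-path reuses R1, so depth is 2
        adj = [[0, 1, 0], [0, 0, 1], [0, 0, 0]]
        g = graph_from_adjacency(adj, ["R1", "R2", "R1"])
        depth, chains = longest_chains(g)
        assert depth == 2
        names = {tuple(n.gate_name for n in c.nodes) for c in chains}
        assert names == {("R1-R10", "R2-R21"), ("R2-R21", "R1-R12")}

    def test_complete_graph_distinct_families(self):
        adj = 1 - np.eye(4, dtype=int)
        g = graph_from_adjacency(adj, ["A", "B", "C", "D"])
        depth, chains = longest_chains(g)
        assert depth == 4
        assert len(chains) == 24  # 4! orderings

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(21)
        fams = ["A", "B", "C", "D", "E"]
        for _ in range(25):
            n = int(rng.integers(2, 9))
            families = [fams[int(rng.integers(0, 5))] for _ in range(n)]
            adj = (rng.random((n, n)) < 0.35).astype(int)
            np.fill_diagonal(adj, 0)
            g = graph_from_adjacency(adj, ["X"] * n)
            g = CompatibilityGraph(nodes=g.nodes, adjacency=adj, repressors=families)
            depth, chains = longest_chains(g)
            b_depth, b_paths = brute_force_longest(adj.tolist(), families)
            assert depth == b_depth
            got = {tuple(g.nodes.index(x) for x in c.nodes) for c in chains}
            assert got == b_paths

    def test_depth_bounded_by_family_count(self):
        rng = np.random.default_rng(22)
        n = 10
        families = [f"F{i % 3}" for i in range(n)]
        adj = (rng.random((n, n)) < 0.9).astype(int)
        np.fill_diagonal(adj, 0)
        g = graph_from_adjacency(adj, ["X"] * n)
        g = CompatibilityGraph(nodes=g.nodes, adjacency=adj, repressors=families)
        depth, _ = longest_chains(g)
        assert depth <= 3

    def test_adding_edges_never_decreases_depth(self):
        rng = np.random.default_rng(23)
        n = 7
        families = list("ABCDEFG")
        adj = (rng.random((n, n)) < 0.2).astype(int)
        np.fill_diagonal(adj, 0)
        g1 = graph_from_adjacency(adj, families)
        more = adj | (rng.random((n, n)) < 0.3).astype(int)
        np.fill_diagonal(more, 0)
        g2 = graph_from_adjacency(more, families)
        assert longest_chains(g2)[0] >= longest_chains(g1)[0]


class TestBuildGraph:
    def library(self):
        ops = Thresholds(OL=0.1, OH=1.0, IL=0.2, IH=0.8, operational=True)
        return [
            (gc("AmtR-A1", backbone="pAN"), ops),
            (gc("PhlF-P1", backbone="pAN"), ops),
            (gc("AmtR-A1", backbone="pSEVA221"), ops),
            (gc("PhlF-P1", backbone="pSEVA221"), ops),
        ]

    def test_single_context_filter_halves_balanced_library(self):
        table = compatibility_matrix(self.library())
        g = build_graph(table, context_filter=lambda x: x.backbone == "pAN")
        assert len(g.nodes) == 2

    def test_all_negative_scores_give_edgeless_graph(self):
        a = gc("AmtR-A1")
        b = gc("PhlF-P1")
        table = CompatibilityTable(
            edges=[
                CompatibilityEdge(source=a, target=b, score=-0.5, compatible=False),
                CompatibilityEdge(source=b, target=a, score=-0.1, compatible=False),
            ],
            nodes=[a, b],
            n_compatible=0,
        )
        g = build_graph(table)
        assert g.adjacency.sum() == 0

    def test_adjacency_equals_pairwise_sign_oracle(self):
        table = compatibility_matrix(self.library())
        g = build_graph(table)
        idx = {n: i for i, n in enumerate(g.nodes)}
        for e in table.edges:
            assert g.adjacency[idx[e.source], idx[e.target]] == int(e.compatible)

    def test_empty_filter_rejected(self):
        table = compatibility_matrix(self.library())
        with pytest.raises(DataError):
            build_graph(table, context_filter=lambda x: x.host == "PpKT2440")


class TestDepthByPolicy:
    def test_nested_policies_monotone(self):
        ops = Thresholds(OL=0.1, OH=1.0, IL=0.2, IH=0.8, operational=True)
        fams = ["AmtR", "PhlF", "QacR", "SrpR", "BetI"]
        lib = []
        for i, f in enumerate(fams):
            for backbone in ("pAN", "pSEVA221"):
                lib.append((gc(f"{f}-{f[0]}1", backbone=backbone), ops))
        table = compatibility_matrix(lib)
        policies = [
            ("pAN", lambda x: x.backbone == "pAN"),
            ("any", None),
        ]
        report = depth_by_context_policy(table, policies)
        assert report[0]["max_depth"] <= report[1]["max_depth"]

    def test_cross_backbone_only_chain(self):
        """A 5-deep chain wired strictly across alternating backbones:
        single-backbone policies cannot reach depth 5, the mixed policy can."""
        fams = ["AmtR", "PhlF", "QacR", "SrpR", "BetI"]
        backbones = ["pAN", "pSEVA221", "pAN", "pSEVA221", "pAN"]
        nodes = [gc(f"{f}-{f[0]}1", backbone=b) for f, b in zip(fams, backbones)]
        edges = []
        for i in range(4):
            edges.append(CompatibilityEdge(source=nodes[i], target=nodes[i + 1], score=0.2, compatible=True))
        table = CompatibilityTable(edges=edges, nodes=nodes, n_compatible=4)
        report = depth_by_context_policy(
            table,
            [
                ("pAN-only", lambda x: x.backbone == "pAN"),
                ("mixed", None),
            ],
        )
        assert report[0]["max_depth"] < 5
        assert report[1]["max_depth"] == 5

    def test_requires_policies(self):
        with pytest.raises(ValueError):
            depth_by_context_policy(CompatibilityTable(edges=[], nodes=[], n_compatible=0), [])


def test_chain_annotations_count_host_switches():
    from contextgates.chains import Chain

    chain = Chain(nodes=(
        gc("AmtR-A1", host="EcDH5a"),
        gc("PhlF-P1", host="EcDH5a", backbone="pSEVA221"),
        gc("QacR-Q1", host="EcCC118lpir", backbone="pSEVA221"),
    ))
    assert chain.depth == 3
    assert chain.n_host_switches == 1
    assert chain.backbones_per_host["EcDH5a"] == ("pAN", "pSEVA221")
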