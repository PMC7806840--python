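"""Maximum circuit depth by layering compatible inverters.

The compatibility table, thresholded at score > 0, is the adjacency matrix
of a directed graph over gate-context devices. The depth of the deepest
layered circuit the library supports is the length (in gates) of the
longest path in that graph in which no repressor family appears twice —
reusing a repressor would crosstalk between layers. With R distinct
families in the library this bounds the depth at R.

Because the family constraint is what makes the problem tractable, the
search runs as a dynamic program over (node, used-family-set) states:
``longest(v, S)`` is the deepest chain starting at v given families S
already consumed. With <= ~20 families the state space is small even for
dense graphs, and all maximal chains can then be enumerated by following
only DP-optimal edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np

from .core import GateContext
from .compatibility import CompatibilityTable
from .errors import DataError


@dataclass
class CompatibilityGraph:
    """Directed graph of composable gate-context devices."""

    nodes: list[GateContext]
    adjacency: np.ndarray  # 0/1, no self-loops
    repressors: list[str]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square over the node list")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-loops are not allowed")
        if len(self.repressors) != n:
            raise ValueError("one repressor family per node required")

    @property
    def n_families(self) -> int:
        return len(set(self.repressors))


@dataclass(frozen=True)
class Chain:
    """One layered inverter chain; depth counts gates, not connections."""

    nodes: tuple[GateContext, ...]

    @property
    def depth(self) -> int:
        return len(self.nodes)

    @property
    def hosts(self) -> tuple[str, ...]:
        return tuple(n.host for n in self.nodes)

    @property
    def n_host_switches(self) -> int:
        """Inter-host connections the chain needs (multicellular links)."""
        return sum(a != b for a, b in zip(self.hosts, self.hosts[1:]))

    @property
    def backbones_per_host(self) -> dict[str, tuple[str, ...]]:
        """Backbone multiset per host, for origin-coexistence checks."""
        out: dict[str, list[str]] = {}
        for n in self.nodes:
            out.setdefault(n.host, []).append(n.backbone)
        return {h: tuple(sorted(v)) for h, v in out.items()}


def build_graph(
    table: CompatibilityTable,
    context_filter: Callable[[GateContext], bool] | None = None,
) -> CompatibilityGraph:
    """Restrict a compatibility table to a context policy and build the graph."""
    nodes = [gc for gc in table.nodes if context_filter is None or context_filter(gc)]
    if not nodes:
        raise DataError("context filter leaves no gate-context devices")
    index = {gc: i for i, gc in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=int)
    for e in table.edges:
        if e.compatible and e.source in index and e.target in index:
            adj[index[e.source], index[e.target]] = 1
    return CompatibilityGraph(
        nodes=nodes,
        adjacency=adj,
        repressors=[gc.repressor_family for gc in nodes],
    )


def longest_chains(g: CompatibilityGraph, max_chains: int | None = None) -> tuple[int, list[Chain]]:
    """Maximum depth and all chains achieving it.

    Returns (max_depth, chains) where chains are ordered lexicographically
    by node index. An edgeless graph has depth 1 (every gate is a
    singleton chain). ``max_chains`` optionally caps the enumeration (the
    depth itself is always exact).
    """
    n = len(g.nodes)
    if n == 0:
        raise DataError("graph has no nodes")
    families = sorted(set(g.repressors))
    fam_bit = {f: 1 << i for i, f in enumerate(families)}
    node_bit = [fam_bit[f] for f in g.repressors]
    succ = [np.flatnonzero(g.adjacency[i]).tolist() for i in range(n)]

    @lru_cache(maxsize=None)
    def deepest(v: int, used: int) -> int:
        """Longest chain starting at v; ``used`` includes v's family."""
        best = 1
        for u in succ[v]:
            b = node_bit[u]
            if used & b:
                continue
            d = 1 + deepest(u, used | b)
            if d > best:
                best = d
        return best

    max_depth = max(deepest(v, node_bit[v]) for v in range(n))

    chains: list[Chain] = []
    path: list[int] = []

    def walk(v: int, used: int, remaining: int) -> None:
        if max_chains is not None and len(chains) >= max_chains:
            return
        path.append(v)
        if remaining == 1:
            chains.append(Chain(nodes=tuple(g.nodes[i] for i in path)))
        else:
            for u in succ[v]:
                b = node_bit[u]
                if used & b:
                    continue
                if deepest(u, used | b) == remaining - 1:
                    walk(u, used | b, remaining - 1)
        path.pop()

    for v in range(n):
        if deepest(v, node_bit[v]) == max_depth:
            walk(v, node_bit[v], max_depth)
    deepest.cache_clear()
    return max_depth, chains


def depth_by_context_policy(
    table: CompatibilityTable,
    policies: list[tuple[str, Callable[[GateContext], bool] | None]],
    max_chains: int | None = None,
) -> list[dict]:
    """Max depth (and node/edge counts) under each context policy.

    ``policies`` are (name, filter) pairs; relaxing a policy by set
    inclusion can only add nodes and edges, so depth is monotone
    non-decreasing along nested policies.
    """
    if not policies:
        raise ValueError("at least one policy is required")
    report = []
    for name, pred in policies:
        graph = build_graph(table, context_filter=pred)
        depth, chains = longest_chains(graph, max_chains=max_chains)
        report.append(
            {
                "policy": name,
                "n_nodes": len(graph.nodes),
                "n_edges": int(graph.adjacency.sum()),
                "max_depth": depth,
                "n_maximal_chains": len(chains),
                "chains": chains,
            }
        )
    return report
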