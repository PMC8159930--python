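"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written from first principles (exhaustive
enumeration, exact rational arithmetic, textbook formulas) or taken from a
library implementation that shares no code with the package, so that
agreement is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import itertools
from collections import Counter
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from flowcontrast.io import ExpressionMatrix
from flowcontrast.network import (
    SINK_NODE,
    SOURCE_NODE,
    AnalysisConfig,
    ContextFlowNetwork,
)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def expr_from_dict(values: dict[str, list[float]], samples: list[str] | None = None,
                   phenotype: dict[str, str] | None = None) -> ExpressionMatrix:
    """ExpressionMatrix from {gene: row} with auto-named samples."""
    n = len(next(iter(values.values())))
    samples = samples or [f"S{i}" for i in range(1, n + 1)]
    frame = pd.DataFrame(values, index=samples).T
    frame.index = [g.upper() for g in frame.index]
    return ExpressionMatrix(frame, phenotype)


def make_network(
    edges: list[tuple[str, str, float]],
    source_caps: dict[str, int],
    config: AnalysisConfig | None = None,
) -> ContextFlowNetwork:
    """ContextFlowNetwork straight from weighted edges and S-arc capacities."""
    config = config or AnalysisConfig()
    frame = pd.DataFrame(
        sorted((min(u, v), max(u, v), w) for u, v, w in edges),
        columns=["u", "v", "weight"],
    )
    return ContextFlowNetwork(
        phenotype="test", edges=frame, source_caps=source_caps, config=config
    )


def random_tiny_network(rng: np.random.Generator) -> ContextFlowNetwork:
    """A random ≤6-gene-node instance with small integer capacities, suitable
    for exhaustive oracle comparison."""
    n = int(rng.integers(3, 7))
    genes = [f"N{i}" for i in range(n)]
    # random connected-ish edge set
    possible = list(itertools.combinations(genes, 2))
    k = int(rng.integers(n - 1, min(len(possible), n + 3) + 1))
    idx = rng.choice(len(possible), size=k, replace=False)
    edges = [
        (possible[i][0], possible[i][1], float(rng.integers(1, 7)) / 100.0)
        for i in sorted(idx)
    ]
    present = sorted({g for u, v, _w in edges for g in (u, v)})
    n_src = int(rng.integers(1, min(3, len(present)) + 1))
    src = rng.choice(present, size=n_src, replace=False)
    caps = {str(g): int(rng.integers(1, 3)) for g in sorted(src)}
    config = AnalysisConfig(integer_scale=100, epsilon_terminal=0.5, supply=1.0)
    return make_network(edges, caps, config)


# ---------------------------------------------------------------------------
# flow oracles
# ---------------------------------------------------------------------------


def exhaustive_min_cost_max_flow(network: ContextFlowNetwork) -> tuple[int, int]:
    """Exhaustive integral-flow enumeration oracle.

    Every optimal integral flow is cycle-free (all costs positive) and hence
    decomposes into simple S→T paths, so enumerating all multisets of simple
    paths whose additive arc usage respects capacities covers the optimum
    exactly; multisets with antiparallel overlap only overestimate cost and
    never win. Returns (max delivered, min cost at that value).
    """
    arc_cap = {(a.tail, a.head): a.capacity for a in network.arcs}
    arc_cost = {(a.tail, a.head): a.cost for a in network.arcs}
    graph = nx.DiGraph()
    graph.add_edges_from(arc_cap)
    if SOURCE_NODE not in graph or SINK_NODE not in graph:
        return 0, 0
    paths = [
        [(p[i], p[i + 1]) for i in range(len(p) - 1)]
        for p in nx.all_simple_paths(graph, SOURCE_NODE, SINK_NODE)
    ]
    if not paths:
        return 0, 0
    path_costs = [sum(arc_cost[e] for e in p) for p in paths]
    best = [0, 0]  # (max delivered, min cost at that value)

    def dfs(start: int, value: int, cost: int, caps: dict) -> None:
        if value > best[0] or (value == best[0] and cost < best[1]):
            best[0], best[1] = value, cost
        for j in range(start, len(paths)):
            if all(caps[e] >= 1 for e in paths[j]):
                for e in paths[j]:
                    caps[e] -= 1
                dfs(j, value + 1, cost + path_costs[j], caps)
                for e in paths[j]:
                    caps[e] += 1

    dfs(0, 0, 0, dict(arc_cap))
    return best[0], best[1]


def networkx_min_cost_max_flow(network: ContextFlowNetwork) -> tuple[int, int]:
    """Independent library oracle: networkx max-flow-then-min-cost."""
    graph = nx.DiGraph()
    for arc in network.arcs:
        graph.add_edge(arc.tail, arc.head, capacity=arc.capacity, weight=arc.cost)
    if SOURCE_NODE not in graph or SINK_NODE not in graph:
        return 0, 0
    try:
        flow_dict = nx.max_flow_min_cost(graph, SOURCE_NODE, SINK_NODE)
    except nx.NetworkXUnfeasible:
        return 0, 0
    delivered = sum(flow_dict[SOURCE_NODE].values())
    cost = sum(
        graph[u][v]["weight"] * f
        for u, targets in flow_dict.items()
        for v, f in targets.items()
        if f > 0
    )
    return delivered, cost


def assert_conservation(network: ContextFlowNetwork, solution) -> None:
    """Independent exact-integer conservation check from raw arc flows."""
    inflow: Counter = Counter()
    outflow: Counter = Counter()
    for (tail, head), flow in solution.arc_flows.items():
        outflow[tail] += flow
        inflow[head] += flow
    for gene in network.nodes:
        assert inflow[gene] == outflow[gene], gene
    assert sum(solution.terminal_flow_int.values()) == solution.delivered_int


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------


def exact_hypergeom_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Upper-tail P(X >= k) by direct summation in exact rational arithmetic."""
    if k <= 0:
        return Fraction(1)
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(total, comb(N, n))


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up written out directly from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(0)
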