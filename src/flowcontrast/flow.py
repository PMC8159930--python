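"""Exact integral minimum-cost maximum-flow and flow summaries.

The solver routes as much of the injected supply as the network admits from
the super-source to the super-sink, and among all maximum flows returns one
of minimum total cost. It is a successive-shortest-augmenting-path
implementation with Johnson potentials over the scaled integer capacities
and costs produced by :mod:`flowcontrast.network`, so results are exact and
platform-independent: conservation holds as integer identities and the
objective is unique even when the flow decomposition is not. Canonical arc
ordering makes the returned arc flows reproducible.

Because every arc cost is strictly positive, an optimal flow never carries
flow in both directions of an antiparallel arc pair; this is asserted on
every solve.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import pandas as pd

from .network import SINK_NODE, SOURCE_NODE, ContextFlowNetwork

logger = logging.getLogger(__name__)

__all__ = ["FlowSolution", "solve_min_cost_flow", "summarize_flows", "validate_solution"]


@dataclass
class FlowSolution:
    """Arc flows and per-node summaries for one phenotype.

    Integer quantities (``*_int``) are in scaled units; the float views
    divide by ``scale`` and are in supply units. ``objective_int`` is in
    (scaled cost) x (scaled flow) units and is the canonical quantity for
    exact comparisons.
    """

    phenotype: str
    scale: int
    arc_flows: dict[tuple[str, str], int]
    node_throughput_int: dict[str, int]
    terminal_flow_int: dict[str, int]
    total_edge_flow_int: dict[tuple[str, str], int]
    objective_int: int
    delivered_int: int

    @property
    def node_throughput(self) -> dict[str, float]:
        return {g: f / self.scale for g, f in self.node_throughput_int.items()}

    @property
    def terminal_flow(self) -> dict[str, float]:
        return {g: f / self.scale for g, f in self.terminal_flow_int.items()}

    @property
    def total_edge_flow(self) -> dict[tuple[str, str], float]:
        return {e: f / self.scale for e, f in self.total_edge_flow_int.items()}

    @property
    def delivered(self) -> float:
        return self.delivered_int / self.scale

    @property
    def objective(self) -> float:
        return self.objective_int / (self.scale * self.scale)

    def throughput_of(self, gene: str) -> float:
        return self.node_throughput_int.get(gene, 0) / self.scale

    def terminal_of(self, gene: str) -> float:
        return self.terminal_flow_int.get(gene, 0) / self.scale


def empty_solution(phenotype: str, scale: int) -> FlowSolution:
    return FlowSolution(phenotype, scale, {}, {}, {}, {}, 0, 0)


def solve_min_cost_flow(network: ContextFlowNetwork) -> FlowSolution:
    """Minimum-cost maximum flow from the super-source to the super-sink.

    Returns a solution with delivered = 0 (and a warning) when no
    augmenting path exists.
    """
    arcs = sorted(network.arcs, key=lambda a: (a.tail, a.head))
    nodes = sorted({a.tail for a in arcs} | {a.head for a in arcs} | {SOURCE_NODE, SINK_NODE})
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    s, t = index[SOURCE_NODE], index[SINK_NODE]

    # residual graph in parallel arrays; forward/backward arcs paired by xor 1
    to: list[int] = []
    cap: list[int] = []
    cost: list[int] = []
    adj: list[list[int]] = [[] for _ in range(n)]
    for arc in arcs:
        u, v = index[arc.tail], index[arc.head]
        adj[u].append(len(to))
        to.append(v)
        cap.append(arc.capacity)
        cost.append(arc.cost)
        adj[v].append(len(to))
        to.append(u)
        cap.append(0)
        cost.append(-arc.cost)

    INF = float("inf")
    potential = [0] * n  # all costs positive, so zero potentials are valid
    delivered = 0
    objective = 0
    while True:
        dist = [INF] * n
        dist[s] = 0
        prev_arc = [-1] * n
        heap = [(0, s)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u]:
                continue
            for ai in adj[u]:
                if cap[ai] <= 0:
                    continue
                v = to[ai]
                nd = d + cost[ai] + potential[u] - potential[v]
                if nd < dist[v]:
                    dist[v] = nd
                    prev_arc[v] = ai
                    heapq.heappush(heap, (nd, v))
        if dist[t] == INF:
            break
        for i in range(n):
            if dist[i] < INF:
                potential[i] += dist[i]
        # bottleneck along the shortest path
        push = None
        v = t
        while v != s:
            ai = prev_arc[v]
            push = cap[ai] if push is None else min(push, cap[ai])
            v = to[ai ^ 1]
        v = t
        while v != s:
            ai = prev_arc[v]
            cap[ai] -= push
            cap[ai ^ 1] += push
            objective += push * cost[ai]
            v = to[ai ^ 1]
        delivered += push

    if delivered == 0:
        logger.warning("no augmenting path: delivered = 0 (%s)", network.phenotype or "unnamed")

    # recover per-arc flows (flow on forward arc = residual on its partner)
    arc_flows: dict[tuple[str, str], int] = {}
    cursor = 0
    for arc in arcs:
        flow = cap[2 * cursor + 1]
        cursor += 1
        if flow:
            arc_flows[(arc.tail, arc.head)] = flow

    node_throughput: dict[str, int] = {}
    terminal_flow: dict[str, int] = {}
    edge_flow: dict[tuple[str, str], int] = {}
    for (tail, head), flow in arc_flows.items():
        if head == SINK_NODE:
            terminal_flow[tail] = terminal_flow.get(tail, 0) + flow
        if head not in (SINK_NODE,):
            node_throughput[head] = node_throughput.get(head, 0) + flow
        if tail != SOURCE_NODE and head != SINK_NODE:
            key = (tail, head) if tail < head else (head, tail)
            edge_flow[key] = edge_flow.get(key, 0) + flow

    solution = FlowSolution(
        phenotype=network.phenotype,
        scale=network.config.integer_scale,
        arc_flows=arc_flows,
        node_throughput_int=node_throughput,
        terminal_flow_int=terminal_flow,
        total_edge_flow_int=edge_flow,
        objective_int=objective,
        delivered_int=delivered,
    )
    validate_solution(network, solution)
    return solution


def validate_solution(network: ContextFlowNetwork, solution: FlowSolution) -> None:
    """Assert the structural invariants of a solved instance (exact integers):
    conservation at every gene node, capacity bounds, terminal balance, and
    no antiparallel waste."""
    caps = {(a.tail, a.head): a.capacity for a in network.arcs}
    inflow: dict[str, int] = {}
    outflow: dict[str, int] = {}
    for (tail, head), flow in solution.arc_flows.items():
        assert 0 <= flow <= caps[(tail, head)], f"capacity violated on {tail}->{head}"
        outflow[tail] = outflow.get(tail, 0) + flow
        inflow[head] = inflow.get(head, 0) + flow
    for gene in network.nodes:
        assert inflow.get(gene, 0) == outflow.get(gene, 0), f"conservation violated at {gene}"
    assert sum(solution.terminal_flow_int.values()) == solution.delivered_int
    assert solution.delivered_int <= network.total_supply
    for (tail, head), flow in solution.arc_flows.items():
        if tail in (SOURCE_NODE,) or head in (SINK_NODE,):
            continue
        reverse = solution.arc_flows.get((head, tail), 0)
        assert min(flow, reverse) == 0, f"antiparallel waste on {tail}<->{head}"


def summarize_flows(
    solution: FlowSolution,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tables of node throughput, terminal flow, and total edge flow, in
    supply units, sorted descending (ties by name)."""
    throughput = pd.DataFrame(
        sorted(solution.node_throughput.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "throughput"],
    )
    terminal = pd.DataFrame(
        sorted(solution.terminal_flow.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "terminal_flow"],
    )
    edges = pd.DataFrame(
        [
            (u, v, f)
            for (u, v), f in sorted(
                solution.total_edge_flow.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ],
        columns=["u", "v", "total_flow"],
    )
    return throughput, terminal, edges
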