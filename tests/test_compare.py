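"""phenotype_compare module: flow differences, roles, impact, key edges,
subnetwork, and motif views."""

import pandas as pd
import pytest

from flowcontrast.compare import (
    classify_roles,
    dominant_in_b,
    extract_motif,
    impact_score,
    key_edges,
    node_flow_difference,
    prioritized_subnetwork,
)
from flowcontrast.errors import GeneNotFoundError
from flowcontrast.flow import FlowSolution, solve_min_cost_flow
from flowcontrast.network import AnalysisConfig
from flowcontrast.stratify import SourceSet

from conftest import make_network


def solution(
    scale=10_000,
    throughput=None,
    terminal=None,
    edge_flow=None,
    phenotype="X",
):
    """Hand-built FlowSolution (integer fields in scaled units)."""
    return FlowSolution(
        phenotype=phenotype,
        scale=scale,
        arc_flows={},
        node_throughput_int=throughput or {},
        terminal_flow_int=terminal or {},
        total_edge_flow_int=edge_flow or {},
        objective_int=0,
        delivered_int=sum((terminal or {}).values()),
    )


def source_set(genes):
    return SourceSet(
        pd.DataFrame(
            {"gene": genes, "log2fc": 2.0, "p": 0.001, "q": 0.01, "selected": True}
        )
    )


# ---------------------------------------------------------------------------
# node_flow_difference
# ---------------------------------------------------------------------------


def test_identical_solutions_zero_diff():
    sol = solution(throughput={"G1": 500, "G2": 300})
    frame = node_flow_difference(sol, sol)
    assert (frame["flow_diff"] == 0).all()


def test_gene_only_in_b():
    sol_a = solution(throughput={"G1": 500})
    sol_b = solution(throughput={"G1": 500, "G2": 300})
    frame = node_flow_difference(sol_a, sol_b).set_index("gene")
    assert frame.loc["G2", "flow_a"] == 0
    assert frame.loc["G2", "flow_diff"] == pytest.approx(0.03)


def test_swap_negates_and_preserves_ranking():
    sol_a = solution(throughput={"G1": 500, "G2": 100})
    sol_b = solution(throughput={"G1": 100, "G2": 900})
    fwd = node_flow_difference(sol_a, sol_b)
    rev = node_flow_difference(sol_b, sol_a)
    assert list(fwd["gene"]) == list(rev["gene"])
    assert (fwd["flow_diff"].to_numpy() == -rev["flow_diff"].to_numpy()).all()


# ---------------------------------------------------------------------------
# classify_roles
# ---------------------------------------------------------------------------


def test_chain_roles_source_and_target():
    config = AnalysisConfig(epsilon_terminal=0.1)
    net = make_network([("G1", "G2", 1.0)], {"G1": 10_000}, config)
    sol = solve_min_cost_flow(net)  # delivered 0.1, all terminating at G2
    empty = solution(phenotype="A")
    roles = classify_roles(empty, sol, source_set(["G1"]), config).set_index("gene")
    assert roles.loc["G1", "role"] == "source"
    assert roles.loc["G2", "role"] == "target"  # terminal 0.1 >= 0.05 * supply


def test_zero_throughput_gene_excluded():
    sol_a = solution(throughput={"G1": 0})
    sol_b = solution(throughput={"G1": 0})
    roles = classify_roles(sol_a, sol_b, source_set(["G1"]), AnalysisConfig())
    assert roles.empty


def test_router_below_target_fraction():
    config = AnalysisConfig()
    sol_a = solution()
    sol_b = solution(throughput={"G9": 400}, terminal={"G9": 400})
    roles = classify_roles(sol_a, sol_b, source_set(["G1"]), config).set_index("gene")
    assert roles.loc["G9", "role"] == "router"  # 0.04 < tau = 0.05


def test_source_precedence_over_target():
    config = AnalysisConfig()
    sol_b = solution(throughput={"G1": 2000}, terminal={"G1": 2000})
    roles = classify_roles(solution(), sol_b, source_set(["G1"]), config).set_index("gene")
    assert roles.loc["G1", "role"] == "source"


# ---------------------------------------------------------------------------
# impact_score
# ---------------------------------------------------------------------------


def test_impact_zero_when_identical():
    config = AnalysisConfig(integer_scale=1000, epsilon_terminal=0.5)
    net = make_network([("A", "B", 0.9)], {"A": 100}, config)
    sol = solve_min_cost_flow(net)
    assert impact_score(net, net, sol, sol, "A") == 0.0


def test_impact_hand_formula():
    """d_A=4, d_B=6, |N_A ∩ N_B| = 3, |N_A ∪ N_B| = 7, flow component 0.5
    -> impact = (2/6 + 4/7 + 1/2) / 3."""
    config = AnalysisConfig(integer_scale=1000, epsilon_terminal=0.5)
    shared = ["N1", "N2", "N3"]
    only_a = ["A4"]
    only_b = ["B4", "B5", "B6"]
    net_a = make_network(
        [("G", x, 0.9) for x in shared + only_a], {"G": 100}, config
    )
    net_b = make_network(
        [("G", x, 0.9) for x in shared + only_b], {"G": 100}, config
    )
    sol_a = solution(scale=1000, throughput={"G": 100, "OTHER": 0})
    sol_b = solution(scale=1000, throughput={"G": 200, "OTHER": 200})
    # max |flow_diff| = 0.2 (OTHER), G's diff = 0.1 -> flow component 0.5
    got = impact_score(net_a, net_b, sol_a, sol_b, "G")
    assert got == pytest.approx((2 / 6 + 4 / 7 + 1 / 2) / 3)


def test_impact_components_saturate():
    config = AnalysisConfig(integer_scale=1000, epsilon_terminal=0.5)
    net_a = make_network([("G", "X1", 0.9)], {"G": 100}, config)
    net_b = make_network([("G", "Y1", 0.9)], {"G": 100}, config)
    sol_a = solution(scale=1000)
    sol_b = solution(scale=1000, throughput={"G": 100})
    # disjoint neighborhoods, equal degrees, G holds the max flow shift
    got = impact_score(net_a, net_b, sol_a, sol_b, "G")
    assert got == pytest.approx((0 + 1 + 1) / 3)


def test_impact_gene_absent_from_both():
    config = AnalysisConfig(integer_scale=1000, epsilon_terminal=0.5)
    net = make_network([("A", "B", 0.9)], {"A": 100}, config)
    sol = solution(scale=1000)
    with pytest.raises(GeneNotFoundError):
        impact_score(net, net, sol, sol, "NOPE")


# ---------------------------------------------------------------------------
# key_edges
# ---------------------------------------------------------------------------


def test_ratio_boundary_inclusive():
    sol_a = solution(edge_flow={("X", "Y"): 5000})
    sol_b = solution(edge_flow={("X", "Y"): 1000})
    frame = key_edges(sol_a, sol_b, AnalysisConfig())
    row = frame.iloc[0]
    assert row["ratio"] == pytest.approx(5.0)
    assert bool(row["key"]) is True
    assert row["exclusive"] == "none"


def test_ratio_below_threshold_not_key():
    sol_a = solution(edge_flow={("X", "Y"): 4900})
    sol_b = solution(edge_flow={("X", "Y"): 1000})
    row = key_edges(sol_a, sol_b, AnalysisConfig()).iloc[0]
    assert row["ratio"] == pytest.approx(4.9)
    assert bool(row["key"]) is False


def test_exclusive_edge_is_key():
    sol_a = solution()
    sol_b = solution(edge_flow={("X", "Y"): 2000})
    row = key_edges(sol_a, sol_b, AnalysisConfig()).iloc[0]
    assert row["exclusive"] == "B"
    assert bool(row["key"]) is True


def test_dominant_in_b_filter():
    sol_a = solution(edge_flow={("X", "Y"): 100, ("P", "Q"): 900})
    sol_b = solution(edge_flow={("X", "Y"): 900, ("P", "Q"): 100})
    frame = dominant_in_b(key_edges(sol_a, sol_b, AnalysisConfig()))
    assert list(zip(frame["u"], frame["v"])) == [("X", "Y")]


# ---------------------------------------------------------------------------
# prioritized_subnetwork
# ---------------------------------------------------------------------------


def roles_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "role", "flow_a", "flow_b", "flow_diff", "degree_a", "degree_b"],
    ).assign(impact=0.0)


def test_subnetwork_counts_partition_nodes():
    roles = roles_frame(
        [
            ("S1", "source", 0.1, 0.2, 0.1, 1, 1),
            ("R1", "router", 0.0, 0.05, 0.05, 2, 2),
            ("T1", "target", 0.0, 0.2, 0.2, 3, 3),
        ]
    )
    edges = key_edges(
        solution(edge_flow={("S1", "T1"): 100}),
        solution(edge_flow={("S1", "T1"): 2000}),
        AnalysisConfig(),
    )
    sub = prioritized_subnetwork(roles, edges, AnalysisConfig())
    assert sum(sub.counts.values()) == len(sub.nodes)
    assert set(sub.member_genes()) == {"S1", "R1", "T1"}


def test_subnetwork_zero_routers_requested():
    roles = roles_frame(
        [
            ("S1", "source", 0.1, 0.2, 0.1, 1, 1),
            ("R1", "router", 0.0, 0.05, 0.05, 2, 2),
        ]
    )
    config = AnalysisConfig(top_k_routers=0)
    sub = prioritized_subnetwork(roles, pd.DataFrame(), config)
    assert sub.member_genes() == ["S1"]
    assert sub.edges.empty


def test_subnetwork_edge_endpoints_are_members():
    roles = roles_frame(
        [
            ("S1", "source", 0.1, 0.2, 0.1, 1, 1),
            ("T1", "target", 0.0, 0.2, 0.2, 3, 3),
        ]
    )
    edges = key_edges(
        solution(edge_flow={("S1", "T1"): 100, ("S1", "Z9"): 100}),
        solution(edge_flow={("S1", "T1"): 2000}),
        AnalysisConfig(),
    )
    sub = prioritized_subnetwork(roles, edges, AnalysisConfig())
    members = set(sub.member_genes())
    for row in sub.edges.itertuples(index=False):
        assert row.u in members and row.v in members


# ---------------------------------------------------------------------------
# extract_motif
# ---------------------------------------------------------------------------


def test_motif_chain_neighbors():
    config = AnalysisConfig(integer_scale=1000, epsilon_terminal=0.5)
    net = make_network([("G1", "G2", 0.9), ("G2", "G3", 0.9)], {"G1": 100}, config)
    sol = solve_min_cost_flow(net)
    view = extract_motif(net, sol, "G2")
    assert view.degree == 2
    neighbors = set(view.edges["u"]) | set(view.edges["v"]) - {"G2"}
    assert {"G1", "G3"} <= neighbors


def test_motif_absent_gene():
    config = AnalysisConfig(integer_scale=1000, epsilon_terminal=0.5)
    net = make_network([("G1", "G2", 0.9)], {"G1": 100}, config)
    sol = solve_min_cost_flow(net)
    with pytest.raises(GeneNotFoundError):
        extract_motif(net, sol, "NOPE")


def test_motif_degree_matches_network_degree():
    config = AnalysisConfig(integer_scale=1000, epsilon_terminal=0.5)
    net = make_network(
        [("G1", "G2", 0.9), ("G2", "G3", 0.9), ("G3", "G1", 0.9)], {"G1": 100}, config
    )
    sol = solve_min_cost_flow(net)
    for gene in net.nodes:
        assert extract_motif(net, sol, gene).degree == net.degree()[gene]
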