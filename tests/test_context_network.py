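"""context_network module: co-expression weights, thresholding, SNF
neighborhood, and flow-network assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from flowcontrast.errors import DisconnectedSourcesError, ParameterError
from flowcontrast.io import Interactome
from flowcontrast.network import (
    SINK_NODE,
    SOURCE_NODE,
    AnalysisConfig,
    apply_cor_threshold,
    build_flow_network,
    edge_coexpression,
    functional_neighborhood,
)
from flowcontrast.stratify import select_sources

from conftest import expr_from_dict


def weights_of(frame):
    return {(r.u, r.v): r.weight for r in frame.itertuples(index=False)}


# ---------------------------------------------------------------------------
# edge_coexpression
# ---------------------------------------------------------------------------


def test_linear_relation_gives_weight_one():
    expr = expr_from_dict({"A": [1, 2, 3], "B": [3, 5, 7], "C": [-1, -2, -3]})
    inter = Interactome.from_edges([("A", "B"), ("A", "C")])
    w = weights_of(edge_coexpression(expr, inter))
    assert w[("A", "B")] == pytest.approx(1.0)  # y = 2x + 1
    assert w[("A", "C")] == pytest.approx(1.0)  # y = -x, absolute value


def test_hand_pearson_value():
    expr = expr_from_dict({"A": [1, 2, 3], "B": [1, 1, 2]})
    inter = Interactome.from_edges([("A", "B")])
    w = weights_of(edge_coexpression(expr, inter))
    assert w[("A", "B")] == pytest.approx(math.sqrt(3) / 2)


def test_zero_variance_gene_weight_zero():
    expr = expr_from_dict({"A": [1, 1, 1], "B": [1, 2, 3]})
    inter = Interactome.from_edges([("A", "B")])
    w = weights_of(edge_coexpression(expr, inter))
    assert w[("A", "B")] == 0.0


def test_unmeasured_endpoint_dropped():
    expr = expr_from_dict({"A": [1, 2, 3], "B": [1, 1, 2]})
    inter = Interactome.from_edges([("A", "B"), ("A", "ZZZ")])
    frame = edge_coexpression(expr, inter)
    assert set(weights_of(frame)) == {("A", "B")}


def test_too_few_samples():
    expr = expr_from_dict({"A": [1, 2], "B": [1, 2]})
    with pytest.raises(ParameterError):
        edge_coexpression(expr, Interactome.from_edges([("A", "B")]))


# ---------------------------------------------------------------------------
# apply_cor_threshold
# ---------------------------------------------------------------------------


def test_threshold_boundary_inclusive():
    frame = pd.DataFrame(
        {"u": ["A", "A", "A"], "v": ["B", "C", "D"], "weight": [0.49, 0.50, 0.51]}
    )
    retained = apply_cor_threshold(frame, 0.5)
    assert len(retained) == 2
    assert set(retained["v"]) == {"C", "D"}


def test_threshold_extremes():
    frame = pd.DataFrame({"u": ["A", "A"], "v": ["B", "C"], "weight": [0.2, 1.0]})
    assert len(apply_cor_threshold(frame, 0.0)) == 2
    only_one = apply_cor_threshold(frame, 1.0)
    assert list(only_one["v"]) == ["C"]


def test_threshold_monotone():
    rng = np.random.default_rng(2)
    frame = pd.DataFrame(
        {"u": "A", "v": [f"B{i}" for i in range(30)], "weight": rng.uniform(size=30)}
    )
    prev = None
    for t in (0.2, 0.5, 0.8):
        kept = set(apply_cor_threshold(frame, t)["v"])
        if prev is not None:
            assert kept <= prev
        prev = kept


# ---------------------------------------------------------------------------
# functional_neighborhood
# ---------------------------------------------------------------------------


def _neighborhood_expr(n_candidates=21, seed=0):
    rng = np.random.default_rng(seed)
    data = {"SRC": rng.normal(size=10)}
    for i in range(n_candidates):
        data[f"C{i:02d}"] = rng.normal(size=10)
    return expr_from_dict(data)


def test_snf_zero_keeps_everything():
    expr = _neighborhood_expr()
    kept = functional_neighborhood(expr, ["SRC"], 0.0)
    assert kept == set(expr.genes)


def test_snf_quantile_count():
    # 21 candidates at snf = 0.95 -> ceil(21 * 0.05) = 2 kept plus the source
    expr = _neighborhood_expr(21)
    kept = functional_neighborhood(expr, ["SRC"], 0.95)
    assert len(kept) == 3 and "SRC" in kept


def test_snf_nestedness():
    expr = _neighborhood_expr(40)
    tight = functional_neighborhood(expr, ["SRC"], 0.95)
    loose = functional_neighborhood(expr, ["SRC"], 0.90)
    assert tight <= loose


def test_snf_parameter_and_missing_source():
    expr = _neighborhood_expr()
    with pytest.raises(ParameterError):
        functional_neighborhood(expr, ["SRC"], 1.5)
    with pytest.raises(ParameterError):
        functional_neighborhood(expr, ["NOPE"], 0.95)


# ---------------------------------------------------------------------------
# build_flow_network
# ---------------------------------------------------------------------------


def one_source_set(genes_lfc: dict[str, float]):
    frame = pd.DataFrame(
        {
            "gene": list(genes_lfc),
            "log2fc": list(genes_lfc.values()),
            "p": 0.001,
            "q": 0.01,
            "selected": True,
        }
    )
    from flowcontrast.stratify import SourceSet

    return SourceSet(frame)


def test_chain_network_definition_unrolled():
    # one source g1, chain g1-g2 (w=1): S->g1 cap = supply * scale,
    # g1<->g2 caps = scale, g2->T cap = round(0.1 * 1 * scale)
    config = AnalysisConfig(epsilon_terminal=0.1)
    edges = pd.DataFrame({"u": ["G1"], "v": ["G2"], "weight": [1.0]})
    net = build_flow_network(edges, {"G1", "G2"}, one_source_set({"G1": 2.0}), config)
    caps = {(a.tail, a.head): a.capacity for a in net.arcs}
    scale = config.integer_scale
    assert caps[(SOURCE_NODE, "G1")] == scale  # supply = 1.0
    assert caps[("G1", "G2")] == scale and caps[("G2", "G1")] == scale
    assert caps[("G2", SINK_NODE)] == round(0.1 * 1.0 * scale)
    assert all(a.cost > 0 for a in net.arcs)


def test_source_cap_largest_remainder():
    # |log2FC| {2, 1} at supply 1, scale 10^4 -> caps {6667, 3333}
    config = AnalysisConfig()
    edges = pd.DataFrame(
        {"u": ["G1", "G2"], "v": ["G3", "G3"], "weight": [0.9, 0.9]}
    )
    net = build_flow_network(
        edges, {"G1", "G2", "G3"}, one_source_set({"G1": 2.0, "G2": 1.0}), config
    )
    assert net.source_caps == {"G1": 6667, "G2": 3333}
    assert net.total_supply == config.integer_scale


def test_bypass_sources_get_equal_caps():
    config = AnalysisConfig()
    edges = pd.DataFrame(
        {"u": ["G1", "G2"], "v": ["G3", "G3"], "weight": [0.9, 0.9]}
    )
    source_set = select_sources(gene_list=["G1", "G2"])
    net = build_flow_network(edges, {"G1", "G2", "G3"}, source_set, config)
    assert net.source_caps == {"G1": 5000, "G2": 5000}


def test_empty_retained_edges_disconnected_error():
    config = AnalysisConfig()
    edges = pd.DataFrame(columns=["u", "v", "weight"])
    with pytest.raises(DisconnectedSourcesError):
        build_flow_network(edges, {"G1"}, one_source_set({"G1": 2.0}), config)


def test_neighborhood_restriction_drops_outside_edges():
    config = AnalysisConfig()
    edges = pd.DataFrame(
        {"u": ["G1", "G2"], "v": ["G2", "G4"], "weight": [0.9, 0.9]}
    )
    net = build_flow_network(edges, {"G1", "G2"}, one_source_set({"G1": 2.0}), config)
    assert set(net.nodes) == {"G1", "G2"}


def test_config_validation():
    with pytest.raises(ParameterError):
        AnalysisConfig(snf=1.5)
    with pytest.raises(ParameterError):
        AnalysisConfig(ratio_threshold=0.5)
    with pytest.raises(ParameterError):
        AnalysisConfig(integer_scale=10)
    with pytest.raises(ParameterError):
        AnalysisConfig(epsilon_terminal=0.0)


def test_all_arc_parameters_integral():
    config = AnalysisConfig()
    edges = pd.DataFrame(
        {"u": ["G1", "G2"], "v": ["G2", "G3"], "weight": [0.73, 0.581]}
    )
    net = build_flow_network(
        edges, {"G1", "G2", "G3"}, one_source_set({"G1": 1.3}), config
    )
    for arc in net.arcs:
        assert isinstance(arc.capacity, int) and isinstance(arc.cost, int)
        assert arc.capacity >= 0 and arc.cost > 0
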