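"""synthetic module: generator postconditions and planted-structure statistics."""

import numpy as np
import pytest
from scipy import stats

from flowcontrast.errors import ParameterError
from flowcontrast.synthetic import (
    SyntheticScenario,
    generate_dependency_table,
    generate_interactome,
    generate_two_phenotype_expression,
    simulate,
)


def sample_corr(expr, u, v):
    x = expr.data.loc[u].to_numpy()
    y = expr.data.loc[v].to_numpy()
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# interactome generator
# ---------------------------------------------------------------------------


def test_interactome_edge_count_and_connectivity():
    import networkx as nx

    inter = generate_interactome(50, 2, seed=1)
    assert len(inter) == (50 - 2) * 2
    assert nx.is_connected(inter.to_networkx())


def test_interactome_deterministic():
    assert generate_interactome(50, 2, 1).edges == generate_interactome(50, 2, 1).edges


def test_interactome_heavy_tail():
    inter = generate_interactome(500, 3, seed=7)
    degrees = np.array(sorted(inter.degree().values()))
    assert degrees.max() >= 3 * np.median(degrees)


def test_interactome_parameter_error():
    with pytest.raises(ParameterError):
        generate_interactome(2, 2, seed=0)


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------


def test_null_scenario_type_one_error_near_alpha():
    """delta=0, no rewiring: per-gene two-sample t-tests reject at ~5%."""
    rates = []
    for seed in range(3):
        scenario = SyntheticScenario(delta=0.0, rewired_edges=[], seed=seed)
        inter = generate_interactome(scenario.n_genes, scenario.m_attach, seed)
        expr_a, expr_b, _ = generate_two_phenotype_expression(inter, scenario)
        p = stats.ttest_ind(
            expr_b.data.to_numpy(), expr_a.data.to_numpy(), axis=1, equal_var=False
        ).pvalue
        rates.append(float(np.mean(p < 0.05)))
    assert 0.005 <= float(np.mean(rates)) <= 0.10


def test_planted_edge_correlations():
    """Rewired edges: sample r within [0.8, 0.96] in B, within [-0.3, 0.3] in A
    (n = 100 samples; Fisher-z interval)."""
    for seed in (1, 2, 3):
        dataset = simulate(SyntheticScenario(n_samples_per_phenotype=100, seed=seed))
        for u, v in dataset.truth.rewired_edges:
            rb = sample_corr(dataset.expr_b, u, v)
            ra = sample_corr(dataset.expr_a, u, v)
            assert 0.8 <= rb <= 0.96, (seed, u, v, rb)
            assert -0.3 <= ra <= 0.3, (seed, u, v, ra)


def test_planted_source_log2fc():
    """Planted sources: empirical log2FC within 2 ± 0.6."""
    for seed in (1, 2, 3):
        dataset = simulate(SyntheticScenario(seed=seed))
        for g in dataset.truth.sources:
            lfc = float(
                dataset.expr_b.data.loc[g].mean() - dataset.expr_a.data.loc[g].mean()
            )
            assert 1.4 <= lfc <= 2.6, (seed, g, lfc)


def test_planted_correlation_recovery_margin():
    """Mean rewired-edge correlation in B exceeds that in A by >= 0.5."""
    dataset = simulate(SyntheticScenario(n_samples_per_phenotype=100, seed=4))
    gaps = [
        sample_corr(dataset.expr_b, u, v) - sample_corr(dataset.expr_a, u, v)
        for u, v in dataset.truth.rewired_edges
    ]
    assert float(np.mean(gaps)) >= 0.5


def test_expression_deterministic():
    a1 = simulate(SyntheticScenario(seed=5))
    a2 = simulate(SyntheticScenario(seed=5))
    assert a1.expr_a.data.equals(a2.expr_a.data)
    assert a1.expr_b.data.equals(a2.expr_b.data)
    assert a1.truth == a2.truth


def test_router_equals_target_rejected():
    with pytest.raises(ParameterError):
        SyntheticScenario(router="G0001", target="G0001")


def test_truth_genes_exist_and_rewired_edges_in_interactome():
    dataset = simulate(SyntheticScenario(seed=6))
    nodes = dataset.interactome.nodes
    assert dataset.truth.router in nodes and dataset.truth.target in nodes
    assert set(dataset.truth.sources) <= set(nodes)
    for edge in dataset.truth.rewired_edges:
        assert edge in dataset.interactome


def test_router_design_bound():
    """The planted router's only strong phenotype-B edges are its two relay
    edges: no source or target other than the designated feeder is adjacent
    to it in the base interactome."""
    dataset = simulate(SyntheticScenario(seed=7))
    truth = dataset.truth
    router_edges = [e for e in dataset.truth.rewired_edges if truth.router in e]
    assert len(router_edges) == 2  # feeder->router and router->target


# ---------------------------------------------------------------------------
# dependency generator
# ---------------------------------------------------------------------------


def test_dependency_essential_block_scores():
    for seed in range(5):
        table = generate_dependency_table(
            ["RPL6", "A", "B"], [f"L{i}" for i in range(10)], ["RPL6"], seed
        )
        assert (table.scores_for("RPL6") < -0.5).all()


def test_dependency_empty_block_no_strong_medians():
    for seed in range(5):
        table = generate_dependency_table(
            [f"G{i}" for i in range(50)], [f"L{i}" for i in range(10)], [], seed
        )
        medians = table.records.groupby("gene")["score"].median()
        assert (medians >= -1.0).all()


def test_dependency_deterministic():
    args = (["A", "B"], ["L1", "L2"], ["A"], 3)
    assert generate_dependency_table(*args).records.equals(
        generate_dependency_table(*args).records
    )


def test_dependency_errors():
    with pytest.raises(ParameterError):
        generate_dependency_table(["A"], [], [], 0)
    with pytest.raises(ParameterError):
        generate_dependency_table(["A"], ["L1"], ["B"], 0)


def test_simulate_essential_block_contains_router():
    dataset = simulate(SyntheticScenario(seed=8))
    router_scores = dataset.dependency.scores_for(dataset.truth.router)
    assert len(router_scores) == 10
    assert float(router_scores.median()) < -1.0
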