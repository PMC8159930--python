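"""Two-phenotype synthetic benchmark with planted differential network structure.

The generator emulates the statistical structure the pipeline is designed to
detect, without any external downloads:

* a scale-free interactome (preferential attachment), mimicking PPI hubs;
* shared baseline co-expression on interactome edges in both phenotypes,
  via a one-latent-factor-per-edge Gaussian model;
* a planted set of differentially expressed *source* genes (mean shift
  ``delta`` in phenotype B);
* a planted co-expression *module* active only in phenotype B that realizes
  the rewired edges: a hub *target* gene t that most sources wire into, and a
  *router* gene r on a source -> r -> t relay, so that information flow in
  phenotype B converges on t while transiting r;
* a dependency table with a planted essential-gene block
  (scores ~ N(-1.4, 0.2)) against a near-zero background (N(0, 0.3)).

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import DependencyTable, ExpressionMatrix, Interactome

__all__ = [
    "SyntheticScenario",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_interactome",
    "generate_two_phenotype_expression",
    "generate_dependency_table",
    "simulate",
]


@dataclass
class SyntheticScenario:
    """Parameters of the planted two-phenotype benchmark.

    Defaults are the package's standard study conditions: 300 genes on a
    preferential-attachment interactome (2 edges per new node), 50 samples
    per phenotype, baseline edge co-expression 0.3, planted module
    co-expression 0.9, 10 sources shifted by delta = 2 log2 units.
    """

    n_genes: int = 300
    m_attach: int = 2
    n_samples_per_phenotype: int = 50
    baseline_rho: float = 0.3
    rho_hi: float = 0.9
    n_sources: int = 10
    delta: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0
    # planted genes; auto-selected when left unset
    sources: list[str] | None = None
    router: str | None = None
    target: str | None = None
    rewired_edges: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.baseline_rho < self.rho_hi <= 0.99):
            raise ParameterError("require 0 < baseline_rho < rho_hi <= 0.99")
        if self.n_sources >= self.n_genes:
            raise ParameterError("n_sources must be smaller than n_genes")
        if self.n_samples_per_phenotype < 10:
            raise ParameterError("need at least 10 samples per phenotype")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.router is not None and self.router == self.target:
            raise ParameterError("planted router and target must differ")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery checks."""

    sources: tuple[str, ...]
    source_log2fc: dict[str, float]
    router: str
    target: str
    rewired_edges: tuple[tuple[str, str], ...]
    seed: int

    def as_dict(self) -> dict:
        return {
            "sources": list(self.sources),
            "source_log2fc": dict(self.source_log2fc),
            "router": self.router,
            "target": self.target,
            "rewired_edges": [list(e) for e in self.rewired_edges],
            "seed": self.seed,
        }


@dataclass
class SyntheticDataset:
    interactome: Interactome
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    truth: SyntheticTruth
    dependency: DependencyTable
    scenario: SyntheticScenario = field(repr=False, default=None)


def _gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_interactome(n_genes: int, m_attach: int, seed: int) -> Interactome:
    """Scale-free interactome via preferential attachment.

    Produces a connected graph with exactly (n_genes - m_attach) * m_attach
    edges; deterministic given seed.
    """
    if n_genes <= m_attach or m_attach < 1:
        raise ParameterError("require n_genes > m_attach >= 1")
    graph = nx.barabasi_albert_graph(n_genes, m_attach, seed=seed)
    names = _gene_names(n_genes)
    return Interactome.from_edges((names[u], names[v]) for u, v in graph.edges())


def _plant_genes(
    interactome: Interactome, scenario: SyntheticScenario, rng: np.random.Generator
) -> SyntheticScenario:
    """Fill in unset planted genes and the default rewired-edge structure.

    The target is the highest-degree hub (flow-convergence points are
    high-weighted-degree nodes); the router is a low-degree node not
    adjacent to the target, so its rewired relay edges are its only strong
    edges and its terminal capacity stays below the target threshold.
    Sources are sampled away from the router's neighborhood for the same
    reason. The default rewiring wires sources[0:s-2] to the target,
    sources[s-2] to the router, and the router to the target, leaving the
    last source unrewired.
    """
    nodes = sorted(interactome.nodes)
    degree = interactome.degree()
    by_degree = sorted(nodes, key=lambda g: (-degree[g], g))
    target = scenario.target or by_degree[0]
    neighbors_t = {v if u == target else u for u, v in interactome.edges if target in (u, v)}
    router = scenario.router
    if router is None:
        low_degree = sorted(nodes, key=lambda g: (degree[g], g))
        router = next(
            g for g in low_degree if g != target and g not in neighbors_t
        )
    if router == target:
        raise ParameterError("planted router and target must differ")
    neighbors_r = {v if u == router else u for u, v in interactome.edges if router in (u, v)}
    if scenario.sources is None:
        excluded = {router, target} | neighbors_r
        candidates = [g for g in nodes if g not in excluded]
        idx = rng.choice(len(candidates), size=scenario.n_sources, replace=False)
        sources = [candidates[i] for i in sorted(idx)]
    else:
        sources = [g.upper() for g in scenario.sources]
    if scenario.rewired_edges is None:
        s = len(sources)
        rewired = [(src, target) for src in sources[: max(1, s - 2)]]
        if s >= 2:
            rewired.append((sources[s - 2], router))
        rewired.append((router, target))
    else:
        rewired = [tuple(g.upper() for g in e) for e in scenario.rewired_edges]
    return replace(
        scenario,
        sources=sources,
        router=router,
        target=target,
        rewired_edges=rewired,
        n_sources=len(sources),
    )


def generate_two_phenotype_expression(
    interactome: Interactome, scenario: SyntheticScenario
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Draw phenotype A (control) and B (perturbed) expression matrices.

    Baseline: each interactome edge (u, v) outside the rewired set shares a
    latent standard-normal factor with loading sqrt(baseline_rho); each gene
    is normalized to unit variance (residual sd is max(noise_sd,
    sqrt(1 - sum of squared loadings)); hubs whose loadings exceed unit
    variance keep the noise_sd floor and attenuate, as real hubs do).

    Rewired structure: genes touched by a rewired edge form a module sharing
    one factor in phenotype B only, with loading sqrt(rho_hi) on top of a
    down-weighted baseline signal, so rewired edges have population
    correlation exactly rho_hi in B and ~0 in A. Planted sources gain mean
    ``delta`` in B. Deterministic given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    scenario = _plant_genes(interactome, scenario, rng)
    nodes = sorted(interactome.nodes)
    node_set = set(nodes)
    missing = [g for g in scenario.sources + [scenario.router, scenario.target] if g not in node_set]
    if missing:
        raise ParameterError(f"planted genes absent from interactome: {missing}")
    rewired = {tuple(sorted(e)) for e in scenario.rewired_edges}
    not_edges = [e for e in rewired if e not in interactome.edges]
    if not_edges:
        raise ParameterError(f"rewired edges absent from interactome: {sorted(not_edges)}")
    module = sorted({g for e in rewired for g in e})

    baseline_edges = [e for e in interactome.sorted_edges if e not in rewired]
    n = scenario.n_samples_per_phenotype
    gene_idx = {g: i for i, g in enumerate(nodes)}

    def draw(with_module: bool) -> np.ndarray:
        factors = rng.standard_normal((len(baseline_edges), n))
        resid = rng.standard_normal((len(nodes), n))
        module_factor = rng.standard_normal(n)  # drawn always: fixed stream layout
        load = math.sqrt(scenario.baseline_rho)
        signal = np.zeros((len(nodes), n))
        sumsq = np.zeros(len(nodes))
        for k, (u, v) in enumerate(baseline_edges):
            for g in (u, v):
                i = gene_idx[g]
                signal[i] += load * factors[k]
                sumsq[i] += scenario.baseline_rho
        resid_sd = np.maximum(scenario.noise_sd, np.sqrt(np.clip(1.0 - sumsq, 0.0, None)))
        base = (signal + resid_sd[:, None] * resid) / np.sqrt(sumsq + resid_sd**2)[:, None]
        if with_module and module:
            hi, lo = math.sqrt(scenario.rho_hi), math.sqrt(1.0 - scenario.rho_hi)
            for g in module:
                i = gene_idx[g]
                base[i] = hi * module_factor + lo * base[i]
        return base

    mat_a = draw(with_module=False)
    mat_b = draw(with_module=True)
    for g in scenario.sources:
        mat_b[gene_idx[g]] += scenario.delta

    samples_a = [f"A{j:03d}" for j in range(1, n + 1)]
    samples_b = [f"B{j:03d}" for j in range(1, n + 1)]
    expr_a = ExpressionMatrix(
        pd.DataFrame(mat_a, index=nodes, columns=samples_a),
        {s: "A" for s in samples_a},
    )
    expr_b = ExpressionMatrix(
        pd.DataFrame(mat_b, index=nodes, columns=samples_b),
        {s: "B" for s in samples_b},
    )
    truth = SyntheticTruth(
        sources=tuple(scenario.sources),
        source_log2fc={g: scenario.delta for g in scenario.sources},
        router=scenario.router,
        target=scenario.target,
        rewired_edges=tuple(sorted(rewired)),
        seed=scenario.seed,
    )
    return expr_a, expr_b, truth


def generate_dependency_table(
    genes: Sequence[str],
    cell_lines: Sequence[str],
    essential_block: Sequence[str],
    seed: int,
    assay: str = "CRISPR",
) -> DependencyTable:
    """Dependency scores: essential genes ~ N(-1.4, 0.2), others ~ N(0, 0.3)."""
    if not cell_lines:
        raise ParameterError("need at least one cell line")
    genes = [g.upper() for g in genes]
    essential = {g.upper() for g in essential_block}
    if not essential <= set(genes):
        raise ParameterError("essential_block must be a subset of genes")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(genes):
        mean, sd = (-1.4, 0.2) if gene in essential else (0.0, 0.3)
        scores = rng.normal(mean, sd, size=len(cell_lines))
        for line, score in zip(cell_lines, scores):
            rows.append((gene, line, float(score), assay))
    return DependencyTable(
        pd.DataFrame(rows, columns=["gene", "cell_line", "score", "assay"])
    )


def simulate(scenario: SyntheticScenario | None = None) -> SyntheticDataset:
    """Generate a full benchmark dataset: interactome (augmented with the
    planted rewired edges), both expression matrices, truth record, and a
    dependency table whose essential block contains the planted router."""
    scenario = scenario or SyntheticScenario()
    rng = np.random.default_rng(scenario.seed)
    interactome = generate_interactome(scenario.n_genes, scenario.m_attach, scenario.seed)
    planted = _plant_genes(interactome, scenario, rng)
    interactome = interactome.union(planted.rewired_edges)
    expr_a, expr_b, truth = generate_two_phenotype_expression(interactome, planted)

    nodes = sorted(interactome.nodes)
    non_planted = [g for g in nodes if g not in set(truth.sources) | {truth.router, truth.target}]
    extra_idx = rng.choice(len(non_planted), size=2, replace=False)
    essential = sorted([truth.router] + [non_planted[i] for i in sorted(extra_idx)])
    cell_lines = [f"LINE{j:02d}" for j in range(1, 11)]
    dependency = generate_dependency_table(
        nodes, cell_lines, essential, seed=scenario.seed + 1, assay="CRISPR"
    )
    return SyntheticDataset(interactome, expr_a, expr_b, truth, dependency, planted)
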