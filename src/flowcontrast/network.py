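"""Phenotype-specific capacitated flow-network construction.

A context network overlays co-expression weights (|Pearson r| over one
phenotype's samples) on the interactome, keeps edges at or above
``cor_threshold``, restricts to the functional neighborhood of the source
genes (per-source top-(1 - SNF) fraction by |r|), and attaches a
super-source S and super-sink T:

* each retained undirected edge becomes two antiparallel arcs with
  capacity round(w * integer_scale) and cost round((1 - w + delta) *
  integer_scale) -- flow prefers strongly co-expressed routes;
* S -> g arcs for each selected source g, capacities proportional to
  |log2FC| (equal in bypass mode), largest-remainder rounded to sum to
  supply * integer_scale;
* v -> T terminal arcs on every non-source node with capacity
  round(epsilon_terminal * weighted_degree(v) * integer_scale), so flow
  must spread and converges on high-weighted-degree nodes ("targets"
  emerge rather than being declared).

All arc parameters are integers, so the downstream min-cost flow is exact
and platform-independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DisconnectedSourcesError, ParameterError
from .io import ExpressionMatrix, Interactome
from .stratify import SourceSet

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "Arc",
    "ContextFlowNetwork",
    "SOURCE_NODE",
    "SINK_NODE",
    "edge_coexpression",
    "apply_cor_threshold",
    "functional_neighborhood",
    "build_flow_network",
]

SOURCE_NODE = "__S__"
SINK_NODE = "__T__"


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    snf: functional-neighborhood percentile (keep top (1 - snf) fraction of
        genes by |r| per source). cor_threshold: minimum |Pearson r| for an
        edge to be retained. ratio_threshold: minimum cross-phenotype flow
        ratio for a key edge. supply: total flow injected at the
        super-source (supply units). epsilon_terminal: fraction of a node's
        weighted degree usable as terminal capacity; kept small so terminal
        capacity is scarce relative to any single source's supply share and
        flow is forced to traverse and converge. terminal_cost: cost per
        unit on terminal arcs. cost_floor: small positive cost added to
        every arc (no zero-cost cycles). integer_scale: weight -> integer
        multiplier for exact arithmetic. target_fraction: terminal-flow
        share of supply that defines a target node. dependency_threshold:
        strict upper bound for a dependency call.
    """

    snf: float = 0.95
    cor_threshold: float = 0.5
    ratio_threshold: float = 5.0
    supply: float = 1.0
    epsilon_terminal: float = 0.02
    terminal_cost: float = 1.0
    cost_floor: float = 1e-4
    integer_scale: int = 10_000
    top_k_routers: int = 20
    target_fraction: float = 0.05
    dependency_threshold: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.snf <= 1.0:
            raise ParameterError("snf must be in [0, 1]")
        if not 0.0 <= self.cor_threshold <= 1.0:
            raise ParameterError("cor_threshold must be in [0, 1]")
        if self.ratio_threshold < 1.0:
            raise ParameterError("ratio_threshold must be >= 1")
        if self.integer_scale < 100:
            raise ParameterError("integer_scale must be >= 100")
        if self.supply <= 0 or self.epsilon_terminal <= 0:
            raise ParameterError("supply and epsilon_terminal must be positive")
        if self.cost_floor <= 0:
            raise ParameterError("cost_floor must be positive")


@dataclass(frozen=True)
class Arc:
    tail: str
    head: str
    capacity: int
    cost: int


@dataclass
class ContextFlowNetwork:
    """Capacitated, costed flow graph for one phenotype."""

    phenotype: str
    edges: pd.DataFrame  # columns: u, v, weight (canonical u < v, sorted)
    source_caps: dict[str, int]  # gene -> S-arc capacity (scaled integers)
    config: AnalysisConfig
    nodes: tuple[str, ...] = field(init=False)
    arcs: list[Arc] = field(init=False)

    def __post_init__(self) -> None:
        cfg = self.config
        scale = cfg.integer_scale
        self.nodes = tuple(sorted(set(self.edges["u"]) | set(self.edges["v"])))
        node_set = set(self.nodes)
        bad = [g for g in self.source_caps if g not in node_set]
        if bad:
            raise ParameterError(f"source genes not in network: {bad}")

        arcs: list[Arc] = []
        for gene in sorted(self.source_caps):
            cap = int(self.source_caps[gene])
            if cap > 0:
                arcs.append(Arc(SOURCE_NODE, gene, cap, max(1, round(cfg.cost_floor * scale))))
        for row in self.edges.itertuples(index=False):
            cap = int(round(row.weight * scale))
            cost = max(1, int(round((1.0 - row.weight + cfg.cost_floor) * scale)))
            if cap <= 0:
                continue
            arcs.append(Arc(row.u, row.v, cap, cost))
            arcs.append(Arc(row.v, row.u, cap, cost))
        wdeg = self.weighted_degree()
        t_cost = max(1, int(round(cfg.terminal_cost * scale)))
        for gene in self.nodes:
            if gene in self.source_caps:
                continue
            cap = int(round(cfg.epsilon_terminal * wdeg[gene] * scale))
            if cap > 0:
                arcs.append(Arc(gene, SINK_NODE, cap, t_cost))
        self.arcs = arcs

    def weighted_degree(self) -> dict[str, float]:
        wdeg = {g: 0.0 for g in self.nodes}
        for row in self.edges.itertuples(index=False):
            wdeg[row.u] += row.weight
            wdeg[row.v] += row.weight
        return wdeg

    def degree(self) -> dict[str, int]:
        deg = {g: 0 for g in self.nodes}
        for row in self.edges.itertuples(index=False):
            deg[row.u] += 1
            deg[row.v] += 1
        return deg

    def neighbors(self, gene: str) -> set[str]:
        out: set[str] = set()
        for row in self.edges.itertuples(index=False):
            if row.u == gene:
                out.add(row.v)
            elif row.v == gene:
                out.add(row.u)
        return out

    @property
    def total_supply(self) -> int:
        return sum(self.source_caps.values())


def empty_network(phenotype: str, config: AnalysisConfig) -> ContextFlowNetwork:
    """A degenerate network with no nodes (used when a phenotype's sources
    are disconnected and the contrast should still run)."""
    edges = pd.DataFrame(columns=["u", "v", "weight"])
    net = ContextFlowNetwork.__new__(ContextFlowNetwork)
    net.phenotype = phenotype
    net.edges = edges
    net.source_caps = {}
    net.config = config
    net.nodes = ()
    net.arcs = []
    return net


def edge_coexpression(expr: ExpressionMatrix, interactome: Interactome) -> pd.DataFrame:
    """Absolute Pearson correlation per interactome edge.

    Edges with an unmeasured endpoint are dropped (counted in the log);
    zero-variance genes yield w = 0 with a warning rather than an error,
    since constant genes are common in subsetted data.
    """
    if len(expr.samples) < 3:
        raise ParameterError("need at least 3 samples for co-expression")
    measured = set(expr.genes)
    edges = interactome.sorted_edges
    kept = [(u, v) for u, v in edges if u in measured and v in measured]
    dropped = len(edges) - len(kept)
    if dropped:
        logger.info("dropped %d edge(s) with unmeasured endpoints", dropped)
    if not kept:
        return pd.DataFrame(columns=["u", "v", "weight"])

    genes = sorted({g for e in kept for g in e})
    mat = expr.data.loc[genes].to_numpy()
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    idx = {g: i for i, g in enumerate(genes)}
    zero_var = norms == 0
    if zero_var.any():
        logger.warning(
            "%d zero-variance gene(s); their edges get weight 0", int(zero_var.sum())
        )
    iu = np.array([idx[u] for u, _ in kept])
    iv = np.array([idx[v] for _, v in kept])
    denom = norms[iu] * norms[iv]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs((centered[iu] * centered[iv]).sum(axis=1) / denom)
    r = np.where(denom == 0, 0.0, r)
    r = np.clip(r, 0.0, 1.0)
    return pd.DataFrame({"u": [u for u, _ in kept], "v": [v for _, v in kept], "weight": r})


def apply_cor_threshold(weighted_edges: pd.DataFrame, cor_threshold: float) -> pd.DataFrame:
    """Keep edges with weight >= cor_threshold (boundary inclusive)."""
    if not 0.0 <= cor_threshold <= 1.0:
        raise ParameterError("cor_threshold must be in [0, 1]")
    retained = weighted_edges[weighted_edges["weight"] >= cor_threshold].reset_index(drop=True)
    logger.info(
        "cor_threshold %.3g: retained %d / %d edges",
        cor_threshold,
        len(retained),
        len(weighted_edges),
    )
    if retained.empty:
        logger.warning("no edge passed cor_threshold %.3g", cor_threshold)
    return retained


def functional_neighborhood(
    expr: ExpressionMatrix, sources: Sequence[str], snf: float
) -> set[str]:
    """Union of per-source functional neighborhoods.

    For each source, every other measured gene is ranked by |Pearson r| with
    the source, and the top ceil((1 - snf) * n_candidates) genes are kept
    (ties broken by |r| descending then symbol ascending). Returns sources
    plus the union of kept sets; snf = 0 keeps every measured gene.
    """
    if not 0.0 <= snf <= 1.0:
        raise ParameterError("snf must be in [0, 1]")
    sources = [g.upper() for g in sources]
    measured_sources = [g for g in sources if g in expr.data.index]
    if not measured_sources:
        raise ParameterError("no source gene is measured in the expression matrix")
    if len(measured_sources) < len(sources):
        logger.warning(
            "%d source(s) not measured; ignored", len(sources) - len(measured_sources)
        )
    genes = sorted(expr.genes)
    mat = expr.data.loc[genes].to_numpy()
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    idx = {g: i for i, g in enumerate(genes)}

    kept: set[str] = set(measured_sources)
    for source in measured_sources:
        si = idx[source]
        denom = norms * norms[si]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(centered @ centered[si] / denom)
        r = np.where(denom == 0, 0.0, r)
        candidates = [(g, r[idx[g]]) for g in genes if g != source]
        k = math.ceil(len(candidates) * (1.0 - snf))
        candidates.sort(key=lambda item: (-item[1], item[0]))
        kept.update(g for g, _ in candidates[:k])
    return kept


def _largest_remainder(weights: dict[str, float], total: int) -> dict[str, int]:
    """Integer allocation of ``total`` proportional to weights, by largest
    remainder; ties broken by larger weight then symbol order."""
    denom = sum(weights.values())
    if denom <= 0:
        raise ParameterError("cannot allocate supply: non-positive total weight")
    exact = {g: total * w / denom for g, w in weights.items()}
    floors = {g: int(math.floor(x)) for g, x in exact.items()}
    remaining = total - sum(floors.values())
    order = sorted(
        weights, key=lambda g: (-(exact[g] - floors[g]), -weights[g], g)
    )
    for g in order[:remaining]:
        floors[g] += 1
    return floors


def build_flow_network(
    retained_edges: pd.DataFrame,
    neighborhood: Iterable[str],
    source_set: SourceSet,
    config: AnalysisConfig,
    phenotype: str = "",
) -> ContextFlowNetwork:
    """Assemble the capacitated flow network for one phenotype.

    Restricts retained edges to the neighborhood genes, drops isolated
    nodes, and attaches super-source/super-sink arcs. Raises
    :class:`DisconnectedSourcesError` when no selected source survives.
    """
    neighborhood = set(neighborhood)
    mask = retained_edges["u"].isin(neighborhood) & retained_edges["v"].isin(neighborhood)
    edges = retained_edges[mask].copy()
    edges = edges.sort_values(["u", "v"], kind="stable").reset_index(drop=True)
    nodes = set(edges["u"]) | set(edges["v"])

    selected = source_set.selected_genes
    surviving = [g for g in selected if g in nodes]
    if not surviving:
        raise DisconnectedSourcesError(
            f"sources disconnected from context network ({phenotype or 'unnamed'})"
        )

    total = int(round(config.supply * config.integer_scale))
    if source_set.bypass:
        weights = {g: 1.0 for g in surviving}
    else:
        lfc = {g: abs(source_set.log2fc_of(g) or 0.0) for g in surviving}
        weights = lfc if sum(lfc.values()) > 0 else {g: 1.0 for g in surviving}
    caps = _largest_remainder(weights, total)
    return ContextFlowNetwork(
        phenotype=phenotype, edges=edges, source_caps=caps, config=config
    )
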