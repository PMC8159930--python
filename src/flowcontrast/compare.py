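"""Cross-phenotype comparison of flow solutions.

Given solved flow networks for two phenotypes (A = control, B = perturbed),
this module computes node flow differences (flow_B - flow_A), classifies
nodes into the disjoint roles source / router / target (precedence source >
target > router), scores network rewiring per gene (impact), flags key
edges (cross-phenotype flow ratio >= ratio_threshold, or flow exclusive to
one phenotype), extracts the prioritized subnetwork, and produces
first-neighbor motif views for individual genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import GeneNotFoundError
from .flow import FlowSolution
from .network import AnalysisConfig, ContextFlowNetwork
from .stratify import SourceSet

__all__ = [
    "NodeRoleTable",
    "PrioritizedSubnetwork",
    "MotifView",
    "node_flow_difference",
    "classify_roles",
    "impact_score",
    "key_edges",
    "prioritized_subnetwork",
    "extract_motif",
]

ROLE_ORDER = {"source": 0, "router": 1, "target": 2}

NodeRoleTable = pd.DataFrame  # columns: gene, role, flow_a, flow_b, flow_diff,
#                               degree_a, degree_b, impact


def node_flow_difference(sol_a: FlowSolution, sol_b: FlowSolution) -> pd.DataFrame:
    """Per-gene throughput difference flow_B - flow_A over the union of
    gene universes (absent genes get flow 0), sorted by |flow_diff|
    descending, ties by gene symbol."""
    genes = sorted(set(sol_a.node_throughput_int) | set(sol_b.node_throughput_int))
    rows = []
    for gene in genes:
        fa, fb = sol_a.throughput_of(gene), sol_b.throughput_of(gene)
        rows.append((gene, fa, fb, fb - fa))
    frame = pd.DataFrame(rows, columns=["gene", "flow_a", "flow_b", "flow_diff"])
    frame["abs_diff"] = frame["flow_diff"].abs()
    frame = frame.sort_values(["abs_diff", "gene"], ascending=[False, True], kind="stable")
    return frame.drop(columns="abs_diff").reset_index(drop=True)


def classify_roles(
    sol_a: FlowSolution,
    sol_b: FlowSolution,
    source_set: SourceSet,
    config: AnalysisConfig,
    network_a: ContextFlowNetwork | None = None,
    network_b: ContextFlowNetwork | None = None,
) -> pd.DataFrame:
    """Assign each flow-carrying gene exactly one role.

    source: selected source genes with nonzero throughput in either
    phenotype; target: non-source genes whose terminal flow reaches
    target_fraction x supply in either phenotype; router: every other gene
    with nonzero throughput. Genes with zero throughput in both phenotypes
    are excluded. When the context networks are supplied, retained-edge
    degrees and impact scores are filled in.
    """
    selected = set(source_set.selected_genes)
    tau = config.target_fraction * config.supply
    diffs = node_flow_difference(sol_a, sol_b)
    deg_a = network_a.degree() if network_a is not None else {}
    deg_b = network_b.degree() if network_b is not None else {}

    records = []
    for row in diffs.itertuples(index=False):
        gene = row.gene
        if row.flow_a == 0 and row.flow_b == 0:
            continue
        if gene in selected:
            role = "source"
        elif max(sol_a.terminal_of(gene), sol_b.terminal_of(gene)) >= tau:
            role = "target"
        else:
            role = "router"
        records.append(
            (
                gene,
                role,
                row.flow_a,
                row.flow_b,
                row.flow_diff,
                deg_a.get(gene, 0),
                deg_b.get(gene, 0),
            )
        )
    frame = pd.DataFrame(
        records,
        columns=["gene", "role", "flow_a", "flow_b", "flow_diff", "degree_a", "degree_b"],
    )
    if network_a is not None and network_b is not None and not frame.empty:
        max_abs = float(frame["flow_diff"].abs().max())
        frame["impact"] = [
            impact_score(network_a, network_b, sol_a, sol_b, g, max_abs_diff=max_abs)
            for g in frame["gene"]
        ]
    else:
        frame["impact"] = float("nan")
    frame["abs_diff"] = frame["flow_diff"].abs()
    frame = frame.sort_values(["abs_diff", "gene"], ascending=[False, True], kind="stable")
    return frame.drop(columns="abs_diff").reset_index(drop=True)


def impact_score(
    network_a: ContextFlowNetwork,
    network_b: ContextFlowNetwork,
    sol_a: FlowSolution,
    sol_b: FlowSolution,
    gene: str,
    max_abs_diff: float | None = None,
) -> float:
    """Rewiring impact in [0, 1]: mean of (i) normalized degree shift,
    (ii) neighbor turnover (1 - Jaccard), (iii) normalized flow shift."""
    in_a = gene in set(network_a.nodes)
    in_b = gene in set(network_b.nodes)
    if not in_a and not in_b:
        raise GeneNotFoundError(f"gene {gene!r} absent from both context networks")
    n_a = network_a.neighbors(gene) if in_a else set()
    n_b = network_b.neighbors(gene) if in_b else set()
    d_a, d_b = len(n_a), len(n_b)
    degree_shift = abs(d_b - d_a) / max(d_a, d_b, 1)
    union = n_a | n_b
    turnover = 1.0 - (len(n_a & n_b) / len(union)) if union else 0.0
    diff = abs(sol_b.throughput_of(gene) - sol_a.throughput_of(gene))
    if max_abs_diff is None:
        all_genes = set(sol_a.node_throughput_int) | set(sol_b.node_throughput_int)
        max_abs_diff = max(
            (abs(sol_b.throughput_of(g) - sol_a.throughput_of(g)) for g in all_genes),
            default=0.0,
        )
    flow_shift = diff / max_abs_diff if max_abs_diff > 0 else 0.0
    return (degree_shift + turnover + flow_shift) / 3.0


def key_edges(
    sol_a: FlowSolution, sol_b: FlowSolution, config: AnalysisConfig
) -> pd.DataFrame:
    """Edge comparison records over edges carrying flow in either phenotype.

    ratio = max(flow_A, flow_B) / min(flow_A, flow_B), the minimum floored
    at 1/integer_scale; exclusive marks edges with nonzero flow in exactly
    one phenotype; key iff ratio >= ratio_threshold (inclusive) or
    exclusive. Sorted by max flow descending, ties by edge.
    """
    floor = 1.0 / config.integer_scale
    edges = sorted(set(sol_a.total_edge_flow_int) | set(sol_b.total_edge_flow_int))
    rows = []
    for u, v in edges:
        fa = sol_a.total_edge_flow_int.get((u, v), 0) / sol_a.scale
        fb = sol_b.total_edge_flow_int.get((u, v), 0) / sol_b.scale
        if fa == 0 and fb == 0:
            continue
        if fa == 0 or fb == 0:
            exclusive = "A" if fb == 0 else "B"
        else:
            exclusive = "none"
        ratio = max(fa, fb) / max(min(fa, fb), floor)
        key = bool(ratio >= config.ratio_threshold or exclusive != "none")
        rows.append((u, v, fa, fb, ratio, exclusive, key))
    frame = pd.DataFrame(
        rows, columns=["u", "v", "flow_a", "flow_b", "ratio", "exclusive", "key"]
    )
    if not frame.empty:
        frame["max_flow"] = frame[["flow_a", "flow_b"]].max(axis=1)
        frame = frame.sort_values(
            ["max_flow", "u", "v"], ascending=[False, True, True], kind="stable"
        ).drop(columns="max_flow")
    return frame.reset_index(drop=True)


def dominant_in_b(edge_records: pd.DataFrame) -> pd.DataFrame:
    """Filter the edge comparison to edges with higher flow in phenotype B."""
    return edge_records[edge_records["flow_b"] > edge_records["flow_a"]].reset_index(
        drop=True
    )


@dataclass
class PrioritizedSubnetwork:
    """Compact contrast subgraph: active sources, targets, top routers, and
    key-edge endpoints, with the induced flow-carrying edges."""

    nodes: pd.DataFrame  # role table restricted to members
    edges: pd.DataFrame  # edge comparison records restricted to induced edges
    counts: dict[str, int]

    def member_genes(self) -> list[str]:
        return sorted(self.nodes["gene"])


def prioritized_subnetwork(
    roles: pd.DataFrame, edge_records: pd.DataFrame, config: AnalysisConfig
) -> PrioritizedSubnetwork:
    """Members: sources with nonzero flow, all targets, the top
    ``top_k_routers`` routers by |flow_diff|, and endpoints of key edges.
    Edges: key edges plus flow-carrying edges induced among members."""
    sources = roles.loc[roles["role"] == "source", "gene"]
    targets = roles.loc[roles["role"] == "target", "gene"]
    routers = roles.loc[roles["role"] == "router"].copy()
    routers["abs_diff"] = routers["flow_diff"].abs()
    routers = routers.sort_values(
        ["abs_diff", "gene"], ascending=[False, True], kind="stable"
    )
    top_routers = routers["gene"].head(config.top_k_routers)

    members = set(sources) | set(targets) | set(top_routers)
    if not edge_records.empty:
        key_rows = edge_records[edge_records["key"]]
        members |= set(key_rows["u"]) | set(key_rows["v"])

    node_table = roles[roles["gene"].isin(members)].reset_index(drop=True)
    if edge_records.empty:
        edge_table = edge_records.copy()
    else:
        induced = (
            edge_records["u"].isin(members)
            & edge_records["v"].isin(members)
            & ((edge_records["flow_a"] > 0) | (edge_records["flow_b"] > 0))
        )
        edge_table = edge_records[edge_records["key"] | induced].reset_index(drop=True)
        edge_table = edge_table[
            edge_table["u"].isin(set(node_table["gene"]))
            & edge_table["v"].isin(set(node_table["gene"]))
        ].reset_index(drop=True)
    counts = {
        role: int((node_table["role"] == role).sum()) for role in ("source", "router", "target")
    }
    return PrioritizedSubnetwork(nodes=node_table, edges=edge_table, counts=counts)


@dataclass
class MotifView:
    """First-neighbor subgraph around a gene in one phenotype's network."""

    center: str
    phenotype: str
    degree: int
    edges: pd.DataFrame  # columns: u, v, weight, total_flow


def extract_motif(
    network: ContextFlowNetwork, solution: FlowSolution, gene: str
) -> MotifView:
    """Neighborhood motif: the retained edges incident to ``gene`` with
    their co-expression weights and total edge flows."""
    gene = gene.upper()
    if gene not in set(network.nodes):
        raise GeneNotFoundError(f"gene {gene!r} not in the {network.phenotype or 'context'} network")
    rows = []
    for row in network.edges.itertuples(index=False):
        if gene not in (row.u, row.v):
            continue
        flow = solution.total_edge_flow_int.get((row.u, row.v), 0) / solution.scale
        rows.append((row.u, row.v, row.weight, flow))
    edges = pd.DataFrame(rows, columns=["u", "v", "weight", "total_flow"])
    return MotifView(center=gene, phenotype=network.phenotype, degree=len(edges), edges=edges)
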