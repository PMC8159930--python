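"""End-to-end orchestration: stratify -> sources -> build -> flow ->
compare -> [ora] -> [dependency] -> [cluster], with a reproducibility
manifest.

A run is configured by a YAML file (or an equivalent dict) with these
blocks, all optional unless noted:

.. code-block:: yaml

    seed: 7
    simulate: true          # generate the synthetic benchmark as input
    scenario: {n_genes: 300, n_samples_per_phenotype: 50}   # overrides
    analysis: {cor_threshold: 0.5, snf: 0.95}               # overrides
    sources: {lfc_min: 1.0, alpha: 0.05}    # or gene_list: path
    inputs:                 # used when simulate is false
      expression: expr.tsv          # single labeled matrix, or
      expression_a: a.tsv           # two per-phenotype matrices
      expression_b: b.tsv
      phenotype_map: labels.tsv
      marker: CCN1                  # median stratification of `expression`
      interactome: ppi.sif
    ora: {gmt: sets.gmt, reference: universe.txt}   # optional stage
    dependency: {scores: dep.csv, assay: CRISPR}    # optional stage
    cluster: true

Outputs are deterministic given the config and seed: identical reruns
produce byte-identical result tables and manifest (timestamps are kept out
of the manifest; wall-clock timings go only to the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .compare import (
    classify_roles,
    key_edges,
    node_flow_difference,
    prioritized_subnetwork,
)
from .crossdata import build_flow_profile_matrix, upgma_cluster
from .dependency import flag_dependencies, summarize_by_role
from .enrichment import run_ora
from .errors import DisconnectedSourcesError, FlowContrastError, ParameterError
from .flow import FlowSolution, empty_solution, solve_min_cost_flow
from .io import (
    Interactome,
    read_dependency_table,
    read_expression_matrix,
    read_gmt,
    read_interactome,
    write_dependency_table,
    write_expression_matrix,
    write_network,
)
from .network import (
    AnalysisConfig,
    ContextFlowNetwork,
    apply_cor_threshold,
    build_flow_network,
    edge_coexpression,
    empty_network,
    functional_neighborhood,
)
from .stratify import SourceSet, select_sources, split_by_marker_median
from .synthetic import SyntheticScenario, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineStageError", "analyze_phenotype", "run_pipeline"]


class PipelineStageError(FlowContrastError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def analyze_phenotype(
    expr,
    interactome: Interactome,
    source_set: SourceSet,
    config: AnalysisConfig,
    phenotype: str,
    allow_disconnected: bool = True,
) -> tuple[ContextFlowNetwork, FlowSolution]:
    """Build and solve one phenotype's context flow network.

    When the selected sources are disconnected after filtering (common for
    a control phenotype whose co-expression never reaches cor_threshold)
    and ``allow_disconnected`` is set, an empty network and a delivered=0
    solution are returned so the cross-phenotype contrast can proceed.
    """
    weighted = edge_coexpression(expr, interactome)
    retained = apply_cor_threshold(weighted, config.cor_threshold)
    neighborhood = functional_neighborhood(expr, source_set.selected_genes, config.snf)
    try:
        net = build_flow_network(retained, neighborhood, source_set, config, phenotype)
    except DisconnectedSourcesError:
        if not allow_disconnected:
            raise
        logger.warning(
            "phenotype %s: sources disconnected; using an empty flow solution", phenotype
        )
        return empty_network(phenotype, config), empty_solution(phenotype, config.integer_scale)
    return net, solve_min_cost_flow(net)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(frame: pd.DataFrame, path: Path, written: list[Path]) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    written.append(path)


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Run the full contrast pipeline; returns the output directory.

    Declared outputs: roles.tsv, edges.tsv, node_flow_diff.tsv, flows.tsv,
    subnetwork.graphml, manifest.json, plus ora.tsv, dep.tsv /
    dep_summary.tsv and dendrogram.newick / cluster_merges.tsv when the
    corresponding optional stages are configured. Any stage error aborts
    with the stage name and removes partial outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = dict(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("flowcontrast")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)

    written: list[Path] = []
    stage = "configure"
    try:
        return _run_stages(cfg, out_dir, written)
    except PipelineStageError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineStageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name: str):
    """Decorator-free stage wrapper: call fn, re-raise as PipelineStageError."""

    class _Ctx:
        def __init__(self, stage_name: str):
            self.name = stage_name
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", self.name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                if isinstance(exc, PipelineStageError):
                    return False
                raise PipelineStageError(self.name, exc) from exc
            logger.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
            return False

    return _Ctx(name)


def _run_stages(cfg: dict, out_dir: Path, written: list[Path]) -> Path:
    seed = int(cfg.get("seed", 0))
    analysis = AnalysisConfig(**{**cfg.get("analysis", {}), "seed": seed})
    manifest: dict[str, Any] = {
        "tool": "flowcontrast",
        "version": __version__,
        "seed": seed,
        "analysis": {k: getattr(analysis, k) for k in vars(analysis)},
        "inputs": {},
        "counts": {},
    }

    # ---------------- inputs ----------------
    truth = None
    dataset = None
    with _stage("inputs"):
        if cfg.get("simulate"):
            scenario = SyntheticScenario(**{**cfg.get("scenario", {}), "seed": seed})
            dataset = simulate(scenario)
            expr_a, expr_b = dataset.expr_a, dataset.expr_b
            interactome, truth = dataset.interactome, dataset.truth
            sim_dir = out_dir / "simulated"
            sim_dir.mkdir(exist_ok=True)
            for name, writer in (
                ("exprA.tsv", lambda p: write_expression_matrix(expr_a, p)),
                ("exprB.tsv", lambda p: write_expression_matrix(expr_b, p)),
                ("interactome.sif", lambda p: write_network(interactome, p, "sif")),
                ("dependency.csv", lambda p: write_dependency_table(dataset.dependency, p)),
            ):
                writer(sim_dir / name)
                written.append(sim_dir / name)
            (sim_dir / "truth.json").write_text(
                json.dumps(truth.as_dict(), indent=2, sort_keys=True) + "\n"
            )
            written.append(sim_dir / "truth.json")
            manifest["scenario"] = _jsonable(vars(dataset.scenario))
            manifest["inputs"] = {name: _digest(sim_dir / name) for name in
                                  ("exprA.tsv", "exprB.tsv", "interactome.sif", "dependency.csv")}
        else:
            inputs = cfg.get("inputs", {})
            if not inputs.get("interactome"):
                raise ParameterError("inputs.interactome is required when simulate is false")
            interactome = read_interactome(inputs["interactome"])
            manifest["inputs"]["interactome"] = _digest(Path(inputs["interactome"]))
            if inputs.get("expression_a") and inputs.get("expression_b"):
                expr_a = read_expression_matrix(inputs["expression_a"])
                expr_b = read_expression_matrix(inputs["expression_b"])
                manifest["inputs"]["expression_a"] = _digest(Path(inputs["expression_a"]))
                manifest["inputs"]["expression_b"] = _digest(Path(inputs["expression_b"]))
            elif inputs.get("expression") and inputs.get("marker"):
                expr = read_expression_matrix(
                    inputs["expression"], inputs.get("phenotype_map")
                )
                if inputs.get("linear_scale"):
                    expr = expr.log2_transform()
                labels = split_by_marker_median(expr, inputs["marker"])
                expr_a = expr.subset_samples(labels.low)
                expr_b = expr.subset_samples(labels.high)
                manifest["inputs"]["expression"] = _digest(Path(inputs["expression"]))
                manifest["counts"]["n_high"] = len(labels.high)
                manifest["counts"]["n_low"] = len(labels.low)
            else:
                raise ParameterError(
                    "provide expression_a/expression_b, or expression with marker"
                )
        manifest["counts"]["n_interactome_edges"] = len(interactome)

    # ---------------- sources ----------------
    with _stage("sources"):
        src_cfg = cfg.get("sources", {})
        if src_cfg.get("gene_list"):
            genes = [
                line.strip()
                for line in Path(src_cfg["gene_list"]).read_text().splitlines()
                if line.strip()
            ]
            source_set = select_sources(gene_list=genes)
        else:
            source_set = select_sources(
                expr_a,
                expr_b,
                lfc_min=float(src_cfg.get("lfc_min", 1.0)),
                alpha=float(src_cfg.get("alpha", 0.05)),
            )
        _write_table(source_set.records, out_dir / "sources.tsv", written)
        manifest["counts"]["n_sources_selected"] = len(source_set.selected_genes)

    # ---------------- build + flow per phenotype ----------------
    with _stage("flow"):
        net_a, sol_a = analyze_phenotype(expr_a, interactome, source_set, analysis, "A")
        net_b, sol_b = analyze_phenotype(expr_b, interactome, source_set, analysis, "B")
        manifest["counts"]["n_network_nodes_a"] = len(net_a.nodes)
        manifest["counts"]["n_network_nodes_b"] = len(net_b.nodes)
        manifest["counts"]["delivered_a"] = sol_a.delivered
        manifest["counts"]["delivered_b"] = sol_b.delivered

    # ---------------- compare ----------------
    with _stage("compare"):
        diffs = node_flow_difference(sol_a, sol_b)
        roles = classify_roles(sol_a, sol_b, source_set, analysis, net_a, net_b)
        edges = key_edges(sol_a, sol_b, analysis)
        sub = prioritized_subnetwork(roles, edges, analysis)
        _write_table(diffs, out_dir / "node_flow_diff.tsv", written)
        _write_table(roles, out_dir / "roles.tsv", written)
        _write_table(edges, out_dir / "edges.tsv", written)
        profile = build_flow_profile_matrix({"A": sol_a, "B": sol_b})
        profile.index.name = "gene"
        profile.to_csv(out_dir / "flows.tsv", sep="\t", float_format="%.10g")
        written.append(out_dir / "flows.tsv")
        if not sub.edges.empty or not sub.nodes.empty:
            _write_subnetwork_graphml(sub, out_dir / "subnetwork.graphml")
            written.append(out_dir / "subnetwork.graphml")
        manifest["counts"]["subnetwork"] = sub.counts
        manifest["counts"]["n_key_edges"] = int(edges["key"].sum()) if not edges.empty else 0

    # ---------------- optional: ORA ----------------
    ora_cfg = cfg.get("ora") or {}
    if ora_cfg.get("gmt"):
        with _stage("ora"):
            collection = read_gmt(ora_cfg["gmt"])
            if ora_cfg.get("reference"):
                reference = [
                    line.strip()
                    for line in Path(ora_cfg["reference"]).read_text().splitlines()
                    if line.strip()
                ]
            else:  # measured-gene universe
                reference = sorted(set(expr_a.genes) | set(expr_b.genes))
            query = sub.member_genes()
            ora_table = run_ora(query, collection, reference)
            _write_table(ora_table, out_dir / "ora.tsv", written)
            manifest["counts"]["n_ora_sets"] = len(ora_table)

    # ---------------- optional: dependency ----------------
    dep_cfg = cfg.get("dependency") or {}
    dep_table = None
    if dep_cfg.get("scores"):
        dep_table = read_dependency_table(dep_cfg["scores"], dep_cfg.get("assay", "CRISPR"))
        manifest["inputs"]["dependency"] = _digest(Path(dep_cfg["scores"]))
    elif cfg.get("simulate") and dataset is not None and dep_cfg.get("enabled", True):
        dep_table = dataset.dependency
    if dep_table is not None and not roles.empty:
        with _stage("dependency"):
            flags = flag_dependencies(dep_table, list(roles["gene"]), analysis)
            summary, joined = summarize_by_role(flags, roles)
            _write_table(joined, out_dir / "dep.tsv", written)
            _write_table(summary, out_dir / "dep_summary.tsv", written)
            manifest["counts"]["n_dependency_flagged"] = int(joined["dependency"].sum())

    # ---------------- optional: clustering ----------------
    if cfg.get("cluster", True):
        with _stage("cluster"):
            if len(profile) >= 2:
                dendro = upgma_cluster(profile, axis="rows")
                (out_dir / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
                written.append(out_dir / "dendrogram.newick")
                merges = pd.DataFrame(
                    dendro.merges, columns=["left", "right", "height", "size"]
                )
                _write_table(merges, out_dir / "cluster_merges.tsv", written)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return out_dir


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    return str(obj)


def _write_subnetwork_graphml(sub, path: Path) -> None:
    import networkx as nx

    graph = nx.Graph()
    for row in sub.nodes.itertuples(index=False):
        graph.add_node(
            row.gene,
            role=row.role,
            flow_a=float(row.flow_a),
            flow_b=float(row.flow_b),
            flow_diff=float(row.flow_diff),
            impact=float(row.impact) if pd.notna(row.impact) else 0.0,
        )
    for row in sub.edges.itertuples(index=False):
        graph.add_edge(
            row.u,
            row.v,
            flow_a=float(row.flow_a),
            flow_b=float(row.flow_b),
            ratio=float(row.ratio),
            exclusive=row.exclusive,
            key=bool(row.key),
        )
    nx.write_graphml(graph, path)
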