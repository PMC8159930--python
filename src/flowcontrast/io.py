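"""Readers and writers for the formats the pipeline touches.

All downstream stages consume only the in-memory containers defined here:

* :class:`ExpressionMatrix` -- log2-normalized gene x sample expression with
  optional phenotype labels (TSV on disk, header row of sample IDs, first
  column of gene symbols).
* :class:`Interactome` -- an undirected, deduplicated protein-protein
  interaction edge set (SIF or two-column TSV, no header).
* :class:`GeneSetCollection` -- named gene sets for over-representation
  analysis (GMT).
* :class:`DependencyTable` -- long-form gene x cell-line dependency scores
  from RNAi (DEMETER2-style) or CRISPR (Avana-style) screens (CSV, wide
  DepMap layout with "SYMBOL (entrez)" columns, or long three-column layout).

Gene identifiers are uppercase HGNC-style symbols throughout; mapping from
probe or Ensembl IDs is the caller's job. Expression is assumed already
normalized; apply :meth:`ExpressionMatrix.log2_transform` when inputs are
linear-scale (e.g. FPKM-UQ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "Interactome",
    "GeneSet",
    "GeneSetCollection",
    "DependencyTable",
    "read_expression_matrix",
    "read_interactome",
    "read_gmt",
    "read_dependency_table",
    "write_network",
    "write_expression_matrix",
    "write_dependency_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2-normalized expression values.

    ``data`` is indexed by uppercase gene symbol (unique) with sample IDs as
    columns (unique); ``phenotype`` optionally maps sample ID -> label.
    """

    data: pd.DataFrame
    phenotype: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains non-finite values")
        if self.phenotype is not None:
            unknown = set(self.phenotype) - set(self.data.columns)
            if unknown:
                raise FormatError(
                    f"phenotype labels for unknown samples: {sorted(unknown)[:5]}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def samples_with_label(self, label: str) -> list[str]:
        """Samples carrying the given phenotype label, in column order."""
        if self.phenotype is None:
            raise ParameterError("expression matrix has no phenotype labels")
        return [s for s in self.data.columns if self.phenotype.get(s) == label]

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        keep = [s for s in self.data.columns if s in set(samples)]
        pheno = (
            {s: self.phenotype[s] for s in keep if s in self.phenotype}
            if self.phenotype
            else None
        )
        return ExpressionMatrix(self.data[keep].copy(), pheno)

    def log2_transform(self) -> "ExpressionMatrix":
        """Apply log2(x + 1); for linear-scale inputs such as FPKM-UQ."""
        values = self.data.to_numpy()
        if (values < 0).any():
            raise ParameterError("negative values: input does not look linear-scale")
        return ExpressionMatrix(
            pd.DataFrame(
                np.log2(values + 1.0), index=self.data.index, columns=self.data.columns
            ),
            dict(self.phenotype) if self.phenotype else None,
        )


def _canonical_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Interactome:
    """Undirected PPI edge set; no self-loops, no duplicate edges."""

    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "Interactome":
        """Build from (possibly messy) pairs: uppercase, dedup, drop self-loops."""
        edges: set[tuple[str, str]] = set()
        self_loops = 0
        for u, v in pairs:
            u, v = u.strip().upper(), v.strip().upper()
            if u == v:
                self_loops += 1
                continue
            edges.add(_canonical_edge(u, v))
        if self_loops:
            logger.info("dropped %d self-loop(s)", self_loops)
        return cls(frozenset(edges))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(g for edge in self.edges for g in edge)

    @property
    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for u, v in self.edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        return deg

    def union(self, pairs: Iterable[tuple[str, str]]) -> "Interactome":
        return Interactome.from_edges(list(self.edges) + list(pairs))

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_edges_from(self.sorted_edges)
        return graph

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        u, v = edge
        return _canonical_edge(u.upper(), v.upper()) in self.edges


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways, GO terms) keyed by set name."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name: {name}")
        unique = tuple(dict.fromkeys(g.upper() for g in genes))
        if not unique:
            raise FormatError(f"gene set {name} is empty")
        self.sets[name] = GeneSet(name, description, unique)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


@dataclass
class DependencyTable:
    """Long-form (gene, cell_line, score, assay) dependency records."""

    records: pd.DataFrame  # columns: gene, cell_line, score, assay

    def __post_init__(self) -> None:
        required = ["gene", "cell_line", "score", "assay"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise FormatError(f"dependency table missing columns: {missing}")
        self.records = self.records[required].reset_index(drop=True)
        if self.records.duplicated(["gene", "cell_line", "assay"]).any():
            raise FormatError("duplicate (gene, cell_line, assay) records")
        if not np.isfinite(self.records["score"].to_numpy()).all():
            raise FormatError("dependency scores must be finite")

    def scores_for(self, gene: str, assay: str | None = None) -> pd.Series:
        mask = self.records["gene"] == gene.upper()
        if assay is not None:
            mask &= self.records["assay"] == assay
        return self.records.loc[mask, "score"]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path, phenotype_map: str | Path | Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes x samples).

    First column holds gene symbols, the header row holds sample IDs.
    Symbols are uppercased and duplicate gene rows collapsed by mean.
    ``phenotype_map`` is a two-column TSV (sample, label) or an in-memory
    mapping.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty expression file")
    lines = text.splitlines()
    header = lines[0].rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ID(s): {dups}")
    if not samples:
        raise FormatError(f"{path}: no sample columns")

    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(fields)}"
            )
        gene = fields[0].strip().upper()
        row = []
        for col_idx, cell in enumerate(fields[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row {gene!r}, "
                    f"column {samples[col_idx]!r}"
                ) from None
            if not np.isfinite(value):
                raise ParseError(
                    f"{path}: non-finite value at row {gene!r}, column {samples[col_idx]!r}"
                )
            row.append(value)
        genes.append(gene)
        rows.append(row)
    if not genes:
        raise FormatError(f"{path}: no gene rows")

    frame = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    if frame.index.has_duplicates:
        frame = frame.groupby(level=0, sort=True).mean()
    else:
        frame = frame.sort_index()

    phenotype: dict[str, str] | None = None
    if phenotype_map is not None:
        if isinstance(phenotype_map, (str, Path)):
            phenotype = _read_phenotype_map(Path(phenotype_map))
        else:
            phenotype = dict(phenotype_map)
    return ExpressionMatrix(frame, phenotype)


def _read_phenotype_map(path: Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sample, label = fields[0].strip(), fields[1].strip()
        if lineno == 1 and sample.lower() in {"sample", "sample_id"}:
            continue  # optional header row
        if sample in mapping:
            raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
        mapping[sample] = label
    return mapping


def read_interactome(path: str | Path) -> Interactome:
    """Read a SIF ("A <relation> B [C ...]") or 2-column TSV interactome."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        tokens = [t.strip() for t in tokens if t.strip()]
        if len(tokens) < 2:
            raise FormatError(f"{path}:{lineno}: expected at least 2 tokens")
        if len(tokens) == 2:  # plain TSV pair
            pairs.append((tokens[0], tokens[1]))
        else:  # SIF: source, relation, one or more targets
            source = tokens[0]
            for target in tokens[2:]:
                pairs.append((source, target))
    if not pairs:
        logger.warning("%s: empty interactome", path)
    return Interactome.from_edges(pairs)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file ("name<TAB>description<TAB>gene1<TAB>...")."""
    path = Path(path)
    collection = GeneSetCollection()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        try:
            collection.add(fields[0], fields[1], fields[2:])
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return collection


def read_dependency_table(path: str | Path, assay: str) -> DependencyTable:
    """Read a dependency-score CSV (wide DepMap layout or long 3-column).

    Wide layout: rows = cell lines, columns = genes, DepMap column style
    "SYMBOL (entrez)" accepted. Long layout: columns gene, cell_line, score.
    Missing values are skipped with a logged count.
    """
    if assay not in {"RNAi", "CRISPR"}:
        raise ParameterError(f"assay must be RNAi or CRISPR, got {assay!r}")
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    lower = {c.strip().lower() for c in frame.columns}
    if {"gene", "cell_line", "score"} <= lower:
        frame.columns = [c.strip().lower() for c in frame.columns]
        long = frame[["gene", "cell_line", "score"]].copy()
    else:  # wide: first column = cell line, remaining columns = genes
        first = frame.columns[0]
        long = frame.melt(id_vars=[first], var_name="gene", value_name="score")
        long = long.rename(columns={first: "cell_line"})
    long["gene"] = [g.split(" (")[0].strip().upper() for g in long["gene"]]
    long["cell_line"] = long["cell_line"].str.strip()

    n_missing = int(long["score"].isna().sum())
    long = long.dropna(subset=["score"])
    scores = []
    for row in long.itertuples(index=False):
        try:
            scores.append(float(row.score))
        except ValueError:
            raise ParseError(
                f"{path}: unparseable score {row.score!r} for gene {row.gene!r}, "
                f"cell line {row.cell_line!r}"
            ) from None
    long = long.assign(score=scores, assay=assay)
    if n_missing:
        logger.info("%s: skipped %d record(s) with missing scores", path, n_missing)
    return DependencyTable(long.reset_index(drop=True))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_network(
    network,
    path: str | Path,
    fmt: str = "sif",
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
    edge_attrs: Mapping[tuple[str, str], Mapping[str, object]] | None = None,
) -> Path:
    """Write a network as SIF (relation token "pp") or GraphML.

    ``network`` may be an :class:`Interactome`, a ``networkx.Graph``, or any
    object exposing ``sorted_edges``. GraphML output carries the supplied
    node/edge attribute maps.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt not in {"sif", "graphml"}:
        raise ParameterError(f"unknown network format: {fmt!r}")

    if isinstance(network, nx.Graph):
        edges = sorted(_canonical_edge(u, v) for u, v in network.edges())
        nodes = sorted(network.nodes())
    else:
        edges = list(network.sorted_edges)
        nodes = sorted({g for e in edges for g in e})
    if not edges and not nodes:
        raise ParameterError("refusing to write an empty network")

    if fmt == "sif":
        with path.open("w") as fh:
            for u, v in edges:
                fh.write(f"{u}\tpp\t{v}\n")
        return path

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(edges)
    for node, attrs in (node_attrs or {}).items():
        if node in graph:
            graph.nodes[node].update(attrs)
    for (u, v), attrs in (edge_attrs or {}).items():
        if graph.has_edge(u, v):
            graph.edges[u, v].update(attrs)
    nx.write_graphml(graph, path)
    return path


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> Path:
    """Write an expression matrix as TSV (first column "gene")."""
    path = Path(path)
    frame = expr.data.copy()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.10g")
    return path


def write_dependency_table(table: DependencyTable, path: str | Path) -> Path:
    """Write a dependency table as long-form CSV (gene, cell_line, score)."""
    path = Path(path)
    table.records[["gene", "cell_line", "score"]].to_csv(
        path, index=False, float_format="%.10g"
    )
    return path
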