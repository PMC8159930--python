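"""Multi-dataset generalization: gene-set intersections across networks and
UPGMA clustering of total-flow profiles.

The flow-profile matrix collects total node flow (supply units) per gene
per context (e.g. control/perturbed networks from several datasets); a
gene filtered out of one context genuinely carries no flow there, so
absent gene-context pairs are imputed 0. Clustering is classical UPGMA
(average linkage) on Euclidean distances with a deterministic tie-break:
among minimum-distance cluster pairs, the pair whose representative leaf
labels sort lexicographically smallest is merged first.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError
from .flow import FlowSolution

__all__ = [
    "build_flow_profile_matrix",
    "IntersectionResult",
    "intersect_gene_sets",
    "Dendrogram",
    "upgma_cluster",
]


def build_flow_profile_matrix(solutions: Mapping[str, FlowSolution]) -> pd.DataFrame:
    """Genes x contexts matrix of total node flow, zero-imputed."""
    if not solutions:
        raise ParameterError("no flow solutions supplied")
    contexts = sorted(solutions)
    genes = sorted({g for sol in solutions.values() for g in sol.node_throughput_int})
    data = {
        ctx: [solutions[ctx].throughput_of(g) for g in genes] for ctx in contexts
    }
    return pd.DataFrame(data, index=genes, columns=contexts)


@dataclass
class IntersectionResult:
    """Exclusive region membership for 2-5 named gene sets."""

    regions: dict[tuple[str, ...], tuple[str, ...]]  # member-set names -> genes
    set_names: tuple[str, ...]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def full_intersection(self) -> tuple[str, ...]:
        return self.regions.get(self.set_names, ())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(names), len(genes), ";".join(genes))
            for names, genes in sorted(self.regions.items())
        ]
        return pd.DataFrame(rows, columns=["region", "count", "genes"])


def intersect_gene_sets(named_sets: Mapping[str, Iterable[str]]) -> IntersectionResult:
    """All 2^m - 1 exclusive Venn regions plus the full intersection."""
    if not 2 <= len(named_sets) <= 5:
        raise ParameterError("need between 2 and 5 sets")
    names = tuple(sorted(named_sets))
    sets = {name: {g.upper() for g in named_sets[name]} for name in names}
    regions: dict[tuple[str, ...], tuple[str, ...]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            exclusive = inside - outside
            regions[combo] = tuple(sorted(exclusive))
    # the full m-way region is both exclusive and the complete intersection
    full = set.intersection(*(sets[n] for n in names))
    regions[names] = tuple(sorted(full))
    return IntersectionResult(regions=regions, set_names=names)


@dataclass
class Dendrogram:
    """UPGMA merge history: (left, right, height, size) per merge, with the
    children given as cluster labels (leaf label, or the lexicographically
    smallest leaf of a merged cluster)."""

    merges: list[tuple[str, str, float, int]]
    leaf_order: list[str]
    heights: list[float]

    def to_newick(self) -> str:
        """Ultrametric Newick string; branch lengths are half-height gaps."""
        return self._newick + ";"

    _newick: str = ""


def upgma_cluster(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration on Euclidean distances.

    ``axis`` selects whether rows or columns are clustered. Merge heights
    are non-decreasing; ties are broken by the lexicographically smallest
    pair of cluster representatives.
    """
    if axis not in {"rows", "columns"}:
        raise ParameterError("axis must be 'rows' or 'columns'")
    frame = matrix if axis == "rows" else matrix.T
    labels = [str(x) for x in frame.index]
    if len(labels) < 2:
        raise ParameterError(f"need at least 2 items on the {axis} axis")
    if len(set(labels)) != len(labels):
        raise ParameterError("duplicate labels on the clustering axis")

    dist = squareform(pdist(frame.to_numpy(dtype=float), metric="euclidean"))
    # active clusters: id -> (representative label, size, member row indices)
    clusters: dict[int, tuple[str, int]] = {
        i: (labels[i], 1) for i in range(len(labels))
    }
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    newick: dict[int, str] = {i: labels[i] for i in range(len(labels))}
    height: dict[int, float] = {i: 0.0 for i in range(len(labels))}
    merges: list[tuple[str, str, float, int]] = []
    next_id = len(labels)

    def pair_key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    while len(clusters) > 1:
        best = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted((clusters[kv[0][0]][0], clusters[kv[0][1]][0]))),
            ),
        )
        (i, j), h = best
        rep_i, size_i = clusters[i]
        rep_j, size_j = clusters[j]
        left, right = ((i, j) if rep_i <= rep_j else (j, i))
        merges.append((clusters[left][0], clusters[right][0], h, size_i + size_j))

        bl_left = h / 2.0 - height[left] / 2.0
        bl_right = h / 2.0 - height[right] / 2.0
        newick[next_id] = (
            f"({newick[left]}:{bl_left:.10g},{newick[right]}:{bl_right:.10g})"
        )
        height[next_id] = h
        clusters[next_id] = (min(rep_i, rep_j), size_i + size_j)
        for k in list(clusters):
            if k in (i, j, next_id):
                continue
            dik = d.pop(pair_key(i, k))
            djk = d.pop(pair_key(j, k))
            sk = clusters[k][1]
            d[pair_key(next_id, k)] = (size_i * dik + size_j * djk) / (size_i + size_j)
        del d[pair_key(i, j)]
        del clusters[i], clusters[j]
        del newick[i], newick[j]
        next_id += 1

    root = next(iter(clusters))
    leaf_order: list[str] = []
    _collect_leaves(newick[root], leaf_order)
    dendro = Dendrogram(
        merges=merges, leaf_order=leaf_order, heights=[m[2] for m in merges]
    )
    dendro._newick = newick[root]
    return dendro


def _collect_leaves(newick: str, out: list[str]) -> None:
    # leaves are the label tokens directly followed by a branch length
    out.extend(re.findall(r"([^(),:]+):", newick))
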