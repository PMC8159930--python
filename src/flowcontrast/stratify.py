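"""Phenotype stratification, differential-expression source selection, and
marker correlation.

Stratification follows the marker-median convention: samples with marker
expression strictly above the median are "high", all others "low", so a
marker-high bin unambiguously means above-median. Source selection uses a
Welch two-sample t-test with Benjamini-Hochberg adjustment; a bypass mode
accepts a published gene list verbatim (the usual situation when sources
come from an earlier differential-expression study).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .errors import GeneNotFoundError, ParameterError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StratifiedLabels",
    "SourceSet",
    "split_by_marker_median",
    "select_sources",
    "marker_correlation",
]


@dataclass(frozen=True)
class StratifiedLabels:
    high: frozenset[str]
    low: frozenset[str]
    marker: str
    median_value: float

    def as_phenotype_map(self, high_label: str = "high", low_label: str = "low") -> dict[str, str]:
        mapping = {s: high_label for s in self.high}
        mapping.update({s: low_label for s in self.low})
        return mapping


@dataclass
class SourceSet:
    """Per-gene differential-expression records with a selection flag.

    ``records`` columns: gene, log2fc, p, q, selected. In bypass mode
    log2fc/p/q are NaN and every listed gene is selected.
    """

    records: pd.DataFrame
    bypass: bool = False

    def __post_init__(self) -> None:
        required = ["gene", "log2fc", "p", "q", "selected"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ParameterError(f"SourceSet records missing columns: {missing}")
        finite = self.records.dropna(subset=["p", "q"])
        if (finite["q"] + 1e-12 < finite["p"]).any():
            raise ParameterError("BH-adjusted q must be >= p")

    @property
    def selected_genes(self) -> list[str]:
        return sorted(self.records.loc[self.records["selected"], "gene"])

    def log2fc_of(self, gene: str) -> float | None:
        if self.bypass:
            return None
        row = self.records.loc[self.records["gene"] == gene, "log2fc"]
        return None if row.empty else float(row.iloc[0])


def split_by_marker_median(expr: ExpressionMatrix, marker: str) -> StratifiedLabels:
    """Split samples at the median of the marker gene (strictly greater -> high)."""
    marker = marker.upper()
    if marker not in expr.data.index:
        raise GeneNotFoundError(f"marker gene {marker!r} not in expression matrix")
    if len(expr.samples) < 4:
        raise ParameterError("need at least 4 samples to stratify")
    values = expr.data.loc[marker]
    if float(values.max()) == float(values.min()):
        raise ParameterError(f"degenerate stratification: marker {marker!r} is constant")
    median = float(values.median())
    high = frozenset(values.index[values > median])
    low = frozenset(values.index[values <= median])
    return StratifiedLabels(high=high, low=low, marker=marker, median_value=median)


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test p-values per gene row; the zero-variance
    convention is p = 1 for equal means and p = 0 otherwise."""
    res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        diff = b.mean(axis=1) - a.mean(axis=1)
        p[degenerate] = np.where(np.isclose(diff[degenerate], 0.0), 1.0, 0.0)
    return p


def select_sources(
    expr_a: ExpressionMatrix | None = None,
    expr_b: ExpressionMatrix | None = None,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    gene_list: list[str] | None = None,
) -> SourceSet:
    """Select differentially expressed source genes.

    Two-matrix mode: per-gene log2FC = mean(B) - mean(A), Welch p, BH q;
    selected iff |log2FC| >= lfc_min and q <= alpha. Bypass mode
    (``gene_list``): the listed genes are selected verbatim with statistics
    marked unavailable.
    """
    if gene_list is not None:
        genes = sorted(dict.fromkeys(g.upper() for g in gene_list))
        records = pd.DataFrame(
            {
                "gene": genes,
                "log2fc": np.nan,
                "p": np.nan,
                "q": np.nan,
                "selected": True,
            }
        )
        return SourceSet(records, bypass=True)

    if expr_a is None or expr_b is None:
        raise ParameterError("provide two expression matrices or a gene list")
    if len(expr_a.samples) < 2 or len(expr_b.samples) < 2:
        raise ParameterError("each phenotype needs at least 2 samples")
    common = sorted(set(expr_a.genes) & set(expr_b.genes))
    if not common:
        raise ParameterError("no common genes between the two phenotypes")
    a = expr_a.data.loc[common].to_numpy()
    b = expr_b.data.loc[common].to_numpy()
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    p = _welch(a, b)
    q = bh_adjust(p)
    selected = (np.abs(log2fc) >= lfc_min) & (q <= alpha)
    if not selected.any():
        logger.warning("no gene passed |log2FC| >= %g and q <= %g", lfc_min, alpha)
    records = pd.DataFrame(
        {"gene": common, "log2fc": log2fc, "p": p, "q": q, "selected": selected}
    )
    return SourceSet(records)


def marker_correlation(
    expr: ExpressionMatrix, gene_x: str, gene_y: str, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation between two genes across samples, with two-sided p."""
    gene_x, gene_y = gene_x.upper(), gene_y.upper()
    for g in (gene_x, gene_y):
        if g not in expr.data.index:
            raise GeneNotFoundError(f"gene {g!r} not in expression matrix")
    if len(expr.samples) < 4:
        raise ParameterError("need at least 4 samples for a correlation")
    x = expr.data.loc[gene_x].to_numpy()
    y = expr.data.loc[gene_y].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance: correlation undefined")
    if method == "spearman":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ParameterError(f"unknown correlation method: {method!r}")
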