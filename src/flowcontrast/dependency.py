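"""Gene-dependency integration.

Joins RNAi/CRISPR dependency screens onto network roles: a gene is called a
dependency (vulnerability) when its median score across available cell
lines is strictly below the threshold (default -1.0, the conventional
cutoff for strong essentiality in CRISPR screens). The median is used for
the gene-level call because per-line scores are noisy; per-line counts
below threshold are emitted alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import DependencyTable
from .network import AnalysisConfig

__all__ = ["flag_dependencies", "summarize_by_role"]


def flag_dependencies(
    table: DependencyTable, genes: list[str], config: AnalysisConfig
) -> pd.DataFrame:
    """Per gene and assay: cell-line count, median score, dependency call.

    Genes absent from the table are reported with n_lines = 0 and
    dependency = False.
    """
    if not genes:
        raise ParameterError("gene list is empty")
    genes = sorted(dict.fromkeys(g.upper() for g in genes))
    threshold = config.dependency_threshold
    assays = sorted(table.records["assay"].unique()) or ["CRISPR"]
    grouped = table.records.groupby(["gene", "assay"])["score"]
    medians = grouped.median()
    counts = grouped.size()
    below = table.records.assign(below=table.records["score"] < threshold).groupby(
        ["gene", "assay"]
    )["below"].sum()

    rows = []
    for gene in genes:
        for assay in assays:
            key = (gene, assay)
            if key in medians.index:
                median = float(medians.loc[key])
                rows.append(
                    (
                        gene,
                        assay,
                        int(counts.loc[key]),
                        median,
                        int(below.loc[key]),
                        bool(median < threshold),
                    )
                )
            else:
                rows.append((gene, assay, 0, np.nan, 0, False))
    return pd.DataFrame(
        rows,
        columns=["gene", "assay", "n_lines", "median_score", "n_lines_below", "dependency"],
    )


def summarize_by_role(flags: pd.DataFrame, roles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency summary (role x assay -> flagged / total) plus the
    per-gene joined table in waterfall order (median score ascending)."""
    joined = flags.merge(roles[["gene", "role"]], on="gene", how="inner")
    joined = joined.sort_values(
        ["median_score", "gene", "assay"], ascending=[True, True, True], kind="stable"
    ).reset_index(drop=True)
    if joined.empty:
        summary = pd.DataFrame(columns=["role", "assay", "n_flagged", "n_total"])
    else:
        summary = (
            joined.groupby(["role", "assay"])
            .agg(n_flagged=("dependency", "sum"), n_total=("dependency", "size"))
            .reset_index()
        )
        summary["n_flagged"] = summary["n_flagged"].astype(int)
    return summary, joined
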