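"""Exact hypergeometric over-representation analysis (ORA) with BH-FDR.

For a query gene list and a gene set, both restricted to an explicit
reference universe of size N, the over-representation p-value is the exact
upper hypergeometric tail

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N - K, n - i) / C(N, n)

where n is the restricted query size, K the restricted set size, and k the
overlap. The enrichment ratio is (k/n) / (K/N), observed over expected.
Only the upper tail is tested (over-representation); the reference universe
is a required input because gene-set statistics are meaningless without a
declared background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .io import GeneSetCollection

__all__ = ["ORAResult", "hypergeometric_ora", "bh_adjust", "run_ora"]


@dataclass(frozen=True)
class ORAResult:
    set_name: str
    k: int  # query ∩ set overlap (within reference)
    n: int  # restricted query size
    K: int  # restricted set size
    N: int  # reference size
    p: float
    q: float = float("nan")

    @property
    def enrichment_ratio(self) -> float:
        return (self.k / self.n) / (self.K / self.N)

    @property
    def neg_log10_fdr(self) -> float:
        return -np.log10(self.q) if self.q > 0 else np.inf


def _upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k), computed in
    log space (scipy's survival function) to avoid underflow at genome
    scale."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_ora(
    query: Iterable[str], gene_set: Iterable[str], reference: Iterable[str], name: str = ""
) -> ORAResult:
    """Over-representation of ``gene_set`` in ``query`` against ``reference``.

    Query and set are restricted to the reference before counting; genes
    outside the reference never affect any statistic.
    """
    ref = {g.upper() for g in reference}
    if not ref:
        raise ParameterError("reference universe is empty")
    q = {g.upper() for g in query} & ref
    s = {g.upper() for g in gene_set} & ref
    if not q:
        raise ParameterError("query is empty after restriction to the reference")
    if not s:
        raise ParameterError(f"gene set {name or '(unnamed)'} is empty after restriction")
    k = len(q & s)
    n, K, N = len(q), len(s), len(ref)
    return ORAResult(set_name=name, k=k, n=n, K=K, N=N, p=_upper_tail(k, n, K, N))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query: Iterable[str], collection: GeneSetCollection, reference: Iterable[str]
) -> pd.DataFrame:
    """ORA of the query against every set in the collection.

    Sets that vanish after restriction to the reference are skipped; BH
    adjustment spans exactly the tests performed. Sorted by q ascending,
    then enrichment ratio descending, then set name.
    """
    if len(collection) == 0:
        raise ParameterError("gene-set collection is empty")
    ref = {g.upper() for g in reference}
    results: list[ORAResult] = []
    for gene_set in collection:
        restricted = set(gene_set.genes) & ref
        if not restricted:
            continue
        results.append(
            hypergeometric_ora(query, gene_set.genes, ref, name=gene_set.name)
        )
    if not results:
        raise ParameterError("no gene set overlaps the reference universe")
    qvals = bh_adjust([r.p for r in results])
    frame = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "enrichment_ratio": [r.enrichment_ratio for r in results],
            "p": [r.p for r in results],
            "q": qvals,
        }
    )
    frame["neg_log10_fdr"] = -np.log10(frame["q"].clip(lower=np.finfo(float).tiny))
    frame = frame.sort_values(
        ["q", "enrichment_ratio", "set_name"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    return frame
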