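"""Hypergeometric over-representation of a gene list against named sets.

For a universe of N genes, a set of K genes and a query of n genes with k
genes overlapping the set, the enrichment p-value is the exact upper tail
P[X >= k] of the hypergeometric distribution; Benjamini-Hochberg step-up
controls the FDR across sets.  This is a desk-scale replacement for web
enrichment services: deterministic, offline, and exact.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .labeled_io import SignatureDefinition

logger = logging.getLogger(__name__)


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P[X >= k] for overlap k under the hypergeometric null."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query_genes: Iterable[str],
    gene_sets: Sequence[SignatureDefinition],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` in each gene set.

    Query genes outside the universe are dropped with a warning; each set
    is intersected with the universe before testing.  Returns one row per
    set with columns ``set_name, N, K, n, k, pvalue, qvalue``, sorted by
    p-value (ties by set name).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes)
    outside = query - universe_set
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped", len(outside)
        )
        query &= universe_set

    N, n = len(universe_set), len(query)
    rows = []
    for sig in gene_sets:
        members = set(sig.gene_ids) & universe_set
        K = len(members)
        k = len(members & query)
        rows.append({
            "set_name": sig.name, "N": N, "K": K, "n": n, "k": k,
            "pvalue": hypergeom_pvalue(N, K, n, k),
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["qvalue"] = multipletests(result["pvalue"], method="fdr_bh")[1]
        result = result.sort_values(
            ["pvalue", "set_name"], kind="stable"
        ).reset_index(drop=True)
    else:
        result["qvalue"] = pd.Series(dtype=float)
    return result
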