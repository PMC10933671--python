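"""Marker-gene module scoring, tumor-cluster assignment and quadrant calls.

The module score follows the binned-control convention that is the de-facto
standard for marker-set scoring in single-cell analysis: expression is
normalised (counts-per-10k, log1p), genes are binned by mean expression, and
the score of a cell is the mean normalised expression of the signature genes
minus the mean of control genes sampled from the signatures' expression bins.
A score near zero therefore means "no enrichment beyond expression-matched
background"; the cGAS-STING pathway score (CSPS), the Tfh score and the
exhaustion score are all instances of this with seven-gene marker lists.

Quadrant phenotyping partitions cells into four classes by joint positivity
of two genes (e.g. cGAS+/STING+, cGAS+/STING-, cGAS-/STING+, cGAS-/STING-);
positivity is called on raw counts (default threshold: at least one count),
which makes the call invariant to library-size rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._normalize import cp10k_log1p
from .errors import GeneNotFoundError, SignatureGenesMissingError
from .labeled_io import LabeledExpressionMatrix, SignatureDefinition

logger = logging.getLogger(__name__)


def module_score(
    matrix: LabeledExpressionMatrix,
    signature: SignatureDefinition,
    *,
    layer: str = "total",
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    Parameters
    ----------
    matrix
        Expression container; scoring uses the chosen ``layer`` (``total``
        by default).
    signature
        Gene list plus the number of expression bins and controls per gene.
    seed
        Seeds the control-gene sampling; scores are deterministic for a
        fixed seed and invariant to gene/cell ordering.

    Returns
    -------
    pandas.Series indexed by cell id, named after the signature.
    """
    normed = cp10k_log1p(matrix.layer(layer))
    present = [g for g in signature.gene_ids if g in matrix.gene_ids]
    if not present:
        raise SignatureGenesMissingError(
            f"no gene of signature {signature.name!r} present in matrix"
        )
    if len(present) < len(signature.gene_ids):
        logger.warning(
            "signature %r: %d of %d genes absent from matrix",
            signature.name, len(signature.gene_ids) - len(present),
            len(signature.gene_ids),
        )

    gene_mean = np.asarray(normed.mean(axis=1)).ravel()
    # order-invariant binning: rank genes by (mean expression, gene id),
    # then cut the rank range into equal-size bins
    order_idx = np.lexsort((matrix.gene_ids.to_numpy(), gene_mean))
    rank = np.empty(matrix.n_genes, dtype=np.int64)
    rank[order_idx] = np.arange(matrix.n_genes)
    n_bins = min(signature.n_control_bins, matrix.n_genes)
    if n_bins < signature.n_control_bins:
        logger.warning(
            "only %d genes: control bins reduced from %d to %d",
            matrix.n_genes, signature.n_control_bins, n_bins,
        )
    bins = pd.Series(rank * n_bins // matrix.n_genes, index=matrix.gene_ids)

    sig_set = set(present)
    rng = np.random.default_rng(seed)
    control: set[str] = set()
    by_bin = {
        b: idx.sort_values() for b, idx in bins.groupby(bins).groups.items()
    }
    for gene in sorted(sig_set):
        b = bins.loc[gene]
        candidates = by_bin[b].difference(present)
        if len(candidates) == 0:
            logger.warning("no control candidates in bin of gene %r", gene)
            continue
        k = min(signature.n_control_per_gene, len(candidates))
        chosen = rng.choice(len(candidates), size=k, replace=False)
        control.update(candidates[chosen])

    if not control:
        raise SignatureGenesMissingError(
            f"signature {signature.name!r}: no control genes could be sampled"
        )

    sig_rows = matrix.gene_ids.get_indexer(present)
    ctrl_rows = matrix.gene_ids.get_indexer(sorted(control))
    sig_mean = np.asarray(normed[sig_rows].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(normed[ctrl_rows].mean(axis=0)).ravel()
    return pd.Series(sig_mean - ctrl_mean, index=matrix.cell_ids,
                     name=signature.name)


def score_table(
    matrix: LabeledExpressionMatrix,
    signatures: Sequence[SignatureDefinition],
    *,
    layer: str = "total",
    seed: int = 0,
) -> pd.DataFrame:
    """Long-form table of scores: one row per (cell, signature)."""
    rows = []
    for sig in signatures:
        s = module_score(matrix, sig, layer=layer, seed=seed)
        rows.append(
            pd.DataFrame({"cell_id": s.index, "signature": sig.name,
                          "score": s.to_numpy()})
        )
    return pd.concat(rows, ignore_index=True)


def assign_tumor_clusters(
    scores: pd.Series,
    cluster_labels: pd.Series,
    top_k: int,
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag the cells of the ``top_k`` clusters by mean signature score.

    This mirrors the study design of calling the clusters with the highest
    Tfh scores tumor cells.  Ranking is by cluster-mean score, ties at the
    k-th rank broken by lexicographic cluster label, so the call is
    deterministic and idempotent.

    Returns
    -------
    (mask, ranking)
        ``mask`` — boolean Series over cells (True = in a top-k cluster);
        ``ranking`` — per-cluster mean score, size and selection flag,
        in rank order.
    """
    cluster_labels = cluster_labels.reindex(scores.index)
    if cluster_labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    cluster_labels = cluster_labels.astype(str)
    grouped = scores.groupby(cluster_labels)
    ranking = pd.DataFrame({
        "mean_score": grouped.mean(),
        "n_cells": grouped.size(),
    })
    ranking.index.name = "cluster"
    empty = ranking["n_cells"] == 0
    if empty.any():
        logger.warning("ignoring %d empty cluster(s)", int(empty.sum()))
        ranking = ranking[~empty]
    if top_k > len(ranking):
        raise ValueError(
            f"top_k={top_k} exceeds number of non-empty clusters ({len(ranking)})"
        )
    # descending score, ascending label on ties
    ranking = (
        ranking.reset_index()
        .sort_values(["mean_score", "cluster"], ascending=[False, True],
                     kind="stable")
        .set_index("cluster")
    )
    ranking["selected"] = False
    ranking.iloc[:top_k, ranking.columns.get_loc("selected")] = True
    selected = set(ranking.index[ranking["selected"]])
    mask = cluster_labels.isin(selected)
    mask.name = "tumor"
    return mask, ranking


@dataclass
class QuadrantResult:
    """Per-cell quadrant calls and per-group composition."""

    calls: pd.DataFrame          # cell_id, phenotype, threshold
    composition: pd.DataFrame    # group x phenotype counts and proportions
    gene_a: str
    gene_b: str
    threshold: int


def quadrant_phenotype(
    matrix: LabeledExpressionMatrix,
    gene_a: str,
    gene_b: str,
    *,
    threshold: int = 1,
    layer: str = "total",
    group_key: str | None = "group",
) -> QuadrantResult:
    """Partition cells into four joint-positivity phenotypes.

    Positivity of a gene in a cell means its raw count in ``layer`` is at
    least ``threshold`` (default 1).  Phenotype labels follow the
    ``A+/B+`` convention, e.g. ``cGAS+/STING+``.
    """
    counts = matrix.layer(layer)
    a = np.asarray(counts[matrix.gene_index(gene_a)].todense()).ravel()
    b = np.asarray(counts[matrix.gene_index(gene_b)].todense()).ravel()
    pos_a = a >= threshold
    pos_b = b >= threshold

    def _label(pa: bool, pb: bool) -> str:
        return f"{gene_a}{'+' if pa else '-'}/{gene_b}{'+' if pb else '-'}"

    phenotypes = pd.Categorical(
        [_label(pa, pb) for pa, pb in zip(pos_a, pos_b)],
        categories=[_label(True, True), _label(True, False),
                    _label(False, True), _label(False, False)],
    )
    calls = pd.DataFrame({
        "cell_id": matrix.cell_ids,
        "phenotype": phenotypes,
        "threshold": threshold,
    })

    if group_key is not None and group_key in matrix.cell_annotations.columns:
        groups = matrix.cell_annotations[group_key].to_numpy()
    else:
        groups = np.repeat("all", matrix.n_cells)
    comp = (
        pd.crosstab(pd.Series(groups, name="group"),
                    pd.Series(phenotypes, name="phenotype"), dropna=False)
        .reindex(columns=phenotypes.categories, fill_value=0)
    )
    proportions = comp.div(comp.sum(axis=1).replace(0, np.nan), axis=0)
    composition = pd.concat(
        {"count": comp, "proportion": proportions}, axis=1
    )
    return QuadrantResult(calls=calls, composition=composition,
                          gene_a=gene_a, gene_b=gene_b, threshold=threshold)


@dataclass
class AssociationResult:
    statistic: float   # Spearman rho
    pvalue: float
    n: int


def score_association(score_x: pd.Series, score_y: pd.Series) -> AssociationResult:
    """Spearman rank correlation between two per-cell scores."""
    aligned = pd.concat([score_x, score_y], axis=1, join="inner").dropna()
    if len(aligned) < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = stats.spearmanr(aligned.iloc[:, 0], aligned.iloc[:, 1])
    return AssociationResult(statistic=float(rho), pvalue=float(p),
                             n=len(aligned))
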