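"""Dual-layer (new/old RNA) count matrices and their on-disk formats.

The central container is :class:`LabeledExpressionMatrix`: a genes x cells
pair of integer count layers produced by metabolic-labeling scRNA-seq, where
every captured transcript is classified as newly synthesised ("new") or
pre-existing ("old").  Total expression is always *derived* as new + old and
never stored, so the two layers cannot drift out of sync.

On disk a matrix is a directory of plain-text files:

* ``new.mtx`` / ``old.mtx`` — Matrix-Market coordinate integer matrices
  (genes x cells, 1-based per the MM standard; in-memory indices are
  0-based — the conversion happens only inside scipy's reader/writer);
* ``features.tsv`` — gene id and symbol, one per row, matrix order;
* ``barcodes.tsv`` — cell id, one per row, matrix order;
* ``cells.tsv`` — cell id plus ``group`` / ``cluster`` / ``cell_type``
  annotation columns.

Gene sets are read from standard GMT files (name, description, then
tab-separated gene ids).

Conventional unlabeled experiments are represented as the degenerate case
``new == 0``: total expression then equals the old layer, and every
downstream scoring function applies unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    DuplicateIdentifierError,
    GeneNotFoundError,
    LayerShapeMismatchError,
    NegativeCountError,
    UnknownAnnotationError,
)

logger = logging.getLogger(__name__)

LAYERS = ("new", "old", "total")

ANNOTATION_COLUMNS = ("group", "cluster", "cell_type")


def _as_int_csr(matrix) -> sp.csr_matrix:
    m = sp.csr_matrix(matrix)
    if m.nnz and m.data.min() < 0:
        raise NegativeCountError("count layer contains negative entries")
    if not np.issubdtype(m.dtype, np.integer):
        data = m.data
        if m.nnz and not np.allclose(data, np.round(data)):
            raise NegativeCountError(
                "count layer contains non-integer entries"
            )
        m = m.astype(np.int64)
    m.sum_duplicates()
    return m


@dataclass
class LabeledExpressionMatrix:
    """Genes x cells new/old count layers with per-cell annotations.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers (rows).
    cell_ids
        Ordered unique cell identifiers (columns).
    new_counts, old_counts
        Sparse integer matrices of identical shape ``(n_genes, n_cells)``.
    cell_annotations
        DataFrame indexed by cell id with any of the columns ``group``,
        ``cluster``, ``cell_type``.  Every annotated cell must exist in the
        matrix.
    """

    gene_ids: pd.Index
    cell_ids: pd.Index
    new_counts: sp.csr_matrix
    old_counts: sp.csr_matrix
    cell_annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        if self.gene_ids.has_duplicates:
            raise DuplicateIdentifierError("duplicate gene identifiers")
        if self.cell_ids.has_duplicates:
            raise DuplicateIdentifierError("duplicate cell identifiers")
        self.new_counts = _as_int_csr(self.new_counts)
        self.old_counts = _as_int_csr(self.old_counts)
        if self.new_counts.shape != self.old_counts.shape:
            raise LayerShapeMismatchError(
                f"new layer {self.new_counts.shape} != old layer "
                f"{self.old_counts.shape}"
            )
        expected = (len(self.gene_ids), len(self.cell_ids))
        if self.new_counts.shape != expected:
            raise LayerShapeMismatchError(
                f"layers {self.new_counts.shape} do not match identifiers "
                f"{expected}"
            )
        ann = pd.DataFrame(self.cell_annotations)
        if not ann.empty:
            unknown = ann.index.difference(self.cell_ids)
            if len(unknown):
                raise UnknownAnnotationError(
                    f"annotated cells absent from matrix: {list(unknown[:5])}"
                )
            ann = ann.reindex(self.cell_ids)
        else:
            ann = pd.DataFrame(index=self.cell_ids)
        ann.index.name = "cell_id"
        self.cell_annotations = ann

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def total_counts(self) -> sp.csr_matrix:
        """Total expression, derived on demand as new + old."""
        return (self.new_counts + self.old_counts).tocsr()

    def layer(self, name: str) -> sp.csr_matrix:
        """Return the ``new``, ``old`` or derived ``total`` count layer."""
        if name == "new":
            return self.new_counts
        if name == "old":
            return self.old_counts
        if name == "total":
            return self.total_counts
        raise ValueError(f"unknown layer {name!r}; expected one of {LAYERS}")

    def gene_index(self, gene_id: str) -> int:
        try:
            return int(self.gene_ids.get_loc(gene_id))
        except KeyError:
            raise GeneNotFoundError(f"gene {gene_id!r} not in matrix") from None

    def groups(self, key: str = "group") -> pd.Series:
        """Per-cell annotation column, validated to exist."""
        if key not in self.cell_annotations.columns:
            raise UnknownAnnotationError(
                f"annotation column {key!r} not present "
                f"(have {list(self.cell_annotations.columns)})"
            )
        return self.cell_annotations[key]

    def subset_cells(self, mask: np.ndarray | pd.Series) -> "LabeledExpressionMatrix":
        if isinstance(mask, pd.Series):
            mask = mask.reindex(self.cell_ids).to_numpy()
        mask = np.asarray(mask, dtype=bool)
        return LabeledExpressionMatrix(
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[mask],
            new_counts=self.new_counts[:, mask],
            old_counts=self.old_counts[:, mask],
            cell_annotations=self.cell_annotations.loc[mask],
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes) with
        ``new``/``old`` layers and total counts in ``X``."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.total_counts.T.tocsr(),
            obs=self.cell_annotations.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.layers["new"] = self.new_counts.T.tocsr()
        adata.layers["old"] = self.old_counts.T.tocsr()
        return adata


@dataclass
class SignatureDefinition:
    """A named marker-gene list with control-bin scoring parameters.

    ``n_control_bins`` and ``n_control_per_gene`` parameterise the
    binned-control module score (see :mod:`scdyn.signatures`).
    """

    name: str
    gene_ids: list[str]
    n_control_bins: int = 25
    n_control_per_gene: int = 100

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"signature {self.name!r} has no genes")
        seen: dict[str, None] = {}
        dropped = 0
        for g in self.gene_ids:
            if g in seen:
                dropped += 1
            else:
                seen[g] = None
        if dropped:
            logger.warning(
                "signature %r: %d duplicate gene(s) removed", self.name, dropped
            )
        self.gene_ids = list(seen)

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# Matrix-Market directory I/O
# ---------------------------------------------------------------------------

def write_labeled_matrix(matrix: LabeledExpressionMatrix, directory: str | Path) -> Path:
    """Write a matrix as new.mtx/old.mtx + TSV sidecars under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "new.mtx", matrix.new_counts.tocoo(), field="integer")
    scipy.io.mmwrite(directory / "old.mtx", matrix.old_counts.tocoo(), field="integer")
    pd.DataFrame({"id": matrix.gene_ids, "symbol": matrix.gene_ids}).to_csv(
        directory / "features.tsv", sep="\t", index=False
    )
    pd.DataFrame({"id": matrix.cell_ids}).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False
    )
    cells = matrix.cell_annotations.reindex(columns=list(ANNOTATION_COLUMNS))
    cells.to_csv(directory / "cells.tsv", sep="\t", index=True)
    return directory


def read_labeled_matrix(directory: str | Path) -> LabeledExpressionMatrix:
    """Read a matrix directory written by :func:`write_labeled_matrix`."""
    directory = Path(directory)
    new = sp.csr_matrix(scipy.io.mmread(directory / "new.mtx")).astype(np.int64)
    old = sp.csr_matrix(scipy.io.mmread(directory / "old.mtx")).astype(np.int64)
    if new.shape != old.shape:
        raise LayerShapeMismatchError(
            f"new.mtx {new.shape} != old.mtx {old.shape}"
        )
    features = pd.read_csv(directory / "features.tsv", sep="\t", dtype=str)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", dtype=str)
    cells_path = directory / "cells.tsv"
    if cells_path.exists():
        ann = pd.read_csv(cells_path, sep="\t", index_col="cell_id", dtype=str)
        ann = ann.dropna(axis=1, how="all")
    else:
        ann = pd.DataFrame()
    return LabeledExpressionMatrix(
        gene_ids=pd.Index(features["id"].fillna("").tolist() if len(features) else []),
        cell_ids=pd.Index(barcodes["id"].fillna("").tolist() if len(barcodes) else []),
        new_counts=new,
        old_counts=old,
        cell_annotations=ann,
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, *, n_control_bins: int = 25,
             n_control_per_gene: int = 100) -> list[SignatureDefinition]:
    """Parse a GMT file into signatures (order-preserving; duplicates within a
    set are removed with a logged warning)."""
    signatures: list[SignatureDefinition] = []
    text = Path(path).read_text()
    for raw in text.splitlines():
        line = raw.strip("\r\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            logger.warning("GMT line with fewer than 3 fields skipped: %r", line[:60])
            continue
        name, _description, *genes = parts
        genes = [g for g in genes if g]
        signatures.append(
            SignatureDefinition(
                name=name,
                gene_ids=genes,
                n_control_bins=n_control_bins,
                n_control_per_gene=n_control_per_gene,
            )
        )
    return signatures


def write_gmt(signatures: Iterable[SignatureDefinition], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> Path:
    path = Path(path)
    lines = []
    for sig in signatures:
        desc = (descriptions or {}).get(sig.name, "na")
        lines.append("\t".join([sig.name, desc, *sig.gene_ids]))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
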