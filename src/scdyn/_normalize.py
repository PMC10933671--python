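"""Shared count normalisation: counts-per-10k followed by log1p.

One fixed convention used by both signature scoring and PC embedding, so the
two stages can never disagree about the expression scale.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

TARGET_SUM = 1e4


def cp10k_log1p(counts: sp.spmatrix) -> sp.csr_matrix:
    """Normalise a genes x cells count matrix to 10k counts per cell, log1p.

    Cells with zero total counts are left as all-zero columns.
    """
    counts = sp.csc_matrix(counts, dtype=np.float64)
    libsize = np.asarray(counts.sum(axis=0)).ravel()
    scale = np.divide(
        TARGET_SUM, libsize, out=np.zeros_like(libsize, dtype=np.float64),
        where=libsize > 0,
    )
    normed = counts @ sp.diags(scale)
    normed.data = np.log1p(normed.data)
    return normed.tocsr()
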