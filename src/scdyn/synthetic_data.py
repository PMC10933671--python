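"""Synthetic dual-layer and cohort count generators with known ground truth.

Two generators cover the two study designs the package analyses:

``generate_labeled_counts``
    A metabolic-labeling experiment on a cell line treated with DMSO, the
    cGAS inhibitor G150, or G150 plus the CLK1 inhibitor TG003 ("GT", the
    combination).  Total counts per gene are negative-binomial; new counts
    are a binomial split of the total with a per-gene, per-group
    new-to-total ratio (NTR) mean.  A designated set of "program" genes
    (proliferation / DNA-repair stand-ins) carries group-specific NTR
    shifts — by default the combination group is shifted more negatively
    than G150 alone, emulating suppressed nascent synthesis of those
    programs.  An optional ``synthesis_drop`` mechanism instead thins the
    nascent counts of program genes directly (old counts untouched), which
    is the appropriate model when only newly-made RNA should distinguish a
    treatment group.

``generate_lymphnode_cohort``
    An unlabeled lymph-node cohort with treatment-naive (ND), relapsed/
    refractory (RR) and normal (NC) groups, Tfh-tumor versus non-Tfh cells,
    cluster labels, and marker-gene sets (Tfh markers, cGAS-STING pathway
    genes, exhaustion genes) whose expression is shifted multiplicatively
    in designated cell types or cohort groups.

Both return the generated matrix together with a ground-truth record so
downstream recovery can be tested quantitatively.  All randomness descends
from a single root seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .labeled_io import LabeledExpressionMatrix, SignatureDefinition

logger = logging.getLogger(__name__)

NTR_CLIP = (0.001, 0.999)


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float, size: tuple[int, ...]) -> np.ndarray:
    """Gamma-Poisson draw with Var = mean + dispersion * mean^2."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Dynamic (metabolic-labeling) design
# ---------------------------------------------------------------------------

@dataclass
class DynGenParams:
    """Parameters of the labeled-counts generator.

    Attributes
    ----------
    n_genes, n_cells_per_group
        Matrix dimensions; groups are balanced by default (pass a mapping in
        ``group_sizes`` to unbalance them).
    groups
        Ordered treatment labels; defaults to DMSO / G150 / GT (combination).
    baseline_ntr
        Per-gene baseline NTR mean.  ``None`` draws each gene's baseline from
        Beta(2, 4) (mean 1/3 — a realistic nascent fraction for a labeling
        window of a few hours); a scalar applies to all genes; an array gives
        per-gene values.
    program_genes
        Indices of the proliferation/DNA-repair stand-in genes.  Defaults to
        the first 10% of genes.
    ntr_shift
        Additive NTR shift applied to program genes, per group.  Defaults
        leave DMSO at baseline and shift G150 by -0.05 and the combination
        by -0.25, so the combination-minus-G150 contrast is -0.2 (a ΔNTR of
        +0.2 for G150 minus combination).
    synthesis_drop
        Optional per-group fraction of nascent transcription *retained* for
        program genes (binomial thinning of new counts; old counts are left
        untouched).  Use this when only the new layer should separate a
        group.  Empty by default.
    nb_mean, nb_dispersion
        Negative-binomial total-count parameters (Var = m + d*m^2).  The
        defaults give roughly 2400 total counts per gene per group at the
        default group size.
    labeling_efficiency
        Probability that a truly nascent transcript is captured in the new
        layer (multiplicative thinning of the NTR mean).
    seed
        Root seed; every draw descends from it.
    """

    n_genes: int = 3000
    n_cells_per_group: int = 300
    groups: tuple[str, ...] = ("DMSO", "G150", "GT")
    baseline_ntr: float | Sequence[float] | None = None
    program_genes: Sequence[int] | None = None
    ntr_shift: Mapping[str, float] = field(
        default_factory=lambda: {"DMSO": 0.0, "G150": -0.05, "GT": -0.25}
    )
    synthesis_drop: Mapping[str, float] = field(default_factory=dict)
    nb_mean: float = 8.0
    nb_dispersion: float = 0.4
    labeling_efficiency: float = 1.0
    seed: int = 0
    group_sizes: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_group <= 0:
            raise ValueError("n_genes and n_cells_per_group must be positive")
        if not self.groups:
            raise ValueError("at least one group required")
        if not (0 < self.labeling_efficiency <= 1) and self.labeling_efficiency != 0:
            raise ValueError("labeling_efficiency must be in [0, 1]")
        if self.program_genes is None:
            self.program_genes = tuple(range(max(1, self.n_genes // 10)))
        self.program_genes = tuple(int(i) for i in self.program_genes)
        if self.n_genes < len(self.program_genes):
            raise ValueError("more program genes than genes")
        if any(i < 0 or i >= self.n_genes for i in self.program_genes):
            raise ValueError("program gene index out of range")
        for g, f in self.synthesis_drop.items():
            if not (0 <= f <= 1):
                raise ValueError(f"synthesis_drop[{g!r}] must be in [0, 1]")

    def size_of(self, group: str) -> int:
        if self.group_sizes and group in self.group_sizes:
            return int(self.group_sizes[group])
        return self.n_cells_per_group


@dataclass
class DynGroundTruth:
    """True generative quantities for recovery tests.

    ``configured_ntr`` is the NTR mean handed to the binomial split
    (baseline + shift, clipped, times labeling efficiency);
    ``expected_ntr`` additionally accounts for synthesis thinning, i.e. it
    is the population new/(new+old) ratio an ideal estimator converges to.
    """

    configured_ntr: pd.DataFrame
    expected_ntr: pd.DataFrame
    program_genes: list[str]
    params: DynGenParams

    def expected_delta(self, minuend: str, subtrahend: str) -> pd.Series:
        return self.expected_ntr[minuend] - self.expected_ntr[subtrahend]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "configured_ntr": self.configured_ntr.round(6).to_dict(orient="index"),
            "expected_ntr": self.expected_ntr.round(6).to_dict(orient="index"),
            "program_genes": self.program_genes,
            "params": _params_dict(self.params),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _params_dict(params) -> dict:
    def conv(v):
        if isinstance(v, tuple):
            return [conv(x) for x in v]
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {
                (k if isinstance(k, str) else "|".join(map(str, k))): conv(x)
                for k, x in v.items()
            }
        return v

    return {k: conv(v) for k, v in asdict(params).items()}


def generate_labeled_counts(
    params: DynGenParams,
) -> tuple[LabeledExpressionMatrix, DynGroundTruth]:
    """Draw a dual-layer count matrix under the configured dynamic design."""
    rng = np.random.default_rng(params.seed)
    n_genes = params.n_genes

    if params.baseline_ntr is None:
        baseline = rng.beta(2.0, 4.0, size=n_genes)
    else:
        baseline = np.broadcast_to(
            np.asarray(params.baseline_ntr, dtype=float), (n_genes,)
        ).copy()
    program = np.zeros(n_genes, dtype=bool)
    program[list(params.program_genes)] = True

    gene_ids = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene_id")
    lo, hi = NTR_CLIP
    configured = {}
    expected = {}
    new_blocks, old_blocks, cell_ids, group_labels = [], [], [], []

    for group in params.groups:
        shift = float(params.ntr_shift.get(group, 0.0))
        p = baseline.copy()
        p[program] += shift
        n_clipped = int(np.sum((p < lo) | (p > hi)))
        if n_clipped:
            logger.warning(
                "group %s: %d gene NTR mean(s) clipped to [%g, %g]",
                group, n_clipped, lo, hi,
            )
        p = np.clip(p, lo, hi) * params.labeling_efficiency

        n_cells = params.size_of(group)
        total = _negative_binomial(
            rng, params.nb_mean, params.nb_dispersion, (n_genes, n_cells)
        )
        new = rng.binomial(total, p[:, None])
        old = total - new
        retain = float(params.synthesis_drop.get(group, 1.0))
        if retain < 1.0:
            thinned = rng.binomial(new, retain)
            new = new.copy()
            new[program] = thinned[program]

        configured[group] = p
        p_eff = np.where(
            program, p * retain / (1.0 - p + p * retain), p
        )
        expected[group] = p_eff

        new_blocks.append(sp.csr_matrix(new))
        old_blocks.append(sp.csr_matrix(old))
        cell_ids.extend(f"{group}_{i:05d}" for i in range(n_cells))
        group_labels.extend([group] * n_cells)

    matrix = LabeledExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=pd.Index(cell_ids, name="cell_id"),
        new_counts=sp.hstack(new_blocks, format="csr"),
        old_counts=sp.hstack(old_blocks, format="csr"),
        cell_annotations=pd.DataFrame(
            {"group": group_labels}, index=pd.Index(cell_ids, name="cell_id")
        ),
    )
    truth = DynGroundTruth(
        configured_ntr=pd.DataFrame(configured, index=gene_ids),
        expected_ntr=pd.DataFrame(expected, index=gene_ids),
        program_genes=list(gene_ids[program]),
        params=params,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Lymph-node cohort design
# ---------------------------------------------------------------------------

@dataclass
class CohortGenParams:
    """Parameters of the unlabeled lymph-node cohort generator.

    ``effect_sizes`` maps ``(marker_set, annotation_column, annotation_value)``
    to a natural-log fold change applied multiplicatively to the marker set's
    genes in matching cells; effects stack additively on the log scale when a
    cell matches several conditions.
    """

    n_genes: int = 1000
    n_cells_per_group: int = 200
    cell_types: tuple[str, ...] = ("Tfh-tumor", "non-Tfh")
    cohort_groups: tuple[str, ...] = ("NC", "ND", "RR")
    tfh_fraction: float = 0.3
    n_clusters: int = 6
    tfh_clusters: tuple[str, ...] = ("3", "11")
    marker_sets: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {
            "tfh": tuple(range(0, 7)),
            "csps": tuple(range(7, 14)),
            "exhaustion": tuple(range(14, 21)),
        }
    )
    effect_sizes: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: {
            ("tfh", "cell_type", "Tfh-tumor"): 1.0,
            ("csps", "cell_type", "Tfh-tumor"): 0.8,
            ("csps", "group", "RR"): 0.4,
            ("exhaustion", "cell_type", "Tfh-tumor"): 0.6,
        }
    )
    nb_dispersion: float = 0.3
    base_mean_log_sd: float = 1.0
    base_mean_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_group <= 0:
            raise ValueError("n_genes and n_cells_per_group must be positive")
        if not (0 <= self.tfh_fraction <= 1):
            raise ValueError("tfh_fraction must be in [0, 1]")
        for name, idx in self.marker_sets.items():
            if any(i < 0 or i >= self.n_genes for i in idx):
                raise ValueError(f"marker set {name!r} has gene index out of range")
        for (name, col, _val), eff in self.effect_sizes.items():
            if name not in self.marker_sets:
                raise ValueError(f"effect references unknown marker set {name!r}")
            if col not in ("cell_type", "group", "cluster"):
                raise ValueError(f"effect references unknown annotation {col!r}")
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")


@dataclass
class CohortGroundTruth:
    """Marker-set membership (as gene ids) and applied effects."""

    marker_sets: dict[str, list[str]]
    effect_sizes: dict[str, float]
    params: CohortGenParams

    def signature(self, name: str, **kwargs) -> SignatureDefinition:
        return SignatureDefinition(name=name, gene_ids=list(self.marker_sets[name]),
                                   **kwargs)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "marker_sets": self.marker_sets,
            "effect_sizes": self.effect_sizes,
            "params": _params_dict(self.params),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def generate_lymphnode_cohort(
    params: CohortGenParams,
) -> tuple[LabeledExpressionMatrix, CohortGroundTruth]:
    """Draw an unlabeled cohort matrix (returned with new == 0).

    Cells carry ``group`` (NC/ND/RR), ``cell_type`` and ``cluster``
    annotations; Tfh-tumor cells are confined to the designated Tfh
    clusters, non-Tfh cells to the remaining clusters.
    """
    rng = np.random.default_rng(params.seed)
    n_genes = params.n_genes
    gene_ids = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene_id")

    base_mean = params.base_mean_scale * rng.lognormal(
        mean=0.0, sigma=params.base_mean_log_sd, size=n_genes
    )

    all_clusters = [str(c) for c in params.tfh_clusters]
    other_clusters = [
        str(i) for i in range(params.n_clusters)
        if str(i) not in set(all_clusters)
    ]
    if not other_clusters and params.tfh_fraction < 1:
        raise ValueError("no non-Tfh clusters available")

    records = []
    for group in params.cohort_groups:
        n = params.n_cells_per_group
        n_tfh = int(round(params.tfh_fraction * n))
        types = ["Tfh-tumor"] * n_tfh + ["non-Tfh"] * (n - n_tfh)
        for t in types:
            pool = all_clusters if t == "Tfh-tumor" else other_clusters
            records.append((group, t, pool[rng.integers(len(pool))]))
    ann = pd.DataFrame(records, columns=["group", "cell_type", "cluster"])
    ann.index = pd.Index(
        [f"{g}_{i:05d}" for i, g in enumerate(ann["group"])], name="cell_id"
    )

    # per-cell log-fold offsets per gene, from stacked marker-set effects
    log_offset = np.zeros((n_genes, len(ann)))
    for (set_name, col, val), eff in params.effect_sizes.items():
        cells = (ann[col] == val).to_numpy()
        idx = np.fromiter(params.marker_sets[set_name], dtype=int)
        log_offset[np.ix_(idx, np.nonzero(cells)[0])] += eff

    mean = base_mean[:, None] * np.exp(log_offset)
    counts = _negative_binomial(rng, mean, params.nb_dispersion, mean.shape)

    matrix = LabeledExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=ann.index,
        new_counts=sp.csr_matrix((n_genes, len(ann)), dtype=np.int64),
        old_counts=sp.csr_matrix(counts),
        cell_annotations=ann,
    )
    truth = CohortGroundTruth(
        marker_sets={
            name: list(gene_ids[np.fromiter(idx, dtype=int)])
            for name, idx in params.marker_sets.items()
        },
        effect_sizes={
            f"{name}|{col}={val}": eff
            for (name, col, val), eff in params.effect_sizes.items()
        },
        params=params,
    )
    return matrix, truth
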