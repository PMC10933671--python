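"""End-to-end workflows: cohort scoring and dynamic-RNA treatment comparison.

Both workflows run from a single :class:`RunConfig` (JSON-serialisable),
write tidy TSVs into the output directory, and record a run manifest with
the seed, the configuration and library versions, so a run can be
reproduced exactly.  Identical config + seed yields byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from . import dynamics, enrichment, geometry, signatures, synthetic_data
from .errors import ConfigError
from .labeled_io import (
    LabeledExpressionMatrix,
    read_gmt,
    read_labeled_matrix,
    write_labeled_matrix,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def default_signatures_path() -> Path:
    """Packaged placeholder GMT (editable defaults, not the study's lists)."""
    return Path(resources.files("scdyn") / "data" / "default_signatures.gmt")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_dir`` (a matrix directory readable by
    :func:`scdyn.labeled_io.read_labeled_matrix`) or ``simulate``
    (``"dynamics"`` or ``"cohort"``, with optional generator overrides in
    ``sim_params``) must be provided.
    """

    out_dir: str
    seed: int = 0
    input_dir: str | None = None
    simulate: str | None = None
    sim_params: dict = field(default_factory=dict)
    gmt: str | None = None
    # dynamics workflow
    group_key: str = "group"
    minuend: str = "G150"
    subtrahend: str = "GT"
    pooled_side: list[str] = field(default_factory=lambda: ["DMSO", "G150"])
    other_side: list[str] = field(default_factory=lambda: ["GT"])
    top_k: int = 500
    min_total: int = 10
    n_pcs: int = 20
    n_boot: int = 1000
    distance_metric: str = "centroid"
    rank_absolute: bool = False
    # cohort workflow
    tumor_signature: str = "tfh"
    tumor_top_k: int = 3
    quadrant_genes: list[str] = field(default_factory=list)
    quadrant_threshold: int = 1

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of input_dir or simulate must be set"
            )
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ConfigError(f"input_dir does not exist: {self.input_dir}")
        if self.simulate not in (None, "dynamics", "cohort"):
            raise ConfigError(f"unknown simulate mode {self.simulate!r}")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise ConfigError(f"GMT file does not exist: {self.gmt}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _write_manifest(out: Path, config: RunConfig, extra: dict) -> None:
    import numpy, scipy, sklearn, statsmodels

    manifest = {
        "scdyn_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _load_or_simulate(config: RunConfig):
    """Returns (matrix, ground_truth_or_None)."""
    if config.input_dir is not None:
        return read_labeled_matrix(config.input_dir), None
    params_kwargs = dict(config.sim_params)
    params_kwargs.setdefault("seed", config.seed)
    if config.simulate == "dynamics":
        params = synthetic_data.DynGenParams(**params_kwargs)
        return synthetic_data.generate_labeled_counts(params)
    params = synthetic_data.CohortGenParams(**params_kwargs)
    return synthetic_data.generate_lymphnode_cohort(params)


def _signatures_for(config: RunConfig, truth) -> list:
    if config.gmt is not None:
        return read_gmt(config.gmt)
    if isinstance(truth, synthetic_data.CohortGroundTruth):
        return [truth.signature(name) for name in truth.marker_sets]
    return read_gmt(default_signatures_path())


def run_cohort(config: RunConfig) -> Path:
    """Cohort workflow: module scores, tumor-cluster call, quadrants,
    score associations.  Returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = _load_or_simulate(config)
    if truth is not None:
        write_labeled_matrix(matrix, out / "matrix")
        truth.to_json(out / "ground_truth.json")

    sigs = _signatures_for(config, truth)
    scores = signatures.score_table(matrix, sigs, seed=config.seed)
    _write_tsv(scores, out / "scores.tsv")

    wide = scores.pivot(index="cell_id", columns="signature", values="score")
    extra: dict = {}
    if (config.tumor_signature in wide.columns
            and "cluster" in matrix.cell_annotations.columns):
        mask, ranking = signatures.assign_tumor_clusters(
            wide[config.tumor_signature].reindex(matrix.cell_ids),
            matrix.cell_annotations["cluster"],
            top_k=min(config.tumor_top_k,
                      matrix.cell_annotations["cluster"].nunique()),
        )
        _write_tsv(mask.rename("tumor").reset_index(), out / "tumor_mask.tsv")
        _write_tsv(ranking.reset_index(), out / "cluster_ranking.tsv")
        extra["n_tumor_cells"] = int(mask.sum())

    quadrant_genes = config.quadrant_genes
    if len(quadrant_genes) == 2:
        result = signatures.quadrant_phenotype(
            matrix, quadrant_genes[0], quadrant_genes[1],
            threshold=config.quadrant_threshold,
        )
        _write_tsv(result.calls, out / "quadrants.tsv")
        comp = result.composition.copy()
        comp.columns = [f"{a}:{b}" for a, b in comp.columns]
        _write_tsv(comp.reset_index(), out / "composition.tsv")

    assoc_rows = []
    cols = sorted(wide.columns)
    for i, x in enumerate(cols):
        for y in cols[i + 1:]:
            a = signatures.score_association(wide[x], wide[y])
            assoc_rows.append({"score_x": x, "score_y": y,
                               "spearman_rho": a.statistic,
                               "pvalue": a.pvalue, "n": a.n})
    if assoc_rows:
        _write_tsv(pd.DataFrame(assoc_rows), out / "associations.tsv")

    _write_manifest(out, config, {"workflow": "cohort", **extra})
    return out


def run_dynamics(config: RunConfig) -> Path:
    """Dynamic-RNA workflow: NTR tables, ΔNTR ranking, top-k genes,
    per-layer group distances, enrichment.  Returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = _load_or_simulate(config)
    if truth is not None:
        write_labeled_matrix(matrix, out / "matrix")
        truth.to_json(out / "ground_truth.json")

    per_cell = dynamics.cell_ntr(matrix)
    cells = matrix.cell_annotations.copy()
    cells["ntr"] = per_cell
    _write_tsv(cells.reset_index(), out / "ntr_cells.tsv")

    table = dynamics.gene_group_ntr(
        matrix, group_key=config.group_key, min_total=config.min_total
    )
    _write_tsv(table.reset_index(), out / "ntr_gene_group.tsv")

    delta = dynamics.delta_ntr(table, config.minuend, config.subtrahend)
    ranked = delta.dropna(subset=["delta_ntr"]).sort_values(
        ["delta_ntr", "gene_id"], ascending=[False, True], kind="stable"
    )
    ranked["rank"] = range(1, len(ranked) + 1)
    _write_tsv(ranked.reset_index(), out / "delta_ntr.tsv")

    top = dynamics.top_k_genes(delta, config.top_k,
                               absolute=config.rank_absolute)
    _write_tsv(pd.DataFrame({"gene_id": top}), out / "top_genes.tsv")

    rows = []
    group_labels = sorted(matrix.groups(config.group_key).astype(str).unique())
    pairs = [
        ((a,), (b,))
        for i, a in enumerate(group_labels) for b in group_labels[i + 1:]
    ]
    pairs.append((tuple(config.pooled_side), tuple(config.other_side)))
    for layer in ("new", "old", "total"):
        emb = geometry.pc_embedding(
            matrix, layer=layer,
            n_pcs=min(config.n_pcs, min(matrix.n_cells, matrix.n_genes)),
            seed=config.seed,
        )
        for side_a, side_b in pairs:
            res = geometry.bootstrap_distances(
                emb, matrix.groups(config.group_key), side_a, side_b,
                n_boot=config.n_boot, seed=config.seed,
                metric=config.distance_metric,
            )
            rows.append(res.summary())
    _write_tsv(pd.DataFrame(rows), out / "distances.tsv")

    universe = delta.dropna(subset=["delta_ntr"]).index
    gene_sets = []
    if config.gmt is not None:
        gene_sets = read_gmt(config.gmt)
    elif isinstance(truth, synthetic_data.DynGroundTruth):
        from .labeled_io import SignatureDefinition
        gene_sets = [SignatureDefinition("program_genes", truth.program_genes)]
    if gene_sets:
        enr = enrichment.hypergeom_enrich(top, gene_sets, universe)
        _write_tsv(enr, out / "enrichment.tsv")

    _write_manifest(out, config, {
        "workflow": "dynamics",
        "n_genes": matrix.n_genes,
        "n_cells": matrix.n_cells,
    })
    return out
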