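import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scdyn import signatures, synthetic_data as sd
from scdyn.errors import GeneNotFoundError, SignatureGenesMissingError
from scdyn.labeled_io import LabeledExpressionMatrix, SignatureDefinition


def _matrix_from_counts(counts, groups=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    cells = pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id")
    ann = pd.DataFrame(index=cells)
    if groups is not None:
        ann["group"] = groups
    return LabeledExpressionMatrix(
        gene_ids=pd.Index([f"g{i:03d}" for i in range(n_genes)]),
        cell_ids=cells,
        new_counts=sp.csr_matrix((n_genes, n_cells), dtype=int),
        old_counts=sp.csr_matrix(counts),
        cell_annotations=ann,
    )


class TestModuleScore:
    def test_constant_genes_score_zero(self):
        """If every gene carries the same constant expression, controls
        cancel the signature exactly."""
        counts = np.full((40, 6), 5)
        matrix = _matrix_from_counts(counts)
        sig = SignatureDefinition("s", ["g003", "g010", "g020"],
                                  n_control_bins=5, n_control_per_gene=10)
        scores = signatures.module_score(matrix, sig, seed=0)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_null_signature_centers_near_zero(self):
        """Monte-Carlo oracle: on exchangeable Poisson data a random
        signature's grand mean score is ~0."""
        rng = np.random.default_rng(0)
        grand_means = []
        for seed in range(10):
            counts = rng.poisson(3.0, size=(300, 80))
            matrix = _matrix_from_counts(counts)
            genes = rng.choice(matrix.gene_ids, size=7, replace=False)
            sig = SignatureDefinition("null", list(genes))
            grand_means.append(
                signatures.module_score(matrix, sig, seed=seed).mean()
            )
        grand_means = np.asarray(grand_means)
        assert abs(grand_means.mean()) <= 3 * grand_means.std(ddof=1) / np.sqrt(
            len(grand_means)
        ) + 1e-3

    def test_planted_shift_separates_cell_types(self, cohort_small):
        matrix, truth = cohort_small
        score = signatures.module_score(matrix, truth.signature("tfh"), seed=0)
        by_type = score.groupby(matrix.cell_annotations["cell_type"]).mean()
        assert by_type["Tfh-tumor"] > by_type["non-Tfh"]

    def test_invariant_under_gene_and_cell_reordering(self, cohort_small):
        matrix, truth = cohort_small
        sig = truth.signature("tfh")
        base = signatures.module_score(matrix, sig, seed=3)
        rng = np.random.default_rng(1)
        gperm = rng.permutation(matrix.n_genes)
        cperm = rng.permutation(matrix.n_cells)
        shuffled = LabeledExpressionMatrix(
            gene_ids=matrix.gene_ids[gperm],
            cell_ids=matrix.cell_ids[cperm],
            new_counts=matrix.new_counts[gperm][:, cperm],
            old_counts=matrix.old_counts[gperm][:, cperm],
            cell_annotations=matrix.cell_annotations.iloc[cperm],
        )
        other = signatures.module_score(shuffled, sig, seed=3)
        pd.testing.assert_series_equal(base.sort_index(), other.sort_index())

    def test_no_signature_gene_present_raises(self, tiny_matrix):
        with pytest.raises(SignatureGenesMissingError):
            signatures.module_score(
                tiny_matrix, SignatureDefinition("s", ["nope"]), seed=0
            )

    def test_deterministic_for_fixed_seed(self, cohort_small):
        matrix, truth = cohort_small
        sig = truth.signature("csps")
        a = signatures.module_score(matrix, sig, seed=5)
        b = signatures.module_score(matrix, sig, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_agrees_with_scanpy_score_genes(self, cohort_small):
        """Independent cross-check: correlation with scanpy's binned-control
        score should be very high (different control draws, same construction)."""
        sc = pytest.importorskip("scanpy")
        matrix, truth = cohort_small
        ours = signatures.module_score(matrix, truth.signature("tfh"), seed=0)
        adata = matrix.to_anndata()
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.tl.score_genes(adata, truth.marker_sets["tfh"], ctrl_size=100,
                          n_bins=25, score_name="sc_score", random_state=0)
        r = np.corrcoef(ours.to_numpy(), adata.obs["sc_score"].to_numpy())[0, 1]
        assert r > 0.95


class TestScoreTable:
    def test_one_row_per_cell_signature(self, cohort_small):
        matrix, truth = cohort_small
        sigs = [truth.signature(n) for n in truth.marker_sets]
        table = signatures.score_table(matrix, sigs, seed=0)
        assert len(table) == matrix.n_cells * len(sigs)
        assert table["score"].notna().all()


class TestAssignTumorClusters:
    def test_all_flagged_when_top_k_covers_all_clusters(self):
        scores = pd.Series([1.0, 0.5, 0.1], index=["c0", "c1", "c2"])
        clusters = pd.Series(["a", "b", "c"], index=scores.index)
        mask, _ = signatures.assign_tumor_clusters(scores, clusters, top_k=3)
        assert mask.all()

    def test_top_one_selects_highest_mean_cluster(self):
        scores = pd.Series([1.0, 1.0, 0.5, 0.1], index=list("wxyz"))
        clusters = pd.Series(["c1", "c1", "c2", "c3"], index=list("wxyz"))
        mask, ranking = signatures.assign_tumor_clusters(scores, clusters, top_k=1)
        assert set(mask.index[mask]) == {"w", "x"}
        assert ranking.index[0] == "c1"

    def test_tie_at_kth_rank_broken_lexicographically(self):
        scores = pd.Series([0.5, 0.5, 0.9], index=["a", "b", "c"])
        clusters = pd.Series(["z2", "z1", "top"], index=scores.index)
        mask, ranking = signatures.assign_tumor_clusters(scores, clusters, top_k=2)
        # z1 and z2 tie; lexicographically smaller z1 is kept
        assert list(ranking.index[:2]) == ["top", "z1"]
        assert set(mask.index[mask]) == {"c", "b"}

    def test_idempotent_and_deterministic(self, cohort_small):
        matrix, truth = cohort_small
        score = signatures.module_score(matrix, truth.signature("tfh"), seed=0)
        clusters = matrix.cell_annotations["cluster"]
        m1, r1 = signatures.assign_tumor_clusters(score, clusters, top_k=2)
        m2, r2 = signatures.assign_tumor_clusters(score, clusters, top_k=2)
        pd.testing.assert_series_equal(m1, m2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_recovers_planted_tfh_clusters(self, cohort_small):
        matrix, truth = cohort_small
        score = signatures.module_score(matrix, truth.signature("tfh"), seed=0)
        mask, _ = signatures.assign_tumor_clusters(
            score, matrix.cell_annotations["cluster"], top_k=2
        )
        truth_mask = matrix.cell_annotations["cell_type"] == "Tfh-tumor"
        recall = (mask & truth_mask).sum() / truth_mask.sum()
        assert recall >= 0.95

    def test_top_k_exceeding_clusters_raises(self):
        scores = pd.Series([1.0, 0.5], index=["c0", "c1"])
        clusters = pd.Series(["a", "b"], index=scores.index)
        with pytest.raises(ValueError, match="top_k"):
            signatures.assign_tumor_clusters(scores, clusters, top_k=3)


class TestQuadrantPhenotype:
    def test_forced_calls(self):
        counts = np.array([[0, 5, 0, 2], [0, 0, 3, 2]])
        matrix = _matrix_from_counts(counts)
        res = signatures.quadrant_phenotype(matrix, "g000", "g001")
        expect = ["g000-/g001-", "g000+/g001-", "g000-/g001+", "g000+/g001+"]
        assert list(res.calls["phenotype"]) == expect

    def test_partition_sums_to_n_cells(self, dyn_small):
        matrix, _ = dyn_small
        res = signatures.quadrant_phenotype(matrix, "g0000", "g0001")
        counts = res.composition["count"]
        assert counts.to_numpy().sum() == matrix.n_cells
        props = res.composition["proportion"].sum(axis=1)
        np.testing.assert_allclose(props, 1.0)

    def test_calls_depend_only_on_the_two_genes(self, tiny_matrix):
        res1 = signatures.quadrant_phenotype(tiny_matrix, "gA", "gB")
        bumped = LabeledExpressionMatrix(
            gene_ids=tiny_matrix.gene_ids,
            cell_ids=tiny_matrix.cell_ids,
            new_counts=tiny_matrix.new_counts,
            old_counts=tiny_matrix.old_counts + sp.csr_matrix(
                np.vstack([np.zeros((2, 3), int), np.full((2, 3), 7)])
            ),
            cell_annotations=tiny_matrix.cell_annotations,
        )
        res2 = signatures.quadrant_phenotype(bumped, "gA", "gB")
        assert list(res1.calls["phenotype"]) == list(res2.calls["phenotype"])

    def test_threshold_changes_positivity(self):
        counts = np.array([[2, 0], [1, 1]])
        matrix = _matrix_from_counts(counts)
        low = signatures.quadrant_phenotype(matrix, "g000", "g001", threshold=1)
        high = signatures.quadrant_phenotype(matrix, "g000", "g001", threshold=2)
        assert list(low.calls["phenotype"])[0] == "g000+/g001+"
        assert list(high.calls["phenotype"])[0] == "g000+/g001-"

    def test_absent_gene_raises(self, tiny_matrix):
        with pytest.raises(GeneNotFoundError):
            signatures.quadrant_phenotype(tiny_matrix, "gA", "missing")


class TestScoreAssociation:
    def test_identical_vectors_rho_one(self):
        s = pd.Series(np.arange(10, dtype=float), index=[f"c{i}" for i in range(10)])
        res = signatures.score_association(s, s * 2 + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        idx = [f"c{i}" for i in range(10)]
        x = pd.Series(np.arange(10, dtype=float), index=idx)
        res = signatures.score_association(x, -x)
        assert res.statistic == pytest.approx(-1.0)

    def test_independent_scores_within_permutation_null_band(self):
        """Permutation oracle: |rho| of independent vectors stays below the
        97.5th percentile of the permuted-rho null in most draws."""
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(60)]
        x = pd.Series(rng.normal(size=60), index=idx)
        y = pd.Series(rng.normal(size=60), index=idx)
        observed = abs(signatures.score_association(x, y).statistic)
        perms = []
        xv = x.to_numpy()
        for _ in range(500):
            perm = rng.permutation(60)
            perms.append(abs(
                signatures.score_association(
                    pd.Series(xv[perm], index=idx), y
                ).statistic
            ))
        assert observed <= np.quantile(perms, 0.99)

    def test_too_few_pairs_raise(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            signatures.score_association(s, s)
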