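from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lactoscore import synth
from lactoscore.io import CountMatrix
from lactoscore.qc import (
    HvgPcaParams,
    QCThresholds,
    apply_qc,
    cluster_cells,
    find_markers,
    lognormalize,
    run_pca,
    select_hvgs,
)


def _counts(x, genes=None, cells=None):
    n, g = x.shape
    return CountMatrix(
        values=sp.csr_matrix(x),
        cell_ids=cells or [f"c{i}" for i in range(n)],
        gene_ids=genes or [f"g{i}" for i in range(g)],
    )


class TestApplyQc:
    def test_gene_count_bounds_inclusive(self, rng):
        """Cells with 150/500/8000 detected genes against bounds [200,7000]:
        only the 500-gene cell survives."""
        n_genes = 9000
        x = np.zeros((3, n_genes), dtype=int)
        x[0, :150] = 1
        x[1, :500] = 1
        x[2, :8000] = 1
        cm = _counts(x)
        out, report = apply_qc(cm, QCThresholds(min_cells_per_gene=1))
        survivors = set(out.cell_ids)
        assert survivors == {"c1"}
        assert report.cells_removed_low_genes == 1
        assert report.cells_removed_high_genes == 1

    def test_boundary_gene_counts_retained(self):
        n_genes = 7200
        x = np.zeros((2, n_genes), dtype=int)
        x[0, :200] = 1   # exactly the lower bound
        x[1, :7000] = 1  # exactly the upper bound
        cm = _counts(x)
        out, _ = apply_qc(cm, QCThresholds(min_cells_per_gene=1))
        assert {"c0", "c1"} <= set(out.cell_ids)

    def test_mito_fraction_exactly_at_threshold_retained(self):
        genes = ["MT-1"] + [f"g{i}" for i in range(4)]
        x = np.array([
            [2, 2, 2, 2, 2],   # mito fraction 0.2 exactly -> kept
            [6, 1, 1, 1, 1],   # 0.6 -> removed
            [0, 2, 2, 2, 2],
            [1, 2, 2, 2, 2],
            [0, 1, 1, 1, 1],
        ])
        cm = _counts(x, genes=genes)
        th = QCThresholds(min_cells_per_gene=1, min_genes_per_cell=1,
                          max_genes_per_cell=10)
        out, report = apply_qc(cm, th)
        assert "c0" in set(out.cell_ids)
        assert "c1" not in set(out.cell_ids)
        assert report.cells_removed_mito == 1

    def test_low_prevalence_genes_removed_by_enumeration(self, rng):
        """100x50 matrix where 10 designated genes appear in <5 cells."""
        x = rng.poisson(5.0, size=(100, 50)) + 1
        rare = rng.choice(50, size=10, replace=False)
        for j in rare:
            x[:, j] = 0
            on = rng.choice(100, size=int(rng.integers(0, 5)), replace=False)
            x[on, j] = 1
        cm = _counts(x)
        out, report = apply_qc(
            cm, QCThresholds(min_genes_per_cell=1, max_genes_per_cell=10000)
        )
        assert out.n_genes == 40
        assert report.genes_removed_min_cells == 10

    def test_idempotent(self, rng):
        cfg = synth.SimulationConfig(n_cells=300, n_genes=500, seed=1)
        cm, _ = synth.simulate_sc_counts(cfg)
        once, _ = apply_qc(cm)
        twice, rep2 = apply_qc(once)
        assert once.values.shape == twice.values.shape
        assert (once.values != twice.values).nnz == 0

    def test_all_cells_removed_fatal(self):
        x = np.ones((3, 10), dtype=int)  # 10 detected genes < 200 minimum
        with pytest.raises(ValueError, match="all cells removed"):
            apply_qc(_counts(x), QCThresholds(min_cells_per_gene=1))


class TestLognormalize:
    def test_all_zero_cell_stays_zero(self):
        x = np.array([[0, 0, 0], [1, 2, 3]])
        out = lognormalize(_counts(x))
        np.testing.assert_array_equal(out.dense()[0], 0.0)

    def test_single_gene_cell_closed_form(self):
        x = np.array([[7, 0], [1, 1]])
        out = lognormalize(_counts(x))
        assert out.dense()[0, 0] == pytest.approx(np.log1p(1e4))

    def test_expm1_row_sums_equal_scale_total(self, rng):
        x = rng.poisson(3.0, size=(10, 20)) + 1
        out = lognormalize(_counts(x))
        sums = np.expm1(out.dense()).sum(axis=1)
        np.testing.assert_allclose(sums, 1e4, rtol=1e-10)


class TestHvg:
    def _lognorm(self, x):
        cm = _counts(x)
        return lognormalize(cm)

    def test_identity_when_n_equals_genes(self, rng):
        norm = self._lognorm(rng.poisson(3.0, size=(30, 25)) + 1)
        got = select_hvgs(norm, 25)
        assert sorted(got) == sorted(norm.gene_ids)

    def test_over_request_warns_and_returns_all(self, rng):
        norm = self._lognorm(rng.poisson(3.0, size=(30, 10)) + 1)
        with pytest.warns(UserWarning, match="returning all"):
            got = select_hvgs(norm, 50)
        assert len(got) == 10

    def test_tie_break_lexicographic(self):
        x = np.ones((10, 4), dtype=int)  # all genes identical -> all tied
        norm = self._lognorm(x)
        assert select_hvgs(norm, 2) == ["g0", "g1"]

    def test_planted_signature_ranks_high_at_fold4(self):
        """Signature genes are strongly shifted toward the top of the HVG
        ranking, and the selected half of the genome captures nearly all."""
        import scipy.stats

        cfg = synth.SimulationConfig(n_cells=500, n_genes=500, n_celltypes=1,
                                     lactylation_set_size=25, seed=2)
        cm, truth = synth.simulate_sc_counts(cfg)
        norm = lognormalize(cm)
        ranked = select_hvgs(norm, norm.n_genes)
        pos = np.array([ranked.index(g) for g in sorted(truth.signature_genes)])
        rest = np.setdiff1d(np.arange(norm.n_genes), pos)
        p = scipy.stats.mannwhitneyu(pos, rest, alternative="less").pvalue
        assert p < 1e-6
        assert np.mean(pos < norm.n_genes // 2) >= 0.9


class TestPca:
    def test_rank_one_matrix_pc1_dominates(self, rng):
        u = rng.normal(size=50)
        v = rng.normal(size=20)
        x = np.outer(u, v)
        x = (x - x.min() + 0.1) * 10
        cm = _counts(np.round(x).astype(int))
        emb = run_pca(lognormalize(cm), n_pcs=5)
        var = emb.var(axis=0)
        assert var.iloc[0] / var.sum() > 0.9

    def test_reproducible(self, rng):
        x = rng.poisson(4.0, size=(40, 15)) + 1
        norm = lognormalize(_counts(x))
        a = run_pca(norm, n_pcs=5)
        b = run_pca(norm, n_pcs=5)
        pd.testing.assert_frame_equal(a, b)

    def test_agrees_with_reference_svd(self, rng):
        """10x6 toy: embedding matches a directly computed SVD to 1e-8."""
        x = rng.poisson(4.0, size=(10, 6)) + 1
        norm = lognormalize(_counts(x))
        emb = run_pca(norm, n_pcs=3).to_numpy()

        z = norm.dense()
        z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) == 0, 1, z.std(axis=0))
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        ref = u[:, :3] * s[:3]
        for j in range(3):  # sign convention may differ from raw SVD
            col = ref[:, j]
            if np.abs(col - emb[:, j]).max() > np.abs(col + emb[:, j]).max():
                col = -col
            np.testing.assert_allclose(emb[:, j], col, atol=1e-8)


class TestClustering:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 0.3, size=(60, 5))
        b = rng.normal(8, 0.3, size=(60, 5))
        emb = pd.DataFrame(np.vstack([a, b]),
                           index=[f"c{i}" for i in range(120)])
        labels = cluster_cells(emb, resolution=0.8, seed=0)
        assert labels.nunique() == 2
        assert labels.iloc[:60].nunique() == 1
        assert labels.iloc[60:].nunique() == 1

    def test_too_few_cells_fatal(self, rng):
        emb = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="too few"):
            cluster_cells(emb, n_neighbors=15)

    def test_planted_celltypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = synth.SimulationConfig(n_cells=800, n_genes=600, n_celltypes=4,
                                     lactylation_fold=1.0, seed=4)
        cm, truth = synth.simulate_sc_counts(cfg)
        norm = lognormalize(cm)
        hvgs = select_hvgs(norm, 300)
        emb = run_pca(norm, hvgs, n_pcs=20)
        labels = cluster_cells(emb, resolution=0.8, seed=0)
        planted = [truth.celltype_assignments[c] for c in labels.index]
        assert adjusted_rand_score(planted, labels.tolist()) >= 0.9


class TestFindMarkers:
    def test_identical_groups_empty_table(self, rng):
        x = rng.poisson(3.0, size=(20, 10)) + 1
        x[10:] = x[:10]
        norm = lognormalize(_counts(x))
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=norm.cell_ids)
        out = find_markers(norm, groups)
        assert out.empty

    def test_planted_marker_detected(self, rng):
        x = rng.poisson(2.0, size=(100, 20)) + 1
        x[:50, 7] *= 8  # gene g7 up 8-fold in group a
        norm = lognormalize(_counts(x))
        groups = pd.Series(["a"] * 50 + ["b"] * 50, index=norm.cell_ids)
        out = find_markers(norm, groups)
        hit = out[(out["group"] == "a") & (out["gene"] == "g7")]
        assert len(hit) == 1

    def test_group_label_permutation_stable(self, rng):
        x = rng.poisson(2.0, size=(60, 15)) + 1
        x[:30, 3] *= 6
        norm = lognormalize(_counts(x))
        g1 = pd.Series(["a"] * 30 + ["b"] * 30, index=norm.cell_ids)
        g2 = pd.Series(["z"] * 30 + ["y"] * 30, index=norm.cell_ids)
        a = find_markers(norm, g1)
        b = find_markers(norm, g2)
        assert set(zip(a["gene"], a["group"].map({"a": 1, "b": 2}))) == set(
            zip(b["gene"], b["group"].map({"z": 1, "y": 2}))
        )

    def test_wilcoxon_p_matches_enumeration_6v6(self, rng):
        """p for a 6-vs-6 comparison equals exhaustive enumeration over all
        C(12,6) rank assignments."""
        import scipy.stats

        vals = rng.normal(size=12)
        x = np.zeros((12, 2))
        x[:, 0] = np.abs(vals) + 0.1
        x[:, 1] = 1.0
        norm = CountMatrix(
            values=sp.csr_matrix(x),
            cell_ids=[f"c{i}" for i in range(12)],
            gene_ids=["g0", "g1"],
            layer_tag="lognorm",
        )
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=norm.cell_ids)
        # oracle
        ranks = scipy.stats.rankdata(x[:, 0])
        obs = ranks[:6].sum()
        sums = np.array([sum(c) for c in combinations(ranks, 6)])
        center = sums.mean()
        p_exact = np.mean(np.abs(sums - center) >= abs(obs - center) - 1e-12)
        # markers table reports only passing genes; recompute via the helper
        from lactoscore.qc import rank_sum_test

        p_impl = rank_sum_test(x[:6, 0], x[6:, 0])
        assert p_impl == pytest.approx(p_exact, abs=1e-12)


def test_hvg_pca_param_validation():
    with pytest.raises(ValueError):
        HvgPcaParams(n_hvgs=10, n_pcs=20)
    with pytest.raises(ValueError):
        QCThresholds(min_genes_per_cell=100, max_genes_per_cell=50)
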