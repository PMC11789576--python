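"""Normalization, HVGs, profiles, module scores, markers, biotype counts."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

import snpipe


def _cm(counts, barcodes=None, genes=None):
    counts = np.asarray(counts)
    barcodes = barcodes or [f"c{i}" for i in range(counts.shape[0])]
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    return snpipe.CountMatrix(sp.csr_matrix(counts), barcodes, genes)


class TestNormalizeLog:
    def test_depth_invariance(self):
        cm = _cm([[1, 2, 3], [2, 4, 6]])
        norm = snpipe.normalize_log(cm).to_dense()
        np.testing.assert_allclose(norm[0], norm[1])

    def test_unit_count_arithmetic(self):
        # one count out of a 1e4-total cell at scale 1e4 -> log(2)
        row = np.zeros(10000, dtype=int)
        row[:10000] = 1
        cm = _cm(row[None, :])
        norm = snpipe.normalize_log(cm, scale=1e4).to_dense()
        np.testing.assert_allclose(norm[0, 0], np.log(2))

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            snpipe.normalize_log(_cm([[1, 1], [0, 0]]))

    def test_zeros_stay_zero(self):
        cm = _cm([[0, 5], [3, 0]])
        norm = snpipe.normalize_log(cm).to_dense()
        assert norm[0, 0] == 0 and norm[1, 1] == 0


class TestSelectHvg:
    def test_constant_matrix_tie_broken_lexicographically(self):
        cm = _cm(np.ones((5, 4)), genes=["gd", "gb", "gc", "ga"])
        assert snpipe.select_hvg(cm, n=2) == ["ga", "gb"]

    def test_planted_variance_dominates(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(1.0, size=(60, 50))
        counts[:30, 7] += 20  # strong two-group split on one gene
        cm = _cm(counts)
        assert "g7" in snpipe.select_hvg(snpipe.normalize_log(cm), n=5)

    def test_n_equal_gene_count_is_identity_set(self):
        cm = _cm(np.arange(20).reshape(4, 5))
        assert set(snpipe.select_hvg(cm, n=5)) == set(cm.genes)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            snpipe.select_hvg(_cm(np.ones((2, 3))), n=10)


class TestClusterProfile:
    def test_hand_computed_means(self):
        cm = _cm([[2, 0], [4, 0], [0, 6], [0, 2]])
        labels = pd.Series(["a", "a", "b", "b"], index=cm.barcodes)
        prof = snpipe.cluster_profile(cm, labels)
        np.testing.assert_allclose(prof.values, [[3, 0], [0, 4]])
        assert prof.clusters == ["a", "b"]

    def test_invariant_to_cell_permutation(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2, size=(12, 6))
        cm = _cm(counts)
        labels = pd.Series(rng.choice(["x", "y", "z"], 12), index=cm.barcodes)
        perm = rng.permutation(12)
        cm2 = cm.subset(barcode_mask=perm)
        p1 = snpipe.cluster_profile(cm, labels)
        p2 = snpipe.cluster_profile(cm2, labels)
        np.testing.assert_allclose(p1.values, p2.values)

    def test_unlabeled_cell_rejected(self):
        cm = _cm(np.ones((3, 2)))
        labels = pd.Series(["a", "b"], index=["c0", "c1"])
        with pytest.raises(ValueError, match="label"):
            snpipe.cluster_profile(cm, labels)


class TestModuleScore:
    def test_identical_genes_score_zero(self):
        cm = _cm(np.full((20, 200), 3.0))
        scores = snpipe.module_score(cm, ["g1", "g5", "g10"], seed=0)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        cm = _cm(rng.poisson(2, (30, 300)))
        a = snpipe.module_score(cm, ["g3", "g4"], seed=5)
        b = snpipe.module_score(cm, ["g3", "g4"], seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_null_sets_centred_at_zero_across_seeds(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(2.0, 0.5, size=(100, 400))
        cm = _cm(values)
        means = []
        for seed in range(100):
            gene_set = [f"g{i}" for i in np.random.default_rng(seed).choice(400, 25, replace=False)]
            means.append(snpipe.module_score(cm, gene_set, seed=seed).mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-3

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersection"):
            snpipe.module_score(_cm(np.ones((5, 5))), ["nope"], seed=0)


class TestFindMarkers:
    def test_exclusive_gene_retained_with_pcts(self):
        counts = np.zeros((12, 3))
        counts[:, 0] = 1.0  # uniform gene -> filtered by logfc
        counts[:6, 1] = 5.0  # exclusive to cluster a
        cm = _cm(counts)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=cm.barcodes)
        table = snpipe.find_markers(cm, labels)
        row = table[(table.gene == "g1") & (table.cluster == "a")].iloc[0]
        assert row.pct_in == 1.0 and row.pct_out == 0.0
        assert "g0" not in set(table.gene)

    def test_small_n_pvalue_matches_permutation_enumeration(self):
        x = np.array([1.2, 3.4, 2.2, 5.1])
        y = np.array([0.3, 0.9, 1.5, 0.1])
        counts = np.zeros((8, 2))
        counts[:, 0] = np.concatenate([x, y])
        counts[:, 1] = 1.0
        cm = _cm(counts)
        labels = pd.Series(["in"] * 4 + ["out"] * 4, index=cm.barcodes)
        table = snpipe.find_markers(cm, labels, min_pct=0, logfc_min=0)
        got = table[(table.gene == "g0") & (table.cluster == "in")].iloc[0].pval

        ranks = scipy.stats.rankdata(np.concatenate([x, y]))
        obs = ranks[:4].sum()
        hits = sum(
            ranks[list(comb)].sum() >= obs for comb in itertools.combinations(range(8), 4)
        )
        assert got == pytest.approx(hits / 70)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(6)
        cm = _cm(rng.poisson(3, (40, 30)))
        labels = pd.Series(rng.choice(["a", "b"], 40), index=cm.barcodes)
        table = snpipe.find_markers(cm, labels, min_pct=0, logfc_min=-10, only_pos=False)
        assert (table.padj >= table.pval - 1e-15).all()

    def test_permuted_labels_yield_few_discoveries(self):
        rng = np.random.default_rng(7)
        cm = _cm(rng.poisson(3, (80, 100)))
        labels = pd.Series(rng.permutation(["a"] * 40 + ["b"] * 40), index=cm.barcodes)
        table = snpipe.find_markers(cm, labels, min_pct=0, logfc_min=0)
        assert (table.padj < 0.05).mean() < 0.1


class TestBiotypeCounts:
    def test_detected_definition_and_truth(self):
        cfg = snpipe.SimConfig(seed=10, cells_per_cluster=10, n_planted_pairs=5)
        cm, _ = snpipe.simulate_count_matrix(cfg)
        counts = snpipe.biotype_counts(cm, cm.var)
        detected = np.asarray((cm.matrix > 0).sum(axis=0)).ravel() > 0
        expect = cm.var.loc[np.array(cm.genes)[detected], "biotype"].value_counts()
        for bt in snpipe.BIOTYPES:
            assert counts[bt] == expect.get(bt, 0)

    def test_empty_matrix_all_zero(self):
        cm = _cm(np.zeros((3, 4)))
        ann = pd.DataFrame({"biotype": ["lncRNA"] * 4}, index=cm.genes)
        assert (snpipe.biotype_counts(cm, ann) == 0).all()

    def test_silent_genes_not_counted(self):
        counts = np.zeros((2, 4))
        counts[0, :2] = 1
        cm = _cm(counts)
        ann = pd.DataFrame({"biotype": ["lncRNA"] * 4}, index=cm.genes)
        assert snpipe.biotype_counts(cm, ann)["lncRNA"] == 2
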