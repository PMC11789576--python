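"""The six-step lncRNA-mRNA pairing procedure."""

import numpy as np
import pandas as pd
import pytest

import snpipe
from snpipe.expression import ClusterProfile
from snpipe.lncpairs import build_pair_cluster_matrix


def _profile(values, genes=None, clusters=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    clusters = clusters if clusters is not None else list(range(values.shape[1]))
    return ClusterProfile(genes, clusters, values)


class TestSplitProfile:
    def test_partition_by_biotype_drops_other(self):
        prof = _profile(np.ones((6, 3)), genes=[f"g{i}" for i in range(6)])
        ann = pd.DataFrame(
            {"biotype": ["protein_coding"] * 3 + ["lncRNA"] * 2 + ["snoRNA"]},
            index=prof.genes,
        )
        mrna, lnc = snpipe.split_profile(prof, ann)
        assert len(mrna.genes) == 3 and len(lnc.genes) == 2
        assert set(mrna.genes) | set(lnc.genes) == set(prof.genes) - {"g5"}

    def test_no_lncrna_is_an_error(self):
        prof = _profile(np.ones((2, 3)))
        ann = pd.DataFrame({"biotype": ["protein_coding"] * 2}, index=prof.genes)
        with pytest.raises(ValueError, match="partition empty"):
            snpipe.split_profile(prof, ann)


class TestCorrelatePairs:
    def test_identical_profiles_retained_anticorrelated_excluded(self):
        lnc = _profile([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]], genes=["l_up", "l_down"])
        mrna = _profile([[2.0, 4.0, 6.0, 8.0]], genes=["m_up"])
        out = snpipe.correlate_pairs(lnc, mrna, pcc_min=0.85)
        assert set(zip(out.lnc_id, out.mrna_id)) == {("l_up", "m_up")}
        assert out.pcc.iloc[0] == pytest.approx(1.0)

    def test_matches_independent_correlation_oracle(self):
        rng = np.random.default_rng(8)
        lnc = _profile(rng.normal(size=(10, 6)))
        mrna = _profile(rng.normal(size=(15, 6)), genes=[f"m{i}" for i in range(15)])
        out = snpipe.correlate_pairs(lnc, mrna, pcc_min=-1.1)  # keep everything
        byhand = {
            (l, m): np.corrcoef(lnc.values[i], mrna.values[j])[0, 1]
            for i, l in enumerate(lnc.genes)
            for j, m in enumerate(mrna.genes)
        }
        for row in out.itertuples():
            assert row.pcc == pytest.approx(byhand[(row.lnc_id, row.mrna_id)], abs=1e-12)

    def test_strict_inequality_at_threshold(self):
        lnc = _profile([[1.0, 2.0, 3.0]])
        mrna = _profile([[1.0, 2.0, 3.0]], genes=["m0"])
        assert snpipe.correlate_pairs(lnc, mrna, pcc_min=1.0).empty

    def test_fewer_than_three_clusters_rejected(self):
        with pytest.raises(ValueError, match="3 clusters"):
            snpipe.correlate_pairs(_profile(np.ones((1, 2))), _profile(np.ones((1, 2))))

    def test_zero_variance_rows_skipped(self):
        lnc = _profile([[5.0, 5.0, 5.0]])
        mrna = _profile([[1.0, 2.0, 3.0]], genes=["m0"])
        assert snpipe.correlate_pairs(lnc, mrna, pcc_min=0.0).empty


class TestPairClusterMatrix:
    def test_joint_one_hot_pair(self):
        lnc = _profile([[0.0, 3.0, 0.0, 0.0]], genes=["l0"])
        mrna = _profile([[0.1, 7.0, 0.1, 0.1]], genes=["m0"])
        pairs = pd.DataFrame({"lnc_id": ["l0"], "mrna_id": ["m0"], "pcc": [0.99]})
        pcm = build_pair_cluster_matrix(pairs, lnc, mrna)
        np.testing.assert_allclose(pcm.activity, [[0, 1, 0, 0]])

    def test_disjoint_one_hots_give_zero_activity(self):
        lnc = _profile([[0.0, 1.0, 0.0, 0.0]], genes=["l0"])
        mrna = _profile([[0.0, 0.0, 1.0, 0.0]], genes=["m0"])
        pairs = pd.DataFrame({"lnc_id": ["l0"], "mrna_id": ["m0"], "pcc": [0.9]})
        pcm = build_pair_cluster_matrix(pairs, lnc, mrna)
        np.testing.assert_allclose(pcm.activity, 0.0)

    def test_activity_bounded_in_unit_interval(self):
        rng = np.random.default_rng(9)
        lnc = _profile(rng.normal(size=(5, 6)))
        mrna = _profile(rng.normal(size=(5, 6)), genes=[f"m{i}" for i in range(5)])
        pairs = pd.DataFrame(
            {"lnc_id": [f"g{i}" for i in range(5)], "mrna_id": [f"m{i}" for i in range(5)], "pcc": 1.0}
        )
        for rule in ("min", "product"):
            pcm = build_pair_cluster_matrix(pairs, lnc, mrna, rule=rule)
            assert (pcm.activity >= 0).all() and (pcm.activity <= 1).all()

    def test_constant_row_pair_dropped(self):
        lnc = _profile([[2.0, 2.0, 2.0]], genes=["l0"])
        mrna = _profile([[0.0, 1.0, 0.0]], genes=["m0"])
        pairs = pd.DataFrame({"lnc_id": ["l0"], "mrna_id": ["m0"], "pcc": [0.9]})
        assert len(build_pair_cluster_matrix(pairs, lnc, mrna).pairs) == 0


class TestAssignSpecificPairs:
    def _pcm(self, activity):
        activity = np.asarray(activity, dtype=float)
        n = activity.shape[0]
        pairs = pd.DataFrame(
            {"lnc_id": [f"l{i}" for i in range(n)], "mrna_id": [f"m{i}" for i in range(n)], "pcc": 0.9}
        )
        from snpipe.lncpairs import PairClusterMatrix

        return PairClusterMatrix(pairs, list(range(activity.shape[1])), activity)

    def test_one_hot_scores_unity(self):
        out = snpipe.assign_specific_pairs(self._pcm([[0, 0, 1, 0]]))
        assert out.cosine.iloc[0] == pytest.approx(1.0)
        assert out.assigned_cluster.iloc[0] == 2

    def test_uniform_over_four_clusters_eliminated_at_half(self):
        # cos(uniform, one-hot) = 1/sqrt(4) = 0.5 exactly
        pcm = self._pcm([[1, 1, 1, 1]])
        kept = snpipe.assign_specific_pairs(pcm, cos_min=0.95)
        assert kept.empty
        kept_low = snpipe.assign_specific_pairs(pcm, cos_min=0.5)
        assert kept_low.cosine.iloc[0] == pytest.approx(0.5)

    def test_near_one_hot_closed_form(self):
        out = snpipe.assign_specific_pairs(self._pcm([[1.0, 0.1, 0.0, 0.0]]), cos_min=0.95)
        assert out.cosine.iloc[0] == pytest.approx(1 / np.sqrt(1.01))
        assert out.assigned_cluster.iloc[0] == 0

    def test_all_zero_rows_eliminated(self):
        assert snpipe.assign_specific_pairs(self._pcm([[0, 0, 0]])).empty


class TestCountPairsByCelltype:
    def _pairs(self):
        return pd.DataFrame(
            {
                "lnc_id": ["l1", "l2", "l3"],
                "mrna_id": ["m1", "m2", "m3"],
                "pcc": [0.9, 0.95, 0.99],
                "assigned_cluster": [0, 1, 7],
                "cosine": [0.96, 0.97, 0.98],
            }
        )

    def test_aggregation(self):
        counts, top = snpipe.count_pairs_by_celltype(self._pairs(), {0: "T", 1: "T", 7: "B"})
        assert counts["T"] == 2 and counts["B"] == 1
        assert len(top) == 3

    def test_empty_input_empty_table(self):
        counts, _ = snpipe.count_pairs_by_celltype(pd.DataFrame(columns=["assigned_cluster", "cosine"]), {})
        assert counts.empty

    def test_unmapped_cluster_goes_to_unassigned(self):
        counts, _ = snpipe.count_pairs_by_celltype(self._pairs(), {0: "T"})
        assert counts["unassigned"] == 2


@pytest.fixture(scope="module")
def planted():
    cfg = snpipe.SimConfig(
        seed=15, cells_per_cluster=40, n_planted_pairs=10,
        n_genes={"protein_coding": 300, "lncRNA": 100},
    )
    return snpipe.simulate_count_matrix(cfg)


class TestEndToEndProperties:
    def test_threshold_monotonicity(self, planted):
        cm, truth = planted
        sizes = [
            len(snpipe.find_lnc_pairs(cm, truth.labels, cm.var, n_hvg=400, pcc_min=p, cos_min=c))
            for p, c in [(0.9, 0.97), (0.85, 0.95), (0.7, 0.9), (0.5, 0.8)]
        ]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_invariant_to_cluster_relabeling(self, planted):
        cm, truth = planted
        out1 = snpipe.find_lnc_pairs(cm, truth.labels, cm.var, n_hvg=400)
        relabel = {c: f"z{9 - c}" for c in truth.labels.unique()}  # reverses sort order
        out2 = snpipe.find_lnc_pairs(cm, truth.labels.map(relabel), cm.var, n_hvg=400)
        key = lambda df: set(zip(df.lnc_id, df.mrna_id))
        assert key(out1) == key(out2)
        merged = out1.merge(out2, on=["lnc_id", "mrna_id"])
        assert (merged.assigned_cluster_y == merged.assigned_cluster_x.map(relabel)).all()
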