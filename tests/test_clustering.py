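"""Distances, Ward.D2 clustering and cluster-validation indices."""

import numpy as np
import pandas as pd
import pytest

from traceviz.clustering import (
    calinski_harabasz,
    cvi_scan,
    dtw_distance,
    dtw_distance_matrix,
    dunn_index,
    euclidean_distance_matrix,
    hierarchical_cluster,
    render_cluster_facets,
    silhouette_index,
    trace_matrix,
    ward_linkage_heights,
)
from traceviz.dataio import TraceSet
from traceviz.normalize import NormalizationSpec, apply_normalization
from traceviz.simulate import FixtureSpec, generate_clustered_traces


def ts_from_rows(rows_by_object, times=None):
    rows = []
    for obj, vals in rows_by_object.items():
        tt = times if times is not None else range(len(vals))
        for t, v in zip(tt, vals):
            rows.append((float(t), float(v), obj, "1"))
    return TraceSet(pd.DataFrame(rows, columns=["time", "value", "object_id", "condition_id"]))


class TestTraceMatrix:
    def test_shared_grid(self):
        ts = ts_from_rows({"a": [1, 2, 3, 4], "b": [5, 6, 7, 8], "c": [9, 8, 7, 6]})
        M, ids, times = trace_matrix(ts)
        assert M.shape == (3, 4)
        assert ids == ["a", "b", "c"]
        assert times.tolist() == [0.0, 1.0, 2.0, 3.0]

    def test_incomplete_time_dropped_with_warning(self):
        ts = ts_from_rows({"a": [1, 2, 3], "b": [4, 5, 6]})
        df = ts.data.copy()
        df.loc[(df["object_id"] == "a") & (df["time"] == 1.0), "value"] = np.nan
        with pytest.warns(UserWarning, match="dropping 1"):
            M, _, times = trace_matrix(TraceSet(df))
        assert M.shape == (2, 2)
        assert times.tolist() == [0.0, 2.0]

    def test_no_common_times_rejected(self):
        rows = [(0.0, 1.0, "a", "1"), (1.0, 2.0, "b", "1")]
        ts = TraceSet(pd.DataFrame(rows, columns=["time", "value", "object_id", "condition_id"]))
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="common"):
            trace_matrix(ts)

    def test_single_object(self):
        M, ids, _ = trace_matrix(ts_from_rows({"a": [1, 2, 3]}))
        assert M.shape == (1, 3) and ids == ["a"]

    def test_cross_condition_id_collision_prefixed(self):
        rows = [(t, 1.0, "a", c) for c in ("x", "y") for t in (0.0, 1.0)]
        ts = TraceSet(pd.DataFrame(rows, columns=["time", "value", "object_id", "condition_id"]))
        _, ids, _ = trace_matrix(ts)
        assert ids == ["x:a", "y:a"]


class TestEuclideanDistance:
    def test_identical_rows_zero(self):
        D = euclidean_distance_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert D[0, 1] == 0

    def test_3_4_5(self):
        D = euclidean_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        M = rng.normal(size=(5, 10))
        D = euclidean_distance_matrix(M)
        brute = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                brute[i, j] = np.sqrt(((M[i] - M[j]) ** 2).sum())
        assert np.allclose(D, brute)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance_matrix(np.array([[np.nan, 0.0], [1.0, 2.0]]))


def dtw_oracle(a, b):
    """Plain-python DP table, written independently of the implementation."""
    n, m = len(a), len(b)
    import math

    D = [[math.inf] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            D[i][j] = c + min(D[i - 1][j], D[i][j - 1], D[i - 1][j - 1])
    return D[n][m]


class TestDTW:
    def test_identical_series_zero(self):
        assert dtw_distance([1, 2, 3], [1, 2, 3]) == 0

    def test_constant_offset(self):
        assert dtw_distance([0, 0, 0], [1, 1, 1]) == 3

    def test_warping_absorbs_repeat(self):
        assert dtw_distance([0, 1, 0], [0, 1, 1, 0]) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 12)).tolist()
        b = rng.normal(size=rng.integers(2, 12)).tolist()
        assert dtw_distance(a, b) == pytest.approx(dtw_oracle(a, b))

    def test_symmetric_and_bounded_by_euclidean_alignment(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))
        # the diagonal path is one admissible alignment
        assert dtw_distance(a, b) <= np.abs(a - b).sum() + 1e-12

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(4, 6))
        D = dtw_distance_matrix(M)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)


class TestHierarchicalCluster:
    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        pts = np.concatenate([rng.normal(0, 0.1, 5), rng.normal(10, 0.1, 5)])[:, None]
        labels = hierarchical_cluster(euclidean_distance_matrix(pts), 2)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_equals_m_minus_one_merges_one_pair(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        labels = hierarchical_cluster(euclidean_distance_matrix(pts), 5)
        counts = np.bincount(labels)[1:]
        assert sorted(counts) == [1, 1, 1, 1, 2]

    def test_duplicate_points_co_clustered(self):
        pts = np.array([[0.0], [0.0], [5.0], [9.0]])
        labels = hierarchical_cluster(euclidean_distance_matrix(pts), 3)
        assert labels[0] == labels[1]

    def test_k_out_of_range(self):
        D = euclidean_distance_matrix(np.arange(4.0)[:, None])
        for bad in (1, 4):
            with pytest.raises(ValueError):
                hierarchical_cluster(D, bad)

    def test_labels_contiguous_from_one(self):
        rng = np.random.default_rng(3)
        D = euclidean_distance_matrix(rng.normal(size=(8, 3)))
        labels = hierarchical_cluster(D, 3)
        assert sorted(set(labels)) == [1, 2, 3]

    def test_matches_sklearn_ward_partition(self):
        from sklearn.cluster import AgglomerativeClustering

        rng = np.random.default_rng(4)
        M = rng.normal(size=(12, 5))
        ours = hierarchical_cluster(euclidean_distance_matrix(M), 3)
        theirs = AgglomerativeClustering(n_clusters=3, linkage="ward").fit_predict(M)
        # same partition up to label names
        pairs = {(a, b) for a, b in zip(ours, theirs)}
        assert len(pairs) == 3

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(5)
        h = ward_linkage_heights(euclidean_distance_matrix(rng.normal(size=(10, 4))))
        assert np.all(np.diff(h) >= -1e-12)


class TestCalinskiHarabasz:
    def test_hand_computed_example(self):
        """1-D {0,1,10,11} split {1,1,2,2}: B=100, W=1, CH=(100/1)/(1/2)=200."""
        M = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert calinski_harabasz(M, [1, 1, 2, 2]) == pytest.approx(200.0)

    def test_tight_clusters_infinite(self):
        M = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert calinski_harabasz(M, [1, 1, 2, 2]) == np.inf

    def test_all_identical_zero(self):
        M = np.zeros((4, 2))
        assert calinski_harabasz(M, [1, 1, 2, 2]) == 0.0

    def test_matches_sklearn(self):
        from sklearn.metrics import calinski_harabasz_score

        rng = np.random.default_rng(6)
        M = rng.normal(size=(20, 4))
        labels = rng.integers(1, 4, size=20)
        if len(set(labels)) < 2:
            labels[0] = 1
            labels[1] = 2
        assert calinski_harabasz(M, labels) == pytest.approx(
            calinski_harabasz_score(M, labels)
        )

    def test_degenerate_k_rejected(self):
        M = np.arange(8.0).reshape(4, 2)
        with pytest.raises(ValueError):
            calinski_harabasz(M, [1, 1, 1, 1])
        with pytest.raises(ValueError):
            calinski_harabasz(M, [1, 2, 3, 4])


class TestOtherIndices:
    def test_silhouette_matches_sklearn(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(7)
        M = rng.normal(size=(15, 3))
        labels = np.array([1] * 5 + [2] * 5 + [3] * 5)
        D = euclidean_distance_matrix(M)
        assert silhouette_index(D, labels) == pytest.approx(
            silhouette_score(M, labels), abs=1e-12
        )

    def test_dunn_well_separated_exceeds_one(self):
        # two tight groups far apart: min separation >> max diameter
        M = np.array([[0.0], [0.2], [10.0], [10.2]])
        D = euclidean_distance_matrix(M)
        assert dunn_index(D, [1, 1, 2, 2]) == pytest.approx(9.8 / 0.2)

    def test_dunn_zero_diameter_infinite(self):
        M = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert dunn_index(euclidean_distance_matrix(M), [1, 1, 2, 2]) == np.inf


class TestCviScan:
    def shape_normalized(self, ts):
        return apply_normalization(ts, NormalizationSpec("minmax"))

    def test_recovers_three_groups(self):
        ts, _ = generate_clustered_traces(3, 1.0, FixtureSpec(seed=123))
        M, ids, _ = trace_matrix(self.shape_normalized(ts))
        res = cvi_scan(M, k_range=range(2, 7), object_ids=ids)
        assert res.best_k["calinski_harabasz"] == 3
        assert res.k == 3
        assert set(res.assignments) == set(ids)

    def test_table_consistent_with_direct_call(self):
        ts, _ = generate_clustered_traces(3, 1.0, FixtureSpec(seed=5, n_objects=5))
        M, ids, _ = trace_matrix(self.shape_normalized(ts))
        res = cvi_scan(M, k_range=[2, 3, 4], object_ids=ids)
        D = euclidean_distance_matrix(M)
        for k in (2, 3, 4):
            labels = hierarchical_cluster(D, k)
            expect = calinski_harabasz(M, labels)
            got = res.cvi_table.query("index == 'calinski_harabasz' and k == @k")["value"].iloc[0]
            assert got == pytest.approx(expect)

    def test_three_objects_only_k2(self):
        rng = np.random.default_rng(8)
        M = rng.normal(size=(3, 4))
        res = cvi_scan(M, k_range=[2])
        assert res.k == 2
        with pytest.raises(ValueError):
            cvi_scan(M, k_range=[3])

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cvi_scan(np.zeros((5, 3)), k_range=[])

    def test_all_indices_higher_is_better_orientation(self):
        """All three CVIs peak at the true k on a well-separated fixture."""
        ts, _ = generate_clustered_traces(3, 1.0, FixtureSpec(seed=77))
        M, ids, _ = trace_matrix(self.shape_normalized(ts))
        res = cvi_scan(M, k_range=range(2, 7), object_ids=ids)
        assert res.best_k["silhouette"] == 3
        assert res.best_k["dunn"] == 3

    def test_dtw_distance_option(self):
        ts, _ = generate_clustered_traces(2, 1.0, FixtureSpec(seed=3, n_objects=4))
        M, ids, _ = trace_matrix(self.shape_normalized(ts))
        res = cvi_scan(M, distance="dtw", k_range=[2, 3], object_ids=ids)
        assert res.distance == "dtw"
        assert len(res.assignments) == len(ids)


class TestClusterFacets:
    def test_one_panel_per_cluster_all_traces_drawn(self):
        ts, _ = generate_clustered_traces(3, 1.0, FixtureSpec(seed=21, n_objects=4))
        norm = apply_normalization(ts, NormalizationSpec("minmax"))
        M, ids, _ = trace_matrix(norm)
        res = cvi_scan(M, k_range=range(2, 6), object_ids=ids)
        fig = render_cluster_facets(norm, res)
        panels = [ax for ax in fig.axes if ax.get_title().startswith("Cluster")]
        assert len(panels) == res.k
        total = sum(len([l for l in ax.lines if l.get_gid() == "trace"]) for ax in panels)
        assert total == len(ids)
        sizes = [int(ax.get_title().split("n=")[1].rstrip(")")) for ax in panels]
        assert sum(sizes) == len(ids)

    def test_unassigned_object_rejected(self):
        ts, _ = generate_clustered_traces(2, 1.0, FixtureSpec(seed=1, n_objects=3))
        M, ids, _ = trace_matrix(ts)
        res = cvi_scan(M, k_range=[2], object_ids=ids)
        del res.assignments[ids[0]]
        with pytest.raises(ValueError, match="assignment"):
            render_cluster_facets(ts, res)
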