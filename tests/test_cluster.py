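"""Agglomerative clustering, PCoA ordination and extreme-cow selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from rumiclust.cluster import (AgnesClustering, PCoA, SelectionShortfallError,
                               agglomerative_cluster, agglomerative_coefficient,
                               cut_tree, pcoa, select_extremes)
from rumiclust.dtw import DistanceMatrix, pairwise_distances, preprocess_series
from rumiclust.simulate import SimConfig, simulate_herd

from conftest import noiseless_config


def _dm(values, labels=None):
    values = np.asarray(values, float)
    labels = labels or tuple(f"c{i}" for i in range(len(values)))
    return DistanceMatrix(tuple(labels), values)


def _two_pair_matrix(tight=1.0, far=10.0):
    d = np.full((4, 4), far)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = tight
    d[2, 3] = d[3, 2] = tight
    return _dm(d)


class TestAgglomerative:
    def test_two_points_single_merge(self):
        d = _dm([[0.0, 3.0], [3.0, 0.0]])
        tree = agglomerative_cluster(d)
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.merge_heights[0] == pytest.approx(3.0)

    def test_two_tight_pairs_merge_first(self):
        # hand-computed average linkage: (0,1)@1, (2,3)@1, then pairs @10
        tree = agglomerative_cluster(_two_pair_matrix())
        Z = tree.linkage_matrix
        assert {frozenset(Z[0, :2].astype(int)), frozenset(Z[1, :2].astype(int))} \
            == {frozenset({0, 1}), frozenset({2, 3})}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(1.0)
        assert Z[2, 2] == pytest.approx(10.0)  # average of the 4 cross distances

    def test_merge_heights_nondecreasing_average_linkage(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pts = rng.normal(size=(12, 3))
            d = _dm(squareform(pdist(pts)))
            heights = agglomerative_cluster(d, "average").merge_heights
            assert np.all(np.diff(heights) >= -1e-12)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            agglomerative_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            agglomerative_cluster(_dm([[0, 1], [1, 0]]), linkage="ward")

    def test_label_order_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2)) + np.repeat([[0, 0], [6, 6]], 5, axis=0)
        d = squareform(pdist(pts))
        labels = [f"c{i}" for i in range(10)]
        base = cut_tree(agglomerative_cluster(_dm(d, labels)), 2).labels
        perm = rng.permutation(10)
        d_p = d[np.ix_(perm, perm)]
        permuted = cut_tree(
            agglomerative_cluster(_dm(d_p, [labels[i] for i in perm])), 2).labels
        partition = lambda m: frozenset(
            frozenset(c for c, l in m.items() if l == lab) for lab in set(m.values()))
        assert partition(base) == partition(permuted)


class TestAgglomerativeCoefficient:
    def test_no_structure_when_all_distances_equal(self):
        d = np.full((5, 5), 4.0)
        np.fill_diagonal(d, 0.0)
        tree = agglomerative_cluster(_dm(d))
        assert agglomerative_coefficient(tree) == pytest.approx(0.0)

    def test_tight_far_pairs_close_to_one(self):
        # closed form: every leaf first merges at 1, final merge at 10
        tree = agglomerative_cluster(_two_pair_matrix(tight=1.0, far=10.0))
        assert agglomerative_coefficient(tree) == pytest.approx(1 - 1 / 10)

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pts = rng.normal(size=(8, 4))
            tree = agglomerative_cluster(_dm(squareform(pdist(pts))))
            assert 0.0 <= agglomerative_coefficient(tree) <= 1.0

    def test_requires_three_leaves(self):
        tree = agglomerative_cluster(_dm([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            agglomerative_coefficient(tree)


class TestCutTree:
    def test_k_equals_n_all_singletons(self):
        tree = agglomerative_cluster(_two_pair_matrix())
        a = cut_tree(tree, 4)
        assert sorted(a.labels.values()) == [1, 2, 3, 4]

    def test_k_one_single_cluster(self):
        tree = agglomerative_cluster(_two_pair_matrix())
        assert set(cut_tree(tree, 1).labels.values()) == {1}

    def test_k_out_of_range(self):
        tree = agglomerative_cluster(_two_pair_matrix())
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_tree(tree, k)

    def test_labels_ordered_by_size_then_smallest_member(self):
        d = np.full((5, 5), 10.0)
        np.fill_diagonal(d, 0.0)
        d[3, 4] = d[4, 3] = 1.0  # the only tight pair; cut at 4 clusters
        a = cut_tree(agglomerative_cluster(_dm(d)), 4)
        assert a.labels["c3"] == a.labels["c4"] == 1  # largest cluster first
        assert a.labels["c0"] == 2                    # then smallest member id

    def test_recovers_truth_on_noiseless_two_group_herd(self):
        dataset, truths = simulate_herd(noiseless_config(n_cows=10, seed=3))
        series = [preprocess_series(rows, cow_id=c)
                  for c, rows in dataset.sensor.groupby("cow_id")]
        d = pairwise_distances(series)
        a = cut_tree(agglomerative_cluster(d), 2)
        truth = [t.group_label for t in truths]
        pred = [a.labels[t.cow_id] for t in truths]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_ari_monotone_in_group_separation(self):
        # widen the RT/ET gap symmetrically; recovery only improves
        aris = []
        for scale in (0.05, 0.4, 1.0):
            base = SimConfig(n_cows=12, n_days=3, seed=17)
            mid_rt, mid_et = 1197.5, 785.0
            for g in base.groups:
                g.mean_hourly_rt = mid_rt + scale * (g.mean_hourly_rt - mid_rt)
                g.mean_hourly_et = mid_et + scale * (g.mean_hourly_et - mid_et)
            dataset, truths = simulate_herd(base)
            series = [preprocess_series(rows, cow_id=c)
                      for c, rows in dataset.sensor.groupby("cow_id")]
            a = cut_tree(agglomerative_cluster(pairwise_distances(series)), 2)
            truth = [t.group_label for t in truths]
            pred = [a.labels[t.cow_id] for t in truths]
            aris.append(adjusted_rand_score(truth, pred))
        assert aris[0] <= aris[1] <= aris[2]
        assert aris[2] == 1.0

    def test_estimator_interface(self):
        est = AgnesClustering(n_clusters=2)
        labels = est.fit_predict(_two_pair_matrix())
        assert sorted(labels) == [1, 1, 2, 2]
        assert est.agglomerative_coefficient_ == pytest.approx(0.9)
        assert est.get_params()["linkage"] == "average"


class TestPCoA:
    def test_planar_round_trip_to_1e8(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 2))
        d = squareform(pdist(pts))
        ord_ = pcoa(_dm(d))
        recon = squareform(pdist(ord_.coordinates))
        assert np.allclose(recon, d, atol=1e-8)

    def test_collinear_points_give_flat_axis2(self):
        x = np.linspace(0, 9, 10)[:, None]
        d = squareform(pdist(np.hstack([x, np.zeros_like(x)])))
        ord_ = pcoa(_dm(d))
        assert np.abs(ord_.coordinates[:, 1]).max() < 1e-8

    def test_coordinates_centered(self):
        rng = np.random.default_rng(5)
        d = squareform(pdist(rng.normal(size=(8, 3))))
        ord_ = pcoa(_dm(d))
        assert np.allclose(ord_.coordinates.mean(axis=0), 0.0, atol=1e-10)

    def test_eigenvalues_nonincreasing_and_proportions(self):
        rng = np.random.default_rng(6)
        d = squareform(pdist(rng.normal(size=(9, 4))))
        ord_ = pcoa(_dm(d))
        assert np.all(np.diff(ord_.eigenvalues) <= 1e-9)
        pos = ord_.proportion_explained[ord_.proportion_explained > 0]
        assert pos.sum() == pytest.approx(1.0)

    def test_matches_skbio_classical_scaling(self):
        # independent oracle: scikit-bio's PCoA on the same matrix
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(7)
        d = squareform(pdist(rng.normal(size=(10, 3))))
        ours = pcoa(_dm(d))
        ref = skbio_ordination.pcoa(d, method="eigh")
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1]
        assert np.allclose(ours.eigenvalues[:3], ref_eig[:3], atol=1e-8)
        for axis in range(2):
            ref_ax = ref.samples.iloc[:, axis].to_numpy()
            assert np.allclose(np.abs(ours.coordinates[:, axis]),
                               np.abs(ref_ax), atol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pcoa(_dm([[0.0, 1.0], [1.0, 0.0]]))

    def test_transformer_interface(self):
        rng = np.random.default_rng(8)
        d = squareform(pdist(rng.normal(size=(7, 2))))
        est = PCoA()
        coords = est.fit_transform(_dm(d))
        assert coords.shape == (7, 2)
        assert est.eigenvalues_[0] >= est.eigenvalues_[1]


class TestSelectExtremes:
    @staticmethod
    def _setup(n=10, meta=None):
        """n cows on a line: c0..c4 cluster 1 (ascending extremeness),
        c5..c9 cluster 2."""
        from rumiclust.cluster import ClusterAssignment, Ordination
        labels = tuple(f"c{i}" for i in range(n))
        axis1 = np.array([-(i + 1.0) for i in range(n // 2)]
                         + [(i + 1.0) for i in range(n // 2)])
        coords = np.column_stack([axis1 - axis1.mean(), np.zeros(n)])
        ordination = Ordination(labels, coords,
                                np.array([1.0] + [0.0] * (n - 1)),
                                np.array([1.0] + [0.0] * (n - 1)))
        assignment = ClusterAssignment(
            {l: (1 if i < n // 2 else 2) for i, l in enumerate(labels)}, 2, 0.5)
        if meta is None:
            meta = pd.DataFrame({"parity": 1, "dim": 50.0, "my": 30.0},
                                index=list(labels))
        return ordination, assignment, meta

    def test_identical_metadata_selects_most_extreme(self):
        ordination, assignment, meta = self._setup()
        res = select_extremes(ordination, assignment, meta, 2)
        assert res.selected[1][0] != res.selected[1][1]
        # extremeness after centering: c4 and c9 are the outermost cows
        assert res.selected[1] == ["c4", "c3"]
        assert res.selected[2] == ["c9", "c8"]

    def test_whole_cluster_when_n_equals_size(self):
        ordination, assignment, meta = self._setup()
        res = select_extremes(ordination, assignment, meta, 5)
        assert sorted(res.selected[1]) == [f"c{i}" for i in range(5)]
        assert res.shortfall == {1: 0, 2: 0}

    def test_shortfall_error_names_cluster(self):
        ordination, assignment, meta = self._setup()
        with pytest.raises(SelectionShortfallError, match="cluster"):
            select_extremes(ordination, assignment, meta, 6)
        res = select_extremes(ordination, assignment, meta, 6, strict=False)
        assert res.shortfall == {1: 1, 2: 1}

    def test_parity_matched_exactly_when_possible(self):
        ordination, assignment, meta = self._setup()
        meta = meta.copy()
        meta.loc["c4", "parity"] = 3
        meta.loc["c8", "parity"] = 3          # only parity-3 cow in cluster 2
        res = select_extremes(ordination, assignment, meta, 1)
        assert res.selected == {1: ["c4"], 2: ["c8"]}
        assert res.blocking_report["parity_match"].all()

    def test_blocking_minimizes_dim_my_distance(self):
        ordination, assignment, meta = self._setup()
        meta = meta.copy()
        meta["dim"] = [10, 20, 30, 40, 50, 90, 80, 70, 60, 49.0]
        res = select_extremes(ordination, assignment, meta, 1,
                              blocking=("dim", "my"))
        # most extreme cluster-1 cow is c4 (dim 50); best match is c9 (dim 49)
        assert res.selected == {1: ["c4"], 2: ["c9"]}

    def test_no_cow_selected_twice(self):
        ordination, assignment, meta = self._setup()
        res = select_extremes(ordination, assignment, meta, 5)
        picked = res.selected[1] + res.selected[2]
        assert len(picked) == len(set(picked)) == 10
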