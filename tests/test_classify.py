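"""Subject summaries, distance matrices, trees and the parallelepiped rule."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from sigquant.classify import (
    SubjectTree,
    distance_matrix,
    feature_summary,
    hierarchical_tree,
    neighbor_joining_tree,
    parallelepiped_fit,
    parallelepiped_predict,
    summarize_subjects,
)
from sigquant.quantifiers import FEATURE_COLUMNS, QuantifierVector


def qv(**kw):
    base = dict(h_x=0.2, h_y=0.2, c_x=0.1, c_y=0.1, f_x=0.4, f_y=0.4)
    base.update(kw)
    return QuantifierVector(**base)


class TestFeatureSummary:
    def test_identical_vectors_have_zero_sd(self):
        s = feature_summary("s1", [qv()] * 5)
        np.testing.assert_array_equal(s.sd, 0.0)

    def test_two_point_sd_closed_form(self):
        s = feature_summary("s1", [qv(h_x=0.2), qv(h_x=0.4)])
        assert s.sd[0] == pytest.approx(0.2 / math.sqrt(2))  # 0.1414...
        np.testing.assert_allclose(s.sd[1:], 0.0, atol=1e-15)

    def test_means_bounded_by_inputs(self, rng):
        vectors = [
            QuantifierVector(*rng.uniform(0, 1, size=6)) for _ in range(10)
        ]
        s = feature_summary("s1", vectors)
        arr = np.stack([v.as_array() for v in vectors])
        assert np.all(s.mean >= arr.min(axis=0)) and np.all(s.mean <= arr.max(axis=0))

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            feature_summary("s1", [qv()])


class TestDistanceMatrix:
    def _summaries(self, points):
        rows = {}
        for i, (mean_h, sd_h) in enumerate(points):
            rows[f"s{i}"] = {
                **{f"mean_{c}": mean_h for c in FEATURE_COLUMNS},
                **{f"sd_{c}": sd_h for c in FEATURE_COLUMNS},
            }
        return pd.DataFrame(rows).T

    def test_textbook_metrics(self):
        # entropy subset uses (mean, sd) of h_x and h_y: point (0,0) vs (3,4)
        # duplicated over both coordinates
        summ = pd.DataFrame(
            {
                "s0": {"mean_h_x": 0, "sd_h_x": 0, "mean_h_y": 0, "sd_h_y": 0},
                "s1": {"mean_h_x": 3, "sd_h_x": 4, "mean_h_y": 0, "sd_h_y": 0},
            }
        ).T
        for extra in FEATURE_COLUMNS[2:]:
            summ[f"mean_{extra}"] = 0.0
            summ[f"sd_{extra}"] = 0.0
        d_euc, _ = distance_matrix(summ, "entropy", "euclidean")
        d_man, _ = distance_matrix(summ, "entropy", "manhattan")
        d_che, _ = distance_matrix(summ, "entropy", "chebyshev")
        assert d_euc[0, 1] == pytest.approx(5.0)
        assert d_man[0, 1] == pytest.approx(7.0)
        assert d_che[0, 1] == pytest.approx(4.0)

    def test_symmetric_with_zero_diagonal(self, small_features):
        summ = summarize_subjects(small_features)
        dist, labels = distance_matrix(summ, "all")
        assert len(labels) == len(summ)
        np.testing.assert_array_equal(dist, dist.T)
        np.testing.assert_array_equal(np.diag(dist), 0.0)

    def test_unknown_subset_rejected(self, small_features):
        with pytest.raises(ValueError, match="unknown quantifier"):
            distance_matrix(summarize_subjects(small_features), "bogus")


class TestHierarchicalTree:
    def _blob_distances(self, rng):
        a = rng.normal(0.0, 0.05, size=(5, 2))
        b = rng.normal(3.0, 0.05, size=(5, 2))
        pts = np.vstack([a, b])
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"s{i}" for i in range(10)]
        return dist, labels

    def test_two_blobs_recovered_at_half_height(self, rng):
        dist, labels = self._blob_distances(rng)
        tree = hierarchical_tree(dist, labels)
        members = tree.cut(height_pct=50.0)
        first = {labels[i] for i in range(5)}
        groups = {}
        for subject, cluster in members.items():
            groups.setdefault(cluster, set()).add(subject)
        assert first in groups.values()

    def test_leaf_and_merge_counts(self, rng):
        dist, labels = self._blob_distances(rng)
        tree = hierarchical_tree(dist, labels)
        assert tree.n_leaves == 10
        assert tree.linkage.shape[0] == 9  # n - 1 merges

    def test_partition_invariant_to_input_order(self, rng):
        dist, labels = self._blob_distances(rng)
        perm = rng.permutation(len(labels))
        tree_a = hierarchical_tree(dist, labels)
        tree_b = hierarchical_tree(dist[np.ix_(perm, perm)], [labels[i] for i in perm])
        cut_a = tree_a.cut(n_clusters=2)
        cut_b = tree_b.cut(n_clusters=2)
        # same partition of subject ids regardless of cluster numbering
        parts_a = {frozenset(s for s, c in cut_a.items() if c == k) for k in set(cut_a.values())}
        parts_b = {frozenset(s for s, c in cut_b.items() if c == k) for k in set(cut_b.values())}
        assert parts_a == parts_b

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_tree(bad, ["a", "b"])

    def test_newick_export_is_readable(self, rng):
        from skbio import TreeNode

        dist, labels = self._blob_distances(rng)
        tree = hierarchical_tree(dist, labels)
        parsed = TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == set(labels)


class TestNeighborJoining:
    def test_additive_distances_reproduced_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) => pairwise path lengths
        labels = ["A", "B", "C", "D"]
        dist = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining_tree(dist, labels, rooted=False)
        tip_dist = tree.tip_tip_distances(endpoints=labels)
        np.testing.assert_allclose(np.asarray(tip_dist.data), dist, atol=1e-9)

    def test_unrooted_edge_count(self):
        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(3)
        pts = rng.uniform(size=(5, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        tree = neighbor_joining_tree(dist, labels, rooted=False)
        n_edges = sum(1 for node in tree.traverse() if node.parent is not None)
        assert n_edges == 2 * len(labels) - 3

    def test_equidistant_points_do_not_crash(self):
        dist = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining_tree(dist, ["a", "b", "c", "d"])
        assert {t.name for t in tree.tips()} == {"a", "b", "c", "d"}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining_tree(np.zeros((2, 2)), ["a", "b"])


class TestParallelepiped:
    def test_training_points_classified_as_their_class(self, rng):
        pts = {"H1": rng.uniform(0, 1, size=(5, 3)), "H2": rng.uniform(2, 3, size=(5, 3))}
        model = parallelepiped_fit(pts)
        for cls, arr in pts.items():
            for p in arr:
                assert parallelepiped_predict(model, p) == cls

    def test_point_outside_all_boxes_is_unclassified(self):
        model = parallelepiped_fit({"H1": np.array([[0.0, 0.0], [1.0, 1.0]])})
        assert parallelepiped_predict(model, np.array([5.0, 5.0])) is None

    def test_overlap_resolved_by_smaller_box(self):
        # big box [0,4]^2, small box [1,2]^2 overlapping it
        model = parallelepiped_fit(
            {
                "big": np.array([[0.0, 0.0], [4.0, 4.0]]),
                "small": np.array([[1.0, 1.0], [2.0, 2.0]]),
            }
        )
        assert parallelepiped_predict(model, np.array([1.5, 1.5])) == "small"
        assert parallelepiped_predict(model, np.array([3.0, 3.0])) == "big"

    def test_dimension_mismatch_rejected(self):
        model = parallelepiped_fit({"H1": np.array([[0.0, 0.0]])})
        with pytest.raises(ValueError):
            parallelepiped_predict(model, np.array([0.0, 0.0, 0.0]))
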