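"""One-class verification: splits, scoring, ACC/AUC/EER and the protocol."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import grid_search_eer, pair_count_auc
from sigquant.verify import (
    VerificationConfig,
    accuracy,
    equal_error_rate,
    one_class_train,
    roc_auc,
    run_protocol,
    split_train_test,
)


class TestSplit:
    def test_counts_for_paper_protocol_shape(self, rng):
        genuine = rng.uniform(size=(25, 6))
        forgery = rng.uniform(size=(25, 6))
        train, pos, neg = split_train_test(genuine, forgery, 5, rng)
        assert train.shape == (5, 6) and pos.shape == (20, 6) and neg.shape == (25, 6)

    def test_same_seed_gives_identical_split(self):
        genuine = np.arange(50.0).reshape(25, 2)
        forgery = -np.arange(50.0).reshape(25, 2)
        a = split_train_test(genuine, forgery, 10, np.random.default_rng(5))
        b = split_train_test(genuine, forgery, 10, np.random.default_rng(5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_train_and_test_partition_the_genuine_set(self, rng):
        genuine = rng.uniform(size=(25, 3))
        train, pos, _ = split_train_test(genuine, genuine, 14, rng)
        combined = np.vstack([train, pos])
        assert combined.shape == genuine.shape
        a = {tuple(r) for r in combined}
        b = {tuple(r) for r in genuine}
        assert a == b

    def test_oversized_train_rejected(self, rng):
        with pytest.raises(ValueError):
            split_train_test(np.zeros((25, 2)), np.zeros((25, 2)), 25, rng)


class TestOneClassModel:
    def test_far_query_scores_negative(self, rng):
        train = rng.normal(0, 0.05, size=(10, 6))
        model = one_class_train(train, sigma2=10.0)
        far = np.full((1, 6), 100.0)
        assert model.decision_function(far)[0] < 0

    def test_training_scores_bounded_below_by_min(self, rng):
        train = rng.normal(size=(15, 6))
        model = one_class_train(train)
        scores = model.decision_function(train)
        assert scores.max() >= scores.min()  # well-defined decision function
        assert np.all(np.isfinite(scores))

    def test_order_invariance(self, rng):
        train = rng.normal(size=(12, 6))
        model_a = one_class_train(train)
        model_b = one_class_train(train[::-1])
        query = rng.normal(size=(5, 6))
        np.testing.assert_allclose(
            model_a.decision_function(query), model_b.decision_function(query), atol=1e-5
        )

    def test_degenerate_identical_training_points_still_fit(self):
        train = np.tile([0.5, 0.5], (8, 1))
        model = one_class_train(train)
        assert np.isfinite(model.decision_function([[0.5, 0.5]])[0])

    def test_kernel_conventions_differ(self, rng):
        train = rng.normal(size=(10, 2))
        q = rng.normal(size=(3, 2)) + 2.0
        a = one_class_train(train, sigma2=10, kernel_convention="half").decision_function(q)
        b = one_class_train(train, sigma2=10, kernel_convention="inverse").decision_function(q)
        assert not np.allclose(a, b)


class TestAccuracy:
    def test_perfect_separation(self):
        assert accuracy([0.5, 1.0], [-1.0, -0.5]) == 1.0

    def test_all_negative_scores(self):
        assert accuracy([-1.0] * 20, [-2.0] * 25) == pytest.approx(25 / 45)

    def test_mixed_confusion_arithmetic(self):
        pos = [1.0] * 18 + [-1.0] * 2  # 18 TP of 20
        neg = [-1.0] * 20 + [1.0] * 5  # 20 TN of 25
        assert accuracy(pos, neg) == pytest.approx(38 / 45)


class TestRocAuc:
    def test_separated_and_identical_scores(self):
        assert roc_auc([0.9, 0.8], [0.2, 0.1]) == 1.0
        assert roc_auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_small_brute_force_case(self):
        assert roc_auc([0.9, 0.4], [0.6, 0.1]) == 0.75

    @given(st.integers(0, 2**32 - 1))
    def test_exact_match_with_pair_counting_on_integer_scores(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 10, size=rng.integers(2, 20)).astype(float)
        neg = rng.integers(0, 10, size=rng.integers(2, 20)).astype(float)
        assert roc_auc(pos, neg) == pair_count_auc(list(pos), list(neg))

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.normal(1.0, 1.0, size=40)
        neg = rng.normal(0.0, 1.0, size=30)
        labels = np.r_[np.ones(40), np.zeros(30)]
        assert roc_auc(pos, neg) == pytest.approx(
            roc_auc_score(labels, np.r_[pos, neg]), abs=1e-12
        )


class TestEqualErrorRate:
    def test_perfectly_separated_scores(self):
        assert equal_error_rate([1.0, 2.0, 3.0], [-3.0, -2.0, -1.0]) == 0.0

    def test_identical_score_distributions(self):
        s = [0.1, 0.2, 0.3, 0.4]
        assert equal_error_rate(s, list(s)) == pytest.approx(0.5)

    def test_hand_listed_scores_match_grid_oracle(self):
        pos = [0.9, 0.8, 0.75, 0.4, 0.3]
        neg = [0.85, 0.6, 0.35, 0.2, 0.1]
        assert equal_error_rate(pos, neg) == pytest.approx(
            grid_search_eer(pos, neg), abs=0.05
        )

    @given(st.integers(0, 2**32 - 1))
    def test_matches_dense_grid_oracle_on_large_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.6, 0.2, size=1200)
        neg = rng.normal(0.3, 0.2, size=1200)
        assert equal_error_rate(pos, neg) == pytest.approx(
            grid_search_eer(pos, neg), abs=1e-3
        )

    def test_within_valid_range(self, rng):
        pos = rng.normal(0.5, 1.0, size=50)
        neg = rng.normal(0.0, 1.0, size=60)
        assert 0.0 <= equal_error_rate(pos, neg) <= 0.5


class TestProtocol:
    def test_indistinguishable_classes_give_half_auc(self, rng):
        import pandas as pd

        genuine = rng.uniform(size=(25, 6))
        rows = []
        for j, arr in enumerate(genuine):
            rows.append(["s1", f"g{j}", "G", *arr])
            rows.append(["s1", f"f{j}", "F", *arr])  # forgeries identical to genuine
        df = pd.DataFrame(
            rows, columns=["subject_id", "signature_id", "authenticity",
                           "h_x", "h_y", "c_x", "c_y", "f_x", "f_y"]
        )
        report = run_protocol(df, VerificationConfig(n_train_values=(5,), repetitions=5, seed=3))
        assert report.summary_frame()["auc"].iloc[0] == pytest.approx(0.5, abs=0.12)

    def test_fixed_seed_reports_are_identical(self, small_features):
        cfg = VerificationConfig(n_train_values=(4,), repetitions=1, seed=11)
        a = run_protocol(small_features, cfg).to_json()
        b = run_protocol(small_features, cfg).to_json()
        assert a == b

    def test_report_shapes_and_export(self, small_features, tmp_path):
        cfg = VerificationConfig(n_train_values=(3, 5), repetitions=2, seed=1)
        report = run_protocol(small_features, cfg)
        per_subject = report.per_subject_frame()
        n_subjects = small_features["subject_id"].nunique()
        assert len(per_subject) == 2 * n_subjects
        summary = report.summary_frame()
        assert list(summary["n_train"]) == [3, 5]
        report.to_json(tmp_path / "report.json")
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["config"]["sigma2"] == 10.0
        assert len(payload["subjects"]) == 2 * n_subjects
        report.to_csv(tmp_path / "report.csv")
        assert (tmp_path / "report.csv").exists()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            VerificationConfig(sigma2=0.0)
        with pytest.raises(ValueError):
            VerificationConfig(nu=0.0)
        with pytest.raises(ValueError):
            VerificationConfig(repetitions=0)
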