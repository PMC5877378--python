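"""Protocol structure, chance levels, metrics and ROC."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from emoeeg.benchmarks import BINARY_CONFUSIONS
from emoeeg.classify import (
    ProtocolError,
    binary_leave_one_clip_out,
    cross_paradigm,
    metrics_from_confusion,
    roc_auc,
    six_class_cv,
    summarize,
)
from tests.conftest import make_protocol_frame


class TestBinaryLeaveOneClipOut:
    def test_fold_structure(self):
        rng = np.random.default_rng(0)
        frame = make_protocol_frame(rng)
        res = binary_leave_one_clip_out(frame)
        assert len(res.fold_accuracies) == 15
        assert res.fold_train_sizes == [686] * 15
        assert res.fold_test_sizes == [49] * 15
        assert res.confusion.to_numpy().sum() == 15 * 49

    def test_separable_features_are_perfect(self):
        rng = np.random.default_rng(1)
        frame = make_protocol_frame(rng, epochs_per_clip=10, separation=50.0)
        res = binary_leave_one_clip_out(frame)
        assert res.accuracy == 100.0

    def test_noise_features_sit_at_chance_level(self):
        """Label-independent features: fold-mean accuracy lands near the
        majority rate — within the clip-level binomial band around the
        classifier's expected chance agreement p_e."""
        from emoeeg.experiments import clip_level_chance_interval, expected_chance_agreement

        results = [
            binary_leave_one_clip_out(
                make_protocol_frame(np.random.default_rng(s), epochs_per_clip=12)
            )
            for s in range(4)
        ]
        rep = summarize("within_movie", "binary", results)
        p_e = expected_chance_agreement(rep)
        assert 0.6 <= p_e <= 0.85  # close to, but below, the 12/15 majority rate
        lo, hi = clip_level_chance_interval(4 * 15, p_e)
        assert lo <= rep.mean_accuracy <= hi

    def test_missing_emotion_raises(self):
        rng = np.random.default_rng(0)
        frame = make_protocol_frame(rng, epochs_per_clip=5)
        frame = frame.loc[frame["emotion"] != "fear"]
        with pytest.raises(ProtocolError, match="fear"):
            binary_leave_one_clip_out(frame)


class TestSixClassCv:
    def test_fold_structure(self):
        rng = np.random.default_rng(2)
        frame = make_protocol_frame(rng)
        res = six_class_cv(frame)
        assert len(res.fold_accuracies) == 3
        assert res.fold_train_sizes == [588] * 3
        assert res.fold_test_sizes == [294] * 3

    def test_encodable_labels_are_perfect(self):
        rng = np.random.default_rng(3)
        frame = make_protocol_frame(rng, epochs_per_clip=8, separation=50.0, n_features=2)
        assert six_class_cv(frame).accuracy == 100.0

    def test_noise_features_near_one_sixth(self):
        accs = [
            six_class_cv(make_protocol_frame(np.random.default_rng(s), epochs_per_clip=12)).accuracy
            for s in range(4)
        ]
        assert 5.0 < np.mean(accs) < 30.0

    def test_unbalanced_clips_raise(self):
        rng = np.random.default_rng(0)
        frame = make_protocol_frame(rng, epochs_per_clip=5)
        frame = frame.loc[frame["clip_id"] != 1]
        with pytest.raises(ProtocolError, match="unbalanced"):
            six_class_cv(frame)

    def test_pooled_accuracy_equals_epochweighted_fold_mean(self):
        rng = np.random.default_rng(5)
        frame = make_protocol_frame(rng, epochs_per_clip=8, separation=1.0)
        res = six_class_cv(frame)
        pooled = metrics_from_confusion(res.confusion)["accuracy"]
        weighted = np.average(res.fold_accuracies, weights=res.fold_test_sizes)
        assert pooled == pytest.approx(weighted)


class TestCrossParadigm:
    def test_sizes_six_class(self):
        rng = np.random.default_rng(4)
        movie = make_protocol_frame(rng, epochs_per_clip=49, paradigm="movie")
        recall = make_protocol_frame(rng, epochs_per_clip=49, paradigm="recall")
        res = cross_paradigm(movie, recall, scheme="six_class")
        assert res.fold_train_sizes == [882]
        assert res.fold_test_sizes == [882]

    def test_binary_restricts_to_eligible_clips(self):
        rng = np.random.default_rng(4)
        movie = make_protocol_frame(rng, epochs_per_clip=10, paradigm="movie")
        recall = make_protocol_frame(rng, epochs_per_clip=10, paradigm="recall")
        res = cross_paradigm(movie, recall, scheme="binary")
        assert res.fold_train_sizes == [150]  # 15 clips x 10 epochs
        assert res.fold_test_sizes == [150]

    def test_identical_recall_equals_resubstitution(self):
        rng = np.random.default_rng(6)
        movie = make_protocol_frame(rng, epochs_per_clip=8, separation=2.0)
        recall = movie.assign(paradigm="recall")
        res = cross_paradigm(movie, recall, scheme="six_class")
        # resubstitution oracle: fit and predict on the training set
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        cols = [c for c in movie.columns if "_F_" in c]
        model = make_pipeline(StandardScaler(), SVC(kernel="linear"))
        model.fit(movie[cols], movie["emotion"])
        resub = 100.0 * np.mean(model.predict(movie[cols]) == movie["emotion"])
        assert res.accuracy == pytest.approx(resub)

    def test_clip_mismatch_raises(self):
        rng = np.random.default_rng(0)
        movie = make_protocol_frame(rng, epochs_per_clip=5)
        recall = make_protocol_frame(rng, epochs_per_clip=5, paradigm="recall")
        recall = recall.loc[recall["clip_id"] != 4]
        with pytest.raises(ProtocolError, match="different clips"):
            cross_paradigm(movie, recall)


class TestMetricsFromConfusion:
    def test_published_self_induced_worked_example(self):
        r = metrics_from_confusion(BINARY_CONFUSIONS["self"])
        assert r["accuracy"] == pytest.approx(87.36, abs=0.005)
        assert r["per_class"]["negative"]["f1"] == pytest.approx(0.92, abs=0.005)

    def test_published_cross_prediction_worked_example(self):
        r = metrics_from_confusion(BINARY_CONFUSIONS["cross"])
        assert r["accuracy"] == pytest.approx(78.53, abs=0.005)
        assert r["per_class"]["negative"]["f1"] == pytest.approx(0.86, abs=0.005)
        assert r["per_class"]["positive"]["f1"] == pytest.approx(0.52, abs=0.005)

    def test_diagonal_matrix_is_perfect(self):
        r = metrics_from_confusion(np.diag([5, 7, 9]))
        assert r["accuracy"] == 100.0
        assert all(v["f1"] == 1.0 for v in r["per_class"].values())

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            metrics_from_confusion(np.array([[1, -1], [0, 1]]))
        # absent class: F1 falls back to 0, no division error
        r = metrics_from_confusion(np.array([[3, 2], [0, 0]]))
        assert r["per_class"]["1"]["f1"] == 0.0


class TestRoc:
    def test_perfect_and_reversed_scores(self):
        labels = np.array([1, 1, -1, -1, 1])
        scores = labels.astype(float)
        assert roc_auc(scores, labels) == 1.0
        assert roc_auc(-scores, labels) == pytest.approx(1.0 - roc_auc(scores, labels))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(10_000)
        labels = np.where(rng.random(10_000) < 0.5, 1, -1)
        assert 0.48 <= roc_auc(scores, labels) <= 0.52

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.standard_normal(500), 1)  # force ties
        labels = np.where(rng.random(500) < 0.3, 1, -1)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score((labels > 0).astype(int), scores)
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5), np.ones(5))


def test_summarize_pools_subjects():
    rng = np.random.default_rng(9)
    results = [
        binary_leave_one_clip_out(
            make_protocol_frame(rng, epochs_per_clip=8, separation=3.0, subject=f"S{i}")
        )
        for i in range(2)
    ]
    rep = summarize("within_movie", "binary", results)
    assert rep.confusion.to_numpy().sum() == 2 * 15 * 8
    assert 0 <= rep.mean_accuracy <= 100
    assert rep.auc is not None and 0.5 <= rep.auc <= 1.0
    assert set(rep.subject_accuracies) == {"S0", "S1"}
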