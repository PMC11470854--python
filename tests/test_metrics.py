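import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

import patatinpred as pp
from patatinpred.metrics import (
    ConfusionMatrix,
    SVMConfig,
    SplitConfig,
    compute_metrics,
    confusion_from_labels,
    trapezoidal_auc,
)

cm_strategy = st.builds(
    ConfusionMatrix,
    TP=st.integers(0, 50),
    FP=st.integers(0, 50),
    FN=st.integers(0, 50),
    TN=st.integers(0, 50),
)


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        report = compute_metrics(ConfusionMatrix(TP=9, FP=1, FN=1, TN=9))
        assert report.precision == pytest.approx(0.9)
        assert report.recall == pytest.approx(0.9)
        assert report.f1 == pytest.approx(0.9)
        assert report.accuracy == pytest.approx(0.9)
        assert report.mcc == pytest.approx(0.8)

    def test_perfect_classifier(self):
        report = compute_metrics(ConfusionMatrix(TP=10, FP=0, FN=0, TN=10))
        assert (
            report.precision == report.recall == report.f1 == report.accuracy == 1.0
        )
        assert report.mcc == 1.0

    def test_constant_classifier_on_balanced_data(self):
        # always-positive on a balanced test set: accuracy 1/2, MCC 0
        report = compute_metrics(ConfusionMatrix(TP=20, FP=20, FN=0, TN=0))
        assert report.accuracy == 0.5
        assert report.mcc == 0.0
        assert report.warnings  # zero denominator flagged

    @settings(max_examples=20, deadline=None)
    @given(cm=cm_strategy)
    def test_matches_sklearn_on_reconstructed_labels(self, cm):
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        if cm.total == 0:
            return
        truth = [1] * (cm.TP + cm.FN) + [0] * (cm.FP + cm.TN)
        pred = [1] * cm.TP + [0] * cm.FN + [1] * cm.FP + [0] * cm.TN
        report = compute_metrics(cm)
        assert report.accuracy == pytest.approx(accuracy_score(truth, pred))
        if cm.TP + cm.FP:
            assert report.precision == pytest.approx(
                precision_score(truth, pred, zero_division=0)
            )
        if cm.TP + cm.FN:
            assert report.recall == pytest.approx(
                recall_score(truth, pred, zero_division=0)
            )
        if report.precision + report.recall > 0:
            assert report.f1 == pytest.approx(f1_score(truth, pred, zero_division=0))
        if len(set(truth)) == 2 and len(set(pred)) == 2:
            assert report.mcc == pytest.approx(matthews_corrcoef(truth, pred))

    @settings(max_examples=50, deadline=None)
    @given(cm=cm_strategy)
    def test_metric_identities(self, cm):
        if cm.total == 0:
            return
        report = compute_metrics(cm)
        if report.precision + report.recall > 0:
            harmonic = (
                2 * report.precision * report.recall
                / (report.precision + report.recall)
            )
            assert report.f1 == pytest.approx(harmonic)
        assert -1.0 <= report.mcc <= 1.0
        if cm.TP * cm.TN == cm.FP * cm.FN:
            assert report.mcc == pytest.approx(0.0)
        # accuracy invariant under class swap (transposing the matrix)
        swapped = compute_metrics(
            ConfusionMatrix(TP=cm.TN, FP=cm.FN, FN=cm.FP, TN=cm.TP)
        )
        assert swapped.accuracy == pytest.approx(report.accuracy)


class TestAUC:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([-2.0, -1.0, 0.5, 3.0])
        assert trapezoidal_auc(y, scores) == 1.0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_equals_mann_whitney_statistic(self, seed):
        rng = np.random.default_rng(seed)
        y = np.array([0] * 12 + [1] * 8)
        scores = rng.normal(size=20) + y  # arbitrary overlap
        ranks = rankdata(scores)
        u = ranks[y == 1].sum() - 8 * 9 / 2
        assert trapezoidal_auc(y, scores) == pytest.approx(u / (12 * 8))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            trapezoidal_auc(np.ones(4), np.arange(4.0))


class TestSplit:
    def test_study_scale_arithmetic(self, ):
        import pandas as pd

        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.random((1170, 3)), columns=list("abc"))
        matrix["label"] = ["positive"] * 585 + ["negative"] * 585
        train, test = pp.split_dataset(matrix, SplitConfig(seed=0))
        assert (len(train), len(test)) == (936, 234)
        assert (train["label"] == "positive").sum() == 468
        assert (test["label"] == "positive").sum() == 117

    def test_small_balanced_split(self):
        import pandas as pd

        matrix = pd.DataFrame(np.arange(20.0).reshape(10, 2), columns=list("ab"))
        matrix["label"] = ["positive"] * 5 + ["negative"] * 5
        train, test = pp.split_dataset(matrix, SplitConfig(seed=1))
        assert (train["label"] == "positive").sum() == 4
        assert (test["label"] == "positive").sum() == 1

    def test_seed_reproducibility(self, separable_small_dpc):
        a = pp.split_dataset(separable_small_dpc, SplitConfig(seed=5))
        b = pp.split_dataset(separable_small_dpc, SplitConfig(seed=5))
        assert a[0].index.tolist() == b[0].index.tolist()
        assert a[1].index.tolist() == b[1].index.tolist()

    def test_disjoint_and_exhaustive(self, separable_small_dpc):
        train, test = pp.split_dataset(separable_small_dpc, SplitConfig(seed=2))
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(separable_small_dpc.index)

    def test_tiny_class_rejected(self):
        import pandas as pd

        matrix = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        matrix["label"] = ["positive", "negative", "negative"]
        with pytest.raises(ValueError, match="at least 2"):
            pp.split_dataset(matrix, SplitConfig())


class TestTrainSVM:
    @pytest.mark.parametrize("kernel", ["rbf", "linear", "sigmoid", "polynomial"])
    def test_separable_clusters_fit_perfectly(self, kernel):
        import pandas as pd

        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.05, (20, 2)), rng.normal(1, 0.05, (20, 2))]
        )
        matrix = pd.DataFrame(X, columns=["f1", "f2"])
        matrix["label"] = ["negative"] * 20 + ["positive"] * 20
        model = pp.train_svm(matrix, SVMConfig(kernel=kernel))
        assert (model.predict(matrix) == matrix["label"]).mean() == 1.0

    def test_training_is_deterministic(self, separable_small_dpc):
        train, test = pp.split_dataset(separable_small_dpc, SplitConfig(seed=3))
        cfg = SVMConfig(kernel="rbf", seed=3)
        pred_a = pp.train_svm(train, cfg).predict(test)
        pred_b = pp.train_svm(train, cfg).predict(test)
        np.testing.assert_array_equal(pred_a, pred_b)

    def test_single_class_rejected(self):
        import pandas as pd

        matrix = pd.DataFrame({"a": [0.0, 1.0]})
        matrix["label"] = ["positive", "positive"]
        with pytest.raises(ValueError, match="both classes"):
            pp.train_svm(matrix, SVMConfig())

    def test_feature_mismatch_rejected(self, separable_small_dpc, separable_small):
        train, _ = pp.split_dataset(separable_small_dpc, SplitConfig(seed=0))
        model = pp.train_svm(train, SVMConfig())
        other = pp.encode_dataset(separable_small, "AAC")
        with pytest.raises(ValueError, match="feature columns"):
            model.predict(other)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SVMConfig(kernel="laplacian")
        with pytest.raises(ValueError):
            SVMConfig(C=0.0)
        with pytest.raises(ValueError):
            SVMConfig(gamma=-1.0)
        with pytest.raises(ValueError):
            SplitConfig(train_fraction=1.0)


class TestConfusion:
    def test_perfect_and_inverted(self):
        truth = ["positive"] * 10 + ["negative"] * 10
        cm = confusion_from_labels(truth, truth)
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (10, 10, 0, 0)
        inverted = [
            "negative" if t == "positive" else "positive" for t in truth
        ]
        cm2 = confusion_from_labels(truth, inverted)
        assert (cm2.TP, cm2.TN) == (0, 0)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_counts_partition_the_test_set(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.choice(["positive", "negative"], 30)
        pred = rng.choice(["positive", "negative"], 30)
        assert confusion_from_labels(truth, pred).total == 30
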