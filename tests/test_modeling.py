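"""Classifier evaluation protocol, PCA reduction and the experiment matrix."""

import numpy as np
import pandas as pd
import pytest

from actifuse import PipelineConfig, pca_reduce, train_eval
from actifuse.modeling import (
    CLASSIFIERS,
    enumerate_matrix,
    permuted_label_tp,
    reports_to_frame,
    run_experiment_matrix,
)


def _separable_table(n_per_class=30, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, label in enumerate(["walking", "running"]):
        X = rng.normal(loc=10.0 * i, scale=0.5, size=(n_per_class, 3))
        for j, x in enumerate(X):
            rows.append({"label": label, "device": "phone",
                         "segment_id": i, "window_index": j,
                         "f1": x[0], "f2": x[1], "f3": x[2]})
    return pd.DataFrame(rows)


class TestTrainEval:
    @pytest.mark.parametrize("clf", ["c45", "cart", "nb"])
    def test_separable_classes_are_perfect(self, clf):
        report = train_eval(_separable_table(), clf, folds=5, seed=0)
        assert report.overall_tp_pct == 100.0
        assert all(v == 100.0 for v in report.per_class_tp_pct.values())

    def test_confusion_matrix_consistency(self, nine_class_table):
        report = train_eval(nine_class_table, "cart", folds=5, seed=0)
        conf = report.confusion.to_numpy()
        counts = nine_class_table["label"].value_counts()
        for i, label in enumerate(report.confusion.index):
            assert conf[i].sum() == counts[label]
        assert report.overall_tp_pct == pytest.approx(
            100.0 * np.trace(conf) / conf.sum())

    def test_thin_class_rejected_by_name(self):
        table = _separable_table(n_per_class=4)
        with pytest.raises(ValueError, match="running"):
            train_eval(table, "c45", folds=5, seed=0)

    def test_deterministic_under_seed(self, nine_class_table):
        a = train_eval(nine_class_table, "mlp", folds=4, seed=3)
        b = train_eval(nine_class_table, "mlp", folds=4, seed=3)
        assert a.overall_tp_pct == b.overall_tp_pct
        pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            train_eval(_separable_table(), "j48", folds=5, seed=0)

    def test_permuted_labels_near_chance(self, nine_class_table):
        from actifuse import balance_dataset

        balanced = balance_dataset(nine_class_table, seed=0)
        tps = [permuted_label_tp(balanced, "c45", folds=4, seed=s)
               for s in range(5)]
        assert np.mean(tps) == pytest.approx(100.0 / 9, abs=6.0)


class TestPca:
    def test_single_informative_axis_gives_k1(self):
        # all variance on one axis (the rest constant) -> one component
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"f0": rng.normal(size=100),
                              "f1": 3.0, "f2": -1.0, "f3": 0.0})
        table.insert(0, "label", "walking")
        reduced, _, k = pca_reduce(table, 0.95)
        assert k == 1
        assert list(reduced.filter(like="pc").columns) == ["pc1"]

    def test_isotropic_noise_needs_every_component(self):
        """With equal eigenvalues, d-1 components hold only (d-1)/d of the
        variance, so the 95% target forces k = d."""
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(2000, 10)),
                             columns=[f"f{i}" for i in range(10)])
        table.insert(0, "label", "walking")
        _, loadings, k = pca_reduce(table, 0.95)
        assert k == 10
        assert np.allclose(loadings @ loadings.T, np.eye(10), atol=1e-8)

    def test_k_is_minimal(self, nine_class_table):
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler

        from actifuse.dataset import feature_columns

        reduced, _, k = pca_reduce(nine_class_table, 0.95)
        X = StandardScaler().fit_transform(
            nine_class_table[feature_columns(nine_class_table)])
        cum = np.cumsum(PCA().fit(X).explained_variance_ratio_)
        assert cum[k - 1] >= 0.95
        assert k == 1 or cum[k - 2] < 0.95
        assert reduced.filter(like="pc").shape[1] == k

    def test_correlated_data_compresses(self, nine_class_table):
        _, _, k = pca_reduce(nine_class_table, 0.95)
        assert k < 53

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"label": ["a"] * 5, "f1": 1.0, "f2": 2.0})
        with pytest.raises(ValueError):
            pca_reduce(table, 0.95)


class TestMatrix:
    def test_enumeration_counts(self):
        combos = enumerate_matrix(include_pca=False)
        phone = [c for c in combos if c["device"] == "phone"]
        watch = [c for c in combos if c["device"] == "watch"]
        assert len(phone) == 5 * 2 * 5 == 50
        assert len(watch) == 1 * 2 * 5 == 10
        assert len(enumerate_matrix(include_pca=True)) == 80

    def test_run_matrix_and_rerun_identical(self, mixed_phone_table,
                                            mixed_watch_table):
        config = PipelineConfig(cv_folds=4, seed=2)
        kwargs = dict(config=config, include_pca=True, classifiers=("cart",))
        a = reports_to_frame(run_experiment_matrix(
            mixed_phone_table, mixed_watch_table, **kwargs))
        b = reports_to_frame(run_experiment_matrix(
            mixed_phone_table, mixed_watch_table, **kwargs))
        assert len(a) == 16  # (5 phone + 1 watch + 2 pca) x 2 balance x 1 clf
        pd.testing.assert_frame_equal(a, b)
        assert {"device", "subset", "balanced", "pca", "classifier",
                "overall_tp_pct"} <= set(a.columns)
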