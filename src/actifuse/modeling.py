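"""Classifier evaluation and PCA reduction.

Five classical algorithms are realized with scikit-learn: information-gain
and Gini decision trees (the C4.5 and CART families), Gaussian naive Bayes,
a single-hidden-layer perceptron and an RBF support-vector machine.
Evaluation is stratified k-fold cross-validation; the report aggregates
out-of-fold predictions into a confusion matrix, per-class true-positive
rates and the overall true-positive percentage (trace over total).
Scale-sensitive models (MLP, SVM) standardize features inside the CV
pipeline so the scaler is fit on training folds only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import PipelineConfig
from .dataset import META_COLUMNS, balance_dataset, feature_columns

CLASSIFIERS = ("c45", "cart", "nb", "mlp", "svm")
TREE_CLASSIFIERS = ("c45", "cart")


@dataclass
class EvalReport:
    """Cross-validated performance of one classifier on one dataset."""

    classifier: str
    dataset: dict  # device, subset, balanced, pca ...
    overall_tp_pct: float
    per_class_tp_pct: dict
    confusion: pd.DataFrame  # rows = true, cols = predicted
    cv_folds: int
    seed: int

    def to_row(self) -> dict:
        row = {"classifier": self.classifier, **self.dataset,
               "overall_tp_pct": self.overall_tp_pct,
               "cv_folds": self.cv_folds, "seed": self.seed}
        for label, v in self.per_class_tp_pct.items():
            row[f"tp_{label}_pct"] = v
        return row


def make_classifier(classifier: str, n_features: int, seed: int) -> Pipeline:
    """A leakage-safe sklearn pipeline for one of the five algorithms."""
    steps = [("impute", SimpleImputer(strategy="constant", fill_value=0.0))]
    if classifier == "c45":
        est = DecisionTreeClassifier(criterion="entropy", random_state=seed)
    elif classifier == "cart":
        est = DecisionTreeClassifier(criterion="gini", random_state=seed)
    elif classifier == "nb":
        est = GaussianNB()
    elif classifier == "mlp":
        steps.append(("scale", StandardScaler()))
        est = MLPClassifier(
            hidden_layer_sizes=(max(2, n_features // 2),),
            max_iter=600, random_state=seed,
        )
    elif classifier == "svm":
        steps.append(("scale", StandardScaler()))
        est = SVC(kernel="rbf", C=1.0, gamma="scale")
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    steps.append(("model", est))
    return Pipeline(steps)


def train_eval(
    table: pd.DataFrame,
    classifier: str,
    folds: int = 10,
    seed: int = 0,
    feature_columns=None,
    dataset_info: dict | None = None,
) -> EvalReport:
    """Stratified k-fold CV of one classifier on a labeled feature table."""
    cols = feature_columns or [
        c for c in table.columns
        if c not in META_COLUMNS and c not in ("label",)
    ]
    y = table["label"].to_numpy()
    X = table[cols].to_numpy(dtype=float)
    counts = pd.Series(y).value_counts()
    thin = counts[counts < folds]
    if not thin.empty:
        raise ValueError(
            f"classes with fewer instances than folds={folds}: "
            f"{sorted(thin.index)}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = make_classifier(classifier, len(cols), seed)
    pred = cross_val_predict(model, X, y, cv=skf)
    labels = sorted(np.unique(y))
    conf = pd.crosstab(
        pd.Categorical(y, categories=labels),
        pd.Categorical(pred, categories=labels),
        dropna=False,
    )
    conf.index = labels
    conf.columns = labels
    total = conf.to_numpy().sum()
    overall = 100.0 * np.trace(conf.to_numpy()) / total
    row_sums = conf.to_numpy().sum(axis=1)
    per_class = {
        label: 100.0 * conf.to_numpy()[i, i] / row_sums[i] if row_sums[i] else 0.0
        for i, label in enumerate(labels)
    }
    return EvalReport(
        classifier=classifier,
        dataset=dict(dataset_info or {}),
        overall_tp_pct=float(overall),
        per_class_tp_pct=per_class,
        confusion=conf,
        cv_folds=folds,
        seed=seed,
    )


def pca_reduce(
    table: pd.DataFrame, variance_target: float = 0.95
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Project standardized features onto the minimal number of principal
    components whose cumulative explained variance reaches the target.

    Returns (reduced table with PC columns plus metadata, orthonormal
    loadings (k, p), k).
    """
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 instances for PCA")
    X = SimpleImputer(strategy="constant", fill_value=0.0).fit_transform(X)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("zero-variance table")
    Z = StandardScaler().fit_transform(X)
    pca = PCA(n_components=min(X.shape), random_state=0)
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, scores.shape[1])
    meta = [c for c in table.columns if c in META_COLUMNS]
    reduced = table[meta].copy().reset_index(drop=True)
    for i in range(k):
        reduced[f"pc{i + 1}"] = scores[:, i]
    return reduced, pca.components_[:k], k


# ---------------------------------------------------------------------------
# experiment matrix
# ---------------------------------------------------------------------------

def enumerate_matrix(
    include_pca: bool = True,
    classifiers=CLASSIFIERS,
) -> list[dict]:
    """All device x subset x balance (x pca) x classifier combinations.

    PCA variants run on the fused phone set and the watch accelerometer set,
    matching the reduction applied to each device's full schema.
    """
    combos = []
    for subset in ("fused", "accelerometer", "magnetometer", "gyro", "pressure"):
        for balanced in (False, True):
            for clf in classifiers:
                combos.append(dict(device="phone", subset=subset,
                                   balanced=balanced, pca=False, classifier=clf))
    for balanced in (False, True):
        for clf in classifiers:
            combos.append(dict(device="watch", subset="accelerometer",
                               balanced=balanced, pca=False, classifier=clf))
    if include_pca:
        for device, subset in (("phone", "fused"), ("watch", "accelerometer")):
            for balanced in (False, True):
                for clf in classifiers:
                    combos.append(dict(device=device, subset=subset,
                                       balanced=balanced, pca=True,
                                       classifier=clf))
    return combos


def run_experiment_matrix(
    phone_table: pd.DataFrame,
    watch_table: pd.DataFrame,
    config: PipelineConfig | None = None,
    include_pca: bool = True,
    classifiers=CLASSIFIERS,
) -> list[EvalReport]:
    """Evaluate every matrix combination on prebuilt full feature tables."""
    from .dataset import build_dataset

    config = config or PipelineConfig()
    reports = []
    tables = {"phone": phone_table, "watch": watch_table}
    for combo in enumerate_matrix(include_pca, classifiers):
        base = tables[combo["device"]]
        if base is None or base.empty:
            continue
        table = build_dataset(base, combo["device"], combo["subset"])
        if combo["balanced"]:
            table = balance_dataset(table, seed=config.seed)
        if combo["pca"]:
            reduced, _, k = pca_reduce(table, config.pca_variance)
            reduced["label"] = table["label"].to_numpy()
            table = reduced
            combo = dict(combo, pca_k=k)
        folds = int(max(2, min(config.cv_folds,
                               table["label"].value_counts().min())))
        try:
            reports.append(
                train_eval(table, combo["classifier"], folds=folds,
                           seed=config.seed, dataset_info=combo)
            )
        except ValueError as err:
            raise ValueError(f"{combo}: {err}") from err
    return reports


def reports_to_frame(reports: list[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


def permuted_label_tp(
    table: pd.DataFrame,
    classifier: str = "c45",
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Overall TP% after randomly permuting labels — a chance-level probe."""
    rng = np.random.default_rng(seed)
    shuffled = table.copy()
    shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
    return train_eval(shuffled, classifier, folds=folds, seed=seed).overall_tp_pct
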