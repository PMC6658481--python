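"""Baseline-comparison harness.

Pits SKiNET against the standard chemometric classifiers — k-nearest
neighbours, support vector machines and PLS-DA (each behind a PCA
dimensionality-reduction step, evaluated over a grid of component
counts) and a multi-layer perceptron on the raw channels — on one shared
stratified hold-out split and one shared set of CV folds. Baselines are
thin calls into scikit-learn; hyper-parameters are picked by stratified
CV on the training portion only. PLS-DA is realised the standard
chemometrics way: PLS regression onto one-hot targets, decoded by
argmax.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (PartitionSpec, SpectralDataset, stratified_folds,
                      stratified_partition_indices)
from .hexmap import TrainingSchedule
from .lvq import LVQSchedule, evaluate, predict_dataset, skinet_train

__all__ = ["BenchRow", "BenchReport", "run_benchmark"]

DEFAULT_METHODS = ("skinet", "knn", "svm", "plsda", "mlp")


@dataclass
class BenchRow:
    method: str
    n_components: int | None          # None for methods without PCA
    cv_mean: float | None
    cv_sd: float | None
    test_accuracy: float | None
    params: dict = field(default_factory=dict)
    note: str = ""


@dataclass
class BenchReport:
    rows: list[BenchRow]
    train_indices: np.ndarray
    test_indices: np.ndarray
    partition: PartitionSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "method": r.method,
            "n_components": "n/a" if r.n_components is None else r.n_components,
            "cv_mean": r.cv_mean, "cv_sd": r.cv_sd,
            "test_accuracy": r.test_accuracy,
            "params": json.dumps(r.params), "note": r.note,
        } for r in self.rows])

    def partition_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.train_indices.astype(np.int64).tobytes())
        h.update(self.test_indices.astype(np.int64).tobytes())
        return h.hexdigest()

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps({
                "partition": {"test_fraction": self.partition.test_fraction,
                              "n_folds": self.partition.n_folds,
                              "seed": self.partition.seed},
                "partition_hash": self.partition_hash(),
                "train_indices": self.train_indices.tolist(),
                "test_indices": self.test_indices.tolist(),
                "rows": [r.__dict__ for r in self.rows],
            }))


def _make_baseline(method: str, n_components: int, params: dict, seed: int):
    """A fresh fit/predict pipeline for one baseline configuration."""
    from sklearn.decomposition import PCA
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.svm import SVC

    if method == "knn":
        return make_pipeline(PCA(n_components=n_components, random_state=seed),
                             KNeighborsClassifier(n_neighbors=params["k"]))
    if method == "svm":
        return make_pipeline(PCA(n_components=n_components, random_state=seed),
                             SVC(kernel="rbf", C=params["C"], gamma="scale"))
    if method == "plsda":
        return _PLSDAPipeline(n_components, params["pls_components"], seed)
    if method == "mlp":
        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=300,
                             random_state=seed)
    raise ValueError(f"unknown baseline {method!r}")


class _PLSDAPipeline:
    """PCA then PLS regression on one-hot targets, argmax decoding."""

    def __init__(self, n_pca: int, n_pls: int, seed: int) -> None:
        from sklearn.cross_decomposition import PLSRegression
        from sklearn.decomposition import PCA
        self.pca = PCA(n_components=n_pca, random_state=seed)
        self.pls = PLSRegression(n_components=min(n_pls, n_pca), scale=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PLSDAPipeline":
        self.classes_ = np.unique(y)
        Y = np.eye(self.classes_.size)[np.searchsorted(self.classes_, y)]
        Z = self.pca.fit_transform(X)
        self.pls.fit(Z, Y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.pls.predict(self.pca.transform(X))
        return self.classes_[np.argmax(scores, axis=1)]


_GRIDS = {
    "knn": [{"k": k} for k in (1, 3, 5, 7)],
    "svm": [{"C": C} for C in (1.0, 10.0, 100.0)],
    "plsda": [{"pls_components": 0}],   # tied to n_components below
    "mlp": [{}],
}


def _cv_accuracy(make_model, X, y, folds) -> tuple[float, float]:
    accs = []
    for tr, va in folds:
        model = make_model()
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[va]) == y[va])))
    return float(np.mean(accs)), float(np.std(accs))


def run_benchmark(
    dataset: SpectralDataset,
    partition: PartitionSpec | None = None,
    n_components: tuple[int, ...] = (1, 2, 5, 10, 20),
    methods: tuple[str, ...] = DEFAULT_METHODS,
    map_size: tuple[int, int] = (16, 16),
    schedule: TrainingSchedule | None = None,
    lvq_schedule: LVQSchedule | None = None,
    seed: int = 0,
    cv_skinet: bool = True,
) -> BenchReport:
    """Evaluate every method on one shared split and shared CV folds.

    ``dataset`` should already be per-spectrum standardised. Returns one
    row per (baseline, n_components) pair plus a single SKiNET row (the
    map consumes all channels; no component count applies).
    """
    partition = partition or PartitionSpec(seed=seed)
    train_idx, test_idx = stratified_partition_indices(dataset, partition)
    train, test = dataset.subset(train_idx), dataset.subset(test_idx)
    folds = stratified_folds(train, partition)
    rows: list[BenchRow] = []

    if "skinet" in methods:
        cv_mean = cv_sd = None
        if cv_skinet:
            accs = []
            for tr, va in folds:
                som = skinet_train(train.subset(tr), *map_size,
                                   schedule=schedule, lvq_schedule=lvq_schedule,
                                   seed=seed)
                fold_val = train.subset(va)
                accs.append(float(np.mean(
                    predict_dataset(som, fold_val) == fold_val.labels)))
            cv_mean, cv_sd = float(np.mean(accs)), float(np.std(accs))
        som = skinet_train(train, *map_size, schedule=schedule,
                           lvq_schedule=lvq_schedule, seed=seed)
        rows.append(BenchRow("skinet", None, cv_mean, cv_sd,
                             evaluate(som, test).accuracy,
                             params={"map": list(map_size)}))

    Xtr, ytr = train.X, train.labels
    Xte, yte = test.X, test.labels
    for method in methods:
        if method == "skinet":
            continue
        comps = [None] if method == "mlp" else list(n_components)
        for n_comp in comps:
            if n_comp is not None and n_comp > min(Xtr.shape[0], Xtr.shape[1]):
                continue
            try:
                best = None
                grid = _GRIDS[method]
                if method == "plsda":
                    grid = [{"pls_components": max(1, min(n_comp,
                                                          dataset.n_classes))}]
                for params in grid:
                    cv_mean, cv_sd = _cv_accuracy(
                        lambda: _make_baseline(method, n_comp, params, seed),
                        Xtr, ytr, folds)
                    if best is None or cv_mean > best[0]:
                        best = (cv_mean, cv_sd, params)
                cv_mean, cv_sd, params = best
                model = _make_baseline(method, n_comp, params, seed)
                model.fit(Xtr, ytr)
                test_acc = float(np.mean(model.predict(Xte) == yte))
                rows.append(BenchRow(method, n_comp, cv_mean, cv_sd,
                                     test_acc, params=params))
            except ImportError as exc:
                rows.append(BenchRow(method, n_comp, None, None, None,
                                     note=f"skipped: {exc}"))
    return BenchReport(rows, train_idx, test_idx, partition)
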