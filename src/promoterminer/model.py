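"""RBF-SVM training, hyperparameter grid search, evaluation metrics and
the train / independent-test harness.

The classifier is a soft-margin SVM with radial-basis kernel; cost C and
kernel width gamma are searched over the 16 powers of two from 2^-7 to
2^8.  Model selection uses stratified 10-fold cross-validation accuracy;
reported metrics are overall accuracy (ACC), sensitivity (SN),
specificity (SP) and the Matthews correlation coefficient (MCC).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import descriptors as desc
from .descriptors import FeatureScaler, N_DESCRIPTORS, featurize
from .kmer import KmerScoreTable
from .seqio import NEGATIVE, POSITIVE, LabeledDataset, NucleotideSequence

#: the hyperparameter grid: 2^-7 .. 2^8, ascending
PARAM_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-7, 9))


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]
                         ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE))),
            tn=int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE))),
            fp=int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE))),
            fn=int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE))),
        )


@dataclass(frozen=True)
class Metrics:
    acc: float
    sn: float
    sp: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "SN": self.sn, "SP": self.sp, "MCC": self.mcc}


def confusion_metrics(counts: ConfusionCounts) -> Metrics:
    """ACC, SN, SP and MCC from confusion counts.

    MCC uses the standard numerator TP*TN - FP*FN and is defined as 0 when
    any marginal is empty (degenerate denominator).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total == 0:
        raise ValueError("cannot compute metrics on zero instances")
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return Metrics(acc, sn, sp, mcc)


# ---------------------------------------------------------------------------
# cross-validation

def _check_two_classes(y: np.ndarray) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")


def make_svc(C: float, gamma: float) -> SVC:
    return SVC(C=C, gamma=gamma, kernel="rbf")


def cv_predictions(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                   folds: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold predictions under seeded stratified k-fold CV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=y.dtype)
    for train_idx, test_idx in skf.split(X, y):
        clf = make_svc(C, gamma)
        clf.fit(X[train_idx], y[train_idx])
        pred[test_idx] = clf.predict(X[test_idx])
    return pred


def cv_accuracy(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                folds: int = 10, seed: int = 0) -> float:
    """Cross-validated accuracy: total correct over all folds divided by n
    (the instance-weighted mean of per-fold accuracies)."""
    pred = cv_predictions(X, y, C, gamma, folds, seed)
    return float(np.mean(pred == np.asarray(y)))


def grid_search(X: np.ndarray, y: np.ndarray, folds: int = 10, seed: int = 0,
                C_grid: Sequence[float] = PARAM_GRID,
                gamma_grid: Sequence[float] = PARAM_GRID
                ) -> tuple[float, float, float]:
    """Exhaustive (C, gamma) search by CV accuracy.

    Ties are broken toward the smaller C, then the smaller gamma.
    """
    _check_two_classes(np.asarray(y))
    best: tuple[float, float, float] | None = None
    for C in C_grid:
        for gamma in gamma_grid:
            acc = cv_accuracy(X, y, C, gamma, folds, seed)
            if best is None or acc > best[2]:
                best = (C, gamma, acc)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# trained model

def baseline_masks() -> dict[str, np.ndarray]:
    """Fixed-subset baselines: the 128 4-mer descriptors (P40..P167) and
    the 36 global sequence descriptors (P4..P39)."""
    kmer_mask = np.zeros(N_DESCRIPTORS, dtype=bool)
    kmer_mask[39:167] = True
    gsd_mask = np.zeros(N_DESCRIPTORS, dtype=bool)
    gsd_mask[3:39] = True
    return {"SVM-4mer": kmer_mask, "SVM-GSD": gsd_mask}


def _as_mask(mask: np.ndarray | Sequence[int], n_features: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.size != n_features:
            raise ValueError(
                f"mask length {mask.size} != feature count {n_features}")
        out = mask
    else:
        out = np.zeros(n_features, dtype=bool)
        out[mask.astype(int)] = True
    if not out.any():
        raise ValueError("feature mask selects no features")
    return out


@dataclass
class TrainedModel:
    """A fitted promoter/non-promoter SVM plus the preprocessing state
    (feature mask, scaler, optional k-mer table) needed to reproduce
    predictions end to end."""

    mask: np.ndarray
    scaler: FeatureScaler
    C: float
    gamma: float
    svc: SVC
    kmer_table: KmerScoreTable | None = None
    metadata: dict = field(default_factory=dict)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict classes from a raw (unscaled) full-width feature matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mask.size:
            raise ValueError(
                f"feature count mismatch: matrix has {X.shape[1]} columns, "
                f"model expects {self.mask.size}")
        Xs = self.scaler.transform(X)
        return self.svc.predict(Xs[:, self.mask])

    def predict_sequences(self, sequences: Sequence[NucleotideSequence]
                          ) -> np.ndarray:
        if self.kmer_table is None:
            raise ValueError(
                "model has no k-mer table attached; featurize externally "
                "and use predict_matrix")
        X, _ = featurize(sequences, self.kmer_table)
        return self.predict_matrix(X)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = dict(self.metadata)
        meta.update({
            "mask": np.flatnonzero(self.mask).tolist(),
            "n_features": int(self.mask.size),
            "C": self.C,
            "gamma": self.gamma,
            "scaler_min": self.scaler.data_min_.tolist(),
            "scaler_max": self.scaler.data_max_.tolist(),
        })
        if self.kmer_table is not None:
            meta["kmer_hash"] = self.kmer_table.content_hash()
            self.kmer_table.to_tsv(directory / "kmer_table.tsv")
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        joblib.dump(self.svc, directory / "svm.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        n = meta["n_features"]
        mask = np.zeros(n, dtype=bool)
        mask[meta["mask"]] = True
        scaler = FeatureScaler()
        scaler.fit(np.vstack([meta["scaler_min"], meta["scaler_max"]]))
        svc = joblib.load(directory / "svm.joblib")
        table = None
        kmer_path = directory / "kmer_table.tsv"
        if kmer_path.exists():
            table = KmerScoreTable.from_tsv(kmer_path)
            if table.content_hash() != meta.get("kmer_hash"):
                raise ValueError(
                    "k-mer table hash mismatch: the stored table is not the "
                    "one this model was trained with")
        return cls(mask, scaler, meta["C"], meta["gamma"], svc,
                   kmer_table=table, metadata=meta)


def train(X: np.ndarray, y: np.ndarray,
          mask: np.ndarray | Sequence[int] | None = None,
          C: float = 1.0, gamma: float = 1.0,
          scaler: FeatureScaler | None = None,
          kmer_table: KmerScoreTable | None = None,
          metadata: dict | None = None) -> TrainedModel:
    """Fit the SVM on the masked, min-max-scaled feature matrix.

    ``X`` is the raw (unscaled) full-width matrix; the scaler is fitted on
    it unless one is supplied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    m = _as_mask(mask if mask is not None else np.ones(X.shape[1], dtype=bool),
                 X.shape[1])
    if scaler is None:
        scaler = FeatureScaler().fit(X)
    Xs = scaler.transform(X)
    svc = make_svc(C, gamma)
    svc.fit(Xs[:, m], y)
    meta = dict(metadata or {})
    meta.setdefault("dataset_hash",
                    hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()[:16])
    return TrainedModel(m, scaler, C, gamma, svc, kmer_table=kmer_table,
                        metadata=meta)


# ---------------------------------------------------------------------------
# evaluation harness

@dataclass
class EvaluationReport:
    train_cv: Metrics
    test: Metrics
    C: float
    gamma: float
    n_train: int
    n_test: int
    mask_size: int

    def to_frame(self):
        import pandas as pd

        rows = [
            {"split": "train-10CV", **self.train_cv.as_dict()},
            {"split": "independent-test", **self.test.as_dict()},
        ]
        return pd.DataFrame(rows)


def stratified_split(y: np.ndarray, train_fraction: float = 0.5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded, class-stratified index split (near-equal per class)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def evaluate_split(dataset: LabeledDataset, train_fraction: float = 0.5,
                   mask: np.ndarray | Sequence[int] | None = None,
                   folds: int = 10, seed: int = 0,
                   C: float | None = None, gamma: float | None = None,
                   C_grid: Sequence[float] = PARAM_GRID,
                   gamma_grid: Sequence[float] = PARAM_GRID
                   ) -> EvaluationReport:
    """Split sequences into training and independent-test halves, fit the
    k-mer table and scaler on the training half only, grid-search (C,
    gamma) unless given, and report CV and held-out metrics."""
    y = np.asarray(dataset.labels)
    train_idx, test_idx = stratified_split(y, train_fraction, seed)
    for name, idx in (("train", train_idx), ("test", test_idx)):
        if np.unique(y[idx]).size < 2:
            raise ValueError(f"{name} split lost a class; adjust fractions")
    train_ds = dataset.subset(train_idx)
    test_ds = dataset.subset(test_idx)

    table = KmerScoreTable.fit(train_ds)
    X_train, _ = featurize(train_ds.sequences, table)
    X_test, _ = featurize(test_ds.sequences, table)
    y_train, y_test = y[train_idx], y[test_idx]

    scaler = FeatureScaler().fit(X_train)
    m = _as_mask(mask if mask is not None
                 else np.ones(X_train.shape[1], dtype=bool), X_train.shape[1])
    Xs_train = scaler.transform(X_train)[:, m]

    if C is None or gamma is None:
        C, gamma, _ = grid_search(Xs_train, y_train, folds, seed,
                                  C_grid, gamma_grid)
    cv_pred = cv_predictions(Xs_train, y_train, C, gamma, folds, seed)
    train_metrics = confusion_metrics(
        ConfusionCounts.from_predictions(y_train, cv_pred))

    fitted = train(X_train, y_train, m, C, gamma, scaler=scaler,
                   kmer_table=table)
    test_pred = fitted.predict_matrix(X_test)
    test_metrics = confusion_metrics(
        ConfusionCounts.from_predictions(y_test, test_pred))

    return EvaluationReport(train_metrics, test_metrics, C, gamma,
                            n_train=len(train_ds), n_test=len(test_ds),
                            mask_size=int(m.sum()))
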