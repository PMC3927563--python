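"""End-to-end workflow: a model object built from a labeled sequence
dataset whose fit() runs featurization, ensemble feature mining, SVM
training and evaluation, and returns a results object carrying the
selected descriptors, hyperparameters, stability diagnostics, metrics,
rules and (optionally) the MED contribution analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import numpy as np

from . import medfa, mining, rules as rules_mod
from .descriptors import FeatureScaler, featurize
from .kmer import KmerScoreTable
from .model import (ConfusionCounts, Metrics, confusion_metrics,
                    cv_predictions, stratified_split, train)
from .seqio import LabeledDataset, NucleotideSequence


@dataclass
class PromoterMiningModel:
    """Promoter/non-promoter classification model over a labeled sequence
    dataset.

    fit() splits the data into training and independent-test halves, fits
    the k-mer score table and the feature scaler on the training half,
    runs R independent GA mining runs, selects the consensus best
    descriptor subset with its (C, gamma), trains the final SVM and
    evaluates it.
    """

    dataset: LabeledDataset
    config: mining.IGAConfig = field(default_factory=mining.IGAConfig)
    n_runs: int = 20
    train_fraction: float = 0.5
    extract_rules: bool = True
    compute_med: bool = False

    @classmethod
    def from_files(cls, fasta_path, labels_path, **kwargs
                   ) -> "PromoterMiningModel":
        from .seqio import make_dataset, read_fasta, read_labels

        seqs = read_fasta(fasta_path)
        labels = read_labels(labels_path)
        return cls(make_dataset(seqs, labels), **kwargs)

    def fit(self) -> "PromoterMiningResults":
        y = np.asarray(self.dataset.labels)
        train_idx, test_idx = stratified_split(
            y, self.train_fraction, self.config.seed)
        train_ds = self.dataset.subset(train_idx)
        test_ds = self.dataset.subset(test_idx)

        table = KmerScoreTable.fit(train_ds)
        X_train, names = featurize(train_ds.sequences, table)
        X_test, _ = featurize(test_ds.sequences, table)
        y_train, y_test = y[train_idx], y[test_idx]
        scaler = FeatureScaler().fit(X_train)
        Xs_train = scaler.transform(X_train)

        ensemble = mining.mine_ensemble(Xs_train, y_train, self.config,
                                        R=self.n_runs)
        best = ensemble.best
        mask = best.mask(X_train.shape[1])

        fitted = train(X_train, y_train, mask, best.C, best.gamma,
                       scaler=scaler, kmer_table=table)
        cv_pred = cv_predictions(Xs_train[:, mask], y_train, best.C,
                                 best.gamma, self.config.cv_folds,
                                 self.config.seed)
        train_cv = confusion_metrics(
            ConfusionCounts.from_predictions(y_train, cv_pred))
        test_pred = fitted.predict_matrix(X_test)
        test_metrics = confusion_metrics(
            ConfusionCounts.from_predictions(y_test, test_pred))

        ruleset = None
        if self.extract_rules:
            sel_names = [names[j] for j in best.selected_indices]
            ruleset = rules_mod.induce_rules(
                Xs_train[:, mask], y_train, sel_names)

        med_report = None
        if self.compute_med and best.m >= 2:
            med_report = medfa.compute_med(
                Xs_train, y_train, mask, feature_names=names,
                config=medfa.MEDConfig(C=best.C, gamma=best.gamma,
                                       seed=self.config.seed))

        return PromoterMiningResults(
            model=fitted, ensemble=ensemble, descriptor_names=names,
            train_cv=train_cv, test=test_metrics, ruleset=ruleset,
            med_report=med_report, n_train=len(train_ds),
            n_test=len(test_ds))


@dataclass
class PromoterMiningResults:
    """Fitted estimates, diagnostics and reports from a mining workflow."""

    model: "object"               # TrainedModel
    ensemble: mining.RunEnsemble
    descriptor_names: list[str]
    train_cv: Metrics
    test: Metrics
    ruleset: rules_mod.RuleSet | None
    med_report: medfa.MEDReport | None
    n_train: int
    n_test: int

    @property
    def selected_descriptors(self) -> list[str]:
        return [self.descriptor_names[j]
                for j in self.ensemble.best.selected_indices]

    def predict(self, sequences: Sequence[NucleotideSequence]) -> np.ndarray:
        return self.model.predict_sequences(sequences)

    def summary(self) -> str:
        best = self.ensemble.best
        out = StringIO()
        w = out.write
        w("Promoter descriptor mining results\n")
        w("==================================\n")
        w(f"training sequences:      {self.n_train}\n")
        w(f"independent test:        {self.n_test}\n")
        w(f"mining runs:             {len(self.ensemble.results)}\n")
        w(f"selected descriptors:    {best.m}\n")
        w(f"(C, gamma):              ({best.C:g}, {best.gamma:g})\n")
        w(f"mining fitness (CV acc): {best.fitness:.3f}\n")
        ratios = ", ".join(f"{r:.2f}" for r in self.ensemble.frequencies.ratios)
        w(f"run ratios (mean {self.ensemble.frequencies.mean_ratio:.2f}): "
          f"{ratios}\n\n")
        w("              ACC     SN      SP      MCC\n")
        t = self.train_cv
        w(f"train CV      {t.acc:.3f}   {t.sn:.3f}   {t.sp:.3f}   {t.mcc:.3f}\n")
        t = self.test
        w(f"test          {t.acc:.3f}   {t.sn:.3f}   {t.sp:.3f}   {t.mcc:.3f}\n\n")
        w("selected descriptors:\n  "
          + ", ".join(self.selected_descriptors) + "\n")
        if self.ruleset is not None and self.ruleset.rules:
            w("\ntop rules:\n")
            for i, rule in enumerate(self.ruleset.rules[:5]):
                w(f"  R{i + 1}: {rule}\n")
        if self.med_report is not None:
            w("\ntop MED contributions (percentage points):\n")
            for _, row in self.med_report.to_frame(top_k=5).iterrows():
                w(f"  {row['descriptor']}: {row['MED']:.1f}\n")
        return out.getvalue()

    def plot_trace(self, ax=None):
        """Best-fitness trace of the consensus best run across generations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ensemble.best.trace)
        ax.set_xlabel("generation (all stages)")
        ax.set_ylabel("best 10-CV accuracy")
        return ax

    def plot_med(self, top_k: int = 20, ax=None):
        """Bar chart of the top MED contributions."""
        import matplotlib.pyplot as plt

        if self.med_report is None:
            raise ValueError("fit with compute_med=True first")
        if ax is None:
            _, ax = plt.subplots()
        df = self.med_report.to_frame(top_k)
        ax.barh(df["descriptor"][::-1], df["MED"][::-1])
        ax.set_xlabel("MED (percentage points of accuracy)")
        return ax
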