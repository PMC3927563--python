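import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from promoterminer.descriptors import featurize
from promoterminer.kmer import KmerScoreTable
from promoterminer.model import (ConfusionCounts, TrainedModel,
                                 baseline_masks, confusion_metrics,
                                 cv_accuracy, evaluate_split, grid_search,
                                 stratified_split, train)
from promoterminer.seqio import LabeledDataset
from promoterminer.synth import SynthConfig, generate_sequences

SMALL_GRID = [2.0 ** e for e in (-3, 0, 3)]


class TestMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics(ConfusionCounts(50, 50, 0, 0))
        assert (m.acc, m.sn, m.sp, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_denominator(self):
        m = confusion_metrics(ConfusionCounts(tp=50, tn=0, fp=50, fn=0))
        assert m.acc == 0.5 and m.sn == 1.0 and m.sp == 0.0 and m.mcc == 0.0

    def test_arithmetic_oracle(self):
        m = confusion_metrics(ConfusionCounts(tp=40, tn=45, fp=5, fn=10))
        assert m.acc == pytest.approx(0.85)
        assert m.sn == pytest.approx(0.8)
        assert m.sp == pytest.approx(0.9)
        assert m.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_mcc_against_sklearn(self):
        """Independent cross-check of the MCC formula on random counts."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            if tp + tn + fp + fn == 0:
                continue
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            ours = confusion_metrics(
                ConfusionCounts(int(tp), int(tn), int(fp), int(fn))).mcc
            assert ours == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-9)

    def test_label_swap_symmetry(self):
        a = confusion_metrics(ConfusionCounts(tp=40, tn=45, fp=5, fn=10))
        b = confusion_metrics(ConfusionCounts(tp=45, tn=40, fp=10, fn=5))
        assert a.sn == b.sp and a.sp == b.sn
        assert a.mcc == pytest.approx(b.mcc)

    def test_mcc_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 20, 4))
            if tp + tn + fp + fn == 0:
                continue
            m = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert -1 <= m.mcc <= 1

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))


class TestGridSearch:
    def test_separable_data(self, separable_matrix):
        X, y = separable_matrix
        C, gamma, acc = grid_search(X, y, folds=5, seed=0,
                                    C_grid=SMALL_GRID, gamma_grid=SMALL_GRID)
        assert acc >= 0.95

    def test_deterministic(self, separable_matrix):
        X, y = separable_matrix
        a = grid_search(X, y, folds=5, seed=1, C_grid=SMALL_GRID,
                        gamma_grid=SMALL_GRID)
        b = grid_search(X, y, folds=5, seed=1, C_grid=SMALL_GRID,
                        gamma_grid=SMALL_GRID)
        assert a == b

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            grid_search(X, np.ones(10, dtype=int))

    def test_cv_accuracy_is_instance_weighted(self, separable_matrix):
        """CV accuracy equals total correct over n (weighted fold mean)."""
        from promoterminer.model import cv_predictions

        X, y = separable_matrix
        pred = cv_predictions(X, y, C=1.0, gamma=1.0, folds=7, seed=0)
        assert cv_accuracy(X, y, 1.0, 1.0, folds=7, seed=0) == \
            pytest.approx(np.mean(pred == y))


class TestBaselineMasks:
    def test_sizes_and_coverage(self):
        masks = baseline_masks()
        assert masks["SVM-4mer"].sum() == 128
        assert masks["SVM-GSD"].sum() == 36
        assert not (masks["SVM-4mer"] & masks["SVM-GSD"]).any()
        union = masks["SVM-4mer"] | masks["SVM-GSD"]
        assert union.sum() == 164  # everything except the 3 physicochemical
        assert not union[:3].any()


class TestTrainPredict:
    def test_training_instances_recovered(self, separable_matrix):
        X, y = separable_matrix
        fitted = train(X, y, C=10.0, gamma=1.0)
        assert np.array_equal(fitted.predict_matrix(X), y)

    def test_empty_mask_rejected(self, separable_matrix):
        X, y = separable_matrix
        with pytest.raises(ValueError):
            train(X, y, mask=np.zeros(X.shape[1], dtype=bool))

    def test_feature_count_mismatch_rejected(self, separable_matrix):
        X, y = separable_matrix
        fitted = train(X, y)
        with pytest.raises(ValueError, match="mismatch"):
            fitted.predict_matrix(X[:, :3])

    def test_sequence_path_equals_matrix_path(self):
        dataset, _ = generate_sequences(SynthConfig(n_pos=20, n_neg=20,
                                                    length=60, seed=9))
        table = KmerScoreTable.fit(dataset)
        X, _ = featurize(dataset.sequences, table)
        y = np.array(dataset.labels)
        fitted = train(X, y, C=1.0, gamma=1.0, kmer_table=table)
        assert np.array_equal(fitted.predict_sequences(dataset.sequences),
                              fitted.predict_matrix(X))

    def test_save_load_roundtrip(self, tmp_path):
        dataset, _ = generate_sequences(SynthConfig(n_pos=15, n_neg=15,
                                                    length=60, seed=2))
        table = KmerScoreTable.fit(dataset)
        X, _ = featurize(dataset.sequences, table)
        y = np.array(dataset.labels)
        fitted = train(X, y, C=1.0, gamma=1.0, kmer_table=table)
        fitted.save(tmp_path / "model")
        back = TrainedModel.load(tmp_path / "model")
        assert np.array_equal(back.predict_matrix(X),
                              fitted.predict_matrix(X))

    def test_tampered_kmer_table_refused(self, tmp_path):
        dataset, _ = generate_sequences(SynthConfig(n_pos=15, n_neg=15,
                                                    length=60, seed=2))
        table = KmerScoreTable.fit(dataset)
        X, _ = featurize(dataset.sequences, table)
        fitted = train(X, np.array(dataset.labels), C=1.0, gamma=1.0,
                       kmer_table=table)
        fitted.save(tmp_path / "model")
        # corrupt one count in the stored table
        p = tmp_path / "model" / "kmer_table.tsv"
        lines = p.read_text().splitlines()
        parts = lines[1].split("\t")
        parts[1] = str(int(parts[1]) + 1)
        lines[1] = "\t".join(parts)
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="hash"):
            TrainedModel.load(tmp_path / "model")


class TestEvaluateSplit:
    def test_partition_is_stratified(self):
        y = np.array([1] * 50 + [0] * 50)
        train_idx, test_idx = stratified_split(y, 0.5, seed=0)
        assert len(train_idx) == len(test_idx) == 50
        assert abs(y[train_idx].sum() - 25) <= 1
        assert len(set(train_idx) & set(test_idx)) == 0

    def test_no_gross_overfit_on_planted_signal(self):
        # a strong planted signal: both halves should score high and agree
        dataset, _ = generate_sequences(
            SynthConfig(n_pos=100, n_neg=100, seed=7, leading_A_boost=0.5,
                        gc_pos=0.60, gc_neg=0.45))
        report = evaluate_split(dataset, folds=5, seed=0,
                                C_grid=SMALL_GRID, gamma_grid=SMALL_GRID)
        assert report.train_cv.acc >= 0.9
        assert abs(report.test.acc - report.train_cv.acc) <= 0.05
        assert report.n_train == report.n_test == 100

    def test_lost_class_rejected(self):
        dataset, _ = generate_sequences(
            SynthConfig(n_pos=4, n_neg=0, length=20, seed=1))
        with pytest.raises(ValueError):
            evaluate_split(dataset)
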