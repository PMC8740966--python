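import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irchemo.chemometrics import (
    SplitConfig,
    SVMConfig,
    evaluate_classifier,
    fit_pca,
    fit_pca_lda,
    metrics_from_confusion,
    split_train_test,
    tune_train_svm,
    venetian_blinds_folds,
)
from irchemo.preprocess import mean_center, preprocess_chain
from irchemo.spectra_io import SpectrumSet
from irchemo.synthetic import (
    SimulationConfig,
    build_class_library,
    simulate_spectrum_set,
)

from conftest import make_meta


def brute_force_metrics(cm):
    """Independent one-vs-rest oracle: count TP/FN/FP/TN cell by cell."""
    cm = np.asarray(cm)
    n = cm.sum()
    out = []
    for c in range(cm.shape[0]):
        tp = fn = fp = tn = 0
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1]):
                if i == c and j == c:
                    tp += cm[i, j]
                elif i == c:
                    fn += cm[i, j]
                elif j == c:
                    fp += cm[i, j]
                else:
                    tn += cm[i, j]
        out.append({
            "accuracy": (tp + tn) / n * 100,
            "sensitivity": tp / (tp + fn) * 100 if tp + fn else np.nan,
            "specificity": tn / (tn + fp) * 100 if tn + fp else np.nan,
        })
    return out


def _labelled_set(n_per_class, classes, n_points=30, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_class * len(classes)
    wn = 2000.0 - 4.0 * np.arange(n_points)
    meta = make_meta([f"s{i:03d}" for i in range(n)],
                     plant_type=np.repeat(classes, n_per_class))
    return SpectrumSet(wn, rng.normal(size=(n, n_points)), meta)


class TestSplit:
    def test_1580_at_70_30_gives_1106_and_474(self):
        sset = _labelled_set(395, ["a", "b", "c", "d"])
        train, test = split_train_test(sset, SplitConfig(seed=5))
        assert train.n_spectra == 1106
        assert test.n_spectra == 474

    def test_same_seed_same_partition(self):
        sset = _labelled_set(5, ["a", "b"])
        cfg = SplitConfig(train_fraction=0.5, seed=9)
        t1, _ = split_train_test(sset, cfg)
        t2, _ = split_train_test(sset, cfg)
        assert t1.spectrum_ids == t2.spectrum_ids

    def test_different_seed_different_partition(self):
        sset = _labelled_set(50, ["a", "b"])
        t1, _ = split_train_test(sset, SplitConfig(seed=0))
        t2, _ = split_train_test(sset, SplitConfig(seed=1))
        assert t1.spectrum_ids != t2.spectrum_ids

    def test_stratified_four_classes_of_ten_split_7_3(self):
        sset = _labelled_set(10, ["a", "b", "c", "d"])
        train, test = split_train_test(sset, SplitConfig(seed=2))
        for counts, expected in ((train, 7), (test, 3)):
            tally = pd.Series(counts.labels()).value_counts()
            assert set(tally) == {expected}

    def test_partition_is_disjoint_and_complete(self):
        sset = _labelled_set(13, ["a", "b", "c"])
        train, test = split_train_test(sset, SplitConfig(seed=3))
        ids = set(train.spectrum_ids) | set(test.spectrum_ids)
        assert len(ids) == sset.n_spectra
        assert not set(train.spectrum_ids) & set(test.spectrum_ids)

    def test_singleton_class_rejected_with_hint(self):
        sset = _labelled_set(1, ["solo"], seed=1)
        two = _labelled_set(4, ["other"], seed=2)
        meta = pd.concat([sset.meta, two.meta], ignore_index=True)
        meta["spectrum_id"] = [f"m{i}" for i in range(len(meta))]
        merged = SpectrumSet(
            sset.wavenumbers,
            np.vstack([sset.absorbance, two.absorbance]),
            meta,
        )
        with pytest.raises(ValueError, match="stratified=False"):
            split_train_test(merged, SplitConfig(seed=0))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitConfig(train_fraction=1.0)


class TestVenetianBlinds:
    def test_definition_n5_k2(self):
        np.testing.assert_array_equal(venetian_blinds_folds(5, 2),
                                      [0, 1, 0, 1, 0])

    def test_positions_0_and_10_share_fold(self):
        folds = venetian_blinds_folds(20, 10)
        assert folds[0] == folds[10]

    def test_fold_sizes_n23_k10(self):
        # exhaustive count: 23 = 2*10 + 3 -> three folds of 3, seven of 2
        folds = venetian_blinds_folds(23, 10)
        sizes = sorted(np.bincount(folds).tolist())
        assert sizes == [2] * 7 + [3] * 3

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            venetian_blinds_folds(3, 10)

    @given(n=st.integers(2, 200), k=st.integers(2, 20))
    @settings(max_examples=50, deadline=None)
    def test_folds_deterministic_and_nonempty(self, n, k):
        if k > n:
            return
        a = venetian_blinds_folds(n, k)
        b = venetian_blinds_folds(n, k)
        np.testing.assert_array_equal(a, b)
        assert len(np.unique(a)) == k


class TestPCA:
    def test_points_on_line_give_pc1_everything(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t + 1.0])
        res = fit_pca(X, 1)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(0).normal(size=(30, 50))
        res = fit_pca(X, 10)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)

    def test_scores_equal_centered_projection(self):
        X = np.random.default_rng(1).normal(size=(25, 12))
        res = fit_pca(X, 5)
        np.testing.assert_allclose(
            res.scores, (X - res.column_means) @ res.loadings, atol=1e-8)

    def test_explained_variance_non_increasing(self):
        X = np.random.default_rng(2).normal(size=(40, 8))
        res = fit_pca(X, 8)
        evf = res.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12)
        assert evf.sum() <= 1.0 + 1e-9

    def test_over_rank_request_truncates_with_warning(self):
        X = np.random.default_rng(3).normal(size=(4, 10))
        with pytest.warns(UserWarning, match="truncating"):
            res = fit_pca(X, 10)
        assert res.loadings.shape[1] == 3

    def test_reconstruction_error_non_increasing_in_k(self):
        X = np.random.default_rng(4).normal(size=(20, 10))
        errors = []
        for k in (1, 3, 5, 8):
            res = fit_pca(X, k)
            recon = res.scores @ res.loadings.T + res.column_means
            errors.append(np.linalg.norm(X - recon))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))


class TestPCALDA:
    def test_separable_classes_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 5)),
                       rng.normal(10, 0.1, (10, 5))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_pca_lda(X, y, n_pcs=3)
        assert (model.predict(X) == y).all()

    def test_prediction_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 8))
        y = np.array(["a", "b", "c"] * 10)
        model = fit_pca_lda(X, y, n_pcs=4)
        perm = rng.permutation(30)
        np.testing.assert_array_equal(model.predict(X)[perm],
                                      model.predict(X[perm]))

    def test_discriminant_axes_at_most_classes_minus_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 10))
        y = np.array(["a", "b", "c", "d"] * 10)
        model = fit_pca_lda(X, y, n_pcs=6)
        assert model.transform(X).shape[1] <= 3

    def test_single_class_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError, match="2 classes"):
            fit_pca_lda(X, ["a"] * 5, n_pcs=2)


class TestSVM:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.3, (20, 4)),
                       rng.normal(5, 0.3, (20, 4))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        # interleave classes so venetian folds are stratified-ish
        idx = np.arange(40).reshape(2, 20).T.ravel()
        return X[idx], y[idx]

    def test_single_grid_point_chosen_without_search(self):
        X, y = self._separable()
        cfg = SVMConfig(cost_grid=[7.0], gamma_grid=[0.3], cv_splits=5)
        model = tune_train_svm(X, y, cfg)
        assert model.cost == 7.0 and model.gamma == 0.3

    def test_tie_broken_toward_smaller_cost_then_gamma(self):
        X, y = self._separable()
        cfg = SVMConfig(cost_grid=[100.0, 1.0], gamma_grid=[0.5, 0.05],
                        cv_splits=5)
        model = tune_train_svm(X, y, cfg)
        # separable data: every pair scores 100%; smallest pair must win
        assert model.cv_accuracy == 1.0
        assert model.cost == 1.0 and model.gamma == 0.05

    def test_separable_data_reaches_perfect_cv(self):
        X, y = self._separable(3)
        model = tune_train_svm(X, y, SVMConfig(cost_grid=[1.0, 10.0],
                                               gamma_grid=[0.1, 1.0],
                                               cv_splits=10))
        assert model.cv_accuracy == 1.0
        # verify with a direct refit score
        assert (model.predict(X) == y).all()

    def test_support_vector_count_bounded(self):
        X, y = self._separable(4)
        model = tune_train_svm(X, y, SVMConfig(cost_grid=[1.0],
                                               gamma_grid=[0.1], cv_splits=5))
        assert 0 < model.support_vector_count <= len(y)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SVMConfig(cost_grid=[])


class TestMetrics:
    def test_perfect_predictions_all_100(self):
        cm = np.diag([5, 7, 3])
        m = metrics_from_confusion(cm, ["a", "b", "c"])
        assert m.macro_accuracy == 100.0
        assert m.macro_sensitivity == 100.0
        assert m.macro_specificity == 100.0

    def test_fully_misassigned_class_scores_zero_sensitivity(self):
        cm = np.array([[0, 5], [0, 9]])
        m = metrics_from_confusion(cm, ["lost", "kept"])
        row = m.per_class.set_index("class")
        assert row.loc["lost", "sensitivity"] == 0.0

    def test_example_confusion_matches_brute_force(self):
        cm = [[2, 1, 1], [0, 4, 0], [1, 0, 3]]
        m = metrics_from_confusion(cm, ["a", "b", "c"])
        oracle = brute_force_metrics(cm)
        for rec, exp in zip(m.per_class.to_dict("records"), oracle):
            for key in ("accuracy", "sensitivity", "specificity"):
                assert rec[key] == pytest.approx(exp[key])

    @given(st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_random_confusions_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        cm = rng.integers(0, 9, size=(k, k))
        cm[np.arange(k), np.arange(k)] += 1  # every class has members
        m = metrics_from_confusion(cm, list("abcdef"[:k]))
        oracle = brute_force_metrics(cm)
        for rec, exp in zip(m.per_class.to_dict("records"), oracle):
            for key in ("accuracy", "sensitivity", "specificity"):
                assert rec[key] == pytest.approx(exp[key])
        assert m.macro_accuracy == pytest.approx(
            np.mean([e["accuracy"] for e in oracle]))

    def test_two_class_sensitivity_specificity_duality(self):
        cm = np.array([[8, 2], [3, 7]])
        m = metrics_from_confusion(cm, ["a", "b"])
        row = m.per_class.set_index("class")
        assert row.loc["a", "sensitivity"] == pytest.approx(
            row.loc["b", "specificity"])

    def test_macro_consistent_with_attached_confusion(self):
        rng = np.random.default_rng(8)
        cm = rng.integers(1, 10, size=(4, 4))
        m = metrics_from_confusion(cm, list("abcd"))
        m2 = metrics_from_confusion(m.confusion, m.classes)
        assert m.macro_accuracy == m2.macro_accuracy
        assert m.macro_sensitivity == m2.macro_sensitivity

    def test_absent_class_excluded_with_warning(self):
        cm = np.array([[5, 0, 0], [1, 4, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="no test members"):
            m = metrics_from_confusion(cm, ["a", "b", "ghost"])
        assert np.isnan(
            m.per_class.set_index("class").loc["ghost", "sensitivity"])
        assert not np.isnan(m.macro_sensitivity)

    def test_table_has_average_row(self):
        frame = metrics_from_confusion(np.diag([3, 4]), ["a", "b"]).to_frame()
        assert frame.iloc[-1]["class"] == "Average"


class TestEndToEnd:
    def test_svm_beats_or_matches_pcalda_above_chance(self):
        # moderate overlap: SVM >= PCA-LDA >= chance across seeds
        wins = []
        for seed in range(5):
            lib = build_class_library(3, 3, seed=seed, overlap=1 / 3,
                                      min_spacing=30.0)
            cfg = SimulationConfig(seed=seed, n_samples_per_class=3,
                                   replicates_per_surface=4, noise_sd=0.02,
                                   thickness_sigma=0.2)
            sset = preprocess_chain(simulate_spectrum_set(lib, cfg))
            train, test = split_train_test(sset, SplitConfig(seed=seed))
            x_tr, x_te, _ = mean_center(train.absorbance, test.absorbance)
            svm = tune_train_svm(x_tr, train.labels(),
                                 SVMConfig(cost_grid=[1, 10, 100],
                                           gamma_grid=[0.1, 1, 10],
                                           cv_splits=10))
            lda = fit_pca_lda(x_tr, train.labels(), n_pcs=10)
            svm_acc = (svm.predict(x_te) == test.labels()).mean()
            lda_acc = (lda.predict(x_te) == test.labels()).mean()
            assert svm_acc > 1 / 3 and lda_acc > 1 / 3
            wins.append(svm_acc >= lda_acc)
        assert sum(wins) >= 3

    def test_training_artifacts_independent_of_test_permutation(self):
        lib = build_class_library(2, 2, seed=0, min_spacing=30.0)
        cfg = SimulationConfig(seed=0, n_samples_per_class=3,
                               replicates_per_surface=3)
        sset = preprocess_chain(simulate_spectrum_set(lib, cfg))
        train, test = split_train_test(sset, SplitConfig(seed=0))
        rng = np.random.default_rng(1)
        perm = rng.permutation(test.n_spectra)
        _, _, means1 = mean_center(train.absorbance, test.absorbance)
        _, _, means2 = mean_center(train.absorbance, test.absorbance[perm])
        np.testing.assert_array_equal(means1, means2)

    def test_evaluate_classifier_on_spectrum_sets(self):
        lib = build_class_library(2, 2, seed=1, min_spacing=30.0)
        cfg = SimulationConfig(seed=1, n_samples_per_class=3,
                               replicates_per_surface=3)
        sset = preprocess_chain(simulate_spectrum_set(lib, cfg))
        train, test = split_train_test(sset, SplitConfig(seed=1))
        x_tr, x_te, _ = mean_center(train.absorbance, test.absorbance)
        model = tune_train_svm(x_tr, train.labels(),
                               SVMConfig(cost_grid=[10.0], gamma_grid=[1.0],
                                         cv_splits=5))
        metrics = evaluate_classifier(model, x_te, test.labels())
        assert metrics.confusion.sum() == test.n_spectra
        assert 0.0 <= metrics.macro_accuracy <= 100.0
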