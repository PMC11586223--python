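"""Splitting schemes, model training, cross-validation, evaluation metrics,
and the directional sample-vs-spectra generalisation properties."""

from __future__ import annotations

import numpy as np
import pytest

from ramanbarrier.chemometrics import (
    FeatureTable,
    build_feature_table,
    extract_candidate_peaks,
    fit_pca,
    rank_features,
    select_components,
)
from ramanbarrier.classify import (
    MODEL_FAMILIES,
    ModelSpec,
    SplitPlan,
    compute_metrics,
    cross_validate,
    cv_folds,
    evaluate,
    split_sample_based,
    split_spectra_based,
    train_model,
)
from ramanbarrier.experiment import ExperimentConfig, run_experiment
from ramanbarrier.prep import preprocess_dataset
from ramanbarrier.spectra import CLASSES
from ramanbarrier.synth import GeneratorParams, StudyDesign, generate_dataset


def _toy_ft(n_per_class=30, seed=0, n_classes=2, sep=4.0):
    g = np.random.default_rng(seed)
    labels = np.array(
        [c for c in "ABCD"[:n_classes] for _ in range(n_per_class)], dtype=object
    )
    centers = {c: i * sep for i, c in enumerate("ABCD"[:n_classes])}
    x = np.column_stack(
        [
            np.array([centers[c] for c in labels]) + g.normal(0, 0.2, labels.size),
            g.normal(0, 1.0, labels.size),
        ]
    )
    return FeatureTable(
        matrix=x,
        feature_wavenumbers=np.array([600.0, 700.0]),
        labels=labels,
        membrane_ids=np.array([None] * labels.size, dtype=object),
    )


class TestSplitSpectraBased:
    def test_default_design_counts(self, default_dataset):
        """220 spectra split 80/20 per class: 176 train / 44 test."""
        plan = split_spectra_based(default_dataset, seed=0)
        assert plan.train_ids.size == 176
        assert plan.test_ids.size == 44
        labels = np.array([s.label for s in default_dataset], dtype=object)
        for cls, n_test in (("T0", 12), ("T2", 12), ("T4", 12), ("BLANK", 8)):
            assert np.sum(labels[plan.test_ids] == cls) == n_test

    def test_disjoint_and_covering(self, default_dataset):
        plan = split_spectra_based(default_dataset, seed=5)
        ids = np.concatenate([plan.train_ids, plan.test_ids])
        assert np.array_equal(np.sort(ids), np.arange(len(default_dataset)))

    def test_seed_reproducibility(self, default_dataset):
        a = split_spectra_based(default_dataset, seed=7)
        b = split_spectra_based(default_dataset, seed=7)
        np.testing.assert_array_equal(a.train_ids, b.train_ids)
        np.testing.assert_array_equal(a.test_ids, b.test_ids)

    def test_two_spectrum_class_half_split(self, clean_params):
        design = StudyDesign(n_membranes=1, n_spots_per_timepoint=2,
                             n_blank_spectra=2, grid=(500.0, 2000.0, 10.0))
        ds = generate_dataset(design, clean_params, seed=0)
        plan = split_spectra_based(ds, train_fraction=0.5, seed=0)
        labels = np.array([s.label for s in ds], dtype=object)
        for cls in CLASSES:
            assert np.sum(labels[plan.test_ids] == cls) == 1

    def test_fraction_validation(self, default_dataset):
        with pytest.raises(ValueError):
            split_spectra_based(default_dataset, train_fraction=1.0)


class TestSplitSampleBased:
    def test_holds_out_whole_membrane(self, default_dataset):
        """Holding out one of three membranes: 160 train (120 treated + 40
        blank) vs 60 never-seen test spectra, no blanks in test."""
        plan = split_sample_based(default_dataset, "M3")
        assert plan.train_ids.size == 160
        assert plan.test_ids.size == 60
        test = [default_dataset[i] for i in plan.test_ids]
        assert all(s.membrane_id == "M3" for s in test)
        assert all(s.label != "BLANK" for s in test)
        train_membranes = {
            default_dataset[i].membrane_id for i in plan.train_ids
        } - {None}
        assert "M3" not in train_membranes

    def test_rotating_holdout_partitions_treated_spectra(self, default_dataset):
        seen = []
        for m in ("M1", "M2", "M3"):
            plan = split_sample_based(default_dataset, m)
            seen.extend(plan.test_ids.tolist())
        treated = [i for i, s in enumerate(default_dataset) if s.label != "BLANK"]
        assert sorted(seen) == treated

    def test_unknown_membrane_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="unknown membrane"):
            split_sample_based(default_dataset, "M9")

    def test_plan_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(
                train_ids=np.array([0, 1]), test_ids=np.array([1, 2]),
                scheme="spectra_based",
            )


class TestTrainModel:
    @pytest.mark.parametrize("family", MODEL_FAMILIES)
    def test_separable_toy_trains_perfectly(self, family):
        ft = _toy_ft(n_per_class=30, seed=1)
        model = train_model(ft, ModelSpec(family), seed=0)
        assert np.mean(model.predict(ft.matrix) == ft.labels.astype(str)) == 1.0

    def test_label_permutation_gives_chance_cv(self):
        """Shuffled labels leave nothing to learn: CV accuracy sits near
        1/n_classes."""
        ft = _toy_ft(n_per_class=30, seed=2)
        g = np.random.default_rng(0)
        accs = []
        for _ in range(20):
            perm = g.permutation(ft.labels.size)
            shuffled = FeatureTable(
                matrix=ft.matrix, feature_wavenumbers=ft.feature_wavenumbers,
                labels=ft.labels[perm], membrane_ids=ft.membrane_ids,
            )
            accs.append(
                cross_validate(shuffled, ModelSpec("qSVM"), k=10, seed=0).mean_accuracy
            )
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_retrain_deterministic(self):
        ft = _toy_ft(n_per_class=20, seed=3, n_classes=3)
        probe = np.random.default_rng(1).normal(0, 3, (30, 2))
        for family in MODEL_FAMILIES:
            a = train_model(ft, ModelSpec(family), seed=4).predict(probe)
            b = train_model(ft, ModelSpec(family), seed=4).predict(probe)
            np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        mono = FeatureTable(
            matrix=np.ones((6, 2)),
            feature_wavenumbers=np.array([600.0, 700.0]),
            labels=np.array(["A"] * 6, dtype=object),
            membrane_ids=np.array([None] * 6, dtype=object),
        )
        with pytest.raises(ValueError):
            train_model(mono, ModelSpec("qSVM"))


class TestCrossValidate:
    def test_leave_one_out_on_four_rows(self):
        """k equal to the row count degenerates to leave-one-out."""
        folds = cv_folds(np.array(["A", "A", "B", "B"]), k=4, seed=0)
        assert len(folds) == 4
        assert all(te.size == 1 for _, te in folds)

    def test_perfect_separation_scores_one(self):
        ft = _toy_ft(n_per_class=20, seed=5)
        cv = cross_validate(ft, ModelSpec("qSVM"), k=10, seed=0)
        assert cv.mean_accuracy == 1.0
        assert cv.fold_accuracies.size == 10

    def test_folds_depend_only_on_labels_and_seed(self):
        labels = np.array(["A"] * 12 + ["B"] * 12)
        a = cv_folds(labels, 4, seed=3)
        b = cv_folds(labels.copy(), 4, seed=3)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tra, trb)
            np.testing.assert_array_equal(tea, teb)

    def test_fold_reduction_warns(self):
        ft = _toy_ft(n_per_class=4, seed=6)  # 8 rows, rarest class 4 < k
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_validate(ft, ModelSpec("qSVM"), k=6, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(_toy_ft(), ModelSpec("qSVM"), k=1)


class TestMetrics:
    def test_binary_confusion_arithmetic(self):
        m = compute_metrics(np.array([[9, 1], [2, 8]]), classes=("P", "N"))
        assert m.accuracy == pytest.approx(0.85)
        assert m.precision == pytest.approx((9 / 11 + 8 / 9) / 2)
        assert m.sensitivity == pytest.approx((9 / 10 + 8 / 10) / 2)

    @pytest.mark.parametrize("size", [2, 3, 4])
    def test_identity_confusion_all_ones(self, size):
        m = compute_metrics(np.eye(size) * 5, classes=CLASSES[:size])
        for name in ("accuracy", "specificity", "precision", "sensitivity", "f1"):
            assert getattr(m, name) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((4, 4)))

    def test_absent_class_excluded_from_macro(self):
        """A class with no true instances keeps a zero row and does not
        enter the macro averages."""
        cm = np.zeros((4, 4))
        cm[0, 0] = cm[1, 1] = cm[2, 2] = 10
        m = compute_metrics(cm)
        assert m.per_class["BLANK"] is None
        assert m.accuracy == 1.0
        assert m.sensitivity == 1.0


class TestEvaluate:
    def test_perfect_predictions(self):
        ft = _toy_ft(n_per_class=5, seed=7)
        relabeled = FeatureTable(
            matrix=ft.matrix, feature_wavenumbers=ft.feature_wavenumbers,
            labels=np.array(
                ["T0"] * 5 + ["T2"] * 5, dtype=object
            ),
            membrane_ids=ft.membrane_ids,
        )
        model = train_model(relabeled, ModelSpec("qSVM"))
        report = evaluate(model, relabeled)
        assert report.metrics.accuracy == 1.0
        assert np.trace(report.confusion) == 10

    def test_blank_row_zero_when_absent(self, small_preprocessed):
        """Sample-based test sets contain no blank spectra: the blank row of
        the test confusion stays empty and is flagged."""
        plan = split_sample_based(small_preprocessed, "M2")
        pca = fit_pca([small_preprocessed[i] for i in plan.train_ids])
        cands = extract_candidate_peaks(pca, select_components(pca, 0.99), 30)
        ft = build_feature_table(small_preprocessed, cands)
        ranked = rank_features(ft.subset_rows(plan.train_ids))
        chosen = ranked.order[:10]
        model = train_model(
            ft.subset_rows(plan.train_ids).subset_features(chosen), ModelSpec("qSVM")
        )
        report = evaluate(model, ft.subset_rows(plan.test_ids).subset_features(chosen))
        blank_row = report.confusion[CLASSES.index("BLANK")]
        assert np.all(blank_row == 0)
        assert "BLANK" in report.absent_classes
        assert report.metrics.per_class["BLANK"] is None

    def test_constant_predictor_on_balanced_four_class(self):
        class _Always:
            def predict(self, x):
                return np.array(["T0"] * len(x))

        ft = FeatureTable(
            matrix=np.zeros((20, 1)),
            feature_wavenumbers=np.array([600.0]),
            labels=np.array([c for c in CLASSES for _ in range(5)], dtype=object),
            membrane_ids=np.array([None] * 20, dtype=object),
        )
        report = evaluate(_Always(), ft)
        assert report.metrics.accuracy == 0.25


class TestGeneralisationProperties:
    """Directional analogues of the study's headline findings."""

    N_SEEDS = 20

    @pytest.fixture(scope="class")
    def scheme_accuracies(self, small_design):
        spectra_acc, sample_acc, confusions = [], [], []
        cfg_common = dict(design=small_design, feature_count=13,
                          families=("qSVM",), cv_folds=5)
        for seed in range(self.N_SEEDS):
            pre = preprocess_dataset(
                generate_dataset(small_design, GeneratorParams(), seed=seed)
            )
            r1 = run_experiment(
                ExperimentConfig(scheme="spectra_based", seed=seed, **cfg_common),
                preprocessed_dataset=pre,
            )
            r2 = run_experiment(
                ExperimentConfig(scheme="sample_based", seed=seed,
                                 held_out_membrane=f"M{seed % 3 + 1}", **cfg_common),
                preprocessed_dataset=pre,
            )
            spectra_acc.append(r1.payload["models"]["qSVM"]["test_accuracy"])
            sample_acc.append(r2.payload["models"]["qSVM"]["test_accuracy"])
            confusions.append(np.array(r2.payload["models"]["qSVM"]["confusion"]))
        return np.array(spectra_acc), np.array(sample_acc), np.array(confusions)

    def test_sample_based_harder_than_spectra_based(self, scheme_accuracies):
        """With membrane batch effects on, testing on a never-seen membrane
        is at most as accurate as spectrum-level splitting, on average."""
        spectra_acc, sample_acc, _ = scheme_accuracies
        assert sample_acc.mean() <= spectra_acc.mean()

    def test_dominant_confusion_is_heavy_damage_vs_blank(self, scheme_accuracies):
        """Hole spots make heavily damaged epithelium look like bare
        membrane: the largest off-diagonal mass of the aggregate sample-based
        test confusion sits in the damaged-vs-blank cell."""
        _, _, confusions = scheme_accuracies
        total = confusions.sum(axis=0)
        off = total - np.diag(np.diag(total))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        assert (CLASSES[i], CLASSES[j]) == ("T4", "BLANK")
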