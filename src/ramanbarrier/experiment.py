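"""End-to-end experiment driver.

Simulate (or load) a labelled Raman dataset, preprocess it, derive
PCA-loading candidate wavenumbers and an SVM-weight feature ranking from the
*training* portion, pick the optimal feature count by cross-validation,
train the three model families and evaluate them on the held-out portion.

By default every data-dependent choice (PCA, candidate extraction, ranking,
feature-count search, standardisation) sees training rows only, so the test
set measures generalisation honestly.  ``pooled_selection=True`` instead runs PCA
and ranking on all spectra — the protocol many chemometrics studies report —
at the cost of information leaking from the test rows into feature
selection; the report records which mode produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemometrics as chem
from .classify import (
    MODEL_FAMILIES,
    ModelSpec,
    SplitPlan,
    cross_validate,
    evaluate,
    split_sample_based,
    split_spectra_based,
    train_model,
)
from .prep import PrepConfig, preprocess_dataset
from .spectra import RamanSpectrum
from .synth import GeneratorParams, StudyDesign, generate_dataset


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one classification experiment."""

    design: StudyDesign = field(default_factory=StudyDesign)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    prep: PrepConfig = field(default_factory=PrepConfig)
    variance_threshold: float = 0.99
    n_per_pc: int = 30
    ranking_box_constraint: float = 10.0
    plateau_tolerance: float = 0.005
    max_features: int | None = None
    feature_count: int | None = None  # fixed k; skips the plateau search
    families: tuple[str, ...] = MODEL_FAMILIES
    scheme: str = "spectra_based"
    held_out_membrane: str = "M3"
    train_fraction: float = 0.8
    cv_folds: int = 10
    seed: int = 0
    pooled_selection: bool = False


@dataclass
class RunReport:
    """Serialisable payload plus in-memory artifacts of one run."""

    payload: dict
    artifacts: dict


def _split(dataset: list[RamanSpectrum], config: ExperimentConfig) -> SplitPlan:
    if config.scheme == "spectra_based":
        return split_spectra_based(dataset, config.train_fraction, config.seed)
    if config.scheme == "sample_based":
        return split_sample_based(dataset, config.held_out_membrane)
    raise ValueError(f"unknown scheme {config.scheme!r}")


def run_experiment(
    config: ExperimentConfig | None = None,
    dataset: list[RamanSpectrum] | None = None,
    preprocessed_dataset: list[RamanSpectrum] | None = None,
) -> RunReport:
    """Run the full protocol; returns the report and its artifacts.

    Pass ``dataset`` to analyse measured (raw) spectra instead of
    simulating, or ``preprocessed_dataset`` to skip the cleaning stage
    (e.g. when comparing split schemes on one already-cleaned dataset).
    """
    config = config or ExperimentConfig()
    if preprocessed_dataset is not None:
        dataset = preprocessed_dataset
        pre = preprocessed_dataset
    else:
        if dataset is None:
            dataset = generate_dataset(config.design, config.generator, config.seed)
        pre = preprocess_dataset(dataset, config.prep)
    plan = _split(pre, config)

    fit_rows = np.arange(len(pre)) if config.pooled_selection else plan.train_ids
    pca = chem.fit_pca([pre[i] for i in fit_rows])
    components = chem.select_components(pca, config.variance_threshold)
    candidates = chem.extract_candidate_peaks(pca, components, config.n_per_pc)

    ft = chem.build_feature_table(pre, candidates)
    ft_train = ft.subset_rows(plan.train_ids)
    ft_test = ft.subset_rows(plan.test_ids)
    rank_ft = ft if config.pooled_selection else ft_train
    ranked = chem.rank_features(rank_ft, config.ranking_box_constraint)

    qsvm_factory = ModelSpec("qSVM").build
    if config.feature_count is not None:
        k_opt = int(config.feature_count)
        curve = None
    else:
        subset = chem.select_feature_count(
            ranked, rank_ft, qsvm_factory,
            cv_folds=config.cv_folds, seed=config.seed,
            tolerance=config.plateau_tolerance, max_features=config.max_features,
        )
        k_opt, curve = subset.k, subset.curve
    chosen = ranked.order[:k_opt]
    ft_train_k = ft_train.subset_features(chosen)
    ft_test_k = ft_test.subset_features(chosen)

    models: dict = {}
    model_payload: dict = {}
    for family in config.families:
        spec = ModelSpec(family)
        cv = cross_validate(ft_train_k, spec, k=config.cv_folds, seed=config.seed)
        model = train_model(ft_train_k, spec, seed=config.seed)
        train_acc = float(
            np.mean(model.predict(ft_train_k.matrix) == ft_train_k.labels.astype(str))
        )
        report = evaluate(model, ft_test_k)
        models[family] = model
        model_payload[family] = {
            "cv_accuracy": cv.mean_accuracy,
            "cv_fold_accuracies": cv.fold_accuracies,
            "train_accuracy": train_acc,
            "test_accuracy": report.metrics.accuracy,
            "specificity": report.metrics.specificity,
            "precision": report.metrics.precision,
            "sensitivity": report.metrics.sensitivity,
            "f1": report.metrics.f1,
            "confusion": report.confusion,
            "confusion_row_normalized": report.confusion_row_normalized,
            "absent_classes": report.absent_classes,
        }

    payload = {
        "scheme": config.scheme,
        "seed": config.seed,
        "pooled_selection": config.pooled_selection,
        "n_spectra": len(pre),
        "n_train": int(plan.train_ids.size),
        "n_test": int(plan.test_ids.size),
        "held_out_membrane": plan.held_out_membrane,
        "n_components": len(components),
        "n_candidate_wavenumbers": int(candidates.size),
        "optimal_feature_count": k_opt,
        "selected_wavenumbers": chosen,
        "cv_curve": curve,
        "models": model_payload,
    }
    artifacts = {
        "dataset": dataset,
        "preprocessed": pre,
        "plan": plan,
        "pca": pca,
        "candidates": candidates,
        "ranked": ranked,
        "feature_table": ft,
        "models": models,
    }
    return RunReport(payload=payload, artifacts=artifacts)
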