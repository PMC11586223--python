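"""Chemometric feature engineering: PCA over preprocessed spectra,
loading-based candidate wavenumber extraction, linear-SVM weight ranking and
optimal-feature-count search.

The workflow mirrors standard chemometrics practice for spectral
classification: decompose the (mean-centred, unscaled) spectra with PCA,
keep the leading components up to a cumulative explained-variance threshold,
collect the channels carrying the heaviest |loading| on each kept component
as candidate predictors, rank them by aggregated absolute weights of
one-vs-all linear SVMs, and grow the feature set along the ranking until
cross-validated accuracy plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .spectra import RamanSpectrum


def dataset_matrix(dataset: list[RamanSpectrum]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset sharing one grid into (X, wavenumbers)."""
    if len(dataset) < 1:
        raise ValueError("empty dataset")
    wn = dataset[0].wavenumbers
    for s in dataset[1:]:
        if s.wavenumbers.shape != wn.shape or not np.allclose(s.wavenumbers, wn):
            raise ValueError("spectra are not on a common wavenumber grid")
    return np.vstack([s.intensities for s in dataset]), wn


@dataclass
class PCAResult:
    """PCA decomposition of a spectral dataset.

    ``loadings`` rows are unit-norm; each row's largest-|loading| element is
    made positive so the decomposition is sign-deterministic.  ``degenerate``
    flags a dataset with (numerically) zero total variance.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    wavenumbers: np.ndarray
    degenerate: bool = False

    def reconstruct(self) -> np.ndarray:
        """Back-project all components (adds the mean back)."""
        return self.scores @ self.loadings + self.mean


def fit_pca(dataset: list[RamanSpectrum]) -> PCAResult:
    """PCA on mean-centred (unscaled) preprocessed intensities."""
    if len(dataset) < 2:
        raise ValueError("PCA needs at least 2 spectra")
    x, wn = dataset_matrix(dataset)
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD; components ordered by singular value
    u, sval, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = float(np.sum(sval**2))
    degenerate = total_var <= 1e-24
    if degenerate:
        ratios = np.zeros(sval.size)
    else:
        ratios = sval**2 / total_var
    # deterministic sign: largest-|loading| element of each component positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * sval
    return PCAResult(
        scores=scores,
        loadings=vt,
        explained_variance_ratio=ratios,
        mean=mean,
        wavenumbers=wn,
        degenerate=degenerate,
    )


def select_components(pca: PCAResult, variance_threshold: float = 0.99) -> list[int]:
    """Smallest prefix of components whose cumulative variance ratio reaches
    the threshold (all nonzero-variance components for threshold 1.0)."""
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")
    ratios = pca.explained_variance_ratio
    nonzero = np.where(ratios > 0)[0]
    if nonzero.size == 0:
        return []
    cum = np.cumsum(ratios)
    # guard against the cumulative sum saturating just below the threshold
    target = min(variance_threshold, cum[nonzero[-1]])
    k = int(np.searchsorted(cum, target - 1e-12) + 1)
    return list(range(min(k, nonzero[-1] + 1)))


def extract_candidate_peaks(
    pca: PCAResult, components: list[int], n_per_pc: int = 30
) -> np.ndarray:
    """Union of the ``n_per_pc`` heaviest-|loading| channels per component.

    Returns the corresponding wavenumbers, deduplicated and sorted.  Ties in
    |loading| are broken toward the lower wavenumber.
    """
    n_channels = pca.loadings.shape[1]
    if n_per_pc > n_channels:
        raise ValueError("n_per_pc exceeds channel count")
    chosen: set[int] = set()
    for c in components:
        weights = np.abs(pca.loadings[c])
        # stable sort on (-|w|, channel) -> ties go to the lower wavenumber
        order = np.lexsort((np.arange(n_channels), -weights))
        chosen.update(order[:n_per_pc].tolist())
    idx = np.array(sorted(chosen), dtype=int)
    return pca.wavenumbers[idx]


@dataclass
class FeatureTable:
    """Spectra x selected-wavenumber intensity matrix with labels."""

    matrix: np.ndarray
    feature_wavenumbers: np.ndarray
    labels: np.ndarray
    membrane_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("row/label count mismatch")
        if self.matrix.shape[1] != len(self.feature_wavenumbers):
            raise ValueError("column/wavenumber count mismatch")
        if len(np.unique(self.feature_wavenumbers)) != len(self.feature_wavenumbers):
            raise ValueError("duplicate feature wavenumbers")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite feature values")

    def subset_features(self, wavenumbers: np.ndarray) -> "FeatureTable":
        cols = [int(np.where(self.feature_wavenumbers == w)[0][0]) for w in wavenumbers]
        return FeatureTable(
            matrix=self.matrix[:, cols],
            feature_wavenumbers=self.feature_wavenumbers[cols],
            labels=self.labels,
            membrane_ids=self.membrane_ids,
        )

    def subset_rows(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            matrix=self.matrix[rows],
            feature_wavenumbers=self.feature_wavenumbers,
            labels=self.labels[rows],
            membrane_ids=self.membrane_ids[rows],
        )


def build_feature_table(
    dataset: list[RamanSpectrum], wavenumbers: np.ndarray
) -> FeatureTable:
    """Read each spectrum at the grid channel nearest each wavenumber."""
    x, wn = dataset_matrix(dataset)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    cols = []
    for w in wavenumbers:
        if not (wn[0] <= w <= wn[-1]):
            raise ValueError(f"wavenumber {w} outside grid range [{wn[0]}, {wn[-1]}]")
        cols.append(int(np.argmin(np.abs(wn - w))))
    labels = np.array([s.label for s in dataset], dtype=object)
    membranes = np.array([s.membrane_id for s in dataset], dtype=object)
    return FeatureTable(
        matrix=x[:, cols],
        feature_wavenumbers=wn[np.asarray(cols, dtype=int)],
        labels=labels,
        membrane_ids=membranes,
    )


@dataclass
class RankedFeatures:
    """Wavenumbers ordered by descending linear-SVM importance."""

    order: np.ndarray
    importance: np.ndarray


def rank_features(ft: FeatureTable, box_constraint: float = 10.0) -> RankedFeatures:
    """Rank features by summed |weight| of one-vs-all linear SVMs.

    Features are z-scored before the fit so the weights are comparable.
    Importance of feature j is the sum over class models of |w_class,j|;
    ties in importance are broken toward the lower wavenumber.
    """
    classes = np.unique(ft.labels)
    if classes.size < 2:
        raise ValueError("feature ranking needs >= 2 classes")
    x = StandardScaler().fit_transform(ft.matrix)
    # one-vs-rest linear SVMs; primal solver is deterministic
    svm = LinearSVC(C=box_constraint, dual=False, max_iter=10000)
    svm.fit(x, ft.labels.astype(str))
    coef = svm.coef_ if classes.size > 2 else np.vstack([svm.coef_, -svm.coef_])
    importance = np.sum(np.abs(coef), axis=0)
    n = importance.size
    order_idx = np.lexsort((ft.feature_wavenumbers, -importance))
    return RankedFeatures(
        order=ft.feature_wavenumbers[order_idx],
        importance=importance[order_idx],
    )


@dataclass
class OptimalSubset:
    """Chosen feature count and the full CV-accuracy-vs-k audit curve."""

    k: int
    curve: np.ndarray
    chosen_wavenumbers: np.ndarray


def select_feature_count(
    ranked: RankedFeatures,
    ft: FeatureTable,
    model_factory,
    cv_folds: int = 10,
    seed: int = 0,
    tolerance: float = 0.005,
    max_features: int | None = None,
) -> OptimalSubset:
    """Grow the feature set along the ranking until CV accuracy plateaus.

    Evaluates stratified ``cv_folds``-fold CV accuracy for k = 1..K features
    (standardisation re-fit inside each fold) and returns the smallest k
    whose accuracy is within ``tolerance`` of the curve maximum.
    ``model_factory(seed)`` must return a fresh (pipeline) estimator.
    """
    from .classify import cross_validate  # local import to avoid a cycle

    total = len(ranked.order)
    k_max = total if max_features is None else min(max_features, total)
    curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        sub = ft.subset_features(ranked.order[:k])
        cv = cross_validate(sub, model_factory, k=cv_folds, seed=seed)
        curve[k - 1] = cv.mean_accuracy
    best = float(np.max(curve))
    k_opt = int(np.argmax(curve >= best - tolerance) + 1)
    return OptimalSubset(
        k=k_opt, curve=curve, chosen_wavenumbers=ranked.order[:k_opt]
    )
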