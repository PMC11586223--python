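"""Dataset splitting, classifier training, cross-validation and evaluation.

Two splitting schemes are compared:

* **spectra-based** — each class is split 80/20 at the level of individual
  spectra, so train and test share biological samples (membranes);
* **sample-based** — a whole membrane is held out, so the test set is a
  never-seen specimen.  Blank-membrane spectra (which carry no membrane id)
  all go to the training side: a deployed damage classifier is never asked
  about cell-free supports.

Three model families are trained: quadratic- and cubic-kernel SVMs
(one-vs-one, box constraint 1, automatic kernel scale) and a "wide" neural
network (one fully connected layer of 100 ReLU units, no regularisation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .chemometrics import FeatureTable
from .spectra import CLASSES, RamanSpectrum

SCHEMES = ("spectra_based", "sample_based")


@dataclass(frozen=True)
class SplitPlan:
    """Train/test partition over dataset row indices.

    ``sample_based`` plans additionally guarantee that no membrane id
    appears on both sides.
    """

    train_ids: np.ndarray
    test_ids: np.ndarray
    scheme: str
    held_out_membrane: str | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        overlap = np.intersect1d(self.train_ids, self.test_ids)
        if overlap.size:
            raise ValueError(f"train/test overlap at indices {overlap.tolist()[:5]}")


def split_spectra_based(
    dataset: list[RamanSpectrum], train_fraction: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Per-class random split at the spectrum level.

    Each class contributes floor((1 - train_fraction) * n) spectra to the
    test side and the remainder to training.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.array([s.label for s in dataset], dtype=object)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels.tolist())):
        idx = np.where(labels == cls)[0]
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 spectra")
        perm = rng.permutation(idx)
        # tiny epsilon guards against 1 - 0.8 = 0.19999... dropping a spectrum
        n_test = int(np.floor((1 - train_fraction) * idx.size + 1e-9))
        test.extend(perm[:n_test].tolist())
        train.extend(perm[n_test:].tolist())
    return SplitPlan(
        train_ids=np.array(sorted(train)), test_ids=np.array(sorted(test)),
        scheme="spectra_based",
    )


def split_sample_based(
    dataset: list[RamanSpectrum], held_out_membrane: str
) -> SplitPlan:
    """Hold out one whole membrane for testing.

    All spectra of the held-out membrane form the test set; every other
    membrane's spectra plus all blank-area spectra form the training set.
    """
    membranes = {s.membrane_id for s in dataset if s.membrane_id is not None}
    if len(membranes) < 2:
        raise ValueError("sample-based splitting needs >= 2 membranes")
    if held_out_membrane not in membranes:
        raise ValueError(
            f"unknown membrane {held_out_membrane!r}; have {sorted(membranes)}"
        )
    test = [i for i, s in enumerate(dataset) if s.membrane_id == held_out_membrane]
    train = [i for i in range(len(dataset)) if i not in set(test)]
    return SplitPlan(
        train_ids=np.array(train), test_ids=np.array(test),
        scheme="sample_based", held_out_membrane=held_out_membrane,
    )


class AutoScalePolySVC(BaseEstimator, ClassifierMixin):
    """Polynomial-kernel SVC with data-driven kernel scale.

    The kernel scale s is the median pairwise Euclidean distance of the
    (already standardised) training rows; the kernel is
    ((x.y)/s^2 + 1)^degree, i.e. gamma = 1/s^2, coef0 = 1.  Multiclass by
    one-vs-one voting (libsvm default).
    """

    def __init__(self, degree: int = 2, C: float = 1.0, max_rows_for_scale: int = 500):
        self.degree = degree
        self.C = C
        self.max_rows_for_scale = max_rows_for_scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        rows = X
        if X.shape[0] > self.max_rows_for_scale:
            sel = np.linspace(0, X.shape[0] - 1, self.max_rows_for_scale).astype(int)
            rows = X[sel]
        dists = pdist(rows)
        scale = float(np.median(dists)) if dists.size else 1.0
        if scale <= 0:
            scale = 1.0
        self.kernel_scale_ = scale
        self.svc_ = SVC(
            kernel="poly", degree=self.degree, C=self.C,
            gamma=1.0 / scale**2, coef0=1.0,
        )
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(np.asarray(X, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one model family.

    Defaults are the study settings: SVMs with polynomial kernel (degree 2
    for qSVM, 3 for cSVM), box constraint 1, one-vs-one multiclass,
    automatic kernel scale; WNN with one 100-unit ReLU layer, 1000-iteration
    limit, zero regularisation.  All families standardise features.
    """

    family: str = "qSVM"
    box_constraint: float = 1.0
    layer_width: int = 100
    iteration_limit: int = 1000
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("qSVM", "cSVM", "WNN"):
            raise ValueError(f"unknown family {self.family!r}")

    def build(self, seed: int = 0) -> Pipeline:
        """Fresh standardise+classify pipeline for this family."""
        if self.family == "qSVM":
            est = AutoScalePolySVC(degree=2, C=self.box_constraint)
        elif self.family == "cSVM":
            est = AutoScalePolySVC(degree=3, C=self.box_constraint)
        else:
            est = MLPClassifier(
                hidden_layer_sizes=(self.layer_width,),
                activation="relu",
                solver="lbfgs",  # limited-memory quasi-Newton
                alpha=self.regularization,
                max_iter=self.iteration_limit,
                random_state=seed,
            )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])


MODEL_FAMILIES = ("qSVM", "cSVM", "WNN")


def train_model(ft_train: FeatureTable, spec: ModelSpec, seed: int = 0) -> Pipeline:
    """Fit one model on a training feature table.

    Standardisation parameters are learned inside the pipeline from the
    training rows only.
    """
    if np.unique(ft_train.labels).size < 2:
        raise ValueError("training requires >= 2 classes")
    model = spec.build(seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        model.fit(ft_train.matrix, ft_train.labels.astype(str))
    return model


@dataclass
class CVResult:
    mean_accuracy: float
    fold_accuracies: np.ndarray


def cv_folds(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold assignment from labels and seed alone (feature-blind).

    ``k`` equal to the row count gives leave-one-out; otherwise stratified
    k-fold, with k reduced to the rarest class count (warning) when needed.
    """
    labels = np.asarray(labels).astype(str)
    n = labels.size
    if k >= n:
        return [
            (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
        ]
    _, counts = np.unique(labels, return_counts=True)
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        warnings.warn(
            f"reducing folds from {k} to {k_eff}: rarest class has {counts.min()} members"
        )
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(n), labels))


def cross_validate(
    ft: FeatureTable,
    model: "ModelSpec | callable",
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation accuracy.

    Fold assignment depends only on the labels and the seed (see
    :func:`cv_folds`).  All per-fold preprocessing (standardisation) is
    re-fit on each fold's training rows, so no information leaks from the
    held-out fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = ft.labels.astype(str)
    factory = model.build if isinstance(model, ModelSpec) else model
    accs = []
    for tr, te in cv_folds(labels, k, seed):
        est = factory(seed)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            est.fit(ft.matrix[tr], labels[tr])
        accs.append(float(np.mean(est.predict(ft.matrix[te]) == labels[te])))
    accs = np.array(accs)
    return CVResult(mean_accuracy=float(accs.mean()), fold_accuracies=accs)


@dataclass
class MetricSet:
    """Macro-averaged performance metrics, each in [0, 1].

    Metrics are computed one-vs-rest per class, then averaged over classes
    with at least one true instance; classes hitting an empty denominator
    contribute 0 and are listed in ``flags``.
    """

    accuracy: float
    specificity: float
    precision: float
    sensitivity: float
    f1: float
    per_class: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def compute_metrics(confusion: np.ndarray, classes: tuple = CLASSES) -> MetricSet:
    """Accuracy and macro specificity/precision/sensitivity/F1 from counts."""
    cm = np.asarray(confusion, dtype=float)
    if np.any(cm < 0):
        raise ValueError("confusion counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm) / total)
    per_class: dict = {}
    flags: list = []
    present = []
    for i, cls in enumerate(classes[: cm.shape[0]]):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        support = tp + fn
        if support == 0:
            per_class[cls] = None
            continue
        present.append(cls)

        def _safe(num, den, metric):
            if den == 0:
                flags.append((cls, metric))
                return 0.0
            return float(num / den)

        sens = _safe(tp, tp + fn, "sensitivity")
        prec = _safe(tp, tp + fp, "precision")
        spec = _safe(tn, tn + fp, "specificity")
        f1 = _safe(2 * prec * sens, prec + sens, "f1") if (prec + sens) else 0.0
        per_class[cls] = {
            "sensitivity": sens, "precision": prec,
            "specificity": spec, "f1": f1, "support": int(support),
        }
    if not present:
        raise ValueError("no class has a true instance")
    macro = {
        m: float(np.mean([per_class[c][m] for c in present]))
        for m in ("specificity", "precision", "sensitivity", "f1")
    }
    return MetricSet(
        accuracy=accuracy,
        specificity=macro["specificity"],
        precision=macro["precision"],
        sensitivity=macro["sensitivity"],
        f1=macro["f1"],
        per_class=per_class,
        flags=flags,
    )


@dataclass
class EvaluationReport:
    """Confusion matrices (counts and row-normalised) plus metrics.

    True classes absent from the test set keep an all-zero confusion row
    (listed in ``absent_classes``) and are excluded from macro averages.
    """

    confusion: np.ndarray
    confusion_row_normalized: np.ndarray
    metrics: MetricSet
    classes: tuple = CLASSES
    absent_classes: list = field(default_factory=list)


def evaluate(model, ft_test: FeatureTable) -> EvaluationReport:
    """Predict a test feature table and tabulate the confusion over all
    damage classes (absent true classes yield all-zero rows)."""
    if ft_test.matrix.shape[0] == 0:
        raise ValueError("empty test set")
    pred = model.predict(ft_test.matrix).astype(str)
    true = ft_test.labels.astype(str)
    k = len(CLASSES)
    cm = np.zeros((k, k), dtype=int)
    index = {c: i for i, c in enumerate(CLASSES)}
    for t, p in zip(true, pred):
        cm[index[t], index[p]] += 1
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, cm / np.maximum(row_sums, 1), 0.0)
    absent = [c for c in CLASSES if cm[index[c]].sum() == 0]
    return EvaluationReport(
        confusion=cm,
        confusion_row_normalized=norm,
        metrics=compute_metrics(cm, CLASSES),
        classes=CLASSES,
        absent_classes=absent,
    )
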