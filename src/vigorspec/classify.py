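"""Vigor classification: stratified hold-out, PCA scores, LOO-CV grid search, validation.

The averaged per-sample spectra of one band are split into a training block
(stratified by vigor only; cultivar is deliberately ignored) and an external
validation block that never touches any training or model-selection step.
Training spectra are mean-centered and projected onto principal components;
for each candidate (number of PCs, hyperparameter) cell, leave-one-out
cross-validated accuracy is computed and collected into a heat map, the
best cell is refit on the whole training block, and the resulting model is
scored on the held-out samples.

PCA is fitted once on the full training block before the LOO loop (the
mildly optimistic, conventional variant); ``pca_in_fold=True`` refits it
inside every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from .preprocess import AveragedSample

__all__ = [
    "LABELS",
    "ALGORITHMS",
    "SplitSpec",
    "PCAModel",
    "GridSpec",
    "GridSearchMap",
    "TrainedClassifier",
    "ValidationReport",
    "split_dataset",
    "fit_pca",
    "project",
    "fit_classifier",
    "predict",
    "loo_cv_accuracy",
    "grid_search",
    "train_classifier",
    "external_validate",
    "default_grid",
    "sample_matrix",
]

LABELS = ("HV", "LV")
ALGORITHMS = ("knn", "lda", "qda", "svm")


# ---------------------------------------------------------------------------
# Train / external-validation split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """External hold-out size: per-vigor-class validation counts and RNG seed."""

    n_validation: int = 30
    n_hv: int = 15
    n_lv: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hv + self.n_lv != self.n_validation:
            raise ValueError("n_hv + n_lv must equal n_validation")
        if self.n_hv < 1 or self.n_lv < 1:
            raise ValueError("per-class validation counts must be >= 1")


def split_dataset(
    samples: Sequence[AveragedSample],
    spec: SplitSpec = SplitSpec(),
) -> tuple[list[AveragedSample], list[AveragedSample]]:
    """Stratified (by vigor only) random split into training and validation sets."""
    rng = np.random.default_rng(spec.seed)
    per_class = {"HV": spec.n_hv, "LV": spec.n_lv}
    val_ids: set[str] = set()
    for label, n_val in per_class.items():
        ids = [s.sample_id for s in samples if s.vigor == label]
        if len(ids) < n_val + 1:
            raise ValueError(
                f"class {label} has {len(ids)} samples; needs > {n_val} for a split"
            )
        chosen = rng.choice(len(ids), size=n_val, replace=False)
        val_ids.update(ids[i] for i in chosen)
    train = [s for s in samples if s.sample_id not in val_ids]
    validation = [s for s in samples if s.sample_id in val_ids]
    return train, validation


def sample_matrix(samples: Sequence[AveragedSample]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack averaged samples into (X, labels, ids)."""
    X = np.stack([s.intensities for s in samples])
    y = np.array([s.vigor for s in samples])
    ids = [s.sample_id for s in samples]
    return X, y, ids


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean-centering PCA: orthonormal loadings in decreasing-variance order.

    Sign convention: each loading's largest-magnitude entry is positive.
    """

    mean_: np.ndarray
    components_: np.ndarray  # (n_components, n_features)
    explained_variance_: np.ndarray
    explained_variance_ratio_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]


def fit_pca(X: np.ndarray) -> PCAModel:
    """Fit PCA by SVD of the mean-centered data (no column autoscaling)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA requires a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input must be finite")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] == 0:
        raise ValueError("rank-0 matrix: no variance to decompose")
    keep = s > s[0] * 1e-12
    s, vt = s[keep], vt[keep]
    for row in vt:  # sign convention
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    ev = s**2 / (X.shape[0] - 1)
    return PCAModel(mean, vt, ev, ev / ev.sum())


def project(model: PCAModel, X: np.ndarray, n_pcs: int) -> np.ndarray:
    """Scores of samples on the first ``n_pcs`` components of a fitted model."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean_.size:
        raise ValueError(
            f"grid mismatch: {X.shape[1]} wavelengths vs model's {model.mean_.size}"
        )
    if not 1 <= n_pcs <= model.n_components:
        raise ValueError(f"n_pcs must be in [1, {model.n_components}]")
    return (X - model.mean_) @ model.components_[:n_pcs].T


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class _KNN:
    """K-nearest-neighbour vote with explicit tie rules.

    Euclidean distance, uniform vote over the k nearest training points.
    Distance ties are broken by lower training index (stable sort); vote ties
    by the label of the single nearest neighbour.
    """

    def __init__(self, k: int):
        if int(k) != k or k < 1:
            raise ValueError("k must be a positive integer")
        self.k = int(k)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KNN":
        if self.k > len(X):
            raise ValueError(f"k={self.k} exceeds the training-set size {len(X)}")
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        for x in X:
            d = np.linalg.norm(self._X - x, axis=1)
            order = np.argsort(d, kind="stable")[: self.k]
            votes = self._y[order]
            labels, counts = np.unique(votes, return_counts=True)
            winners = labels[counts == counts.max()]
            out.append(votes[0] if len(winners) > 1 else winners[0])
        return np.array(out)


class _QDA:
    """Gaussian quadratic discriminant with average-variance shrinkage.

    Per-class sample covariance Sigma is shrunk as
    Sigma_r = (1 - r) * Sigma + r * (tr(Sigma) / p) * I
    before evaluating the Gaussian log-density; priors are class frequencies.
    """

    def __init__(self, r: float):
        if not 0.0 <= r <= 1.0:
            raise ValueError("regularization r must be in [0, 1]")
        self.r = float(r)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_QDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        p = X.shape[1]
        self._means, self._chols, self._logdets, self._logpriors = [], [], [], []
        for label in self.classes_:
            Xk = X[y == label]
            if len(Xk) < 2:
                raise ValueError(f"class {label} needs at least 2 samples for QDA")
            mu = Xk.mean(axis=0)
            cov = np.cov(Xk, rowvar=False, ddof=1).reshape(p, p)
            cov = (1.0 - self.r) * cov + self.r * (np.trace(cov) / p) * np.eye(p)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"singular covariance for class {label}; "
                    "increase the regularization parameter r"
                ) from exc
            self._means.append(mu)
            self._chols.append(chol)
            self._logdets.append(2.0 * np.sum(np.log(np.diag(chol))))
            self._logpriors.append(np.log(len(Xk) / len(X)))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.empty((len(X), len(self.classes_)))
        for j in range(len(self.classes_)):
            diff = X - self._means[j]
            # Solve L w = diff^T for the Mahalanobis term.
            w = np.linalg.solve(self._chols[j], diff.T)
            maha = np.sum(w**2, axis=0)
            scores[:, j] = self._logpriors[j] - 0.5 * (self._logdets[j] + maha)
        return self.classes_[np.argmax(scores, axis=1)]


LDA_SOLVERS = ("svd", "lsqr", "eigen")
QDA_REG_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
SVM_C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)


def _make_estimator(algorithm: str, hyperparameter):
    algorithm = algorithm.lower()
    if algorithm == "knn":
        return _KNN(int(hyperparameter))
    if algorithm == "lda":
        if hyperparameter not in LDA_SOLVERS:
            raise ValueError(f"unknown LDA solver {hyperparameter!r}")
        return LinearDiscriminantAnalysis(solver=hyperparameter)
    if algorithm == "qda":
        return _QDA(float(hyperparameter))
    if algorithm == "svm":
        c = float(hyperparameter)
        if c <= 0:
            raise ValueError("SVM penalty C must be > 0")
        return SVC(C=c, kernel="rbf", gamma="scale")
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def fit_classifier(algorithm: str, scores: np.ndarray, labels: np.ndarray, hyperparameter):
    """Fit one classifier on PCA scores; returns the fitted estimator."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    return _make_estimator(algorithm, hyperparameter).fit(np.asarray(scores, float), labels)


def predict(estimator, scores: np.ndarray) -> np.ndarray:
    return np.asarray(estimator.predict(np.atleast_2d(np.asarray(scores, float))))


# ---------------------------------------------------------------------------
# LOO-CV and grid search
# ---------------------------------------------------------------------------

def loo_cv_accuracy(
    scores: np.ndarray,
    labels: np.ndarray,
    algorithm: str,
    hyperparameter,
) -> float:
    """Explicit leave-one-out loop: fit on all-but-one, predict the held-out sample.

    A fold that cannot be fit (e.g. single-class) counts as an error.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    if n < 2:
        raise ValueError("LOO-CV requires at least 2 samples")
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            est = fit_classifier(algorithm, scores[mask], labels[mask], hyperparameter)
            pred = predict(est, scores[i])[0]
            correct += int(pred == labels[i])
        except Exception:
            pass  # counted as an error on this fold
        mask[i] = True
    return correct / n


@dataclass(frozen=True)
class GridSpec:
    """Search grid for one algorithm: candidate PC counts and hyperparameter values."""

    algorithm: str
    pc_grid: tuple[int, ...] = tuple(range(1, 21))
    hyper_grid: tuple = ()

    def __post_init__(self) -> None:
        if self.algorithm.lower() not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.pc_grid or not all(p >= 1 for p in self.pc_grid):
            raise ValueError("pc_grid must be non-empty positive integers")
        if not self.hyper_grid:
            object.__setattr__(self, "hyper_grid", _default_hyper_grid(self.algorithm))


def _default_hyper_grid(algorithm: str) -> tuple:
    return {
        "knn": tuple(range(1, 46)),
        "lda": LDA_SOLVERS,
        "qda": QDA_REG_GRID,
        "svm": SVM_C_GRID,
    }[algorithm.lower()]


def default_grid(algorithm: str, pc_grid: tuple[int, ...] = tuple(range(1, 21))) -> GridSpec:
    """The standard search grid for one of the four algorithms."""
    return GridSpec(algorithm.lower(), pc_grid, _default_hyper_grid(algorithm))


@dataclass
class GridSearchMap:
    """LOO-CV accuracy over (n_PCs x hyperparameter) plus the chosen cell."""

    algorithm: str
    band: str
    pc_grid: tuple[int, ...]
    hyper_grid: tuple
    accuracy: np.ndarray  # shape (len(pc_grid), len(hyper_grid))
    chosen: tuple[int, object]  # (n_pcs, hyperparameter)

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracy.max())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.accuracy, index=list(self.pc_grid),
                             columns=[str(h) for h in self.hyper_grid])
        frame.index.name = "n_pcs"
        return frame


def grid_search(
    X: np.ndarray,
    labels: np.ndarray,
    spec: GridSpec,
    band: str = "",
    pca_in_fold: bool = False,
) -> GridSearchMap:
    """Evaluate LOO-CV accuracy for every grid cell and pick the best.

    Ties are broken by the fewest PCs, then the earliest hyperparameter in
    grid order.  With ``pca_in_fold`` the PCA is refit on each fold's n-1
    samples (the stricter, slower variant); by default it is fitted once on
    the full training block.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    max_pc = max(spec.pc_grid)
    if max_pc > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(f"pc_grid requests {max_pc} PCs; training set supports fewer")

    accuracy = np.zeros((len(spec.pc_grid), len(spec.hyper_grid)))
    if not pca_in_fold:
        model = fit_pca(X)
        Z = project(model, X, min(max_pc, model.n_components))
        for a, n_pcs in enumerate(spec.pc_grid):
            for b, hyper in enumerate(spec.hyper_grid):
                accuracy[a, b] = loo_cv_accuracy(Z[:, :n_pcs], labels, spec.algorithm, hyper)
    else:
        n = len(X)
        folds = []
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            m = fit_pca(X[mask])
            k = min(max_pc, m.n_components)
            folds.append((project(m, X[mask], k), project(m, X[i], k)[0]))
            mask[i] = True
        for a, n_pcs in enumerate(spec.pc_grid):
            for b, hyper in enumerate(spec.hyper_grid):
                correct = 0
                for i in range(n):
                    Ztr, zte = folds[i]
                    mask[i] = False
                    try:
                        est = fit_classifier(
                            spec.algorithm, Ztr[:, :n_pcs], labels[mask], hyper
                        )
                        correct += int(predict(est, zte[:n_pcs])[0] == labels[i])
                    except Exception:
                        pass
                    mask[i] = True
                accuracy[a, b] = correct / n

    best_cell = (0, 0)
    for a in range(len(spec.pc_grid)):
        for b in range(len(spec.hyper_grid)):
            if accuracy[a, b] > accuracy[best_cell] + 1e-12:
                best_cell = (a, b)
    chosen = (spec.pc_grid[best_cell[0]], spec.hyper_grid[best_cell[1]])
    return GridSearchMap(spec.algorithm, band, spec.pc_grid, spec.hyper_grid, accuracy, chosen)


# ---------------------------------------------------------------------------
# Final model and external validation
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A PCA + classifier pair fitted on the training block only."""

    algorithm: str
    band: str
    pca: PCAModel
    n_pcs: int
    hyperparameter: object
    estimator: object
    training_ids: frozenset = field(default_factory=frozenset)


@dataclass
class ValidationReport:
    """Confusion matrix and overall accuracy on the external validation set."""

    algorithm: str
    band: str
    labels: tuple[str, str]
    confusion: np.ndarray  # rows = true label, columns = predicted
    accuracy: float


def train_classifier(
    train: Sequence[AveragedSample],
    algorithm: str,
    n_pcs: int,
    hyperparameter,
    pca: PCAModel | None = None,
) -> TrainedClassifier:
    """Fit the final model (PCA + classifier) on the full training block."""
    X, y, ids = sample_matrix(train)
    model = pca if pca is not None else fit_pca(X)
    Z = project(model, X, n_pcs)
    est = fit_classifier(algorithm, Z, y, hyperparameter)
    return TrainedClassifier(algorithm.lower(), train[0].band, model, n_pcs,
                             hyperparameter, est, frozenset(ids))


def external_validate(
    model: TrainedClassifier,
    validation: Sequence[AveragedSample],
) -> ValidationReport:
    """Score a trained model on held-out samples; refuses overlapping sample ids."""
    X, y, ids = sample_matrix(validation)
    overlap = model.training_ids.intersection(ids)
    if overlap:
        raise ValueError(f"leakage: validation samples also in training: {sorted(overlap)}")
    preds = predict(model.estimator, project(model.pca, X, model.n_pcs))
    confusion = np.zeros((2, 2), dtype=int)
    for true, pred in zip(y, preds):
        confusion[LABELS.index(true), LABELS.index(pred)] += 1
    return ValidationReport(model.algorithm, model.band, LABELS, confusion,
                            float(np.trace(confusion) / confusion.sum()))
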