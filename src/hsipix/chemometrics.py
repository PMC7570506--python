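"""Linear chemometric models: PCA score images, PLSDA, and SVM-ECOC.

PCA compresses the correlated NIR band axis into a few orthogonal score
channels; refolded score images feed the 2-D CNN.  PLSDA regresses one-hot
class indicators on spectra by PLS2 and assigns the argmax column; the
number of latent variables (LVs) is chosen by venetian-blinds
cross-validation.  The multiclass SVM fuses binary max-margin classifiers
through error-correcting output codes (ECOC).

Models are mean-centered only (no autoscaling): the pre-treatments already
normalize scale, and loadings should describe raw spectral variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA
from sklearn.svm import SVC

from hsipix.core_io import FlatSpectra, Hypercube, refold, unfold

__all__ = [
    "PCAModel", "PLSDAModel", "ECOCModel",
    "pca_fit", "pca_project", "plsda_fit", "plsda_predict",
    "select_lvs_venetian", "ecoc_fit", "ecoc_predict",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Fitted PCA: mean spectrum, orthonormal loadings, variance ratios.

    Scores are ``T = (X - mean) @ loadings``.  Sign convention: in each
    loading vector the element of largest magnitude is positive, removing
    the SVD sign ambiguity so refits are comparable.
    """

    mean_spectrum: np.ndarray            # (bands,)
    loadings: np.ndarray                 # (bands x A)
    explained_variance_ratio: np.ndarray  # (A,)

    def __post_init__(self) -> None:
        L = self.loadings
        if np.abs(L.T @ L - np.eye(L.shape[1])).max() > 1e-10:
            raise ValueError("PCA loadings are not orthonormal")
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained variance ratios must be non-increasing, sum <= 1")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray, d: Optional[int] = None) -> np.ndarray:
        d = self.n_components if d is None else d
        return (np.asarray(X) - self.mean_spectrum) @ self.loadings[:, :d]

    def save(self, path) -> None:
        np.savez_compressed(path, mean_spectrum=self.mean_spectrum,
                            loadings=self.loadings,
                            explained_variance_ratio=self.explained_variance_ratio)

    @staticmethod
    def load(path) -> "PCAModel":
        with np.load(path) as z:
            return PCAModel(z["mean_spectrum"], z["loadings"],
                            z["explained_variance_ratio"])


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def pca_fit(training: FlatSpectra | np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA on unfolded training spectra (mean-centering only)."""
    X = training.values if isinstance(training, FlatSpectra) else np.asarray(training)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate input: zero variance in every band")
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(X)
    loadings = _fix_signs(sk.components_.T)
    return PCAModel(mean_spectrum=sk.mean_,
                    loadings=loadings,
                    explained_variance_ratio=sk.explained_variance_ratio_)


def pca_project(cube: Hypercube, model: PCAModel, d: int) -> np.ndarray:
    """Project a (preprocessed) cube onto the first ``d`` PCs as a score stack.

    Returns an ``(x, y, d)`` stack: foreground pixels carry scores,
    background pixels are 0.  The cube must have passed through the same
    pre-treatment chain as the PCA training spectra.
    """
    if d > model.n_components:
        raise ValueError(f"d={d} exceeds the {model.n_components} fitted components")
    if cube.n_bands != model.mean_spectrum.size:
        raise ValueError(
            f"cube has {cube.n_bands} bands; model expects {model.mean_spectrum.size}")
    flat = unfold(cube, use_mask=cube.mask is not None)
    scores = model.transform(flat.values, d)
    return refold(flat, scores, fill=0.0)


# ---------------------------------------------------------------------------
# PLSDA


@dataclass
class PLSDAModel:
    """PLS2 discriminant model on one-hot class indicators.

    Prediction: ``ŷ = (X - x_mean) @ B + y_mean`` followed by argmax over
    the C indicator columns (no threshold or Bayes rule).
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    regression_coefficients: np.ndarray   # (bands x C)
    x_weights: np.ndarray                 # (bands x n_lv)
    x_loadings: np.ndarray                # (bands x n_lv)
    class_ids: np.ndarray                 # sorted original labels, len C
    class_names: Sequence[str] = field(default_factory=list)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return (X - self.x_mean) @ self.regression_coefficients + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.class_ids[np.argmax(self.decision_values(X), axis=1)]

    def save(self, path) -> None:
        np.savez_compressed(
            path, n_lv=self.n_lv, x_mean=self.x_mean, y_mean=self.y_mean,
            regression_coefficients=self.regression_coefficients,
            x_weights=self.x_weights, x_loadings=self.x_loadings,
            class_ids=self.class_ids,
            class_names=np.asarray(list(self.class_names), dtype=object))

    @staticmethod
    def load(path) -> "PLSDAModel":
        with np.load(path, allow_pickle=True) as z:
            return PLSDAModel(int(z["n_lv"]), z["x_mean"], z["y_mean"],
                              z["regression_coefficients"], z["x_weights"],
                              z["x_loadings"], z["class_ids"],
                              list(z["class_names"]))


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(np.float64)
    return Y, classes


def plsda_fit(X: np.ndarray, labels: np.ndarray, n_lv: int,
              class_names: Sequence[str] = ()) -> PLSDAModel:
    """Fit PLSDA: PLS2 (NIPALS, deflation) of one-hot Y on mean-centered X."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n, p = X.shape
    Y, classes = _one_hot(labels)
    if classes.size < 2:
        raise ValueError("plsda_fit requires at least two classes")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0)) if n * p <= 2_000_000 else None
    if rank is not None and n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds the rank {rank} of centered X")
    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(X, Y)
    B = pls.coef_.T  # sklearn stores (n_targets, n_features)
    model = PLSDAModel(
        n_lv=n_lv, x_mean=pls._x_mean, y_mean=pls._y_mean,
        regression_coefficients=B,
        x_weights=pls.x_weights_, x_loadings=pls.x_loadings_,
        class_ids=classes, class_names=list(class_names))
    if not np.isfinite(model.decision_values(X[: min(n, 256)])).all():
        raise ValueError("PLSDA produced non-finite training predictions")
    return model


def plsda_predict(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax class assignment over the predicted indicator columns."""
    return model.predict(X)


def select_lvs_venetian(X: np.ndarray, labels: np.ndarray, max_lv: int = 15,
                        n_splits: int = 10, tol: float = 0.005
                        ) -> tuple[int, np.ndarray]:
    """Choose the number of LVs by venetian-blinds cross-validation.

    Fold ``s`` holds the observations with ``index mod n_splits == s``
    (interleaved "blinds").  Returns the smallest LV count whose CV accuracy
    is within ``tol`` (fraction, default half a percentage point) of the
    curve maximum, plus the accuracy-vs-LV curve.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(labels)
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    max_lv = min(max_lv, X.shape[1], n - n // n_splits - 1)
    idx = np.arange(n)
    folds = [idx[idx % n_splits == s] for s in range(n_splits)]
    n_classes = np.unique(labels).size
    for s, fold in enumerate(folds):
        train = np.setdiff1d(idx, fold)
        if np.unique(labels[train]).size < n_classes:
            raise ValueError(
                f"venetian fold {s} leaves a class unrepresented in training; "
                "use fewer splits or more observations")
    correct = np.zeros(max_lv)
    for fold in folds:
        train = np.setdiff1d(idx, fold)
        pls = PLSRegression(n_components=max_lv, scale=False)
        Y, classes = _one_hot(labels[train])
        pls.fit(X[train], Y)
        # score the fold at every truncated LV count in one pass
        Xc = X[fold] - pls._x_mean
        T = np.empty((len(fold), max_lv))
        R = pls.x_rotations_
        T = Xc @ R
        for a in range(1, max_lv + 1):
            Yhat = T[:, :a] @ pls.y_loadings_[:, :a].T + pls._y_mean
            pred = classes[np.argmax(Yhat, axis=1)]
            correct[a - 1] += np.sum(pred == labels[fold])
    curve = correct / n
    best = curve.max()
    chosen = int(np.argmax(curve >= best - tol)) + 1
    return chosen, curve


# ---------------------------------------------------------------------------
# SVM + ECOC


def _codebook(n_classes: int, coding: str) -> np.ndarray:
    """ECOC codebook over {-1, 0, +1}; 0 marks classes a binary problem skips."""
    if coding == "one-vs-all":
        M = -np.ones((n_classes, n_classes), dtype=np.int8)
        np.fill_diagonal(M, 1)
        return M
    if coding == "one-vs-one":
        pairs = [(i, j) for i in range(n_classes) for j in range(i + 1, n_classes)]
        M = np.zeros((n_classes, len(pairs)), dtype=np.int8)
        for b, (i, j) in enumerate(pairs):
            M[i, b] = 1
            M[j, b] = -1
        return M
    raise ValueError(f"unknown coding '{coding}'")


@dataclass
class ECOCModel:
    """Multiclass SVM fused from binary classifiers by output coding.

    ``codebook[c, b]`` says how class ``c`` enters binary problem ``b``
    (+1 / -1 side, 0 = not used).  Decoding minimizes the hinge-loss-weighted
    distance between the codeword and the vector of binary margins; a
    codeword tie resolves to the lowest class index and increments
    ``tie_count``.
    """

    codebook: np.ndarray
    classifiers: list
    class_ids: np.ndarray
    coding: str
    class_names: Sequence[str] = field(default_factory=list)
    tie_count: int = 0

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ECOCModel":
        import joblib

        return joblib.load(path)


def _default_binary_learner() -> SVC:
    return SVC(kernel="linear", C=1.0)


def ecoc_fit(X: np.ndarray, labels: np.ndarray, coding: str = "one-vs-one",
             learner_factory: Optional[Callable[[], object]] = None,
             class_names: Sequence[str] = ()) -> ECOCModel:
    """Fit one binary max-margin classifier per codebook column.

    The binary learner is pluggable (default: linear SVC, C=1).  With two
    classes either coding degenerates to a single binary classifier.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("ecoc_fit requires at least two classes")
    book = _codebook(classes.size, coding)
    if coding == "one-vs-all" and classes.size == 2:
        book = book[:, :1]  # both columns encode the same binary problem
    factory = learner_factory or _default_binary_learner
    clfs = []
    for b in range(book.shape[1]):
        sides = book[:, b]
        used = np.nonzero(sides != 0)[0]
        sel = np.isin(labels, classes[used])
        yb = np.zeros(sel.sum(), dtype=np.int8)
        for ci in used:
            yb[labels[sel] == classes[ci]] = sides[ci]
        clf = factory()
        clf.fit(X[sel], yb)
        clfs.append(clf)
    return ECOCModel(codebook=book, classifiers=clfs, class_ids=classes,
                     coding=coding, class_names=list(class_names))


def ecoc_predict(model: ECOCModel, X: np.ndarray) -> np.ndarray:
    """Decode binary margins against the codebook (hinge binary loss)."""
    X = np.asarray(X, dtype=np.float64)
    B = len(model.classifiers)
    margins = np.column_stack([
        clf.decision_function(X) if hasattr(clf, "decision_function")
        else 2.0 * clf.predict(X) - 1.0
        for clf in model.classifiers
    ]) if B else np.zeros((len(X), 0))
    book = model.codebook.astype(np.float64)          # (C x B)
    active = np.abs(book)
    # hinge loss of margin m against codeword entry s: max(0, 1 - s*m) / 2
    loss = np.maximum(0.0, 1.0 - book[None, :, :] * margins[:, None, :]) / 2.0
    loss = (loss * active[None, :, :]).sum(axis=2) / active.sum(axis=1)[None, :]
    best = loss.min(axis=1, keepdims=True)
    ties = (np.abs(loss - best) < 1e-12).sum(axis=1) > 1
    model.tie_count += int(ties.sum())
    return model.class_ids[np.argmin(loss, axis=1)]
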