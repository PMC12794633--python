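"""Sparse-representation feature selection and classification.

Selection treats the class labels as a regression target: with standardized
features ``X`` (cases x features) and ``y in {-1, +1}`` (good / poor), solve

    min_w  (1 / 2n) ||y - X w||^2  +  lambda ||w||_1

by cyclic coordinate descent; the features with nonzero coefficients are the
selected set.  The l1 penalty simultaneously favors discriminative features
and suppresses redundant (correlated) ones.

Classification is by sparse representation (SRC): a test sample is coded as a
sparse nonnegative-residual combination of the *training samples* (columns of
a dictionary restricted to the selected features and l2-normalized), and is
assigned to the class whose coefficients reconstruct it with the smallest
residual.  A continuous score is defined from the residual contrast,

    score = (r_good - r_poor) / (r_good + r_poor + eps)  in (-1, 1),

oriented so that higher means more poor-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from sklearn.model_selection import StratifiedKFold

from .imaging_core import GOOD, POOR

LABELS = (GOOD, POOR)


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Cases x named-features matrix with binary outcome labels."""

    case_ids: List[str]
    feature_names: List[str]
    X: np.ndarray                      # (n_cases, n_features)
    labels: np.ndarray                 # array of "good"/"poor"
    mean_: Optional[np.ndarray] = None  # standardization parameters (training)
    sd_: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.shape != (len(self.case_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match ids/names")
        if np.isnan(self.X).any():
            raise ValueError("feature table contains missing values")

    @property
    def n_cases(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def y_signed(self) -> np.ndarray:
        """Labels as +1 (poor) / -1 (good)."""
        return np.where(self.labels == POOR, 1.0, -1.0)

    def subset_rows(self, idx: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            [self.case_ids[i] for i in idx], list(self.feature_names),
            self.X[idx], self.labels[idx],
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        pos = {n: j for j, n in enumerate(self.feature_names)}
        cols = [pos[n] for n in names]
        return FeatureTable(
            list(self.case_ids), list(names), self.X[:, cols], self.labels,
        )


def standardize_fit(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and sd from training rows (sd 0 mapped to 1)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def standardize_apply(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd


# ---------------------------------------------------------------------------
# Lasso by cyclic coordinate descent
# ---------------------------------------------------------------------------

def _soft_threshold(z: np.ndarray | float, t: float):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


@njit(cache=False)
def _cd_gram(G: np.ndarray, c: np.ndarray, lam: float, tol: float,
             max_iter: int, w0: np.ndarray) -> np.ndarray:  # pragma: no cover
    p = G.shape[0]
    w = w0.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            rho = c[j] - np.dot(G[j], w) + gjj * w[j]
            if rho > lam:
                wn = (rho - lam) / gjj
            elif rho < -lam:
                wn = (rho + lam) / gjj
            else:
                wn = 0.0
            d = wn - w[j]
            if d != 0.0:
                w[j] = wn
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            break
    return w


@njit(cache=False)
def _cd_gram_nonneg(G: np.ndarray, c: np.ndarray, lam: float, tol: float,
                    max_iter: int) -> np.ndarray:  # pragma: no cover
    p = G.shape[0]
    w = np.zeros(p)
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            rho = c[j] - np.dot(G[j], w) + gjj * w[j]
            wn = (rho - lam) / gjj
            if wn < 0.0:
                wn = 0.0
            d = wn - w[j]
            if d != 0.0:
                w[j] = wn
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            break
    return w


def lasso_cd(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-6,
             max_iter: int = 5000, warm_start: Optional[np.ndarray] = None
             ) -> np.ndarray:
    """Minimize ``(1/2n)||y - Xw||^2 + lam * ||w||_1`` by coordinate descent.

    The cyclic updates run on the Gram matrix ``X'X/n`` (cheap for the tall
    thin problems here); a sweep converges when the largest coefficient
    update falls below ``tol``.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    G = X.T @ X / n
    c = X.T @ y / n
    w0 = np.zeros(p) if warm_start is None else np.asarray(warm_start, float)
    return _cd_gram(G, c, lam, tol, max_iter, w0)


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda for which the lasso solution is all-zero."""
    n = X.shape[0]
    return float(np.max(np.abs(X.T @ y)) / n)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    selected: np.ndarray               # indices into feature_names
    coef: np.ndarray                   # full-length coefficient vector
    lam: float
    cv_score: Optional[float] = None
    feature_names: List[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def select_features(table: FeatureTable, lam: float,
                    coef_eps: float = 1e-8) -> SelectionResult:
    """Label-regression lasso selection on (already standardized) features."""
    classes = set(table.labels.tolist())
    if len(classes) < 2:
        raise ValueError("selection requires both classes in the training set")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = table.y_signed()
    w = lasso_cd(table.X, y, lam)
    selected = np.flatnonzero(np.abs(w) > coef_eps)
    names = [table.feature_names[j] for j in selected]
    return SelectionResult(selected=selected, coef=w, lam=lam,
                           feature_names=names)


# ---------------------------------------------------------------------------
# Sparse-representation classifier
# ---------------------------------------------------------------------------

@dataclass
class SRCModel:
    """Training dictionary for residual-based classification.

    ``dictionary`` has one l2-normalized column per training case, restricted
    to the selected features (in standardized units); ``column_labels`` holds
    the class of each column.
    """

    dictionary: np.ndarray             # (n_selected_features, n_train)
    column_labels: np.ndarray
    selected_names: List[str]
    mean_: np.ndarray                  # standardization over selected features
    sd_: np.ndarray
    lam_code: float = 0.01
    majority_label: str = GOOD

    def __post_init__(self) -> None:
        present = set(self.column_labels.tolist())
        if not {GOOD, POOR} <= present:
            raise ValueError("dictionary must contain both classes")
        self._gram: Optional[np.ndarray] = None

    @property
    def gram(self) -> np.ndarray:
        """Cached ``A'A`` of the dictionary (reused across predictions)."""
        if self._gram is None:
            self._gram = self.dictionary.T @ self.dictionary
        return self._gram


def fit_src(table: FeatureTable, selected: Sequence[int],
            lam_code: float = 0.01) -> SRCModel:
    """Build the SRC dictionary from training rows and selected features.

    ``table.X`` must be raw (unstandardized): standardization parameters are
    estimated here, on these training rows only, and stored in the model.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("selected feature set is empty")
    Xs = table.X[:, selected]
    mean, sd = standardize_fit(Xs)
    Z = standardize_apply(Xs, mean, sd)        # (n_train, k)
    norms = np.linalg.norm(Z, axis=1)
    keep = norms > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance training "
                      "case vector(s) from the dictionary")
    A = (Z[keep] / norms[keep, None]).T        # columns are cases
    labels = table.labels[keep]
    counts = {c: int((labels == c).sum()) for c in LABELS}
    majority = max(counts, key=counts.get)
    return SRCModel(
        dictionary=A, column_labels=labels,
        selected_names=[table.feature_names[j] for j in selected],
        mean_=mean, sd_=sd, lam_code=lam_code, majority_label=majority,
    )


def sparse_code(A: np.ndarray, x: np.ndarray, lam: float,
                nonnegative: bool = True, tol: float = 1e-6,
                max_iter: int = 500,
                gram: Optional[np.ndarray] = None) -> np.ndarray:
    """Solve ``min_a 1/2 ||x - A a||^2 + lam ||a||_1`` (the coding step).

    Coding is nonnegative by default: after standardization the two
    outcome classes sit at antipodal positions in feature space, so a
    *negatively* weighted column of the wrong class could reconstruct a
    sample as well as the right class and destroy the class specificity of
    the residuals.  Constraining the code to ``a >= 0`` restores it.
    """
    G = A.T @ A if gram is None else gram
    c = A.T @ np.asarray(x, dtype=np.float64)
    if nonnegative:
        return _cd_gram_nonneg(G, c, lam, tol, max_iter)
    return _cd_gram(G, c, lam, tol, max_iter, np.zeros(G.shape[0]))


def src_predict_vector(model: SRCModel, x_raw: np.ndarray,
                       eps: float = 1e-12
                       ) -> Tuple[str, float, float, float]:
    """Classify one case vector (raw selected-feature values).

    Returns ``(label, residual_good, residual_poor, score)`` where score is
    the residual contrast in (-1, 1), higher = more poor-like.
    """
    x = standardize_apply(np.asarray(x_raw, dtype=np.float64),
                          model.mean_, model.sd_)
    alpha = sparse_code(model.dictionary, x, model.lam_code, gram=model.gram)
    if not np.any(alpha):
        warnings.warn("all-zero sparse code; falling back to majority class")
        return model.majority_label, float(np.linalg.norm(x)), \
            float(np.linalg.norm(x)), 0.0
    residuals = {}
    for c in LABELS:
        mask = model.column_labels == c
        recon = model.dictionary[:, mask] @ alpha[mask]
        residuals[c] = float(np.linalg.norm(x - recon))
    r_good, r_poor = residuals[GOOD], residuals[POOR]
    label = POOR if r_poor < r_good else GOOD
    score = (r_good - r_poor) / (r_good + r_poor + eps)
    return label, r_good, r_poor, float(score)


def src_predict(model: SRCModel, X_raw: np.ndarray
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Classify many case vectors; returns (labels, scores)."""
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=np.float64))
    labels, scores = [], []
    for row in X_raw:
        lab, _, _, s = src_predict_vector(model, row)
        labels.append(lab)
        scores.append(s)
    return np.asarray(labels, dtype=object), np.asarray(scores)


# ---------------------------------------------------------------------------
# Cross-validated lambda tuning
# ---------------------------------------------------------------------------

def _cv_evaluate(table: FeatureTable, selected: np.ndarray, folds: int,
                 seed: int, lam_code: float
                 ) -> Tuple[float, np.ndarray, np.ndarray]:
    """Pooled out-of-fold SRC accuracy for a fixed selected-feature set."""
    y = table.labels
    min_class = min(int((y == c).sum()) for c in LABELS)
    if folds > min_class:
        warnings.warn(f"reducing CV folds from {folds} to {min_class} "
                      "(minority class size)")
        folds = min_class
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_labels = np.empty(table.n_cases, dtype=object)
    oof_scores = np.zeros(table.n_cases)
    for tr, te in skf.split(table.X, y):
        model = fit_src(table.subset_rows(tr), selected, lam_code)
        labs, scores = src_predict(model, table.X[np.ix_(te, selected)])
        oof_labels[te] = labs
        oof_scores[te] = scores
    acc = float(np.mean(oof_labels == y))
    return acc, oof_labels, oof_scores


@dataclass
class TuneResult:
    best: SelectionResult
    oof_labels: np.ndarray
    oof_scores: np.ndarray
    path: List[Tuple[float, int, float]]   # (lambda, n_selected, cv accuracy)


def tune_selection(table: FeatureTable, lambda_grid: Sequence[float],
                   folds: int = 10, seed: int = 0, lam_code: float = 0.01,
                   n_features_override: Optional[int] = None) -> TuneResult:
    """Pick the penalty maximizing k-fold CV accuracy of the SRC.

    For each lambda, features are selected on the full training table
    (standardized in place for the selection step only) and the SRC is
    scored by stratified k-fold cross-validation with pooled out-of-fold
    predictions.  Ties break toward the sparser selection.

    ``n_features_override`` instead picks the grid point whose selected-set
    size is closest to the requested count.
    """
    if len(lambda_grid) == 0:
        raise ValueError("lambda grid must be non-empty")
    mean, sd = standardize_fit(table.X)
    std_table = FeatureTable(table.case_ids, table.feature_names,
                             standardize_apply(table.X, mean, sd),
                             table.labels)
    results = []
    for lam in sorted(lambda_grid, reverse=True):   # sparse to dense
        sel = select_features(std_table, lam)
        if sel.n_selected == 0:
            results.append((lam, sel, 0.0, None, None))
            continue
        acc, oof_l, oof_s = _cv_evaluate(table, sel.selected, folds, seed,
                                         lam_code)
        sel.cv_score = acc
        results.append((lam, sel, acc, oof_l, oof_s))

    if n_features_override is not None:
        lam, sel, acc, oof_l, oof_s = min(
            results, key=lambda r: (abs(r[1].n_selected - n_features_override),
                                    -r[0]))
    else:
        # max accuracy; ties -> fewer features, then larger lambda
        lam, sel, acc, oof_l, oof_s = max(
            results, key=lambda r: (r[2], -r[1].n_selected, r[0]))
    if oof_l is None:
        acc, oof_l, oof_s = 0.0, np.empty(0, dtype=object), np.empty(0)
    path = [(r[0], r[1].n_selected, r[2]) for r in results]
    return TuneResult(best=sel, oof_labels=oof_l, oof_scores=oof_s, path=path)
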