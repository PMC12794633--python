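"""Evaluation protocol and statistics.

Covers univariate feature screening (independent-sample t-tests), the
2:1 train/test split with stratified 10-fold cross-validation on the
training portion, the confusion-table metrics (ACC/SEN/SPE/PPV/NPV), ROC and
AUC, the DeLong test for paired AUC differences, and decision-curve
analysis (net benefit across threshold probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .imaging_core import GOOD, POOR
from .sparse_models import (
    FeatureTable,
    TuneResult,
    fit_src,
    src_predict,
    tune_selection,
)


# ---------------------------------------------------------------------------
# Univariate screening
# ---------------------------------------------------------------------------

def t_test_screen(table: FeatureTable, equal_var: bool = False) -> pd.Series:
    """Two-sided independent-sample t-test per feature (Welch by default).

    Features constant within both groups get p = 1 when the group means are
    equal (no evidence of difference) and p = 0 when they differ exactly.
    Returns a Series indexed by feature name.
    """
    g = table.X[table.labels == GOOD]
    b = table.X[table.labels == POOR]
    if len(g) < 2 or len(b) < 2:
        raise ValueError("need >= 2 cases per class for t-tests")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.ttest_ind(g, b, axis=0, equal_var=equal_var)
    p = np.asarray(p, dtype=np.float64)
    nan = ~np.isfinite(p)
    if nan.any():
        same = np.isclose(g.mean(axis=0), b.mean(axis=0))
        p[nan & same] = 1.0
        p[nan & ~same] = 0.0
    return pd.Series(p, index=table.feature_names, name="p_value")


# ---------------------------------------------------------------------------
# Confusion metrics / ROC / AUC
# ---------------------------------------------------------------------------

def confusion_metrics(y_true: Sequence, y_pred: Sequence,
                      positive) -> Dict[str, float]:
    """ACC, SEN, SPE, PPV, NPV from the 2x2 table with the given positive class."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    if pos_t.all() or not pos_t.any():
        raise ValueError("both classes must be present in y_true")
    tp = int((pos_t & pos_p).sum())
    tn = int((~pos_t & ~pos_p).sum())
    fp = int((~pos_t & pos_p).sum())
    fn = int((pos_t & ~pos_p).sum())
    n = tp + tn + fp + fn
    ppv = tp / (tp + fp) if (tp + fp) else np.nan
    npv = tn / (tn + fn) if (tn + fn) else np.nan
    if np.isnan(ppv) or np.isnan(npv):
        warnings.warn("a predicted class is empty; PPV/NPV undefined (NaN)")
    return {
        "ACC": (tp + tn) / n,
        "SEN": tp / (tp + fn),
        "SPE": tn / (tn + fp),
        "PPV": ppv,
        "NPV": npv,
        "TP": tp, "FN": fn, "TN": tn, "FP": fp,
    }


def roc_auc(y_true: Sequence, scores: Sequence,
            positive) -> Tuple[np.ndarray, float]:
    """ROC points and AUC (Mann-Whitney with half credit for ties).

    Returns ``(points, auc)`` where points is an (m, 2) array of
    (FPR, TPR) pairs from a sweep over the unique score thresholds.
    """
    y_true = np.asarray(y_true, dtype=object)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # Mann-Whitney AUC via midranks
    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    pts = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        pts.append((float((pred & ~pos).sum() / n_neg),
                    float((pred & pos).sum() / n_pos)))
    pts.append((1.0, 1.0))
    return np.array(pts), float(auc)


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _delong_structural(pos_scores: np.ndarray, neg_scores: np.ndarray
                       ) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-case structural components V10 (positives) and V01."""
    m, n = len(pos_scores), len(neg_scores)
    all_scores = np.concatenate([pos_scores, neg_scores])
    tx = stats.rankdata(pos_scores)
    ty = stats.rankdata(neg_scores)
    tz = stats.rankdata(all_scores)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_test(y_true: Sequence, scores_a: Sequence, scores_b: Sequence,
                positive=POOR) -> Tuple[float, float]:
    """DeLong test of the difference between two correlated AUCs.

    Returns ``(z, p)``; p is two-sided.  Degenerate (zero-variance)
    differences give p = 1 with a warning.
    """
    y_true = np.asarray(y_true, dtype=object)
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if not (len(y_true) == len(a) == len(b)):
        raise ValueError("scores must be paired on identical cases")
    pos = y_true == positive
    auc_a, v10_a, v01_a = _delong_structural(a[pos], a[~pos])
    auc_b, v10_b, v01_b = _delong_structural(b[pos], b[~pos])
    m, n = int(pos.sum()), int((~pos).sum())
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        warnings.warn("zero estimated variance of the AUC difference; p = 1")
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------

def decision_curve(y_true: Sequence, probs: Sequence,
                   thresholds: Optional[Sequence[float]] = None,
                   positive=POOR) -> pd.DataFrame:
    """Net benefit of treating at each threshold probability.

    ``NB(pt) = TP/n - (FP/n) * pt / (1 - pt)`` for the model, alongside the
    treat-all and treat-none reference strategies.
    """
    y_true = np.asarray(y_true, dtype=object)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    pos = y_true == positive
    n = len(y_true)
    prevalence = pos.mean()
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt)
        pred = probs >= pt
        tp = (pred & pos).sum() / n
        fp = (pred & ~pos).sum() / n
        rows.append({
            "threshold": pt,
            "model": tp - fp * odds,
            "treat_all": prevalence - (1 - prevalence) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Split plan and full protocol
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Stratified 2:1 split and fold count for the CV portion."""

    seed: int = 0
    test_fraction: float = 1.0 / 3.0
    folds: int = 10

    def split(self, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        idx = np.arange(len(labels))
        cv_idx, test_idx = train_test_split(
            idx, test_size=self.test_fraction, random_state=self.seed,
            stratify=labels,
        )
        return np.sort(cv_idx), np.sort(test_idx)


@dataclass
class ModelReport:
    name: str
    cv_metrics: Dict[str, float]
    cv_auc: float
    test_metrics: Dict[str, float]
    test_auc: float
    roc_points: np.ndarray
    test_scores: np.ndarray
    test_pred: np.ndarray
    n_selected: int
    selected_names: List[str]
    best_lambda: float


@dataclass
class EvalReport:
    models: Dict[str, ModelReport]
    delong: Dict[str, Tuple[float, float]]
    decision_curves: Dict[str, pd.DataFrame]
    test_labels: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "models": {}, "delong": {}}
        for name, m in self.models.items():
            out["models"][name] = {
                "cv": {k: m.cv_metrics[k] for k in
                       ("ACC", "SEN", "SPE", "PPV", "NPV")},
                "cv_auc": m.cv_auc,
                "test": {k: m.test_metrics[k] for k in
                         ("ACC", "SEN", "SPE", "PPV", "NPV")},
                "test_auc": m.test_auc,
                "n_selected": m.n_selected,
                "selected_features": m.selected_names,
                "lambda": m.best_lambda,
            }
        for pair, (z, p) in self.delong.items():
            out["delong"][pair] = {"z": z, "p": p}
        return out


def score_to_probability(score: np.ndarray) -> np.ndarray:
    """Map the SRC residual-contrast score from (-1, 1) to (0, 1)."""
    return (np.asarray(score) + 1.0) / 2.0


def run_protocol(table: FeatureTable, plan: SplitPlan,
                 feature_sets: Dict[str, List[str]],
                 lambda_grid: Optional[Sequence[float]] = None,
                 lam_code: float = 0.01,
                 positive=POOR,
                 n_features_override: Optional[int] = None) -> EvalReport:
    """Tune, fit and evaluate the SRC for each feature set.

    For every named feature set the penalty is tuned by stratified k-fold CV
    on the 2/3 training portion (pooled out-of-fold predictions give the CV
    metrics), the model is refit on the whole training portion, and
    evaluated once on the held-out third.  DeLong comparisons and decision
    curves are computed on the test set.
    """
    if lambda_grid is None:
        lambda_grid = np.geomspace(0.01, 0.5, 12)
    cv_idx, test_idx = plan.split(table.labels)
    train = table.subset_rows(cv_idx)
    test = table.subset_rows(test_idx)

    models: Dict[str, ModelReport] = {}
    for name, cols in feature_sets.items():
        tr = train.subset_columns(cols)
        te = test.subset_columns(cols)
        tuned: TuneResult = tune_selection(
            tr, lambda_grid, folds=plan.folds, seed=plan.seed,
            lam_code=lam_code, n_features_override=n_features_override,
        )
        sel = tuned.best
        if sel.n_selected == 0:
            raise RuntimeError(f"{name}: no features selected on the grid")
        cv_metrics = confusion_metrics(tr.labels, tuned.oof_labels, positive)
        _, cv_auc = roc_auc(tr.labels, tuned.oof_scores, positive)

        model = fit_src(tr, sel.selected, lam_code)
        pred, scores = src_predict(model, te.X[:, sel.selected])
        test_metrics = confusion_metrics(te.labels, pred, positive)
        pts, test_auc = roc_auc(te.labels, scores, positive)
        models[name] = ModelReport(
            name=name, cv_metrics=cv_metrics, cv_auc=cv_auc,
            test_metrics=test_metrics, test_auc=test_auc, roc_points=pts,
            test_scores=scores, test_pred=pred,
            n_selected=sel.n_selected, selected_names=sel.feature_names,
            best_lambda=sel.lam,
        )

    names = list(models)
    delong: Dict[str, Tuple[float, float]] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            delong[f"{a} vs {b}"] = delong_test(
                test.labels, models[a].test_scores, models[b].test_scores,
                positive,
            )
    curves = {
        name: decision_curve(test.labels,
                             score_to_probability(m.test_scores),
                             positive=positive)
        for name, m in models.items()
    }
    return EvalReport(models=models, delong=delong, decision_curves=curves,
                      test_labels=test.labels, seed=plan.seed)


# ---------------------------------------------------------------------------
# Deposited prediction tables
# ---------------------------------------------------------------------------

def metrics_from_predictions(df: pd.DataFrame, positive) -> Dict[str, float]:
    """Recompute ACC/SEN/SPE/PPV/NPV and AUC from a prediction table.

    Expects columns ``true_label``, ``predicted_label`` and
    ``predicted_score`` (one row per case), as deposited with published
    model results.
    """
    required = {"true_label", "predicted_label", "predicted_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    out = confusion_metrics(df["true_label"], df["predicted_label"], positive)
    _, auc = roc_auc(df["true_label"], df["predicted_score"], positive)
    out["AUC"] = auc
    return out
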