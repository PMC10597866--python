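"""RBF-kernel SVM with two-stage EFMO hyperparameter tuning, and the
confusion-matrix evaluation metrics.

The decision rule is y = sgn(Σ_i y_i α_i K(z, z_i) + b) with the radial
basis kernel K(z, z') = exp(−γ‖z − z'‖²).  Tuning is coordinate-wise:
stage 1 searches log10 γ ∈ [−4, 2] at fixed C0 = 1 for the best stratified
CV accuracy, stage 2 freezes γ* and searches log10 C ∈ [−2, 4].  Both
stages use EFMO as the search engine.

Evaluation reports sensitivity, specificity, accuracy, PPV and NPV from the
confusion counts (positive class = melanoma, label +1), plus the ROC curve
and its trapezoid AUC.  Ratios with zero denominators are reported as NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import efmo


@dataclass
class TuneConfig:
    log_gamma_bounds: tuple[float, float] = (-4.0, 2.0)
    log_c_bounds: tuple[float, float] = (-2.0, 4.0)
    c0: float = 1.0                # fixed penalty during the γ stage
    cv_folds: int = 5
    n_fish: int = 12
    max_iter: int = 10
    rounds: int = 1                # times the two-stage sweep repeats
    seed: int = 0


class SVMModel:
    """Fitted soft-margin RBF SVM with stored standardization statistics.

    Thin wrapper over sklearn's SVC exposing the dual-form decision
    function and JSON persistence (support vectors, dual coefficients,
    bias, scaler statistics, γ, C).
    """

    def __init__(self, C: float, gamma: float):
        if C <= 0 or gamma <= 0:
            raise ValueError("C and gamma must be positive")
        self.C = float(C)
        self.gamma = float(gamma)
        self.scaler_mean: np.ndarray | None = None
        self.scaler_scale: np.ndarray | None = None
        self.support_vectors: np.ndarray | None = None
        self.dual_coef: np.ndarray | None = None
        self.intercept: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("single-class training set")
        self.scaler_mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scaler_scale = scale
        svc = SVC(C=self.C, gamma=self.gamma, kernel="rbf")
        svc.fit((X - self.scaler_mean) / self.scaler_scale, y)
        self.support_vectors = svc.support_vectors_
        self.dual_coef = svc.dual_coef_.ravel()   # y_i * alpha_i
        self.intercept = float(svc.intercept_[0])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.support_vectors is None:
            raise ValueError("model is not fitted")
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0, 1, -1)

    def to_json(self) -> str:
        return json.dumps({
            "C": self.C, "gamma": self.gamma,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
        })

    @classmethod
    def from_json(cls, text: str) -> "SVMModel":
        d = json.loads(text)
        m = cls(d["C"], d["gamma"])
        m.scaler_mean = np.asarray(d["scaler_mean"])
        m.scaler_scale = np.asarray(d["scaler_scale"])
        m.support_vectors = np.asarray(d["support_vectors"])
        m.dual_coef = np.asarray(d["dual_coef"])
        m.intercept = d["intercept"]
        return m


def _masked_xy(table: pd.DataFrame, mask):
    y = table["label"].to_numpy()
    X = table.drop(columns="label").to_numpy()
    if mask is not None:
        X = X[:, np.asarray(mask, dtype=bool)]
    return X, y


def train_svm(table: pd.DataFrame, mask=None, C: float = 1.0,
              gamma: float = 0.1) -> SVMModel:
    """Fit an RBF SVM on the masked features of a labeled table."""
    X, y = _masked_xy(table, mask)
    return SVMModel(C, gamma).fit(X, y)


def _cv_accuracy(X, y, C, gamma, folds, seed) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = make_pipeline(StandardScaler(), SVC(C=C, gamma=gamma))
    return float(cross_val_score(clf, X, y, cv=cv).mean())


def tune_gamma_then_C(table: pd.DataFrame, mask=None,
                      config: TuneConfig | None = None):
    """Two-stage EFMO hyperparameter search: γ at fixed C0, then C at γ*.

    Returns (gamma*, C*, fitted model).  Deterministic given config.seed.
    """
    config = config or TuneConfig()
    X, y = _masked_xy(table, mask)
    c_star = config.c0
    g_star = None
    for rnd in range(config.rounds):
        g_star = _tune_1d(
            lambda lg: -_cv_accuracy(X, y, c_star, 10.0 ** lg,
                                     config.cv_folds, config.seed),
            config.log_gamma_bounds, config, config.seed + 2 * rnd)
        c_star = _tune_1d(
            lambda lc: -_cv_accuracy(X, y, 10.0 ** lc, g_star,
                                     config.cv_folds, config.seed),
            config.log_c_bounds, config, config.seed + 2 * rnd + 1)
    model = SVMModel(c_star, g_star).fit(X, y)
    return g_star, c_star, model


def _tune_1d(neg_objective, bounds, config: TuneConfig, seed: int) -> float:
    cache: dict[float, float] = {}

    def f(x):
        key = round(float(x[0]), 3)   # CV accuracy is a step function
        if key not in cache:
            cache[key] = neg_objective(key)
        return cache[key]

    space = efmo.SearchSpace([bounds[0]], [bounds[1]], f)
    res = efmo.optimize(space, n_fish=config.n_fish, max_iter=config.max_iter,
                        seed=seed)
    return 10.0 ** float(res.best_position[0])


# -- evaluation --------------------------------------------------------------

@dataclass
class ClassMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    auc: float = float("nan")

    def as_row(self) -> dict:
        return {"Accuracy": self.accuracy, "Sensitivity": self.sensitivity,
                "Specificity": self.specificity, "PPV": self.ppv,
                "NPV": self.npv}


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def evaluate(predictions: np.ndarray, truths: np.ndarray) -> ClassMetrics:
    """Confusion counts and the five derived fractions (positive = +1)."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("prediction/truth length mismatch")
    pos = truths == 1
    pred_pos = predictions == 1
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    return ClassMetrics(
        tp, fp, tn, fn,
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        ppv=_ratio(tp, tp + fp, "PPV"),
        npv=_ratio(tn, tn + fn, "NPV"),
    )


def roc_curve(decision_scores: np.ndarray, truths: np.ndarray):
    """ROC points by threshold sweep and the trapezoid AUC.

    Returns ((fpr, tpr, thresholds), auc); AUC equals the normalized
    Mann-Whitney U statistic (probability a positive outranks a negative).
    """
    truths = np.asarray(truths)
    if len(np.unique(truths)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = skmetrics.roc_curve(truths, np.asarray(decision_scores),
                                        pos_label=1)
    return (fpr, tpr, thr), float(skmetrics.auc(fpr, tpr))
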