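"""Classifier training, selection and evaluation for artifact detection.

The positive class is *artifacted*: the task is to flag contaminated
windows so the remaining ones can be trusted as clean uterine contractions.
Three classifier families are supported -- linear and quadratic
discriminant analysis and an RBF-kernel support vector machine (the SVM is
wrapped in a feature-standardising pipeline; the discriminant analyses are
affine-invariant, so they need none).

Model assessment follows a repeated two-fold protocol: each repetition
draws a random stratified 50/50 split, trains on each half and evaluates on
the other, and the report carries mean +/- SD of accuracy, sensitivity,
specificity, PPV and NPV over repetitions (fold-level values are retained
too).  Feature subsets are chosen by greedy sequential forward selection on
the same cross-validated error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES

log = logging.getLogger("ehgkit")

CLASSIFIER_KINDS = ("lda", "qda", "svm_rbf")
POSITIVE_LABEL = "artifacted"
NEGATIVE_LABEL = "nonartifacted"
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")

#: the seven-feature subset most often found optimal for QDA-based artifact
#: detection in intrapartum EHG; a convenient preset, but sequential forward
#: selection should be re-run on any new dataset.
DEFAULT_ARTIFACT_FEATURES: tuple[str, ...] = (
    "E3", "RA", "kappa", "MD_bs", "MD_x", "En", "Tr_z",
)


def _as_xy(
    table: pd.DataFrame, feature_subset: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feats = list(feature_subset) if feature_subset else [
        f for f in FEATURE_NAMES if f in table.columns
    ]
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise ValueError(f"table lacks feature columns {missing}")
    if "label" not in table.columns:
        raise ValueError("table lacks a 'label' column")
    X = table[feats].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    y = (table["label"].to_numpy() == POSITIVE_LABEL).astype(int)
    return X, y, feats


def evaluate(y_pred: np.ndarray, y_true: np.ndarray) -> dict[str, float]:
    """Confusion-matrix panel in percent; positive class = artifacted (1)."""
    y_pred = np.asarray(y_pred).astype(int)
    y_true = np.asarray(y_true).astype(int)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/label length mismatch")
    if len(np.unique(y_true)) < 2:
        raise ValueError("labels contain a single class; sensitivity/specificity undefined")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    n = tp + tn + fp + fn
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "ppv": 100.0 * tp / (tp + fp) if (tp + fp) else float("nan"),
        "npv": 100.0 * tn / (tn + fn) if (tn + fn) else float("nan"),
    }


def make_classifier(kind: str, hyperparams: Optional[dict] = None):
    """Fresh unfitted estimator of the requested kind."""
    hp = dict(hyperparams or {})
    if kind == "lda":
        return LinearDiscriminantAnalysis(solver="svd")
    if kind == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=hp.get("reg_param", 0.0))
    if kind == "svm_rbf":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"))),
        ])
    raise ValueError(f"unknown classifier kind {kind!r}")


class _RidgeQDA:
    """Gaussian quadratic discriminant with a per-class covariance ridge.

    Fallback for class covariances too singular for the standard QDA
    solver: Sigma_c is replaced by Sigma_c + eps*I with
    eps = reg * max(trace(Sigma_c)/d, 1), which for duplicated training
    points degenerates gracefully to nearest-class-mean assignment.
    """

    def __init__(self, reg: float = 1e-6):
        self.reg = reg

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RidgeQDA":
        d = X.shape[1]
        self.classes_ = np.unique(y)
        self._params = []
        for cls in self.classes_:
            sub = X[y == cls]
            mean = sub.mean(axis=0)
            cov = np.atleast_2d(np.cov(sub, rowvar=False)) if sub.shape[0] > 1 \
                else np.zeros((d, d))
            eps = self.reg * max(np.trace(cov) / d, 1.0)
            cov = cov + eps * np.eye(d)
            prec = np.linalg.inv(cov)
            _, logdet = np.linalg.slogdet(cov)
            prior = sub.shape[0] / X.shape[0]
            self._params.append((mean, prec, logdet, np.log(prior)))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = []
        for mean, prec, logdet, logprior in self._params:
            diff = X - mean
            maha = np.einsum("ij,jk,ik->i", diff, prec, diff)
            scores.append(-0.5 * maha - 0.5 * logdet + logprior)
        return self.classes_[np.argmax(np.column_stack(scores), axis=1)]


def _fit(kind: str, X: np.ndarray, y: np.ndarray, hyperparams: Optional[dict] = None):
    """Fit one estimator, regularising discriminants only when singular."""
    clf = make_classifier(kind, hyperparams)
    try:
        clf.fit(X, y)
    except (np.linalg.LinAlgError, IndexError):
        if kind == "qda":
            log.warning("singular class covariance; falling back to ridge QDA")
            clf = _RidgeQDA().fit(X, y)
        elif kind == "lda":
            log.warning("singular scatter; falling back to shrinkage LDA")
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            clf.fit(X, y)
        else:
            raise
    return clf


@dataclass
class TrainedModel:
    """A fitted classifier bound to its feature subset."""

    kind: str
    features: list[str]
    estimator: object
    hyperparams: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=float)
        return self.estimator.predict(X)


def train_classifier(
    kind: str,
    table: pd.DataFrame,
    feature_subset: Optional[Sequence[str]] = None,
    hyperparams: Optional[dict] = None,
) -> TrainedModel:
    """Fit one classifier on the full table (no internal validation)."""
    X, y, feats = _as_xy(table, feature_subset)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    est = _fit(kind, X, y, hyperparams)
    return TrainedModel(kind=kind, features=feats, estimator=est,
                        hyperparams=dict(hyperparams or {}))


@dataclass
class CVReport:
    """Repeated two-fold cross-validation summary."""

    kind: str
    features: list[str]
    reps: int
    seed: int
    per_rep: pd.DataFrame        # one row per repetition, METRIC_NAMES columns
    per_fold: pd.DataFrame       # one row per fold evaluation
    summary: dict                # metric -> (mean, sd) over repetitions

    def to_text(self) -> str:
        lines = [
            f"classifier: {self.kind}",
            f"features: {','.join(self.features)}",
            f"repetitions: {self.reps}",
            f"seed: {self.seed}",
        ]
        for mname in METRIC_NAMES:
            mean, sd = self.summary[mname]
            lines.append(f"{mname}: {mean:.2f} +/- {sd:.2f} %")
        lines.append("")
        lines.append(self.per_rep.to_csv(sep="\t", index=False,
                                         float_format="%.4f").rstrip())
        return "\n".join(lines) + "\n"


def repeated_two_fold_cv(
    table: pd.DataFrame,
    kind: str,
    feature_subset: Optional[Sequence[str]] = None,
    reps: int = 50,
    seed: int = 0,
    hyperparams: Optional[dict] = None,
) -> CVReport:
    """`reps` random stratified 50/50 splits, each evaluated in both directions."""
    X, y, feats = _as_xy(table, feature_subset)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 rows for a stratified 50/50 split")
    rng = np.random.default_rng(seed)
    fold_rows, rep_rows = [], []
    for rep in range(reps):
        rs = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=rs)
        rep_metrics = []
        for train_idx, test_idx in skf.split(X, y):
            clf = _fit(kind, X[train_idx], y[train_idx], hyperparams)
            m = evaluate(clf.predict(X[test_idx]), y[test_idx])
            fold_rows.append({"rep": rep, **m})
            rep_metrics.append(m)
        rep_rows.append({
            "rep": rep,
            **{k: float(np.mean([m[k] for m in rep_metrics])) for k in METRIC_NAMES},
        })
    per_fold = pd.DataFrame(fold_rows)
    per_rep = pd.DataFrame(rep_rows)
    summary = {
        k: (float(per_rep[k].mean()), float(per_rep[k].std(ddof=1)) if reps > 1 else 0.0)
        for k in METRIC_NAMES
    }
    return CVReport(kind=kind, features=feats, reps=reps, seed=seed,
                    per_rep=per_rep, per_fold=per_fold, summary=summary)


def optimize_svm_params(
    table: pd.DataFrame,
    feature_subset: Optional[Sequence[str]] = None,
    seed: int = 0,
    maxiter: int = 40,
) -> tuple[float, float]:
    """Nelder-Mead search over (log10 C, log10 gamma) minimising CV error.

    The objective is the mean two-fold cross-validated error over a small
    number of seeded splits; the simplex starts at C = 1, gamma = 1/d.
    """
    X, y, feats = _as_xy(table, feature_subset)
    rng = np.random.default_rng(seed)
    split_seeds = [int(rng.integers(2**31)) for _ in range(2)]

    def cv_error(logc: float, logg: float) -> float:
        c = 10.0 ** np.clip(logc, -6, 6)
        g = 10.0 ** np.clip(logg, -8, 6)
        errs = []
        for rs in split_seeds:
            skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=rs)
            for tr, te in skf.split(X, y):
                clf = make_classifier("svm_rbf", {"C": c, "gamma": g})
                clf.fit(X[tr], y[tr])
                errs.append(np.mean(clf.predict(X[te]) != y[te]))
        return float(np.mean(errs))

    x0 = np.array([0.0, np.log10(1.0 / max(len(feats), 1))])
    res = minimize(
        lambda p: cv_error(p[0], p[1]), x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 0.05, "fatol": 1e-4},
    )
    c = float(10.0 ** np.clip(res.x[0], -6, 6))
    g = float(10.0 ** np.clip(res.x[1], -8, 6))
    return c, g


def single_feature_screen(
    table: pd.DataFrame,
    kinds: Sequence[str] = CLASSIFIER_KINDS,
    reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean CV accuracy of every (single feature, classifier) pair.

    Rows are features, columns classifier kinds -- the individual
    discriminatory capacity of each feature.
    """
    feats = [f for f in FEATURE_NAMES if f in table.columns]
    out = pd.DataFrame(index=feats, columns=list(kinds), dtype=float)
    for f in feats:
        for kind in kinds:
            rep = repeated_two_fold_cv(table, kind, [f], reps=reps, seed=seed)
            out.loc[f, kind] = rep.summary["accuracy"][0]
    return out


@dataclass
class SFSResult:
    """Outcome of sequential forward selection."""

    selected: list[str]          # in order of addition
    error_trace: list[float]     # CV error (%) after each addition
    baseline_error: float        # majority-class error before any feature


def sequential_forward_selection(
    table: pd.DataFrame,
    kind: str,
    candidate_features: Optional[Sequence[str]] = None,
    reps: int = 10,
    seed: int = 0,
    tol_pp: float = 0.1,
    hyperparams: Optional[dict] = None,
) -> SFSResult:
    """Greedy forward selection on repeated-two-fold CV error.

    At each step the candidate whose addition yields the lowest CV error is
    taken, provided it improves the current error by more than `tol_pp`
    percentage points (the tolerance keeps pure-noise features out).
    """
    candidates = list(candidate_features) if candidate_features else [
        f for f in FEATURE_NAMES if f in table.columns
    ]
    y = (table["label"].to_numpy() == POSITIVE_LABEL).astype(int)
    majority = max(np.mean(y), 1 - np.mean(y))
    best_err = 100.0 * (1.0 - majority)
    baseline_error = best_err
    selected: list[str] = []
    trace: list[float] = []
    remaining = list(candidates)
    while remaining:
        errs = []
        for cand in remaining:
            rep = repeated_two_fold_cv(
                table, kind, selected + [cand], reps=reps, seed=seed,
                hyperparams=hyperparams,
            )
            errs.append(100.0 - rep.summary["accuracy"][0])
        k = int(np.argmin(errs))
        if best_err - errs[k] <= tol_pp:
            break
        selected.append(remaining.pop(k))
        best_err = errs[k]
        trace.append(best_err)
    return SFSResult(selected=selected, error_trace=trace,
                     baseline_error=baseline_error)


def holdout_test(
    kind: str,
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    feature_subset: Optional[Sequence[str]] = None,
    hyperparams: Optional[dict] = None,
) -> dict[str, float]:
    """Train on `train_table`, evaluate once on `test_table`.

    Guards against leakage: when both tables carry a ``group_id`` column
    (recording/subject identity), the two id sets must be disjoint.
    """
    if len(test_table) == 0:
        raise ValueError("test table is empty")
    if "group_id" in train_table.columns and "group_id" in test_table.columns:
        overlap = set(train_table["group_id"]) & set(test_table["group_id"])
        if overlap:
            raise ValueError(f"group_id leakage between train and test: {sorted(overlap)}")
    model = train_classifier(kind, train_table, feature_subset, hyperparams)
    y_true = (test_table["label"].to_numpy() == POSITIVE_LABEL).astype(int)
    y_pred = model.predict(test_table)
    return evaluate(y_pred, y_true)
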