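"""Supervised classification: stratified partitioning, AUROC-optimized
hyperparameter tuning with 10-fold x 3 repeated stratified cross-validation,
overfitting diagnostics (train - CV AUROC gap), and hybrid Monte-Carlo
learning curves at fixed hyperparameters.

Six algorithms share one contract (fit + class-probability predictor):
random forest, gradient-boosted trees (XGBoost), k-nearest neighbors,
penalized logistic regression (elastic net, parametrized like glmnet by
mixing alpha and penalty strength lambda), polynomial-kernel SVM, and
Gaussian naive Bayes. Grid ties break toward the simpler / more strongly
regularized setting, so tuning is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC
from xgboost import XGBClassifier

ALGORITHMS = ("rf", "xgb", "knn", "penalized_logistic", "svm", "naive_bayes")


# --- stratified partition ----------------------------------------------------


@dataclass
class Partition:
    train_ids: list
    test_ids: list
    train_counts: dict
    test_counts: dict
    seed: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels: pd.Series, train_fraction: float = 0.8, seed: int = 0) -> Partition:
    """Per-class round-half-up split; sampling uniform within class.

    ``labels`` is indexed by sample id; any label alphabet works (diagnostic
    groups G1/G2/G3 here, so an 80/20 split of 50/45/46 gives 113 train and
    28 test samples with test counts 10/9/9).
    """
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    train_counts, test_counts = {}, {}
    for cls in sorted(labels.unique()):
        ids = list(labels.index[labels == cls])
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = _round_half_up(train_fraction * len(ids))
        if n_train == 0:
            raise ValueError(f"class {cls!r} would get 0 training samples")
        perm = rng.permutation(len(ids))
        chosen = [ids[i] for i in perm[:n_train]]
        rest = [ids[i] for i in perm[n_train:]]
        train_ids += chosen
        test_ids += rest
        train_counts[cls] = n_train
        test_counts[cls] = len(rest)
    if not test_ids:
        raise ValueError("test partition is empty; lower train_fraction")
    return Partition(
        train_ids=sorted(train_ids, key=list(labels.index).index),
        test_ids=sorted(test_ids, key=list(labels.index).index),
        train_counts=train_counts,
        test_counts=test_counts,
        seed=seed,
    )


# --- model zoo ---------------------------------------------------------------


def _build_model(algorithm_id: str, params: dict, n_samples: int, seed: int):
    if algorithm_id == "rf":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 300),
            max_features=params.get("max_features", "sqrt"),
            min_samples_leaf=params.get("min_samples_leaf", 1),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm_id == "xgb":
        return XGBClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth", 3),
            learning_rate=params.get("learning_rate", 0.1),
            subsample=params.get("subsample", 0.8),
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if algorithm_id == "knn":
        return KNeighborsClassifier(n_neighbors=params.get("k", 7))
    if algorithm_id == "penalized_logistic":
        alpha = params.get("alpha", 0.0)  # mixing: 0 = ridge, 1 = lasso
        lam = params.get("lam", 0.06)  # penalty strength on the glmnet scale
        c = 1.0 / (lam * n_samples)
        # pure-ridge and pure-lasso corners have fast exact solvers; only the
        # mixed elastic net needs saga
        if alpha == 0.0:
            return LogisticRegression(l1_ratio=0.0, solver="lbfgs", C=c, max_iter=5000)
        if alpha == 1.0:
            return LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c, max_iter=5000)
        return LogisticRegression(solver="saga", l1_ratio=alpha, C=c, max_iter=5000, tol=1e-4)
    if algorithm_id == "svm":
        base = SVC(
            kernel="poly",
            degree=params.get("degree", 2),
            C=params.get("C", 1.0),
            coef0=params.get("coef0", 1.0),
            random_state=seed,
        )
        # Platt-scaled probabilities on held-out folds (deterministic:
        # StratifiedKFold without shuffling)
        return CalibratedClassifierCV(base, method="sigmoid", cv=3, ensemble=False)
    if algorithm_id == "naive_bayes":
        return GaussianNB(var_smoothing=params.get("var_smoothing", 1e-9))
    raise ValueError(f"unknown algorithm {algorithm_id!r}; choose from {ALGORITHMS}")


def default_grid(algorithm_id: str) -> list[dict]:
    """Conventional search grids; the elastic-net grid spans mixing values
    {0, .25, .5, .75, 1} x 20 log-spaced penalties in [1e-4, 1]. All grids
    can be overridden via the ``grid`` argument of :func:`tune_and_fit`."""
    if algorithm_id == "penalized_logistic":
        return [
            {"alpha": a, "lam": float(l)}
            for a in (0.0, 0.25, 0.5, 0.75, 1.0)
            for l in np.logspace(-4, 0, 20)
        ]
    if algorithm_id == "rf":
        return [
            {"max_features": mf, "min_samples_leaf": msl}
            for mf in ("sqrt", 0.5)
            for msl in (1, 3)
        ]
    if algorithm_id == "xgb":
        return [
            {"max_depth": d, "learning_rate": lr}
            for d in (2, 3)
            for lr in (0.1, 0.3)
        ]
    if algorithm_id == "knn":
        return [{"k": k} for k in (5, 7, 9, 11, 15)]
    if algorithm_id == "svm":
        return [{"degree": d, "C": c} for d in (1, 2, 3) for c in (0.25, 0.5, 1.0)]
    if algorithm_id == "naive_bayes":
        return [{"var_smoothing": v} for v in (1e-9, 1e-7, 1e-5)]
    raise ValueError(f"unknown algorithm {algorithm_id!r}")


def _simplicity_key(algorithm_id: str, params: dict):
    """Orders grid points simplest / most regularized first (tie-break)."""
    if algorithm_id == "penalized_logistic":
        return (-params.get("lam", 0.06), -params.get("alpha", 0.0))
    if algorithm_id == "knn":
        return (-params.get("k", 7),)
    if algorithm_id == "rf":
        return (-params.get("min_samples_leaf", 1), params.get("max_features") != "sqrt")
    if algorithm_id == "xgb":
        return (params.get("max_depth", 3), params.get("learning_rate", 0.1))
    if algorithm_id == "svm":
        return (params.get("degree", 2), params.get("C", 1.0))
    if algorithm_id == "naive_bayes":
        return (-params.get("var_smoothing", 1e-9),)
    return ()


@dataclass
class FittedClassifier:
    algorithm_id: str
    hyperparameters: dict
    model: object
    feature_ids: list[str]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(case) for each row of a samples x features array."""
        return self.model.predict_proba(np.asarray(x, dtype=float))[:, 1]


@dataclass
class CvResult:
    grid_results: pd.DataFrame  # one row per setting: params, mean, sd
    chosen: dict
    fold_aurocs: np.ndarray  # per-fold AUROCs of the chosen setting
    cv_mean: float
    cv_sd: float


def tune_and_fit(
    x: np.ndarray,
    labels,
    algorithm_id: str,
    grid: list[dict] | None = None,
    cv_folds: int = 10,
    cv_repeats: int = 3,
    seed: int = 0,
    feature_ids=None,
) -> tuple[FittedClassifier, CvResult]:
    """Grid search by repeated stratified CV with AUROC as the metric.

    Operates on the training partition only. The best mean-AUROC setting is
    refit on the full training data; exact ties go to the simpler setting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=int)
    grid = grid if grid is not None else default_grid(algorithm_id)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    counts = np.bincount(y)
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) cannot stratify into {cv_folds} folds"
        )
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    splits = list(cv.split(x, y))

    rows = []
    fold_aucs_by_setting = []
    for params in grid:
        aucs = []
        for tr, te in splits:
            model = _build_model(algorithm_id, params, n_samples=len(tr), seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x[tr], y[tr])
            aucs.append(roc_auc_score(y[te], model.predict_proba(x[te])[:, 1]))
        aucs = np.asarray(aucs)
        rows.append({**params, "cv_auroc_mean": aucs.mean(), "cv_auroc_sd": aucs.std(ddof=1)})
        fold_aucs_by_setting.append(aucs)

    order = sorted(range(len(grid)), key=lambda i: _simplicity_key(algorithm_id, grid[i]))
    best_i, best_mean = order[0], -np.inf
    for i in order:
        m = rows[i]["cv_auroc_mean"]
        if m > best_mean + 1e-12:
            best_mean, best_i = m, i
    chosen = grid[best_i]

    model = _build_model(algorithm_id, chosen, n_samples=len(y), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    fitted = FittedClassifier(
        algorithm_id=algorithm_id,
        hyperparameters=dict(chosen),
        model=model,
        feature_ids=list(feature_ids) if feature_ids is not None else [],
    )
    cvres = CvResult(
        grid_results=pd.DataFrame(rows),
        chosen=dict(chosen),
        fold_aurocs=fold_aucs_by_setting[best_i],
        cv_mean=float(fold_aucs_by_setting[best_i].mean()),
        cv_sd=float(fold_aucs_by_setting[best_i].std(ddof=1)),
    )
    return fitted, cvres


def overfit_gap(train_auroc: float, cv_mean: float, flag_threshold_pct: float = 5.0):
    """Overfitting diagnostic: Delta = train - CV AUROC and its % of CV AUROC.

    Returns (delta, percent, stable) where ``stable`` is True when the
    percent gap is below the threshold (default 5%); the flag is withheld
    (None) when the CV AUROC is not better than chance.
    """
    delta = train_auroc - cv_mean
    percent = 100.0 * delta / cv_mean
    stable = None if cv_mean <= 0.5 else bool(percent < flag_threshold_pct)
    return delta, percent, stable


@dataclass
class LearningCurve:
    fractions: list[float]
    mean_auroc: list[float]
    sem_auroc: list[float]
    repeats: int
    skipped: list[float] = field(default_factory=list)


def hybrid_learning_curve(
    x: np.ndarray,
    labels,
    algorithm_id: str,
    hyperparameters: dict,
    fractions=tuple(np.round(np.arange(0.1, 0.91, 0.1), 2)),
    repeats: int = 10,
    seed: int = 0,
) -> LearningCurve:
    """Repeated stratified hold-out AUROC across training-set fractions.

    For each fraction f and repeat: a stratified subsample of size f of the
    training set is fit with the fixed hyperparameters (no re-tuning) and
    scored on the complementary (1 - f) hold-out. Fractions leaving either
    side single-class are skipped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    out_f, out_m, out_s, skipped = [], [], [], []
    for f in fractions:
        aucs = []
        for _ in range(repeats):
            fit_idx, hold_idx = [], []
            for cls in np.unique(y):
                ids = np.where(y == cls)[0]
                n_fit = _round_half_up(f * ids.size)
                perm = rng.permutation(ids)
                fit_idx += list(perm[:n_fit])
                hold_idx += list(perm[n_fit:])
            fit_idx, hold_idx = np.array(fit_idx), np.array(hold_idx)
            if (
                fit_idx.size == 0
                or hold_idx.size == 0
                or np.unique(y[fit_idx]).size < 2
                or np.unique(y[hold_idx]).size < 2
            ):
                aucs = None
                break
            model = _build_model(algorithm_id, hyperparameters, n_samples=fit_idx.size, seed=int(rng.integers(2**31 - 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x[fit_idx], y[fit_idx])
            aucs.append(roc_auc_score(y[hold_idx], model.predict_proba(x[hold_idx])[:, 1]))
        if aucs is None:
            warnings.warn(f"fraction {f} leaves a single-class side; skipped", stacklevel=2)
            skipped.append(float(f))
            continue
        aucs = np.asarray(aucs)
        out_f.append(float(f))
        out_m.append(float(aucs.mean()))
        out_s.append(float(aucs.std(ddof=1) / np.sqrt(aucs.size)) if aucs.size > 1 else 0.0)
    return LearningCurve(fractions=out_f, mean_auroc=out_m, sem_auroc=out_s, repeats=repeats, skipped=skipped)
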