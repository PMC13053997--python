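"""PCA-based benchmark classifier.

PCA on the z-scored significant-feature panel, Horn-style Monte-Carlo
parallel analysis to decide how many principal components carry signal
(observed eigenvalues must beat the 95th percentile of eigenvalues from
standard-normal matrices of the same shape), then a maximum-likelihood
logistic regression on the retained PC scores.

The benchmark is deliberately fit on the full dataset with no train/test
split; its metrics are an optimistic reference against which the properly
validated supervised models are compared, never a deployable model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AbundanceMatrix


@dataclass
class PcaModel:
    feature_ids: list[str]
    loadings: np.ndarray  # feature x PC
    eigenvalues: np.ndarray  # non-increasing
    explained_variance_fraction: np.ndarray
    n_retained: int

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Project (samples x features) data onto the retained PCs."""
        return x @ self.loadings[:, : self.n_retained]


@dataclass
class PcaBenchmarkModel:
    pca: PcaModel
    coef: np.ndarray  # intercept first, then one coefficient per retained PC
    threshold: float = 0.5
    separation_warning: bool = False

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        s = self.pca.scores(x)
        eta = self.coef[0] + s @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def _pca_eigh(x: np.ndarray):
    """Eigen-decomposition of the covariance of column-centered data via SVD.

    Population (1/n) covariance, matching the z-score convention, so the
    eigenvalue sum of a z-scored panel equals the number of features.
    Returns (eigenvalues desc, loadings feature x PC) with the sign of each
    loading vector fixed so its largest-|.| element is positive.
    """
    n = x.shape[0]
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / n
    load = vt.T
    for k in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, k]))
        if load[i, k] < 0:
            load[:, k] = -load[:, k]
    return eig, load


def parallel_analysis(
    matrix_or_x, n_sim: int = 1000, percentile: float = 95.0, seed: int = 0
) -> int:
    """Number of PCs whose eigenvalues beat Monte-Carlo noise thresholds.

    For each PC index j the observed eigenvalue is compared with the given
    percentile of the j-th largest eigenvalues across ``n_sim`` standard
    normal matrices of identical shape (appropriate because the input data
    are z-scored); the leading run of exceedances is retained.
    """
    x = _as_samples_by_features(matrix_or_x)
    n, p = x.shape
    if n < 2:
        raise ValueError("parallel analysis needs at least 2 samples")
    eig_obs, _ = _pca_eigh(x)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, min(n, p)))
    for i in range(n_sim):
        e, _ = _pca_eigh(rng.standard_normal((n, p)))
        sims[i] = e[: sims.shape[1]]
    thresh = np.percentile(sims, percentile, axis=0)
    n_retained = 0
    for j in range(min(eig_obs.size, thresh.size)):
        if eig_obs[j] > thresh[j]:
            n_retained += 1
        else:
            break
    return n_retained


def _as_samples_by_features(matrix_or_x) -> np.ndarray:
    if isinstance(matrix_or_x, AbundanceMatrix):
        return matrix_or_x.values.to_numpy(dtype=float).T  # proteins x samples -> transpose
    return np.asarray(matrix_or_x, dtype=float)


def _logistic_fit_irls(s: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 200):
    """Maximum-likelihood logistic regression by IRLS with optional ridge."""
    n, k = s.shape
    design = np.column_stack([np.ones(n), s])
    beta = np.zeros(k + 1)
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = design.T @ (y - mu) - ridge * beta
        hess = design.T @ (design * w[:, None]) + ridge * np.eye(k + 1)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def fit_pca_benchmark(
    matrix: AbundanceMatrix,
    feature_ids,
    labels,
    n_sim: int = 1000,
    seed: int = 0,
    min_retained: int = 1,
) -> PcaBenchmarkModel:
    """Fit PCA + parallel-analysis retention + logistic regression on scores.

    ``labels``: binary (1 = case, i.e. G2 u G3). When the logistic fit
    separates perfectly, a tiny ridge (1e-8) stabilizer is added and a
    warning flag recorded.
    """
    feature_ids = list(feature_ids)
    missing = [f for f in feature_ids if f not in matrix.protein_ids]
    if missing:
        raise KeyError(f"panel features absent from matrix: {missing}")
    x = matrix.values.loc[feature_ids].to_numpy(dtype=float).T  # samples x features
    y = np.asarray(labels, dtype=float)

    eig, load = _pca_eigh(x)
    n_ret = parallel_analysis(x, n_sim=n_sim, seed=seed)
    n_ret = max(n_ret, min_retained)
    pca = PcaModel(
        feature_ids=feature_ids,
        loadings=load,
        eigenvalues=eig,
        explained_variance_fraction=eig / eig.sum(),
        n_retained=n_ret,
    )

    scores = x @ load[:, :n_ret]
    separation = False
    try:
        beta = _logistic_fit_irls(scores, y, ridge=0.0)
        eta = np.column_stack([np.ones(len(y)), scores]) @ beta
        if np.max(np.abs(eta)) > 30.0 or not np.all(np.isfinite(beta)):
            raise FloatingPointError("separation")
    except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
        separation = True
        beta = _logistic_fit_irls(scores, y, ridge=1e-8)
    return PcaBenchmarkModel(pca=pca, coef=beta, separation_warning=separation)


def redundant_group_collapse(feature_ids, families: dict) -> list[str]:
    """Collapse designated redundant families to their representatives.

    ``families`` maps representative id -> iterable of family member ids
    (e.g. one hemoglobin protein standing in for all hemoglobin groups).
    From each family present in the panel only the representative is kept;
    features in no family pass through unchanged, order preserved.
    """
    feature_ids = list(feature_ids)
    drop: set = set()
    for rep, members in families.items():
        members = set(members)
        if rep not in members:
            raise ValueError(f"representative {rep!r} not in its family")
        drop |= members - {rep}
    return [f for f in feature_ids if f not in drop]
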