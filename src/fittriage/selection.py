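"""Multi-seed, multi-algorithm feature ranking with Borda-count consensus.

Five selectors (random forest, a regularized tree ensemble, Boruta-style
shadow-feature testing, SVM-RFE, and L1-penalized logistic regression) are
each run many times with different seeds on the training partition. Each
run's top-K ranking contributes Borda points (K - rank + 1); points are
summed into a per-algorithm consensus, and the per-algorithm consensus lists
are aggregated the same way into the final top-K panel. Stability across
seeds is summarized as the mean pairwise Spearman correlation of top-k
rankings for k = 3..K.

The Boruta and regularized-ensemble selectors are implemented here on top of
scikit-learn (no Python package provides them); the SVM-RFE ranking follows
the kernel-SVM convention of ranking with a resampled per-feature ROC-AUC
filter, with the radial SVM cross-validated to score subset sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import AbundanceMatrix

ALGORITHMS = ("rf", "rrf", "boruta", "svm_rfe", "lasso")


@dataclass
class RankedList:
    algorithm_id: str
    seed: int
    scores: pd.Series  # per-feature importance, higher = better
    ranking: list[str]  # features by decreasing score, deterministic ties
    meta: dict = field(default_factory=dict)


@dataclass
class ConsensusRanking:
    borda_scores: pd.Series
    top_k: list[str]
    source: str  # per_algorithm / across_algorithms


def _order_features(scores: pd.Series) -> list[str]:
    """Decreasing score; ties broken lexicographically by feature id
    (stable sort over a lexicographically pre-sorted index)."""
    df = pd.DataFrame({"score": scores.sort_index()})
    df = df.sort_values("score", ascending=False, kind="mergesort")
    return list(df.index)


def _as_xy(matrix, labels):
    if isinstance(matrix, AbundanceMatrix):
        x = matrix.values.to_numpy(dtype=float).T
        features = list(matrix.protein_ids)
    else:
        x = matrix.to_numpy(dtype=float).T
        features = list(matrix.index)
    y = np.asarray(labels, dtype=int)
    return x, y, features


def _feature_auc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature rank AUC of case vs control (vectorized, ties half-credit)."""
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    ranks = stats.rankdata(x, axis=0)
    return (ranks[y == 1].sum(axis=0) - m * (m + 1) / 2.0) / (m * n)


# --- individual selectors ----------------------------------------------------


def _select_rf(x, y, rng, options):
    model = RandomForestClassifier(
        n_estimators=options.get("n_estimators", 200),
        max_features="sqrt",
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    ).fit(x, y)
    if options.get("importance", "impurity") == "permutation":
        imp = permutation_importance(
            model, x, y, n_repeats=options.get("n_repeats", 5),
            random_state=int(rng.integers(2**31 - 1)), scoring="roc_auc",
        ).importances_mean
    else:
        imp = model.feature_importances_
    return imp, {}


def _select_rrf(x, y, rng, options):
    """Regularized tree ensemble: re-using an already selected feature is
    free, entering a new feature is penalized by only being offered to a
    random ``gamma`` fraction of trees. Importance = accumulated impurity
    decrease across the ensemble."""
    n_trees = options.get("n_trees", 60)
    gamma = options.get("gamma", 0.3)
    p = x.shape[1]
    used = np.zeros(p, dtype=bool)
    total = np.zeros(p)
    idx_all = np.arange(x.shape[0])
    for _ in range(n_trees):
        boot = rng.choice(idx_all, size=idx_all.size, replace=True)
        if y[boot].min() == y[boot].max():  # degenerate bootstrap, resample
            continue
        candidates = used | (rng.random(p) < gamma)
        if not candidates.any():
            candidates[rng.integers(p)] = True
        cols = np.where(candidates)[0]
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            max_depth=options.get("max_depth", 6),
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(x[np.ix_(boot, cols)], y[boot])
        imp = tree.feature_importances_
        total[cols] += imp
        used[cols[imp > 0]] = True
    return total, {}


def _select_boruta(x, y, rng, options):
    """Shadow-feature permutation test. Each iteration appends a shuffled
    copy of every feature; a feature scores a 'hit' when its impurity
    importance beats the best shadow importance. Importance = hit fraction;
    confirmed / tentative / rejected status from a two-sided binomial test."""
    max_iter = options.get("max_iter", 15)
    p = x.shape[1]
    hits = np.zeros(p)
    mean_imp = np.zeros(p)
    for _ in range(max_iter):
        shadow = x.copy()
        for j in range(p):
            shadow[:, j] = rng.permutation(shadow[:, j])
        model = RandomForestClassifier(
            n_estimators=options.get("n_estimators", 40),
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(np.hstack([x, shadow]), y)
        imp = model.feature_importances_
        thresh = imp[p:].max()
        hits += imp[:p] > thresh
        mean_imp += imp[:p]
    frac = hits / max_iter
    mean_imp /= max_iter
    status = np.full(p, "tentative", dtype=object)
    for j in range(p):
        res = stats.binomtest(int(hits[j]), max_iter, 0.5)
        if res.pvalue < 0.05:
            status[j] = "confirmed" if frac[j] > 0.5 else "rejected"
    # ranking: confirmed first, then tentative, then rejected; within a
    # status band order by hit fraction then mean importance
    band = np.select([status == "confirmed", status == "tentative"], [2.0, 1.0], 0.0)
    if options.get("confirmed_only", False):
        score = np.where(status == "confirmed", frac + 1e-9 * mean_imp / (mean_imp.max() + 1e-30), 0.0)
    else:
        score = band + 0.5 * frac + 1e-6 * mean_imp / (mean_imp.max() + 1e-30)
    return score, {"status": status, "hit_fraction": frac}


def _select_svm_rfe(x, y, rng, options):
    """Recursive-elimination ranking for a radial-basis SVM.

    Kernel SVMs expose no coefficients, so per-step feature ranking uses the
    ROC-AUC filter (averaged over stratified bootstrap resamples, which makes
    the ranking seed-dependent); the elimination order it induces is the
    importance. The RBF SVM itself is cross-validated over candidate subset
    sizes and the best size recorded.
    """
    n_resamples = options.get("n_resamples", 8)
    n = x.shape[0]
    auc_acc = np.zeros(x.shape[1])
    for _ in range(n_resamples):
        idx = rng.choice(n, size=n, replace=True)
        if y[idx].min() == y[idx].max():
            idx = np.arange(n)
        auc_acc += np.abs(_feature_auc(x[idx], y[idx]) - 0.5)
    score = auc_acc / n_resamples

    sizes = [s for s in options.get("subset_sizes", (4, 8, 16, 32, 64, 128)) if s <= x.shape[1]]
    best_size, best_auc = None, -np.inf
    if options.get("score_subsets", True) and sizes:
        order = np.argsort(-score, kind="mergesort")
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        for s_ in sizes:
            cols = order[:s_]
            aucs = []
            for tr, te in skf.split(x, y):
                clf = SVC(kernel="rbf", probability=False).fit(x[np.ix_(tr, cols)], y[tr])
                d = clf.decision_function(x[np.ix_(te, cols)])
                aucs.append(_feature_auc(d[:, None], y[te])[0])
            m = float(np.mean(aucs))
            if m > best_auc:
                best_auc, best_size = m, s_
    return score, {"best_subset_size": best_size, "best_subset_auc": best_auc}


def _select_lasso(x, y, rng, options):
    """L1 logistic path; score = |coefficient| at the CV-chosen penalty."""
    c_grid = options.get("c_grid", np.logspace(-2, 2, 9))
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    best_c, best_auc = c_grid[0], -np.inf
    for c in c_grid:
        aucs = []
        for tr, te in skf.split(x, y):
            clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c, max_iter=2000)
            clf.fit(x[tr], y[tr])
            d = clf.decision_function(x[te])
            aucs.append(_feature_auc(d[:, None], y[te])[0])
        m = float(np.mean(aucs))
        if m > best_auc:
            best_auc, best_c = m, c
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=best_c, max_iter=2000).fit(x, y)
    return np.abs(clf.coef_[0]), {"chosen_C": float(best_c)}


_SELECTORS = {
    "rf": _select_rf,
    "rrf": _select_rrf,
    "boruta": _select_boruta,
    "svm_rfe": _select_svm_rfe,
    "lasso": _select_lasso,
}


def run_selector(matrix, labels, algorithm_id: str, seed: int, options: dict | None = None) -> RankedList:
    """Run one selector once; returns the full importance vector and ranking.

    ``options["bootstrap"]`` resamples the training set with replacement
    before fitting (the 'modified models' variant for rrf/lasso).
    """
    if algorithm_id not in _SELECTORS:
        raise ValueError(f"unknown algorithm {algorithm_id!r}; choose from {ALGORITHMS}")
    options = dict(options or {})
    x, y, features = _as_xy(matrix, labels)
    rng = np.random.default_rng(seed)
    if options.pop("bootstrap", False):
        idx = rng.choice(x.shape[0], size=x.shape[0], replace=True)
        if y[idx].min() == y[idx].max():
            idx = np.arange(x.shape[0])
        x, y = x[idx], y[idx]
    scores, meta = _SELECTORS[algorithm_id](x, y, rng, options)
    s = pd.Series(scores, index=pd.Index(features, name="protein_id"))
    return RankedList(algorithm_id=algorithm_id, seed=seed, scores=s, ranking=_order_features(s), meta=meta)


# --- Borda aggregation -------------------------------------------------------


def borda_aggregate(ranked_lists, K: int = 25) -> ConsensusRanking:
    """Truncated Borda count: rank r in 1..K earns K - r + 1 points, 0 beyond.

    Accepts RankedList or ConsensusRanking inputs (the latter for the
    across-algorithms level). Ties in total points break by mean rank across
    lists (features outside a list's top-K counted at K + 1), then by
    feature id.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rankings = []
    for rl in ranked_lists:
        rankings.append(rl.ranking if isinstance(rl, RankedList) else rl.top_k)
    features = sorted({f for r in rankings for f in r})
    points = {f: 0.0 for f in features}
    rank_sum = {f: 0.0 for f in features}
    for r in rankings:
        topk = r[:K]
        pos = {f: i + 1 for i, f in enumerate(topk)}
        for f in features:
            rank = pos.get(f, K + 1)
            rank_sum[f] += rank
            if rank <= K:
                points[f] += K - rank + 1
    borda = pd.Series(points).sort_index()
    order = sorted(features, key=lambda f: (-points[f], rank_sum[f], f))
    scored = [f for f in order if points[f] > 0]
    return ConsensusRanking(borda_scores=borda, top_k=scored[:K], source="per_algorithm")


def across_algorithm_consensus(per_algorithm: dict, K: int = 25) -> ConsensusRanking:
    """Second-level Borda over the per-algorithm consensus top-K lists."""
    cons = borda_aggregate(list(per_algorithm.values()), K=K)
    cons.source = "across_algorithms"
    return cons


@dataclass
class StabilityCurve:
    k_values: list[int]
    mean_pairwise_spearman: list[float]


def stability_curve(ranked_lists, k_min: int = 3, k_max: int = 25) -> StabilityCurve:
    """Mean pairwise Spearman of top-k rankings, for k = k_min..k_max.

    For each pair of runs the correlation is computed on the features both
    runs selected (the intersection of their top-k sets), using each run's
    full ranking position. Pairs sharing fewer than two features contribute
    0 (no measurable agreement). Restricting to features present in either
    top-k (union) or padding absentees with a sentinel rank both condition
    on being top-ranked in exactly one list and therefore score independent
    random rankings strongly negative rather than near zero; the
    intersection form is the one whose null sits at ~0.
    """
    if len(ranked_lists) < 2:
        raise ValueError("need >= 2 ranked lists")
    n_features = min(len(rl.ranking) for rl in ranked_lists)
    if k_max > n_features:
        raise ValueError(f"k_max={k_max} exceeds feature count {n_features}")
    rankings = [rl.ranking for rl in ranked_lists]
    positions = [{f: i + 1 for i, f in enumerate(r)} for r in rankings]
    ks, means = [], []
    for k in range(k_min, k_max + 1):
        vals = []
        for a, b in combinations(range(len(rankings)), 2):
            shared = sorted(set(rankings[a][:k]) & set(rankings[b][:k]))
            if len(shared) < 2:
                vals.append(0.0)
                continue
            ra = [positions[a][f] for f in shared]
            rb = [positions[b][f] for f in shared]
            rho = stats.spearmanr(ra, rb).statistic
            if np.isnan(rho):  # zero-variance ranks within the shared set
                rho = 1.0 if ra == rb else 0.0
            vals.append(rho)
        ks.append(k)
        means.append(float(np.mean(vals)))
    return StabilityCurve(k_values=ks, mean_pairwise_spearman=means)


def consensus_overlap(*consensus_lists) -> dict:
    """Pairwise and common intersection counts of consensus top-K lists."""
    sets = []
    for c in consensus_lists:
        sets.append(set(c.top_k if isinstance(c, ConsensusRanking) else c))
    out = {"pairwise": {}, "common": len(set.intersection(*sets)) if sets else 0}
    for i, j in combinations(range(len(sets)), 2):
        out["pairwise"][(i, j)] = len(sets[i] & sets[j])
    return out


def run_ensemble_selection(
    matrix,
    labels,
    algorithms=ALGORITHMS,
    n_runs: int = 50,
    K: int = 25,
    seed_base: int = 1000,
    options: dict | None = None,
):
    """Full two-level selection: n_runs seeds per algorithm, Borda at both levels.

    Returns a dict with per-run lists, per-algorithm consensus, the final
    across-algorithm consensus, and per-algorithm stability curves. Run
    seeds are ``seed_base + run_index`` shared across algorithms.
    """
    options = options or {}
    runs: dict[str, list[RankedList]] = {}
    per_alg: dict[str, ConsensusRanking] = {}
    curves: dict[str, StabilityCurve] = {}
    for alg in algorithms:
        alg_runs = [
            run_selector(matrix, labels, alg, seed=seed_base + r, options=options.get(alg))
            for r in range(n_runs)
        ]
        runs[alg] = alg_runs
        per_alg[alg] = borda_aggregate(alg_runs, K=K)
        if n_runs >= 2:
            curves[alg] = stability_curve(alg_runs, k_min=3, k_max=min(K, len(alg_runs[0].ranking)))
    final = across_algorithm_consensus(per_alg, K=K)
    return {"runs": runs, "per_algorithm": per_alg, "consensus": final, "stability": curves}
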