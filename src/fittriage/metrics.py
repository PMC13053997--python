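"""Binary-classification metrics: confusion rates, ROC/AUROC with DeLong
confidence intervals, Youden-index thresholding, the DeLong test for
correlated ROC curves, and Benjamini-Hochberg adjustment.

AUROC is computed by the rank (Mann-Whitney) formulation with half credit
for ties; its variance (for the 95% CI and the paired test) uses the DeLong
structural-components estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def display_percent(x: float) -> int:
    """Round a proportion to a whole percent, half up (0.826 -> 83).

    Stored metrics always keep full precision; this is display only.
    """
    return int(np.floor(100.0 * x + 0.5))


@dataclass
class ConfusionReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    undefined: bool = False

    def display(self) -> dict:
        """Whole-percent rendering, matching clinical-report conventions."""
        return {
            "sensitivity_pct": display_percent(self.sensitivity),
            "specificity_pct": display_percent(self.specificity),
            "balanced_accuracy_pct": display_percent(self.balanced_accuracy),
        }


def confusion_metrics(scores, labels, threshold: float = 0.5) -> ConfusionReport:
    """Confusion counts and derived rates at a probability threshold.

    Labels are 0/1 with 1 = case. Values are stored at full precision;
    rounding to whole percent happens only in :meth:`ConfusionReport.display`.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    if (tp + fn) == 0 or (tn + fp) == 0:
        return ConfusionReport(tp, fp, tn, fn, float("nan"), float("nan"), float("nan"), undefined=True)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ConfusionReport(tp, fp, tn, fn, sens, spec, 0.5 * (sens + spec))


def confusion_from_counts(tp: int, fp: int, tn: int, fn: int) -> ConfusionReport:
    """Build the report directly from counts (e.g. published tables)."""
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ConfusionReport(tp, fp, tn, fn, sens, spec, 0.5 * (sens + spec))


# --- DeLong machinery --------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUROC and per-sample structural components (V10 cases, V01 controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def roc_auc(scores, labels):
    """AUROC with DeLong 95% CI and full ROC coordinates.

    Returns ``(auroc, (lo, hi), roc)`` where roc is a record array of
    (threshold, fpr, tpr) evaluated at every distinct score. A fully tied
    score vector gives AUROC 0.5 with a degenerate (flagged NaN) CI.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    auc, v10, v01 = _delong_components(s, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    if var <= 0 or np.isnan(var):
        ci = (float("nan"), float("nan"))
    else:
        half = stats.norm.ppf(0.975) * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))

    thresholds = np.unique(s)[::-1]
    coords = []
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    coords.append((np.inf, 0.0, 0.0))
    for t in thresholds:
        pred = s >= t
        coords.append(
            (float(t), float((pred & (y == 0)).sum() / n_neg), float((pred & (y == 1)).sum() / n_pos))
        )
    roc = np.array(coords, dtype=[("threshold", float), ("fpr", float), ("tpr", float)])
    return float(auc), ci, roc


def youden_threshold(roc: np.ndarray):
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties go to the lowest threshold. Returns (threshold, sensitivity,
    specificity).
    """
    j = roc["tpr"] - roc["fpr"]
    best = np.max(j)
    cand = np.where(j == best)[0]
    i = cand[np.argmin(roc["threshold"][cand])]
    return float(roc["threshold"][i]), float(roc["tpr"][i]), float(1.0 - roc["fpr"][i])


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided p-value for the paired DeLong test of AUROC equality.

    Both score vectors must be computed on the same samples; correlation
    between the two ROC curves is accounted for through the covariance of
    the structural components. Zero variance of the AUROC difference (e.g.
    identical scores) yields p = 1.
    """
    y = np.asarray(labels, dtype=int)
    auc_a, v10_a, v01_a = _delong_components(np.asarray(scores_a, float), y)
    auc_b, v10_b, v01_b = _delong_components(np.asarray(scores_b, float), y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0 or np.isnan(var):
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class EvaluationReport:
    """Overall plus per-subgroup (G2-only, G3-only vs G1) evaluation."""

    confusion: ConfusionReport
    auroc: float
    auroc_ci_95: tuple[float, float]
    roc: np.ndarray
    subgroups: dict = field(default_factory=dict)


def evaluate_scores(scores, labels, sample_groups=None, threshold: float = 0.5) -> EvaluationReport:
    """Full report: confusion at threshold, AUROC + CI, subgroup ROC data.

    ``sample_groups``, when given, is the per-sample diagnostic group used to
    build case=G2-only and case=G3-only comparisons against G1.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    auc, ci, roc = roc_auc(s, y)
    report = EvaluationReport(confusion=confusion_metrics(s, y, threshold), auroc=auc, auroc_ci_95=ci, roc=roc)
    if sample_groups is not None:
        g = np.asarray(sample_groups)
        for case_group in ("G2", "G3"):
            sel = (g == case_group) | (g == "G1")
            if (g == case_group).sum() == 0:
                continue
            ys = (g[sel] == case_group).astype(int)
            auc_s, ci_s, roc_s = roc_auc(s[sel], ys)
            report.subgroups[f"{case_group}_vs_G1"] = EvaluationReport(
                confusion=confusion_metrics(s[sel], ys, threshold), auroc=auc_s, auroc_ci_95=ci_s, roc=roc_s
            )
    return report
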