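"""Rank-based two-group differential abundance with two-stage adaptive FDR.

Per protein, a two-sided Mann-Whitney U test compares cases (G2 u G3) with
controls (G1); multiplicity is handled by the Benjamini-Krieger-Yekutieli
two-stage linear step-up procedure, an adaptive variant of Benjamini-Hochberg
that estimates the number of true nulls in a first BH pass and re-runs BH at
an inflated level. q-values are defined operationally as the smallest nominal
level at which the two-stage procedure rejects a test, located by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AbundanceMatrix, CASE_GROUPS, CONTROL_GROUP


def mann_whitney_u(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for group a, p).

    Exact enumeration when the combined sample is small (<= 12) and tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _bh_rejections(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the BH linear step-up at the given level."""
    m = p_sorted.size
    thresh = level * np.arange(1, m + 1) / m
    passing = np.where(p_sorted <= thresh)[0]
    return 0 if passing.size == 0 else int(passing[-1]) + 1


def bky_rejects(p_values: np.ndarray, q_level: float) -> np.ndarray:
    """Boolean rejection mask of the BKY two-stage step-up procedure.

    Stage 1 runs BH at q' = q/(1+q) giving r1 rejections; if r1 is 0 or m the
    procedure stops there, otherwise stage 2 reruns BH at level q' * m / (m - r1).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    q_prime = q_level / (1.0 + q_level)
    r1 = _bh_rejections(p_sorted, q_prime)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        r_final = m
    else:
        m0_hat = m - r1
        r_final = _bh_rejections(p_sorted, q_prime * m / m0_hat)
    reject = np.zeros(m, dtype=bool)
    reject[order[:r_final]] = True
    return reject


def bky_fdr(p_values, q_level: float = 0.05, q_tol: float = 1e-6):
    """Two-stage BKY FDR control; returns (discoveries mask, q-values).

    The q-value of each test is the smallest nominal level at which the
    two-stage procedure rejects it, found by bisection over levels (the
    procedure is monotone in the level for each fixed test up to numerical
    granularity; bisection is run independently per test).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    discoveries = bky_rejects(p, q_level)
    q_values = np.ones(p.size)
    rejectable = bky_rejects(p, 1.0 - 1e-12)
    for i in range(p.size):
        if not rejectable[i]:
            q_values[i] = 1.0
            continue
        lo, hi = 0.0, 1.0
        while hi - lo > q_tol:
            mid = 0.5 * (lo + hi)
            if bky_rejects(p, mid)[i]:
                hi = mid
            else:
                lo = mid
        q_values[i] = hi
    return discoveries, q_values


@dataclass
class DAResult:
    protein_id: str
    u_statistic: float
    p_value: float
    q_value: float
    log2_fold_change: float
    direction: str  # up_in_case / down_in_case / none


def build_da_table(
    matrix: AbundanceMatrix,
    sample_meta: pd.DataFrame,
    case_groups=CASE_GROUPS,
    control_group: str = CONTROL_GROUP,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Per-protein DA table (U, p, q, log2FC, direction), sorted by p.

    Expects a complete matrix on the log2 scale but pre-z-score, so the fold
    change column (difference of case and control means) is interpretable;
    the rank-based test itself is invariant to per-protein monotone scaling.
    Direction is assigned from the fold-change sign for p <= 0.05, matching
    conventional volcano-plot coloring.
    """
    groups = sample_meta.reindex(matrix.sample_ids)["group"]
    for g in tuple(case_groups) + (control_group,):
        if g not in set(groups):
            raise ValueError(f"group {g!r} absent")
    case = groups.isin(case_groups).to_numpy()
    ctrl = (groups == control_group).to_numpy()
    vals = matrix.values.to_numpy(dtype=float)

    rows = []
    for j, pid in enumerate(matrix.protein_ids):
        u, p = mann_whitney_u(vals[j, case], vals[j, ctrl])
        lfc = float(vals[j, case].mean() - vals[j, ctrl].mean())
        rows.append((pid, u, p, lfc))
    tab = pd.DataFrame(rows, columns=["protein_id", "U", "p", "log2FC"])
    _, qv = bky_fdr(tab["p"].to_numpy(), q_level=q_level)
    tab["q"] = qv
    tab["direction"] = np.where(
        tab["p"] > 0.05, "none", np.where(tab["log2FC"] > 0, "up_in_case", "down_in_case")
    )
    return tab.sort_values("p", kind="mergesort").reset_index(drop=True)
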