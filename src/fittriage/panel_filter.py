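"""Downstream filtering of the consensus feature panel.

Three steps: (1) remove features flagged by manual spectral review (supplied
as an input exclusion list -- the review itself is upstream of this package);
(2) iteratively prune multicollinear features by variance inflation factor,
protecting designated representatives (e.g. keeping one hemoglobin group for
the whole hemoglobin family); (3) flag per-class outliers with the ROUT
method in its constant-model form (robust location = median, robust scale
from the 68.27th percentile of absolute residuals, outermost-first t-based
testing at FDR level Q). Outliers are flagged and reported, never silently
removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AbundanceMatrix


def apply_exclusion_list(panel, exclusion_ids) -> list[str]:
    """Set difference, order preserved; unknown exclusions warn, not fail."""
    panel = list(panel)
    excl = set(exclusion_ids)
    unknown = excl - set(panel)
    if unknown:
        warnings.warn(f"exclusion ids not in panel: {sorted(unknown)}", stacklevel=2)
    return [f for f in panel if f not in excl]


@dataclass
class VifReport:
    iterations: list[tuple[str, float]]  # (feature removed, VIF at removal)
    final_vifs: pd.Series


def _vif_values(x: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others.

    Perfect collinearity (R^2 = 1 to machine precision) reports +inf.
    """
    n, p = x.shape
    xc = x - x.mean(axis=0, keepdims=True)
    out = np.empty(p)
    for j in range(p):
        yj = xc[:, j]
        others = np.delete(xc, j, axis=1)
        tss = float(yj @ yj)
        if tss == 0:
            out[j] = np.inf
            continue
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        rss = float(np.sum((yj - others @ coef) ** 2))
        r2 = 1.0 - rss / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(
    matrix: AbundanceMatrix,
    panel,
    threshold: float = 10.0,
    keep_preferences=(),
) -> tuple[list[str], VifReport]:
    """Iteratively remove the highest-VIF unprotected feature until all < threshold.

    ``keep_preferences`` lists features never to remove (family
    representatives). VIFs are recomputed after every removal; each removal
    is recorded with the VIF it had at removal time.
    """
    panel = list(panel)
    protected = set(keep_preferences)
    iterations: list[tuple[str, float]] = []
    while True:
        x = matrix.values.loc[panel].to_numpy(dtype=float).T
        if x.shape[1] < 2:
            vifs = pd.Series(np.ones(len(panel)), index=panel)
            break
        v = _vif_values(x)
        vifs = pd.Series(v, index=panel)
        removable = vifs.drop(labels=[f for f in panel if f in protected])
        if removable.empty or removable.max() < threshold:
            break
        worst = removable.sort_values(ascending=False, kind="mergesort").index[0]
        iterations.append((worst, float(vifs[worst])))
        panel = [f for f in panel if f != worst]
    return panel, VifReport(iterations=iterations, final_vifs=vifs)


@dataclass
class OutlierFlags:
    flags: pd.Series  # boolean, indexed like the input values
    Q: float
    rsdr: float
    n: int


def rout_outliers(values, Q: float = 0.01) -> OutlierFlags:
    """ROUT outlier flags for one feature within one class (constant model).

    Robust fit = median; robust scale (RSDR) = 68.27th percentile of absolute
    residuals with the small-sample correction n/(n - 1). Residuals are then
    tested outermost first: the i-th outermost of n is flagged while the
    two-sided t tail probability (df = n - 1) of residual / RSDR stays below
    alpha_i = Q * (n - i + 1) / n, the step-down analogue of FDR control at
    level Q. Fewer than 5 values, or zero robust scale, yields no flags.
    """
    if not 0 < Q < 1:
        raise ValueError("Q must be in (0, 1)")
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    n = s.size
    flags = pd.Series(False, index=s.index)
    if n < 5:
        warnings.warn(f"ROUT needs >= 5 values, got {n}; no flags", stacklevel=2)
        return OutlierFlags(flags=flags, Q=Q, rsdr=float("nan"), n=n)
    resid = s - s.median()
    abs_r = resid.abs()
    rsdr = float(np.percentile(abs_r, 68.27) * n / (n - 1))
    if rsdr == 0:
        return OutlierFlags(flags=flags, Q=Q, rsdr=0.0, n=n)
    order = abs_r.sort_values(ascending=False, kind="mergesort").index
    df = n - 1
    for i, idx in enumerate(order, start=1):
        t = abs_r[idx] / rsdr
        p_two = 2.0 * stats.t.sf(t, df)
        alpha_i = Q * (n - i + 1) / n
        if p_two < alpha_i:
            flags[idx] = True
        else:
            break
    return OutlierFlags(flags=flags, Q=Q, rsdr=rsdr, n=n)


def rout_by_class(matrix: AbundanceMatrix, panel, sample_meta: pd.DataFrame, Q: float = 0.01, case_groups=("G2", "G3")) -> pd.DataFrame:
    """ROUT flags per (feature, class); classes are G1 and G2/G3 combined.

    Returns a long-format table (feature, class, sample, flagged) restricted
    to flagged cells.
    """
    groups = sample_meta.reindex(matrix.sample_ids)["group"]
    cls = np.where(groups.isin(case_groups), "G2/G3", "G1")
    rows = []
    for f in panel:
        vals = matrix.values.loc[f]
        for c in ("G1", "G2/G3"):
            sub = vals[cls == c]
            res = rout_outliers(sub, Q=Q)
            for sid in res.flags.index[res.flags]:
                rows.append((f, c, sid))
    return pd.DataFrame(rows, columns=["feature", "class", "sample"])
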