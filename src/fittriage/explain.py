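"""Kernel SHAP attribution for the final classifier.

Shapley values are estimated with the weighted-least-squares kernel
formulation: coalition values v(S) are marginal expectations of the model
output over a background dataset, and attributions solve the Shapley-kernel
weighted regression subject to the local-accuracy constraint (base value +
sum of attributions = model output at the explained sample). Coalitions are
enumerated exhaustively for small feature counts and sampled in complement
pairs otherwise; sampling is deterministic given the seed.

Explanations are on the probability scale (the model's predicted case
probability), so a SHAP value of +0.05 means the feature pushed that
sample's predicted G2/G3 probability up by five points relative to the
background average.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class ShapSummary:
    shap_values: pd.DataFrame  # samples x features
    base_value: float
    model_output: pd.Series  # per explained sample

    @property
    def mean_abs_shap(self) -> pd.Series:
        return self.shap_values.abs().mean(axis=0).sort_values(ascending=False)

    @property
    def sd_shap(self) -> pd.Series:
        return self.shap_values.std(axis=0, ddof=1)

    def table(self) -> pd.DataFrame:
        """Feature table ranked by mean |SHAP|, with SD."""
        return pd.DataFrame(
            {"mean_abs_shap": self.mean_abs_shap, "sd_shap": self.sd_shap.reindex(self.mean_abs_shap.index)}
        )


def _kernel_weight(m: int, s: int) -> float:
    from math import comb

    return (m - 1) / (comb(m, s) * s * (m - s))


def _coalitions(m: int, max_coalitions: int, rng: np.random.Generator) -> np.ndarray:
    """0/1 coalition matrix, excluding the empty and full sets.

    Exhaustive when 2^m - 2 <= max_coalitions; otherwise paired sampling:
    sizes drawn with probability proportional to the Shapley kernel weight
    mass at that size, each sampled subset added with its complement.
    """
    total = 2**m - 2
    if total <= max_coalitions:
        rows = []
        for s in range(1, m):
            for idx in combinations(range(m), s):
                z = np.zeros(m)
                z[list(idx)] = 1.0
                rows.append(z)
        return np.array(rows)
    from math import comb

    sizes = np.arange(1, m)
    size_mass = np.array([_kernel_weight(m, s) * comb(m, s) for s in sizes])
    size_p = size_mass / size_mass.sum()
    seen = set()
    rows = []
    while len(rows) < max_coalitions:
        s = int(rng.choice(sizes, p=size_p))
        idx = tuple(sorted(rng.choice(m, size=s, replace=False)))
        if idx in seen:
            continue
        seen.add(idx)
        z = np.zeros(m)
        z[list(idx)] = 1.0
        rows.append(z)
        comp = tuple(i for i in range(m) if i not in idx)
        if comp and len(rows) < max_coalitions and comp not in seen:
            seen.add(comp)
            rows.append(1.0 - z)
    return np.array(rows)


def kernel_shap(
    model_predict,
    background: np.ndarray,
    instances: np.ndarray,
    feature_ids=None,
    max_coalitions: int = 2048,
    seed: int = 0,
    exact: bool = False,
) -> ShapSummary:
    """Shapley attributions for each instance via the kernel WLS estimator.

    Parameters
    ----------
    model_predict
        Callable mapping a (rows x features) array to a 1-D output
        (probability or margin).
    background
        Reference dataset defining the marginal expectations (the training
        set in the standard workflow).
    instances
        Samples to explain.
    max_coalitions
        Budget of distinct coalitions; ``exact=True`` forces full
        enumeration regardless of feature count.
    """
    bg = np.asarray(background, dtype=float)
    xs = np.atleast_2d(np.asarray(instances, dtype=float))
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    m = xs.shape[1]
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(m)]
    rng = np.random.default_rng(seed)

    base = float(np.mean(model_predict(bg)))
    fx = np.asarray(model_predict(xs), dtype=float)

    if m == 1:
        phi = (fx - base)[:, None]
        return ShapSummary(
            shap_values=pd.DataFrame(phi, columns=list(feature_ids)),
            base_value=base,
            model_output=pd.Series(fx),
        )

    budget = 2**m - 2 if exact else max_coalitions
    z = _coalitions(m, budget, rng)
    w = np.array([_kernel_weight(m, int(zi.sum())) for zi in z])

    n_bg = bg.shape[0]
    n_z = z.shape[0]
    phis = np.empty((xs.shape[0], m))
    # design for constrained WLS: eliminate the last feature via the
    # local-accuracy constraint sum(phi) = f(x) - base
    a = z[:, :-1] - z[:, -1:]
    aw = a * w[:, None]
    gram = a.T @ aw
    gram_inv = np.linalg.pinv(gram)
    for i, x in enumerate(xs):
        # v(S): composite rows take x on S and background values off S
        composite = np.where(z[:, None, :] == 1.0, x[None, None, :], bg[None, :, :])
        v = model_predict(composite.reshape(n_z * n_bg, m)).reshape(n_z, n_bg).mean(axis=1)
        t = v - base - z[:, -1] * (fx[i] - base)
        phi_rest = gram_inv @ (aw.T @ t)
        phi_last = (fx[i] - base) - phi_rest.sum()
        phis[i] = np.append(phi_rest, phi_last)

    return ShapSummary(
        shap_values=pd.DataFrame(phis, columns=list(feature_ids)),
        base_value=base,
        model_output=pd.Series(fx),
    )


def stratified_shap_summary(summary: ShapSummary, sample_groups) -> dict[str, ShapSummary]:
    """Per-diagnostic-group SHAP summaries (plus the global one under 'all').

    ``sample_groups`` aligns positionally with the explained instances.
    Empty groups are skipped.
    """
    g = np.asarray(sample_groups)
    if g.size != summary.shap_values.shape[0]:
        raise ValueError("sample_groups length must match explained instances")
    out = {"all": summary}
    for grp in pd.unique(g):
        sel = g == grp
        if not sel.any():
            continue
        out[str(grp)] = ShapSummary(
            shap_values=summary.shap_values.loc[sel].reset_index(drop=True),
            base_value=summary.base_value,
            model_output=summary.model_output[sel].reset_index(drop=True),
        )
    return out


def beeswarm_table(summary: ShapSummary, feature_values: pd.DataFrame) -> pd.DataFrame:
    """Long-format plot-ready table (sample, feature, shap, scaled abundance 0-1)."""
    fv = feature_values.reset_index(drop=True)
    lo, hi = fv.min(), fv.max()
    scaled = (fv - lo) / (hi - lo).replace(0, 1.0)
    rows = []
    for j, f in enumerate(summary.shap_values.columns):
        for i in range(summary.shap_values.shape[0]):
            rows.append((i, f, float(summary.shap_values.iloc[i, j]), float(scaled.iloc[i][f])))
    return pd.DataFrame(rows, columns=["sample", "feature", "shap", "scaled_abundance"])
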