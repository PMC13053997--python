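"""Filtering rule and five-step processing pipeline.

Order of operations, enforced through the matrix ``scale_state``:

1. ``log2_transform``      -- variance stabilization
2. ``quantile_normalize``  -- align per-sample intensity distributions
3. ``correct_batch``       -- empirical-Bayes location/scale batch adjustment
   (``assess_batch`` quantifies batch influence before/after)
4. ``knn_impute``          -- fill missing cells from the k nearest samples
5. ``zscore``              -- center/scale each protein

``filter_proteins`` precedes step 1: it drops proteins quantified in fewer
than half the samples and proteins not inferred to human (exclusively or
co-inferred with a dietary species).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AbundanceMatrix

#: species annotations retained by default: human-exclusive protein groups and
#: human proteins co-inferred with a dietary (bovine/pig/chicken) species.
HUMAN_SPECIES = ("human", "human+dietary")


def filter_proteins(
    matrix: AbundanceMatrix,
    protein_meta: pd.DataFrame,
    min_quant_fraction: float = 0.5,
    species_policy: tuple[str, ...] = HUMAN_SPECIES,
) -> AbundanceMatrix:
    """Retain human-inferred proteins quantified in >= ``min_quant_fraction`` of samples.

    The quantified-fraction threshold is inclusive (a protein observed in
    exactly half the samples is kept). Row order is preserved.
    """
    matrix.require_state("raw")
    quant_frac = 1.0 - matrix.mask.mean(axis=1)
    species = protein_meta.reindex(matrix.protein_ids)["species"]
    keep = (quant_frac >= min_quant_fraction) & species.isin(species_policy)
    if not keep.any():
        raise ValueError(
            f"no proteins retained: {int((quant_frac >= min_quant_fraction).sum())} pass the "
            f"quantification threshold, {int(species.isin(species_policy).sum())} pass the species policy"
        )
    return AbundanceMatrix(
        values=matrix.values.loc[keep],
        mask=matrix.mask.loc[keep],
        scale_state="raw",
    )


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2 on observed cells (step 1)."""
    matrix.require_state("raw")
    vals = matrix.values.to_numpy(dtype=float)
    obs = ~matrix.mask.to_numpy()
    bad = obs & ~(vals > 0)
    if bad.any():
        j, s = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at protein {matrix.protein_ids[j]!r}, "
            f"sample {matrix.sample_ids[s]!r}"
        )
    return matrix.advance(np.log2(matrix.values), "log2")


def _reference_quantile_curve(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean of per-column empirical quantile functions on a common grid."""
    n_rows, n_cols = values.shape
    grid = np.linspace(0.0, 1.0, n_rows)
    acc = np.zeros(n_rows)
    for c in range(n_cols):
        col = values[:, c]
        col = np.sort(col[~np.isnan(col)])
        if col.size == 0:
            raise ValueError(f"column {c} entirely missing")
        if col.size == 1:
            acc += col[0]
        else:
            acc += np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
    return grid, acc / n_cols


def quantile_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Quantile normalization tolerant of missing cells (step 2).

    Missing cells are skipped when ranking; each observed value is projected
    onto the across-column mean quantile curve at its within-column rank
    position, with ties assigned the average of their target quantiles.
    Complete columns end up with exactly identical sorted values.
    """
    matrix.require_state("log2", "normalized")
    vals = matrix.values.to_numpy(dtype=float).copy()
    grid, ref = _reference_quantile_curve(vals)
    out = np.full_like(vals, np.nan)
    for c in range(vals.shape[1]):
        col = vals[:, c]
        obs = np.where(~np.isnan(col))[0]
        n = obs.size
        order = obs[np.argsort(col[obs], kind="mergesort")]
        pos = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        targets = np.interp(pos, grid, ref)
        # average target quantiles within tie groups
        sorted_vals = col[order]
        k = 0
        while k < n:
            k2 = k
            while k2 + 1 < n and sorted_vals[k2 + 1] == sorted_vals[k]:
                k2 += 1
            targets[k : k2 + 1] = targets[k : k2 + 1].mean()
            k = k2 + 1
        out[order, c] = targets
    return matrix.advance(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        "normalized",
    )


@dataclass
class BatchReport:
    """Per-protein batch association from a one-way F-test on observed cells."""

    p_values: pd.Series  # NaN where undefined (a batch with <2 observed samples)
    undefined: pd.Series  # True where the test could not be run

    @property
    def fraction_significant(self) -> float:
        defined = self.p_values.dropna()
        if defined.empty:
            return float("nan")
        return float((defined < 0.05).mean())


def assess_batch(matrix: AbundanceMatrix, sample_meta: pd.DataFrame) -> BatchReport:
    """One-way F-test of abundance on acquisition batch, per protein."""
    matrix.require_state("normalized", "batch_corrected", "imputed", "zscored")
    batches = sample_meta.reindex(matrix.sample_ids)["batch"].to_numpy()
    levels = np.unique(batches)
    if levels.size < 2:
        raise ValueError("assess_batch requires >= 2 batches")
    vals = matrix.values.to_numpy(dtype=float)
    obs = ~matrix.mask.to_numpy()
    ps = np.full(matrix.n_proteins, np.nan)
    undef = np.zeros(matrix.n_proteins, dtype=bool)
    for j in range(matrix.n_proteins):
        groups = []
        ok = True
        for b in levels:
            g = vals[j, (batches == b) & obs[j]]
            if g.size < 2:
                ok = False
                break
            groups.append(g)
        if not ok:
            undef[j] = True
            continue
        ps[j] = stats.f_oneway(*groups).pvalue
    idx = matrix.protein_ids
    return BatchReport(p_values=pd.Series(ps, index=idx), undefined=pd.Series(undef, index=idx))


def _postmean(gamma_hat, gamma_bar, n, delta_star, tau2):
    return (tau2 * n * gamma_hat + delta_star * gamma_bar) / (tau2 * n + delta_star)


def _postvar(ss, n, a_prior, b_prior):
    return (0.5 * ss + b_prior) / (n / 2.0 + a_prior - 1.0)


def correct_batch(
    matrix: AbundanceMatrix,
    sample_meta: pd.DataFrame,
    parametric: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> AbundanceMatrix:
    """Empirical-Bayes location/scale batch adjustment (step 3).

    Standardizes each protein, estimates per-batch per-protein location
    (gamma) and scale (delta^2) effects, shrinks them toward batch-level
    priors -- parametric normal / inverse-gamma moment-matched priors by
    default, a nonparametric likelihood-weighted prior otherwise -- then
    subtracts/rescales and restores the original location and scale. Missing
    cells stay missing; diagnostic-group labels are deliberately not used as
    covariates, so group signal confounded with batch may be attenuated.
    """
    matrix.require_state("normalized")
    batches = sample_meta.reindex(matrix.sample_ids)["batch"].to_numpy()
    levels = np.unique(batches)
    if levels.size == 1:
        return matrix.advance(matrix.values.copy(), "batch_corrected")
    for b in levels:
        if (batches == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples; variance inestimable")

    vals = matrix.values.to_numpy(dtype=float).copy()
    obs = ~matrix.mask.to_numpy()
    work = np.where(obs, vals, np.nan)
    p, n = work.shape

    # per-batch means and pooled variance (size-weighted grand mean, as ComBat)
    batch_means = np.column_stack(
        [np.nanmean(work[:, batches == b], axis=1) for b in levels]
    )  # p x B
    batch_sizes = np.array([(batches == b).sum() for b in levels], dtype=float)
    grand = batch_means @ (batch_sizes / batch_sizes.sum())
    fitted = batch_means[:, np.searchsorted(levels, batches)]
    resid = work - fitted
    var_pooled = np.nanmean(resid**2, axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    z = (work - grand[:, None]) / np.sqrt(var_pooled)[:, None]

    z_adj = z.copy()
    for bi, b in enumerate(levels):
        sel = batches == b
        zb = z[:, sel]
        n_obs = np.sum(~np.isnan(zb), axis=1).astype(float)
        gamma_hat = np.nanmean(zb, axis=1)
        delta2_hat = np.nanvar(zb, axis=1, ddof=1)
        delta2_hat = np.where(np.isnan(delta2_hat) | (delta2_hat <= 0), 1e-12, delta2_hat)

        if parametric:
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            m, v = delta2_hat.mean(), delta2_hat.var(ddof=1)
            v = max(v, 1e-12)
            a_prior = (2 * v + m**2) / v
            b_prior = (m * v + m**3) / v
            gamma_star = gamma_hat.copy()
            delta_star = delta2_hat.copy()
            for _ in range(max_iter):
                g_new = _postmean(gamma_hat, gamma_bar, n_obs, delta_star, tau2)
                ss = np.nansum((zb - g_new[:, None]) ** 2, axis=1)
                d_new = _postvar(ss, n_obs, a_prior, b_prior)
                change = max(
                    np.max(np.abs(g_new - gamma_star)), np.max(np.abs(d_new - delta_star))
                )
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
        else:
            gamma_star, delta_star = _nonparametric_eb(zb, gamma_hat, delta2_hat)

        z_adj[:, sel] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = z_adj * np.sqrt(var_pooled)[:, None] + grand[:, None]
    out = np.where(obs, out, np.nan)
    return matrix.advance(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        "batch_corrected",
    )


def _nonparametric_eb(zb: np.ndarray, gamma_hat: np.ndarray, delta2_hat: np.ndarray):
    """Likelihood-weighted (Monte Carlo integral) posterior over other proteins."""
    p = zb.shape[0]
    gamma_star = np.empty(p)
    delta_star = np.empty(p)
    for g in range(p):
        x = zb[g][~np.isnan(zb[g])]
        others = np.arange(p) != g
        gh, dh = gamma_hat[others], delta2_hat[others]
        # log-likelihood of protein g's data under each other protein's params
        ll = -0.5 * (
            x.size * np.log(2 * np.pi * dh)
            + ((x[None, :] - gh[:, None]) ** 2).sum(axis=1) / dh
        )
        w = np.exp(ll - ll.max())
        w_sum = w.sum()
        gamma_star[g] = float((w * gh).sum() / w_sum)
        delta_star[g] = float((w * dh).sum() / w_sum)
    return gamma_star, delta_star


def knn_impute(matrix: AbundanceMatrix, k: int = 10, axis: str = "proteins") -> AbundanceMatrix:
    """k-nearest-neighbor imputation (step 4).

    ``axis="proteins"`` (default, the behavior of the Bioconductor impute
    package): a missing cell (protein p, sample s) is filled with the mean
    over the k proteins nearest to p -- by RMS difference across mutually
    observed samples -- that are themselves observed at s. This is what lets
    tightly co-quantified families (hemoglobin protein groups) survive
    imputation with their mutual correlation intact.

    ``axis="samples"``: the transposed variant -- the mean of p's observed
    values in the k samples nearest to s, distances over mutually observed
    proteins. Both distances are RMS over the shared support (Euclidean
    rescaled by the square root of the observed fraction, correcting for
    unequal overlap).

    Rows (or samples) sharing no observed support with any neighbor fall
    back to the protein-wise observed mean. Observed cells are never
    altered.
    """
    matrix.require_state("batch_corrected", "imputed")
    if axis not in ("proteins", "samples"):
        raise ValueError("axis must be 'proteins' or 'samples'")
    n = matrix.n_samples if axis == "samples" else matrix.n_proteins
    if k >= n:
        raise ValueError(f"k={k} must be < number of {axis} ({n})")
    vals = matrix.values.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if obs.all():
        return matrix.advance(matrix.values.copy(), "imputed")
    protein_means = np.nanmean(np.where(obs, vals, np.nan), axis=1)
    if axis == "proteins":
        out = _knn_fill(vals.T, obs.T, k, fallback=protein_means[:, None].T).T
    else:
        out = _knn_fill(vals, obs, k, fallback=protein_means[:, None])
    return matrix.advance(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        "imputed",
    )


def _knn_fill(vals: np.ndarray, obs: np.ndarray, k: int, fallback: np.ndarray) -> np.ndarray:
    """Impute missing cells from the k nearest *columns* of ``vals``.

    Column-to-column distance is the RMS difference over rows observed in
    both. A missing cell (r, c) becomes the mean over the up-to-k nearest
    columns of c that are observed at row r; ``fallback`` (broadcastable to
    vals' shape) covers cells with no usable neighbor.
    """
    x = np.where(obs, vals, 0.0)
    o = obs.astype(float)
    shared = o.T @ o  # columns x columns counts of mutually observed rows
    sq = (x**2).T @ o + o.T @ (x**2) - 2.0 * (x.T @ x)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(sq, 0.0) / shared)
    dist[shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    fallback = np.broadcast_to(fallback, vals.shape)
    out = vals.copy()
    order = np.argsort(dist, axis=1, kind="mergesort")
    for c in range(vals.shape[1]):
        missing_rows = np.where(~obs[:, c])[0]
        if missing_rows.size == 0:
            continue
        neighbors = [t for t in order[c] if np.isfinite(dist[c, t])][:k]
        for r in missing_rows:
            donor = [t for t in neighbors if obs[r, t]]
            if donor:
                out[r, c] = vals[r, donor].mean()
            else:
                out[r, c] = fallback[r, c]
    return out


def zscore(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Center each protein to mean 0 and population SD 1 (step 5)."""
    matrix.require_state("imputed", "zscored")
    vals = matrix.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population (1/n) SD, fixed convention
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        ids = list(matrix.protein_ids[flat])
        raise ValueError(f"zero-variance proteins cannot be z-scored: {ids}")
    return matrix.advance(
        pd.DataFrame((vals - mu) / sd, index=matrix.values.index, columns=matrix.values.columns),
        "zscored",
    )


def run_preprocessing(
    matrix: AbundanceMatrix,
    sample_meta: pd.DataFrame,
    protein_meta: pd.DataFrame,
    min_quant_fraction: float = 0.5,
    knn_k: int = 10,
    knn_axis: str = "proteins",
    parametric_combat: bool = True,
):
    """Filter + steps 1-5; returns the z-scored matrix plus intermediates.

    The returned dict includes the log2-normalized (pre-z-score, pre-batch)
    matrix used for fold changes, the batch reports before and after
    correction, and per-step protein counts.
    """
    filtered = filter_proteins(matrix, protein_meta, min_quant_fraction)
    logged = log2_transform(filtered)
    normalized = quantile_normalize(logged)
    report_before = assess_batch(normalized, sample_meta)
    corrected = correct_batch(normalized, sample_meta, parametric=parametric_combat)
    report_after = assess_batch(corrected, sample_meta)
    imputed = knn_impute(corrected, k=knn_k, axis=knn_axis)
    scored = zscore(imputed)
    return {
        "zscored": scored,
        "imputed": imputed,
        "normalized": normalized,
        "batch_report_before": report_before,
        "batch_report_after": report_after,
        "counts": {
            "proteins_in": matrix.n_proteins,
            "proteins_retained": filtered.n_proteins,
            "cells_imputed": int(filtered.mask.to_numpy().sum()),
        },
    }
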