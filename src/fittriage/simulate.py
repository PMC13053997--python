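"""Synthetic FIT-cohort generator.

Emulates the statistical structure of a label-free stool-proteomics screening
cohort: three diagnostic groups (G1 false-positive controls, G2 advanced
adenomas, G3 colorectal cancers) acquired in balanced batches, a heavy-tailed
log-normal intensity distribution, a small set of planted differentially
abundant proteins, one highly collinear hemoglobin-like block driven by a
shared latent factor, batch location/scale effects, abundance-dependent
(MNAR-leaning) missingness, and occasional gross outliers.

Every draw is controlled by a single integer seed, so identical configs give
bit-identical cohorts. The generator also returns the ground truth needed for
recovery testing (planted ids and effects, the collinear block, the batch
effect table, outlier cells, and the noiseless latent group means).

Default parameters mirror the cohort the pipeline was designed around
(141 samples 50/45/46, 334 proteins, 4 batches, 78% quantification rate).
Per-protein variances and effect magnitudes of the real data are unpublished;
the defaults below are plausible placeholders for an LFQ stool matrix and are
documented as such in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AbundanceMatrix, make_protein_meta, make_sample_meta


def _default_effects() -> tuple[float, ...]:
    # 15 planted log2 shifts, alternating sign (8 up / 7 down in cases),
    # magnitudes 1.2-2.4 on the log2 scale.
    mags = np.linspace(1.2, 2.4, 15)
    signs = np.where(np.arange(15) % 2 == 0, 1.0, -1.0)
    return tuple(np.round(mags * signs, 3))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic cohort.

    Attributes
    ----------
    n_per_group : (int, int, int)
        Sample counts for G1, G2, G3.
    n_proteins : int
        Number of retained protein groups in the matrix.
    n_batches : int
        Acquisition batches, balanced across groups (round-robin).
    n_da : int
        Number of planted differentially abundant proteins.
    effect_sizes : tuple of float
        Signed log2 mean shift of each planted protein in G3 vs G1.
    g2_effect_fraction : float
        G2 shifts are this fraction of the G3 shift (adenomas show more
        subtle alterations than carcinomas).
    collinear_block_size, collinear_rho, block_effect
        Size, target pairwise correlation, and shared case-effect (log2,
        G3 vs G1) of the hemoglobin-like collinear block.
    batch_affected_fraction, batch_shift_sd, batch_scale_sd
        Fraction of proteins with batch effects and the SDs of the
        per-(protein, batch) location shift (log2) and log-scale factor.
    missing_rate_target : float
        Overall fraction of missing cells (1 - quantification rate).
    mnar_weight : float in [0, 1]
        Strength of abundance-dependent missingness (0 = purely random).
    outlier_rate : float
        Fraction of cells perturbed by a gross outlier.
    """

    n_per_group: tuple[int, int, int] = (50, 45, 46)
    n_proteins: int = 334
    n_batches: int = 4
    n_da: int = 15
    effect_sizes: tuple[float, ...] = field(default_factory=_default_effects)
    g2_effect_fraction: float = 0.6
    collinear_block_size: int = 5
    collinear_rho: float = 0.998
    block_effect: float = 1.3
    batch_affected_fraction: float = 0.25
    batch_shift_sd: float = 0.7
    batch_scale_sd: float = 0.15
    missing_rate_target: float = 0.22
    mnar_weight: float = 0.5
    outlier_rate: float = 0.002
    seed: int = 0
    # base-signal hyperprior (log2 scale)
    location_mean: float = 20.0
    location_sd: float = 2.5
    noise_sd_range: tuple[float, float] = (0.6, 1.4)
    dietary_fraction: float = 27 / 334  # human proteins co-inferred with a dietary species

    def validate(self) -> None:
        if min(self.n_per_group) < 1 or self.n_proteins < 1 or self.n_batches < 1:
            raise ValueError("counts must be positive")
        if len(self.effect_sizes) != self.n_da:
            raise ValueError(
                f"effect_sizes has {len(self.effect_sizes)} entries but n_da={self.n_da}"
            )
        if self.n_da + self.collinear_block_size > self.n_proteins:
            raise ValueError("n_da + collinear_block_size exceeds n_proteins")
        for name in ("batch_affected_fraction", "missing_rate_target", "mnar_weight", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.collinear_rho < 1.0:
            raise ValueError("collinear_rho must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for recovery testing."""

    da_effects: pd.Series  # signed log2 G3-vs-G1 shift, index = planted protein ids
    collinear_block_ids: list[str]
    batch_effect_table: pd.DataFrame  # columns: protein_id, batch, shift, log_scale
    outlier_cells: list[tuple[str, str]]  # (protein_id, sample_id)
    latent_group_means: pd.DataFrame  # protein x {G1, G2, G3}, noiseless log2 means


def generate_cohort(config: SimConfig):
    """Generate a fully observed raw-intensity cohort.

    Returns ``(matrix, sample_meta, protein_meta, truth)``. The matrix is on
    the raw intensity scale (2**log2-signal) with no missing cells; apply
    :func:`inject_missingness` to emulate incomplete quantification.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n1, n2, n3 = config.n_per_group
    n_samples = n1 + n2 + n3
    p = config.n_proteins

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    groups = ["G1"] * n1 + ["G2"] * n2 + ["G3"] * n3
    # round-robin batch assignment within each group -> balanced batches
    batches = []
    for n in (n1, n2, n3):
        batches.extend((np.arange(n) % config.n_batches + 1).tolist())
    sample_meta = make_sample_meta(sample_ids, groups, batches)

    protein_ids = [f"P{i + 1:04d}" for i in range(p)]

    # --- plant DA proteins and the collinear block (disjoint sets) ----------
    special = rng.choice(p, size=config.n_da + config.collinear_block_size, replace=False)
    da_idx = special[: config.n_da]
    block_idx = special[config.n_da:]

    loc = rng.normal(config.location_mean, config.location_sd, size=p)
    noise_sd = rng.uniform(*config.noise_sd_range, size=p)
    # planted markers are drawn from the upper (quantifiable) half of the
    # abundance range: a marker below the quantification floor is
    # undiscoverable by construction and would test the 50% filter, not the
    # downstream statistics
    loc[da_idx] = config.location_mean + np.abs(rng.normal(0.0, config.location_sd, size=da_idx.size))
    # the collinear block emulates hemoglobin subunits: the FIT analyte is
    # grossly elevated in FIT-positive stool, so these sit in the
    # high-abundance tail and are nearly always quantified (which is what
    # lets their mutual correlation survive missingness and imputation)
    loc[block_idx] = config.location_mean + 2.0 * config.location_sd + rng.normal(
        0.0, 0.5, size=block_idx.size
    )
    # fecal hemoglobin content also varies over orders of magnitude between
    # FIT-positive individuals, so the block gets a wide cross-sample spread
    noise_sd[block_idx] = rng.uniform(2.0, 3.0, size=block_idx.size)

    # noiseless latent log2 group means
    group_means = np.tile(loc[:, None], (1, 3)).astype(float)  # columns G1,G2,G3
    for j, eff in zip(da_idx, config.effect_sizes):
        group_means[j, 1] += config.g2_effect_fraction * eff
        group_means[j, 2] += eff
    for j in block_idx:
        group_means[j, 1] += config.g2_effect_fraction * config.block_effect
        group_means[j, 2] += config.block_effect

    g_index = np.array([{"G1": 0, "G2": 1, "G3": 2}[g] for g in groups])
    log2_signal = group_means[:, g_index]  # p x n

    # --- noise; collinear block shares a latent per-sample factor ----------
    noise = rng.normal(0.0, 1.0, size=(p, n_samples)) * noise_sd[:, None]
    latent = rng.normal(0.0, 1.0, size=n_samples)
    rho = config.collinear_rho
    for j in block_idx:
        noise[j] = noise_sd[j] * (
            np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, size=n_samples)
        )
    log2_values = log2_signal + noise

    # --- batch location/scale effects ---------------------------------------
    # the block's members behave as shared-peptide protein groups of a single
    # analyte: technical nuisances (batch effects, gross outliers) hit every
    # member coherently, never one member alone
    n_affected = int(round(config.batch_affected_fraction * p))
    affected = rng.choice(p, size=n_affected, replace=False)
    block_set = set(block_idx.tolist())
    block_affected = any(j in block_set for j in affected)
    affected = [j for j in affected if j not in block_set]
    batch_arr = sample_meta["batch"].to_numpy()
    rows = []

    def _apply_batch(j, shifts, log_scales):
        for b in range(config.n_batches):
            sel = batch_arr == b + 1
            centered = log2_values[j, sel] - group_means[j, g_index[sel]]
            log2_values[j, sel] = (
                group_means[j, g_index[sel]] + np.exp(log_scales[b]) * centered + shifts[b]
            )
            rows.append((protein_ids[j], b + 1, shifts[b], log_scales[b]))

    for j in affected:
        _apply_batch(
            j,
            rng.normal(0.0, config.batch_shift_sd, size=config.n_batches),
            rng.normal(0.0, config.batch_scale_sd, size=config.n_batches),
        )
    if block_affected:
        shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)
        log_scales = rng.normal(0.0, config.batch_scale_sd, size=config.n_batches)
        for j in block_idx:
            _apply_batch(j, shifts, log_scales)
    batch_table = pd.DataFrame(rows, columns=["protein_id", "batch", "shift", "log_scale"])

    # --- gross outliers ------------------------------------------------------
    n_out = int(round(config.outlier_rate * p * n_samples))
    outlier_cells: list[tuple[str, str]] = []
    if n_out:
        flat = rng.choice(p * n_samples, size=n_out, replace=False)
        for f in flat:
            jj, ss = divmod(int(f), n_samples)
            bump = rng.uniform(4.0, 8.0) * rng.choice([-1.0, 1.0])
            if jj in block_set:  # shared analyte: the artifact hits all members
                for j in block_idx:
                    log2_values[j, ss] += bump
                    outlier_cells.append((protein_ids[j], sample_ids[ss]))
            else:
                log2_values[jj, ss] += bump
                outlier_cells.append((protein_ids[jj], sample_ids[ss]))

    values = pd.DataFrame(
        np.exp2(log2_values), index=pd.Index(protein_ids, name="protein_id"), columns=sample_ids
    )
    matrix = AbundanceMatrix(values=values, mask=values.isna(), scale_state="raw")

    n_dietary = int(round(config.dietary_fraction * p))
    species = np.array(["human"] * p, dtype=object)
    dietary = rng.choice(p, size=n_dietary, replace=False)
    species[dietary] = "human+dietary"
    protein_meta = make_protein_meta(protein_ids, species)
    protein_meta["quant_fraction"] = 1.0

    truth = GroundTruth(
        da_effects=pd.Series(
            list(config.effect_sizes), index=pd.Index([protein_ids[j] for j in da_idx], name="protein_id")
        ),
        collinear_block_ids=[protein_ids[j] for j in block_idx],
        batch_effect_table=batch_table,
        outlier_cells=outlier_cells,
        latent_group_means=pd.DataFrame(
            group_means, index=pd.Index(protein_ids, name="protein_id"), columns=["G1", "G2", "G3"]
        ),
    )
    return matrix, sample_meta, protein_meta, truth


def inject_missingness(
    matrix: AbundanceMatrix, missing_rate_target: float, mnar_weight: float, seed: int
) -> AbundanceMatrix:
    """Mask cells with abundance-dependent (MNAR) missingness.

    Each cell is masked by an independent Bernoulli draw whose logit is linear
    in the centered log2 intensity: ``logit p = a - slope * mnar_weight * z``,
    with the intercept ``a`` solved by bisection so the expected missing
    fraction equals the target. ``mnar_weight=0`` gives uniform (MCAR)
    missingness; at 1 the logit moves 4 per intensity SD, the steep
    abundance dependence typical of DIA label-free data (high-abundance
    cells are then essentially never missing).
    """
    if not 0.0 <= missing_rate_target < 1.0:
        raise ValueError("missing_rate_target must be in [0, 1)")
    if matrix.mask.to_numpy().any():
        raise ValueError("matrix must be fully observed before injecting missingness")
    if missing_rate_target == 0.0:
        return matrix

    log2v = np.log2(matrix.values.to_numpy())
    z = (log2v - log2v.mean()) / log2v.std()
    slope = 4.0 * mnar_weight

    def mean_rate(a: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(a - slope * z)))).mean())

    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < missing_rate_target:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    p_miss = 1.0 / (1.0 + np.exp(-(a - slope * z)))

    rng = np.random.default_rng(seed)
    miss = rng.random(size=p_miss.shape) < p_miss
    values = matrix.values.where(~miss)
    return AbundanceMatrix(
        values=values,
        mask=pd.DataFrame(miss, index=matrix.values.index, columns=matrix.values.columns),
        scale_state="raw",
    )


def simulate_cohort(config: SimConfig):
    """Generate a cohort and apply the configured missingness in one call."""
    matrix, sample_meta, protein_meta, truth = generate_cohort(config)
    matrix = inject_missingness(
        matrix, config.missing_rate_target, config.mnar_weight, seed=config.seed + 1
    )
    protein_meta["quant_fraction"] = 1.0 - matrix.mask.mean(axis=1)
    return matrix, sample_meta, protein_meta, truth
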