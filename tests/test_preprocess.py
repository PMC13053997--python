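"""Filtering rule and five-step pipeline: hand oracles, invariants, calibration."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from fittriage.data import PipelineStateError, make_protein_meta, make_sample_meta
from fittriage.preprocess import (
    assess_batch,
    correct_batch,
    filter_proteins,
    knn_impute,
    log2_transform,
    quantile_normalize,
    zscore,
)
from tests.conftest import make_matrix


def _meta(n, batches=None, groups=None):
    ids = [f"S{i+1:03d}" for i in range(n)]
    return make_sample_meta(ids, groups or ["G1"] * n, batches or [1] * n)


class TestFilterProteins:
    def test_quantified_fraction_threshold_is_inclusive(self):
        vals = np.ones((3, 10))
        vals[0, :6] = np.nan  # 40% quantified
        vals[1, :5] = np.nan  # 50%
        vals[2, :4] = np.nan  # 60%
        m = make_matrix(vals)
        meta = make_protein_meta(m.protein_ids, ["human"] * 3)
        out = filter_proteins(m, meta, 0.5)
        assert list(out.protein_ids) == ["P002", "P003"]

    def test_nonhuman_dropped_despite_full_quantification(self):
        m = make_matrix(np.ones((2, 4)))
        meta = make_protein_meta(m.protein_ids, ["nonhuman", "human+dietary"])
        out = filter_proteins(m, meta, 0.5)
        assert list(out.protein_ids) == ["P002"]

    def test_zero_threshold_keeps_all_human_eligible(self):
        vals = np.ones((3, 4))
        vals[0, :3] = np.nan
        m = make_matrix(vals)
        meta = make_protein_meta(m.protein_ids, ["human", "human", "nonhuman"])
        out = filter_proteins(m, meta, 0.0)
        assert list(out.protein_ids) == ["P001", "P002"]

    def test_empty_result_is_loud(self):
        m = make_matrix(np.ones((1, 4)))
        meta = make_protein_meta(m.protein_ids, ["nonhuman"])
        with pytest.raises(ValueError, match="species"):
            filter_proteins(m, meta, 0.5)


class TestLog2:
    def test_known_values(self):
        m = make_matrix([[8.0, 1.0], [2.0, 16.0]])
        out = log2_transform(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[3.0, 0.0], [1.0, 4.0]])
        assert out.scale_state == "log2"

    def test_column_powers_of_two(self):
        m = make_matrix([[2.0], [4.0], [16.0]])
        np.testing.assert_allclose(
            log2_transform(m).values.to_numpy().ravel(), [1.0, 2.0, 4.0]
        )

    def test_nonpositive_cell_named_in_error(self):
        m = make_matrix([[4.0, -1.0]])
        with pytest.raises(ValueError, match="P001"):
            log2_transform(m)


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        # columns [1,3] and [2,4] -> both become [1.5, 3.5]
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]], scale_state="log2")
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self):
        m = make_matrix([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]], scale_state="log2")
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_complete_columns_share_sorted_distribution(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(30, 5)), scale_state="log2")
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for c in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, c]), ref)

    def test_idempotent_on_complete_matrices(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(25, 4)), scale_state="log2")
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_missing_cells_stay_missing(self):
        vals = np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]])
        out = quantile_normalize(make_matrix(vals, scale_state="log2"))
        assert np.isnan(out.values.to_numpy()[1, 0])
        assert out.mask.to_numpy()[1, 0]

    def test_entirely_missing_column_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(make_matrix(vals, scale_state="log2"))


class TestAssessBatch:
    def test_permuted_labels_give_alpha_rate(self, processed, sample_meta):
        rng = np.random.default_rng(12)
        permuted = sample_meta.copy()
        permuted["batch"] = rng.permutation(permuted["batch"].to_numpy())
        rep = assess_batch(processed["normalized"], permuted)
        assert abs(rep.fraction_significant - 0.05) <= 0.03

    def test_planted_batch_effects_flagged_near_quarter(self, processed):
        # generator plants batch effects in 25% of proteins
        assert abs(processed["batch_report_before"].fraction_significant - 0.25) <= 0.06

    def test_single_large_shift_is_certain(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(1, 40))
        vals[0, 20:] += 10.0
        m = make_matrix(vals, scale_state="normalized")
        meta = _meta(40, batches=[1] * 20 + [2] * 20)
        rep = assess_batch(m, meta)
        assert rep.p_values.iloc[0] < 1e-6

    def test_underpopulated_batch_flagged_not_dropped(self):
        vals = np.array([[1.0, 2.0, np.nan, 1.5, 2.5, 1.2]])
        m = make_matrix(vals, scale_state="normalized")
        meta = _meta(6, batches=[1, 1, 2, 2, 1, 1])
        rep = assess_batch(m, meta)  # batch 2 has 1 observed cell
        assert rep.undefined.iloc[0]
        assert np.isnan(rep.p_values.iloc[0])


class TestCorrectBatch:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(10, 8)), scale_state="normalized")
        out = correct_batch(m, _meta(8))
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-10)

    def test_constant_shift_removed(self):
        # per-protein constant shifts between two large batches: with many
        # samples per batch the EB shrinkage weight vanishes, so the
        # post-correction batch-mean difference is ~0 for every protein
        rng = np.random.default_rng(6)
        n_b = 200
        base = rng.normal(size=(20, 2 * n_b))
        shifts = rng.normal(size=(20, 1)) * 3
        vals = base.copy()
        vals[:, n_b:] += shifts
        m = make_matrix(vals, scale_state="normalized")
        meta = _meta(2 * n_b, batches=[1] * n_b + [2] * n_b)
        out = correct_batch(m, meta).values.to_numpy()
        diff = out[:, :n_b].mean(axis=1) - out[:, n_b:].mean(axis=1)
        assert np.abs(diff).max() < 0.02

    def test_heterogeneous_shifts_strongly_reduced(self):
        # per-protein shifts of SD 3: EB shrinkage leaves a small residual,
        # but the batch separation collapses by an order of magnitude
        rng = np.random.default_rng(6)
        base = rng.normal(size=(20, 30))
        shifts = rng.normal(size=(20, 1)) * 3
        vals = base.copy()
        vals[:, 15:] += shifts
        m = make_matrix(vals, scale_state="normalized")
        meta = _meta(30, batches=[1] * 15 + [2] * 15)
        out = correct_batch(m, meta).values.to_numpy()
        diff = out[:, :15].mean(axis=1) - out[:, 15:].mean(axis=1)
        assert np.abs(diff).max() < 0.3

    def test_correction_removes_planted_batch_signal(self, processed):
        assert processed["batch_report_after"].fraction_significant <= 0.07

    def test_batch_of_one_rejected(self):
        m = make_matrix(np.ones((3, 5)) + np.arange(15).reshape(3, 5), scale_state="normalized")
        meta = _meta(5, batches=[1, 1, 1, 1, 2])
        with pytest.raises(ValueError, match="fewer than 2"):
            correct_batch(m, meta)

    def test_missing_cells_stay_missing(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(12, 20))
        vals[3, 4] = np.nan
        m = make_matrix(vals, scale_state="normalized")
        out = correct_batch(m, _meta(20, batches=[1] * 10 + [2] * 10))
        assert np.isnan(out.values.to_numpy()[3, 4])

    def test_matches_bioconductor_combat_on_complete_matrix(self, tmp_path):
        # independent oracle: sva::ComBat (parametric, no covariates)
        rng = np.random.default_rng(42)
        vals = rng.normal(loc=10, size=(15, 12))
        vals[:, 6:] += rng.normal(size=(15, 1)) * 1.5
        batches = [1] * 6 + [2] * 6
        m = make_matrix(vals, scale_state="normalized")
        ours = correct_batch(m, _meta(12, batches=batches)).values.to_numpy()

        csv = tmp_path / "mat.csv"
        pd.DataFrame(vals).to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(sva))
            x <- as.matrix(read.csv("{csv}"))
            batch <- c(rep(1, 6), rep(2, 6))
            out <- ComBat(dat = x, batch = batch, par.prior = TRUE, mean.only = FALSE)
            write.csv(out, "{tmp_path}/out.csv", row.names = FALSE)
        """)
        proc = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript/sva unavailable: {proc.stderr[-200:]}")
        theirs = pd.read_csv(tmp_path / "out.csv").to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(6, 5)), scale_state="batch_corrected")
        out = knn_impute(m, k=2)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())
        assert out.scale_state == "imputed"

    def test_three_sample_hand_oracle(self):
        # sample-axis variant. samples: A=(1,1,?), B=(1,1,5), C=(10,10,9);
        # A's nearest samples by RMS distance over shared proteins are B
        # (distance 0) then C; k=2 -> imputed value = mean(5, 9) = 7
        vals = np.array([[1.0, 1.0, 10.0], [1.0, 1.0, 10.0], [np.nan, 5.0, 9.0]])
        m = make_matrix(vals, scale_state="batch_corrected")
        out = knn_impute(m, k=2, axis="samples")
        assert out.values.to_numpy()[2, 0] == pytest.approx(7.0)

    def test_protein_axis_hand_oracle(self):
        # protein-axis (default): proteins A=(1,2,?,4), B=(1,2,3,4) identical
        # where observed, C=(9,9,9,9) far away; k=1 -> the missing cell of A
        # is filled from its nearest protein B at that sample: 3
        vals = np.array([[1.0, 2.0, np.nan, 4.0], [1.0, 2.0, 3.0, 4.0], [9.0, 9.0, 9.0, 9.0]])
        m = make_matrix(vals, scale_state="batch_corrected")
        out = knn_impute(m, k=1, axis="proteins")
        assert out.values.to_numpy()[0, 2] == pytest.approx(3.0)

    def test_identical_samples_impute_common_value(self):
        vals = np.array([[2.0, 2.0, 2.0], [np.nan, 4.0, 4.0]])
        m = make_matrix(vals, scale_state="batch_corrected")
        out = knn_impute(m, k=2, axis="samples")
        assert out.values.to_numpy()[1, 0] == pytest.approx(4.0)

    def test_observed_cells_never_altered(self, processed):
        imputed = processed["imputed"]
        corrected_vals = processed["normalized"]  # same observed mask
        obs = ~imputed.mask.to_numpy()
        # re-run imputation on the batch-corrected intermediate to compare
        assert not np.isnan(imputed.values.to_numpy()[obs]).any()
        assert imputed.mask.to_numpy().sum() > 0  # provenance retained

    def test_k_too_large_rejected(self):
        m = make_matrix(np.ones((2, 3)), scale_state="batch_corrected")
        with pytest.raises(ValueError, match="k="):
            knn_impute(m, k=3, axis="samples")
        with pytest.raises(ValueError, match="k="):
            knn_impute(m, k=2, axis="proteins")


class TestZscore:
    def test_closed_form_row(self):
        m = make_matrix([[1.0, 2.0, 3.0]], scale_state="imputed")
        out = zscore(m).values.to_numpy().ravel()
        np.testing.assert_allclose(out, [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_row_rejected_with_ids(self):
        m = make_matrix([[1.0, 2.0], [5.0, 5.0]], scale_state="imputed")
        with pytest.raises(ValueError, match="P002"):
            zscore(m)

    def test_rows_centered_and_idempotent(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.normal(size=(12, 9)), scale_state="imputed")
        once = zscore(m)
        vals = once.values.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(vals.std(axis=1), 1.0, atol=1e-12)
        twice = zscore(once)
        np.testing.assert_allclose(twice.values.to_numpy(), vals, atol=1e-10)


def test_pipeline_rejects_out_of_order_states():
    m = make_matrix(np.ones((2, 3)) + np.arange(6).reshape(2, 3))
    with pytest.raises(PipelineStateError):
        zscore(m)  # raw -> zscore skips the pipeline
    with pytest.raises(PipelineStateError):
        quantile_normalize(m)  # raw -> normalize without log2
    logged = log2_transform(m)
    with pytest.raises(PipelineStateError):
        log2_transform(logged)  # cannot re-apply
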