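import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mahex.preprocess import (
    background_correct,
    compute_nuse,
    degradation_profile,
    normexp_fit,
    normexp_signal,
    quantile_normalize,
    rma,
    sample_columns,
    summarize_median_polish,
)


def probe_frame(values, probesets=None, positions=None):
    values = np.asarray(values, float)
    n, k = values.shape
    df = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "probeset_id": probesets if probesets is not None else ["ps0"] * n,
    })
    if positions is not None:
        df["position_index"] = positions
    for j in range(k):
        df[f"Sample-{j+1}"] = values[:, j]
    return df


class TestBackgroundCorrect:
    def test_shift_log_identity_when_background_zero(self):
        vals = np.array([[0.5, 0.9], [3.0, 4.0], [7.0, 2.0]])
        m = probe_frame(vals)
        out = background_correct(m, method="shift-log", background=0.0)
        np.testing.assert_array_equal(out[["Sample-1", "Sample-2"]].to_numpy(), vals)

    def test_shift_log_subtracts_half_column_minimum(self):
        m = probe_frame([[101.0], [150.0], [260.0]])
        out = background_correct(m, method="shift-log")
        np.testing.assert_allclose(out["Sample-1"], [50.5, 99.5, 209.5])

    def test_shift_log_background_above_minimum_rejected(self):
        m = probe_frame([[101.0], [150.0]])
        with pytest.raises(ValueError, match="below the column minimum"):
            background_correct(m, method="shift-log", background=120.0)

    def test_normexp_constant_column_stays_constant(self):
        m = probe_frame([[5.0], [5.0], [5.0], [5.0]])
        out = background_correct(m, method="normexp")
        col = out["Sample-1"].to_numpy()
        assert np.allclose(col, col[0]) and (col > 0).all()

    def test_normexp_posterior_mean_matches_numeric_integration(self, rng):
        # independent oracle: E[S|X=x] via quadrature over the
        # normal*exponential joint density
        mu, sigma, alpha = 30.0, 12.0, 200.0
        xs = np.array([20.0, 45.0, 80.0, 300.0, 1500.0])
        implemented = normexp_signal(xs, mu, sigma, alpha)
        for x, got in zip(xs, implemented):
            joint = lambda s: np.exp(-s / alpha) / alpha * stats.norm.pdf(
                x - s, mu, sigma)
            # integrand peaks sharply near s = x - mu; give quad the hint
            upper = x + 20 * sigma
            pts = [p for p in (x - mu - 5 * sigma, x - mu, x - mu + 5 * sigma)
                   if 0 < p < upper]
            num, _ = integrate.quad(lambda s: s * joint(s), 0, upper,
                                    points=pts, limit=400)
            den, _ = integrate.quad(joint, 0, upper, points=pts, limit=400)
            assert got == pytest.approx(num / den, rel=1e-6)

    def test_normexp_output_positive_and_monotone(self, rng):
        x = rng.exponential(100, 3000) + 2 ** rng.normal(8, 2, 3000)
        m = probe_frame(x[:, None])
        out = background_correct(m, method="normexp")
        col = out["Sample-1"].to_numpy()
        assert (col > 0).all()
        order = np.argsort(x)
        assert (np.diff(col[order]) >= -1e-9).all()

    def test_normexp_fit_recovers_true_parameters(self, rng):
        mu, sigma, alpha = 100.0, 20.0, 400.0
        x = rng.normal(mu, sigma, 40_000) + rng.exponential(alpha, 40_000)
        mu_hat, sigma_hat, alpha_hat = normexp_fit(x)
        assert mu_hat == pytest.approx(mu, rel=0.1)
        assert sigma_hat == pytest.approx(sigma, rel=0.25)
        assert alpha_hat == pytest.approx(alpha, rel=0.1)

    def test_gc_stratified_requires_gc_column(self):
        m = probe_frame([[10.0], [20.0]])
        with pytest.raises(ValueError, match="gc_content"):
            background_correct(m, method="gc-stratified")

    def test_gc_stratified_corrects_within_strata(self, rng):
        n = 500
        vals = rng.uniform(50, 500, (n, 1))
        m = probe_frame(vals)
        m["gc_content"] = rng.uniform(0.3, 0.7, n)
        out = background_correct(m, method="gc-stratified")
        assert (out["Sample-1"] > 0).all()
        assert (out["Sample-1"].to_numpy() <= vals[:, 0]).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            background_correct(probe_frame([[1.0]]), method="loess")

    def test_offset_added_after_correction(self):
        m = probe_frame([[0.5], [3.0], [7.0]])
        base = background_correct(m, method="shift-log")
        shifted = background_correct(m, method="shift-log", offset=16.0)
        np.testing.assert_allclose(
            shifted["Sample-1"], base["Sample-1"] + 16.0)


class TestQuantileNormalize:
    def test_two_by_two_oracle(self):
        m = probe_frame([[1.0, 2.0], [3.0, 4.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["Sample-1"], [1.5, 3.5])
        np.testing.assert_allclose(out["Sample-2"], [1.5, 3.5])

    def test_identical_columns_fixed_point(self):
        vals = np.array([[4.0, 4.0], [1.0, 1.0], [9.0, 9.0]])
        out = quantile_normalize(probe_frame(vals))
        np.testing.assert_allclose(out[["Sample-1", "Sample-2"]].to_numpy(), vals)

    def test_constant_matrix_unchanged(self):
        vals = np.full((4, 3), 7.0)
        out = quantile_normalize(probe_frame(vals))
        np.testing.assert_allclose(
            out[[f"Sample-{j+1}" for j in range(3)]].to_numpy(), vals)

    def test_sorted_columns_identical_and_ranks_preserved(self, rng):
        vals = rng.lognormal(5, 1, (300, 4))
        m = probe_frame(vals)
        out = quantile_normalize(m)
        cols = [f"Sample-{j+1}" for j in range(4)]
        sorted_cols = np.sort(out[cols].to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_array_equal(sorted_cols[:, 0], sorted_cols[:, j])
        for j, c in enumerate(cols):
            assert (np.argsort(vals[:, j], kind="stable")
                    == np.argsort(out[c].to_numpy(), kind="stable")).all()

    def test_ties_receive_mean_of_reference_values(self):
        # sorted columns are [2,2] and [1,4] -> reference row means
        # [1.5, 3.0]; the tie spanning ranks 1-2 gets their mean 2.25
        m = probe_frame([[2.0, 1.0], [2.0, 4.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["Sample-1"], [2.25, 2.25])
        np.testing.assert_allclose(out["Sample-2"], [1.5, 3.0])

    def test_empty_matrix_rejected(self):
        m = probe_frame(np.empty((0, 2)))
        with pytest.raises(ValueError, match="empty"):
            quantile_normalize(m)


def median_polish_oracle(block, max_iter=10, tol=0.01):
    """Independent loop-based Tukey median polish (row sweep first)."""
    resid = np.array(block, float)
    overall = 0.0
    row = np.zeros(resid.shape[0])
    col = np.zeros(resid.shape[1])
    for _ in range(max_iter):
        rm = np.median(resid, axis=1)
        resid -= rm[:, None]
        row += rm
        rc = np.median(row)
        row -= rc
        overall += rc
        cm = np.median(resid, axis=0)
        resid -= cm[None, :]
        col += cm
        cc = np.median(col)
        col -= cc
        overall += cc
        if max(np.abs(rm).max(), np.abs(cm).max()) < tol:
            break
    return overall + col, resid


class TestMedianPolish:
    def test_exactly_additive_block(self):
        # [[1,2],[3,4]] is additive: zero residuals, sample effects 1 apart
        m = probe_frame([[1.0, 2.0], [3.0, 4.0]])
        expr, fit = summarize_median_polish(m)
        e = expr[["Sample-1", "Sample-2"]].to_numpy()[0]
        assert e[1] - e[0] == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_single_probe_set_passthrough(self):
        m = probe_frame([[5.0, 8.0, 2.0]])
        expr, _ = summarize_median_polish(m)
        np.testing.assert_allclose(
            expr[["Sample-1", "Sample-2", "Sample-3"]].to_numpy()[0],
            [5.0, 8.0, 2.0])

    def test_matches_independent_sweep_oracle(self, rng):
        for _ in range(10):
            block = rng.normal(8, 2, (5, 4))
            m = probe_frame(block)
            expr, fit = summarize_median_polish(m)
            expected, resid = median_polish_oracle(block)
            got = expr[[f"Sample-{j+1}" for j in range(4)]].to_numpy()[0]
            np.testing.assert_allclose(got, expected, atol=0.01)
            np.testing.assert_allclose(fit.residuals, resid, atol=0.01)

    def test_residual_medians_small_at_convergence(self, rng):
        block = rng.normal(0, 1, (9, 6))
        _, fit = summarize_median_polish(probe_frame(block), max_iter=50,
                                         tol=1e-9)
        resid = fit.residuals
        assert np.abs(np.median(resid, axis=0)).max() < 1e-6
        assert np.abs(np.median(resid, axis=1)).max() < 1e-6

    def test_mixed_probe_set_sizes(self, rng):
        sets = ["a"] * 3 + ["b"] * 5 + ["c"] * 1
        block = rng.normal(8, 1, (9, 3))
        m = probe_frame(block, probesets=sets)
        expr, fit = summarize_median_polish(m)
        assert list(expr["probeset_id"]) == ["a", "b", "c"]
        # singleton set passes its probe through
        np.testing.assert_allclose(
            expr[expr["probeset_id"] == "c"].iloc[0, 1:].to_numpy(float),
            block[8])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_median_polish(probe_frame(np.empty((0, 2))))


class TestNuse:
    def test_identical_chips_give_unit_nuse(self, rng):
        block = rng.normal(8, 1, (6, 1))
        vals = np.repeat(block, 4, axis=1)
        m = probe_frame(vals, probesets=["a"] * 3 + ["b"] * 3)
        _, fit = summarize_median_polish(m)
        table, per_chip = compute_nuse(fit)
        np.testing.assert_allclose(
            table[[f"Sample-{j+1}" for j in range(4)]].to_numpy(), 1.0)
        np.testing.assert_allclose(per_chip.to_numpy(), 1.0)

    def test_noisier_chip_has_elevated_nuse(self, rng):
        n_sets, per_set, k = 40, 5, 4
        base = rng.normal(8, 0.1, (n_sets * per_set, k))
        base[:, 0] += rng.normal(0, 1.0, n_sets * per_set)  # chip 1 noisy
        m = probe_frame(base, probesets=np.repeat(
            [f"s{i}" for i in range(n_sets)], per_set))
        _, fit = summarize_median_polish(m, max_iter=30, tol=1e-6)
        _, per_chip = compute_nuse(fit)
        assert per_chip["Sample-1"] > 1.1
        assert all(per_chip[f"Sample-{j+1}"] <= 1.01 for j in range(1, k))

    def test_single_sample_unit_by_convention(self, rng):
        m = probe_frame(rng.normal(8, 1, (6, 1)), probesets=["a"] * 3 + ["b"] * 3)
        _, fit = summarize_median_polish(m)
        table, per_chip = compute_nuse(fit)
        np.testing.assert_allclose(table["Sample-1"].to_numpy(), 1.0)


class TestDegradation:
    def test_position_independent_slope_zero(self, rng):
        vals = np.full((12, 2), 256.0)
        m = probe_frame(vals, probesets=["a"] * 6 + ["b"] * 6,
                        positions=list(range(6)) * 2)
        deg = degradation_profile(m)
        np.testing.assert_allclose(deg["slope"], 0.0, atol=1e-12)
        assert not deg["flagged"].any()

    def test_exact_linear_profile_recovered(self):
        positions = np.tile(np.arange(5), 2)
        vals = 2.0 ** (8.0 + 0.1 * positions)
        m = probe_frame(vals[:, None], probesets=["a"] * 5 + ["b"] * 5,
                        positions=positions)
        deg = degradation_profile(m)
        assert deg["slope"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_matches_closed_form_least_squares(self, rng):
        positions = np.tile(np.arange(8), 5)
        vals = rng.lognormal(6, 0.5, (40, 3))
        m = probe_frame(vals, probesets=np.repeat([f"s{i}" for i in range(5)], 8),
                        positions=positions)
        deg = degradation_profile(m)
        for j in range(3):
            y = np.array([np.log2(vals[positions == p, j]).mean()
                          for p in range(8)])
            x = np.arange(8)
            slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
            assert deg["slope"].iloc[j] == pytest.approx(slope, abs=1e-10)

    def test_single_position_flagged(self):
        m = probe_frame([[10.0], [20.0]], positions=[0, 0])
        deg = degradation_profile(m)
        assert deg["flagged"].all()
        assert deg["slope"].isna().all()


class TestPipelineCoherence:
    def test_scale_coherence_shift_log_without_normalization(self, small_chips):
        # multiplying all raw intensities by a constant shifts every
        # log2 expression by log2(constant) under shift-log correction
        probes, _ = small_chips
        probes = probes.head(300).copy()
        cols = sample_columns(probes)
        expr1, _, _ = rma(probes, background="shift-log", offset=0.0,
                          normalize=False)
        scaled = probes.copy()
        for c in cols:
            scaled[c] = scaled[c] * 8.0
        expr2, _, _ = rma(scaled, background="shift-log", offset=0.0,
                          normalize=False)
        d = expr2[cols].to_numpy() - expr1[cols].to_numpy()
        np.testing.assert_allclose(d, 3.0, atol=1e-9)

    def test_m_values_invariant_to_global_scaling_after_quantile(self, small_chips):
        from mahex import compute_contrast, default_contrasts

        probes, _ = small_chips
        probes = probes.head(500).copy()
        cols = sample_columns(probes)
        cdef = default_contrasts()[0]
        expr1, _, _ = rma(probes, background="shift-log", offset=0.0)
        scaled = probes.copy()
        for c in cols:
            scaled[c] = scaled[c] * 8.0
        expr2, _, _ = rma(scaled, background="shift-log", offset=0.0)
        m1 = compute_contrast(expr1, cdef)["M"].to_numpy()
        m2 = compute_contrast(expr2, cdef)["M"].to_numpy()
        np.testing.assert_allclose(m1, m2, atol=1e-9)
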