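"""Spike-in-anchored count normalization: fixed-fraction scaling, UQ, RUVg."""

import numpy as np
import pandas as pd
import pytest

from omnictrl.readsim import simulate_count_matrix
from omnictrl.spikenorm import (
    CountMatrix,
    evaluate_abundance,
    ruvg,
    scale_spikes_to_fraction,
    uq_normalize,
)


def tiny_matrix(counts: np.ndarray, n_controls: int) -> CountMatrix:
    n_feat, n_samp = counts.shape
    idx = [f"f{i}" for i in range(n_feat)]
    df = pd.DataFrame(counts, index=idx, columns=[f"s{j}" for j in range(n_samp)])
    meta = pd.DataFrame(
        {"is_control": [i < n_controls for i in range(n_feat)]}, index=idx
    )
    return CountMatrix(df, meta, pd.Series(["A"] * n_samp, index=df.columns))


def batch_fixture(seed=0, batch=1.5, n_samples=6, prep_sd=0.0):
    """Spiked features (controls + evaluable standards) carry a two-level
    batch factor on half the samples and optionally a continuous per-sample
    prep-efficiency factor; standards additionally have a true fold-change
    of 2 between conditions."""
    return simulate_count_matrix(
        n_features=400,
        n_samples=n_samples,
        spike_features=24,
        dispersion=0.002,
        batch_effect_size=batch,
        fold_changes=2.0,
        n_evaluable=30,
        seed=seed,
        base_mean=2000,
        prep_noise_sd=prep_sd,
    )


class TestScaleToFraction:
    def test_derived_scalar(self):
        counts = np.zeros((10, 1))
        counts[0, 0] = 500  # control
        counts[1:, 0] = 9500 / 9
        cm = tiny_matrix(counts, 1)
        scaled, factors = scale_spikes_to_fraction(cm, 0.01)
        # solve s*500 = 0.01*(9500 + s*500)
        assert factors.iloc[0] == pytest.approx(0.191919, abs=1e-5)

    def test_exact_fixed_point(self):
        cm = batch_fixture()
        scaled, _ = scale_spikes_to_fraction(cm, 0.01)
        for s in scaled.counts.columns:
            frac = (
                scaled.counts.loc[scaled.controls, s].sum()
                / scaled.counts[s].sum()
            )
            assert abs(frac - 0.01) < 1e-9

    def test_already_at_fraction_identity(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 10.0
        counts[1, 0] = 990.0
        scaled, factors = scale_spikes_to_fraction(tiny_matrix(counts, 1), 0.01)
        assert factors.iloc[0] == pytest.approx(1.0)

    def test_fraction_zero_warns(self):
        counts = np.ones((3, 2)) * 100
        with pytest.warns(UserWarning):
            scaled, _ = scale_spikes_to_fraction(tiny_matrix(counts, 1), 0.0)
        assert (scaled.counts.iloc[0] == 0).all()

    def test_zero_controls_rejected(self):
        counts = np.ones((3, 1)) * 100
        counts[0, 0] = 0
        with pytest.raises(ValueError):
            scale_spikes_to_fraction(tiny_matrix(counts, 1), 0.01)


class TestUQ:
    def test_identical_samples_equal_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 3)).astype(float)
        res = uq_normalize(tiny_matrix(counts, 5))
        assert np.allclose(res.size_factors, 1.0)

    def test_doubled_sample_factor_ratio(self):
        col = np.arange(1, 101).astype(float)
        counts = np.stack([col, 2 * col], axis=1)
        res = uq_normalize(tiny_matrix(counts, 5))
        assert res.size_factors.iloc[1] / res.size_factors.iloc[0] == pytest.approx(2.0)

    def test_depth_factor_recovery(self):
        cm = simulate_count_matrix(
            500, 3, spike_features=10, dispersion=0.01,
            depth_factors=np.array([1.0, 1.5, 3.0]), seed=4, base_mean=2000,
        )
        res = uq_normalize(cm)
        f = res.size_factors.to_numpy()
        ratios = f / f[0]
        assert np.allclose(ratios, [1.0, 1.5, 3.0], rtol=0.05)

    def test_all_zero_sample_rejected(self):
        counts = np.ones((5, 2)) * 10
        counts[:, 1] = 0
        with pytest.raises(ValueError):
            uq_normalize(tiny_matrix(counts, 1))


class TestRUVg:
    def test_k0_identity(self):
        cm = batch_fixture()
        res = ruvg(cm, k=0)
        pd.testing.assert_frame_equal(res.adjusted_log, res.log_counts)

    def test_batch_factor_removed_from_controls(self):
        cm = batch_fixture()
        res = ruvg(cm, k=1)
        d = res.diagnostics
        assert d["control_variance_after"] < 0.1 * d["control_variance_before"]

    def test_true_fold_change_survives(self):
        # continuous per-sample prep factor, 12 samples: the unwanted factor
        # is separable from the condition contrast
        cm = batch_fixture(seed=3, batch=1.0, n_samples=12, prep_sd=0.35)
        res = ruvg(cm, k=1)
        std = [f for f in cm.counts.index if f.startswith("std_")]
        a = cm.conditions[cm.conditions == "A"].index
        b = cm.conditions[cm.conditions == "B"].index
        lfc = (
            res.adjusted_log.loc[std, b].mean(axis=1)
            - res.adjusted_log.loc[std, a].mean(axis=1)
        ) / np.log(2)
        # fold-change of 2 survives within 10%: |log2 ratio - 1| < log2(1.1)
        assert abs(lfc.mean() - 1.0) < np.log2(1.1)

    def test_idempotence_on_cleaned_fixture(self):
        """Controls constant across samples: RUVg finds no unwanted factor
        and leaves the matrix untouched; a second pass changes nothing."""
        rng = np.random.default_rng(5)
        counts = rng.poisson(1000, size=(50, 6)).astype(float)
        counts[:10] = np.tile(np.arange(900, 1000, 10)[:, None], (1, 6))
        cm = tiny_matrix(counts, 10)
        res1 = ruvg(cm, k=1)
        delta1 = (res1.adjusted_log - res1.log_counts).abs().to_numpy().max()
        assert delta1 < 1e-9
        res2 = ruvg(
            CountMatrix(np.exp(res1.adjusted_log) - 1, cm.feature_meta, cm.conditions),
            k=1,
        )
        delta2 = (res2.adjusted_log - res2.log_counts).abs().to_numpy().max()
        assert delta2 < 1e-6

    def test_k_too_large_rejected(self):
        cm = batch_fixture()
        with pytest.raises(ValueError):
            ruvg(cm, k=100)


class TestEvaluate:
    def test_perfect_data(self):
        idx = [f"std_{i}" for i in range(10)]
        expected = pd.Series(np.linspace(-2, 2, 10), index=idx)
        log = pd.DataFrame(
            {
                "s0": np.zeros(10),
                "s1": np.zeros(10),
                "s2": expected * np.log(2),
                "s3": expected * np.log(2),
            },
            index=idx,
        )
        cond = pd.Series(["A", "A", "B", "B"], index=log.columns)
        table, summary = evaluate_abundance(log, cond, expected)
        assert summary["mad"] == pytest.approx(0.0, abs=1e-12)
        assert summary["r2"] == pytest.approx(1.0)

    def test_normalization_method_ordering(self):
        """On the batch fixture, RUVg beats UQ and unnormalized on the
        expected-vs-observed fold-change MAD, and UQ does not beat RUVg on
        control variance."""
        cm = batch_fixture(seed=7, batch=1.0, n_samples=12, prep_sd=0.35)
        expected = cm.feature_meta["expected_lfc"]
        raw = np.log(cm.counts + 1.0)
        _, s_raw = evaluate_abundance(raw, cm.conditions, expected)
        res_uq = uq_normalize(cm)
        _, s_uq = evaluate_abundance(res_uq.adjusted_log, cm.conditions, expected)
        res_ruv = ruvg(cm, k=1)
        _, s_ruv = evaluate_abundance(res_ruv.adjusted_log, cm.conditions, expected)
        assert s_ruv["mad"] < s_raw["mad"]
        assert s_ruv["mad"] < s_uq["mad"]
        assert (
            res_ruv.diagnostics["control_variance_after"]
            <= res_uq.diagnostics["control_variance_after"]
        )
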