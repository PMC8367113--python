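"""Feature extraction: second-order statistics, multiscale entropy, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbdc.errors import ContractViolation
from nbdc.features import (
    FD_NAMES,
    FEATURE_NAMES,
    MSE_NAMES,
    SECOND_ORDER_NAMES,
    EntropyConfig,
    band_features,
    coarse_grain,
    daily_statistics,
    extract_features,
    multiscale_entropy,
    power_spectrum,
    sample_entropy,
    second_order_features,
)
from oracles import sample_entropy_bruteforce


class TestDailyStatistics:
    def test_constant_day(self):
        stats = daily_statistics(np.full(24, 5.0))
        assert stats.tolist() == [[5.0, 5.0, 0.0, 5.0]]  # max, min, std, mean

    def test_ramp_day(self):
        stats = daily_statistics(np.arange(24, dtype=float))
        mx, mn, _, mean = stats[0]
        assert (mx, mn, mean) == (23.0, 0.0, 11.5)

    def test_one_row_per_day(self):
        assert daily_statistics(np.ones(240)).shape == (10, 4)

    def test_empty_rejected(self):
        with pytest.raises(ContractViolation):
            daily_statistics(np.array([]))


class TestSecondOrder:
    def test_mean_of_daily_maxima(self):
        seq = np.concatenate([np.full(24, 10.0), np.full(24, 20.0)])
        feats = second_order_features(daily_statistics(seq))
        assert feats["Mean_Max"] == 15.0
        assert feats["Max_Max"] == 20.0 and feats["Min_Max"] == 10.0

    def test_identical_days_have_zero_spread(self):
        day = np.arange(24, dtype=float)
        feats = second_order_features(daily_statistics(np.tile(day, 5)))
        for name in ("Std_Max", "Std_Min", "Std_Mean", "Std_Std"):
            assert feats[name] == pytest.approx(0.0, abs=1e-12)

    def test_census(self):
        feats = second_order_features(daily_statistics(np.ones(48)))
        assert tuple(feats) == SECOND_ORDER_NAMES
        assert len(feats) == 16


class TestCoarseGrain:
    def test_block_means(self):
        assert coarse_grain(np.array([1.0, 2.0, 3.0, 4.0]), 2).tolist() == [1.5, 3.5]

    def test_identity_at_scale_one(self):
        x = np.arange(7.0)
        assert np.array_equal(coarse_grain(x, 1), x)

    def test_remainder_dropped(self):
        assert coarse_grain(np.arange(10.0), 3).size == 3

    def test_scale_beyond_length_rejected(self):
        with pytest.raises(ContractViolation):
            coarse_grain(np.arange(4.0), 5)


class TestSampleEntropy:
    def test_constant_sequence_is_zero(self):
        assert sample_entropy(np.full(60, 3.0), m=2, r=0.1) == 0.0

    def test_strict_alternation_is_zero(self):
        x = np.tile([1.0, 5.0], 30)
        assert sample_entropy(x, m=2, r=1.0) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ContractViolation):
            sample_entropy(np.array([1.0, 2.0, 3.0]), m=2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        x = rng.normal(size=n) if rng.random() < 0.7 else rng.integers(0, 4, n).astype(float)
        r = 0.2 * max(x.std(), 1e-3)
        assert sample_entropy(x, 2, r) == pytest.approx(
            sample_entropy_bruteforce(x, 2, r), abs=1e-12
        )


class TestMultiscaleEntropy:
    def test_full_scale_census(self):
        rng = np.random.default_rng(1)
        mse = multiscale_entropy(rng.poisson(5, 336).astype(float))
        assert tuple(mse) == MSE_NAMES
        assert len(mse) == 24

    def test_constant_sequence_all_zero(self):
        mse = multiscale_entropy(np.full(336, 4.0))
        assert all(v == 0.0 for v in mse.values())

    def test_white_noise_entropy_decays_with_scale(self):
        """Coarse-graining averages iid noise, so entropy falls from scale 1 to 12."""
        rng = np.random.default_rng(7)
        m1, m12 = [], []
        for _ in range(50):
            mse = multiscale_entropy(rng.normal(size=336))
            m1.append(mse["MSE_1"])
            m12.append(mse["MSE_12"])
        assert np.mean(m1) > np.mean(m12)

    def test_short_sequence_rejected(self):
        with pytest.raises(ContractViolation):
            multiscale_entropy(np.ones(90), EntropyConfig(max_scale=24))


class TestPowerSpectrum:
    def test_circadian_cosine_peaks_at_one_cycle_per_day(self):
        h = np.arange(336)
        freqs, power, _ = power_spectrum(np.cos(2 * np.pi * h / 24))
        assert freqs[np.argmax(power)] == pytest.approx(1.0)
        assert power.max() > 100 * np.median(power)

    def test_constant_sequence_has_no_ac_power(self):
        _, power, dc = power_spectrum(np.full(336, 3.0))
        assert np.allclose(power, 0.0)
        assert dc > 0

    @pytest.mark.parametrize("n", [336, 240, 241])
    def test_parseval_total_power_is_n_times_variance(self, n):
        rng = np.random.default_rng(n)
        x = rng.poisson(6, n).astype(float)
        _, power, _ = power_spectrum(x)
        assert power.sum() == pytest.approx(n * x.var(), rel=1e-10)

    def test_missing_values_rejected(self):
        x = np.ones(336)
        x[5] = np.nan
        with pytest.raises(ContractViolation):
            power_spectrum(x)


class TestBandFeatures:
    def test_pure_circadian_tone_lands_in_mf(self):
        h = np.arange(336)
        feats = band_features(*power_spectrum(np.cos(2 * np.pi * h / 24))[:2])
        assert feats["MF_pct"] == pytest.approx(1.0, abs=1e-9)
        assert feats["LF_pct"] == pytest.approx(0.0, abs=1e-9)
        assert feats["HF_pct"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        feats = band_features(*power_spectrum(rng.poisson(5, 264).astype(float))[:2])
        total = feats["LF_pct"] + feats["MF_pct"] + feats["HF_pct"]
        assert total == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= feats[f"{b}_se"] <= 1 for b in ("LF", "MF", "HF"))

    def test_flat_band_power_has_maximal_entropy(self):
        freqs = np.linspace(0.05, 12.0, 200)
        feats = band_features(freqs, np.full(200, 2.5))
        for b in ("LF", "MF", "HF"):
            assert feats[f"{b}_se"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_power_flags_ratios(self):
        freqs, power, _ = power_spectrum(np.full(336, 3.0))
        feats = band_features(freqs, power)
        assert np.isnan(feats["LF_pct"]) and np.isnan(feats["MF_se"])
        assert feats["MF_sum"] == 0.0


class TestExtractFeatures:
    def test_forty_nine_named_features(self, small_intervals):
        intervals, _ = small_intervals
        feats = extract_features(intervals[0].sequence)
        assert tuple(feats) == FEATURE_NAMES
        assert len(feats) == 49
        assert len(SECOND_ORDER_NAMES) == 16
        assert len(MSE_NAMES) == 24
        assert len(FD_NAMES) == 9

    def test_constant_interval_degenerates_cleanly(self):
        feats = extract_features(np.full(336, 4.0))
        assert all(feats[f"MSE_{t}"] == 0.0 for t in range(1, 25))
        assert all(feats[n] == 0.0 for n in SECOND_ORDER_NAMES if n.startswith("Std_"))
        assert np.isnan(feats["LF_pct"]) and np.isnan(feats["HF_se"])

    def test_bit_stable_across_runs(self, small_intervals):
        intervals, _ = small_intervals
        a = extract_features(intervals[0].sequence)
        b = extract_features(intervals[0].sequence)
        assert a == b

    @pytest.mark.parametrize("c", [3.0, 0.25])
    def test_scaling_invariances(self, c):
        rng = np.random.default_rng(42)
        x = rng.poisson(5, 336).astype(float)
        base, scaled = extract_features(x), extract_features(c * x)
        for t in range(1, 25):
            assert scaled[f"MSE_{t}"] == pytest.approx(base[f"MSE_{t}"], abs=1e-9)
        for b in ("LF", "MF", "HF"):
            assert scaled[f"{b}_pct"] == pytest.approx(base[f"{b}_pct"], abs=1e-9)
            assert scaled[f"{b}_se"] == pytest.approx(base[f"{b}_se"], abs=1e-9)
            assert scaled[f"{b}_sum"] == pytest.approx(c**2 * base[f"{b}_sum"], rel=1e-9)

    def test_shift_invariances(self):
        rng = np.random.default_rng(43)
        x = rng.poisson(5, 336).astype(float)
        base, shifted = extract_features(x), extract_features(x + 11.0)
        for t in range(1, 25):
            assert shifted[f"MSE_{t}"] == pytest.approx(base[f"MSE_{t}"], abs=1e-9)
        for n in SECOND_ORDER_NAMES:
            if n.startswith("Std_") or n.endswith("_Std"):
                assert shifted[n] == pytest.approx(base[n], abs=1e-9)
        for b in ("LF", "MF", "HF"):
            assert shifted[f"{b}_sum"] == pytest.approx(base[f"{b}_sum"], rel=1e-9)


def test_circadian_coupling_depresses_mf_power():
    """Severity lowers circadian amplitude, so MF power falls with severity."""
    from scipy.stats import spearmanr

    from nbdc.preprocess import build_intervals
    from nbdc.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_participants=200, followup_days=42, seed=77)
    scans, phq8, demo = generate_cohort(cfg)
    intervals, _ = build_intervals(scans, phq8, demo)
    mf, sev = [], []
    for iv in intervals:
        freqs, power, _ = power_spectrum(iv.sequence)
        mf.append(band_features(freqs, power)["MF_sum"])
        sev.append(iv.phq8_score)
    rho, p = spearmanr(mf, sev)
    assert rho < 0 and p < 0.01
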